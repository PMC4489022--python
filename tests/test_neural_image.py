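"""Neural-image construction and the population-vector readouts:
mass conservation, corrections, tie-breaking, and the sparse-code
failure regime versus the classical moving hill."""

import numpy as np
import pytest

from retinotrack.decoding import LinearDecoder
from retinotrack.neural_image import (
    build_image,
    decode_peak,
    decode_weighted_mean,
    normalize_occupancy,
    augment_temporal,
    sparse_estimate_cc,
)
from retinotrack.retina import CellModel, SpikeTrainSet, encode, rate_trace
from retinotrack.trajectory import BarGeometry, Trajectory

BIN = 1.0 / 60.0
GRID = np.arange(-500.0, 501.0, 10.0)


def _one_spike_set(pos_cell=0.0, t=1.0, duration=2.0):
    return SpikeTrainSet(duration=duration, cells=[np.array([t])], ids=[0])


class TestBuildImage:
    def test_single_spike_smoothed_bump(self):
        img = build_image(_one_spike_set(), np.array([120.0]), GRID)
        bins, est = decode_peak(img)
        assert bins.size == 1
        assert est[0] == pytest.approx(120.0, abs=img.pitch / 2)
        col = img.A[:, bins[0]]
        assert col.sum() == pytest.approx(1.0, abs=1e-6)  # mass-preserving

    def test_mass_conservation_recount(self, medium_run):
        """Total smoothed mass per bin equals the spike recount (away
        from grid edges where the kernel clips)."""
        spikes, cells = medium_run["spikes"], medium_run["cells"]
        pos = np.array([c.center for c in cells])
        grid = np.arange(pos.min() - 150, pos.max() + 151, 10.0)
        img = build_image(spikes, pos, grid)
        recount = np.zeros(img.n_time)
        for t in spikes.cells:
            recount += np.histogram(
                t, bins=np.arange(img.n_time + 1) * img.time_bin)[0]
        assert np.array_equal(img.counts, recount)
        assert np.abs(img.A.sum(axis=0) - recount).max() < 1e-6 * max(
            1, recount.max())

    def test_zero_smoothing_raw_histogram(self):
        img = build_image(_one_spike_set(), np.array([0.0]), GRID,
                          smooth_sd=0.0)
        assert img.A.max() == 1.0
        assert (img.A > 0).sum() == 1

    def test_outside_grid_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            img = build_image(_one_spike_set(), np.array([1e4]), GRID)
        bins, est = decode_peak(img)
        assert est[0] == GRID[-1]

    def test_translation_equivariance(self, small_run):
        spikes = small_run["spikes"]
        pos = np.array([c.center for c in small_run["cells"]])
        delta = 50.0
        a = decode_peak(build_image(spikes, pos, GRID))[1]
        b = decode_peak(build_image(spikes, pos + delta, GRID + delta))[1]
        assert np.allclose(b - a, delta)


class TestReadouts:
    def test_single_active_cell_constant_estimate(self):
        rngt = np.sort(np.random.default_rng(0).uniform(0, 10.0, 40))
        spikes = SpikeTrainSet(duration=10.0, cells=[rngt], ids=[0])
        img = build_image(spikes, np.array([-70.0]), GRID)
        _, est_p = decode_peak(img)
        _, est_w = decode_weighted_mean(img)
        assert np.allclose(est_p, -70.0, atol=img.pitch)
        assert np.allclose(est_w, -70.0, atol=img.pitch)

    def test_weighted_mean_symmetry(self):
        spikes = SpikeTrainSet(duration=1.0,
                               cells=[np.array([0.5]), np.array([0.5])],
                               ids=[0, 1])
        img = build_image(spikes, np.array([-60.0, 60.0]), GRID)
        _, est = decode_weighted_mean(img)
        assert est[0] == pytest.approx(0.0, abs=1e-9)

    def test_peak_tie_breaks_leftmost(self):
        spikes = SpikeTrainSet(duration=1.0,
                               cells=[np.array([0.5]), np.array([0.5])],
                               ids=[0, 1])
        img = build_image(spikes, np.array([-60.0, 60.0]), GRID,
                          smooth_sd=0.0)
        _, est = decode_peak(img)
        assert est[0] == -60.0


class TestOccupancyNormalization:
    def test_rows_sum_to_one(self, small_run):
        pos = np.array([c.center for c in small_run["cells"]])
        img = normalize_occupancy(build_image(small_run["spikes"], pos, GRID))
        sums = img.A.sum(axis=1)
        assert np.allclose(sums[img.mask], 1.0)
        assert np.all(sums[~img.mask] == 0.0)

    def test_uniform_population_uniform_rows(self, rng):
        cells = [np.sort(rng.uniform(0, 50.0, 500)) for _ in range(3)]
        spikes = SpikeTrainSet(duration=50.0, cells=cells, ids=[0, 1, 2])
        img = normalize_occupancy(
            build_image(spikes, np.array([-100.0, 0.0, 100.0]), GRID,
                        smooth_sd=0.0))
        totals = img.A.sum(axis=1)
        assert np.allclose(totals[img.mask], 1.0)

    def test_sampling_bias_correction_improves_peak(self, rng):
        """Cells on one side firing far more (a sampling bias) drag the
        raw peak toward them; dividing each position by its total spike
        count removes the bias and improves the peak decode."""
        duration = 240.0
        x = 300.0 * np.sin(2 * np.pi * 0.15
                           * np.arange(int(duration / BIN)) * BIN)
        truth = Trajectory(t0=0.0, dt=BIN, x=x)
        centers = np.arange(-400.0, 401.0, 40.0)
        cells_t = []
        for c in centers:
            gain = 20.0 if c >= 0 else 1.0
            rate = gain * (2.0 + 25.0 * np.exp(-0.5 * ((x - c) / 60.0) ** 2))
            counts = rng.poisson(rate * BIN)
            t = (np.repeat(np.arange(truth.n), counts)
                 + rng.random(counts.sum())) * BIN
            cells_t.append(np.sort(t))
        spikes = SpikeTrainSet(duration=duration, cells=cells_t,
                               ids=list(range(centers.size)))
        grid = np.arange(-420.0, 421.0, 10.0)
        img = build_image(spikes, centers, grid)
        cc_raw = sparse_estimate_cc(*decode_peak(img), truth.x)
        cc_norm = sparse_estimate_cc(*decode_peak(normalize_occupancy(img)),
                                     truth.x)
        assert cc_norm > cc_raw + 0.1


class TestAugmentTemporal:
    def test_delta_profile_identity(self, small_run):
        pos = np.array([c.center for c in small_run["cells"]])
        spikes = small_run["spikes"]
        a = build_image(spikes, pos, GRID)
        b = augment_temporal(spikes, pos,
                             [np.array([1.0])] * spikes.n_cells, GRID)
        assert np.allclose(a.A, b.A, atol=1e-9)

    def test_profile_length_sets_support(self):
        L = 4
        img = augment_temporal(_one_spike_set(t=1.0), np.array([0.0]),
                               [np.ones(L)], GRID, smooth_sd=0.0)
        row = img.A[np.argmax(img.A.sum(axis=1))]
        assert (row > 0).sum() == L
        tb = int(1.0 / img.time_bin)
        assert np.all(row[tb - L + 1:tb + 1] > 0)  # preceding bins

    def test_profile_shape_validated(self):
        with pytest.raises(ValueError, match="1-D"):
            augment_temporal(_one_spike_set(), np.array([0.0]),
                             [np.ones((2, 2))], GRID)


def _moving_hill(rng, duration=240.0):
    """Classical regime: dense tonic cells firing when the bar is in
    their center."""
    x = 300.0 * np.sin(2 * np.pi * 0.15 * np.arange(int(duration / BIN)) * BIN)
    truth = Trajectory(t0=0.0, dt=BIN, x=x)
    centers = np.arange(-400.0, 401.0, 40.0)
    cells_t = []
    for c in centers:
        rate = 25.0 * np.exp(-0.5 * ((x - c) / 60.0) ** 2)
        counts = rng.poisson(rate * BIN)
        t = (np.repeat(np.arange(truth.n), counts) + rng.random(counts.sum())) * BIN
        cells_t.append(np.sort(t))
    spikes = SpikeTrainSet(duration=duration, cells=cells_t,
                           ids=list(range(centers.size)))
    return truth, spikes, centers


class TestRegimeContrast:
    def test_moving_hill_peak_decode_works(self, rng):
        truth, spikes, pos = _moving_hill(rng)
        grid = np.arange(-420.0, 421.0, 10.0)
        img = build_image(spikes, pos, grid)
        cc = sparse_estimate_cc(*decode_peak(img), truth.x)
        assert cc > 0.8

    def test_sparse_code_image_far_below_linear(self, medium_run, medium_fit):
        """The central contrast: on sparse event-like activity the
        neural image fails while the linear decoder succeeds."""
        spikes, cells, traj = (medium_run["spikes"], medium_run["cells"],
                               medium_run["traj"])
        pos = np.array([c.center for c in cells])
        grid = np.arange(pos.min() - 100, pos.max() + 101, 10.0)
        img = build_image(spikes, pos, grid)
        cc_img = sparse_estimate_cc(*decode_peak(img), traj.x)
        assert cc_img < medium_fit.cc_test - 0.4

    def test_corrections_improve_sparse_peak(self, medium_run, medium_fit):
        """Occupancy + temporal-profile corrections raise the image CC,
        which stays far below the linear decoder:
        CC_raw < CC_corrected < CC_linear."""
        spikes, cells, traj = (medium_run["spikes"], medium_run["cells"],
                               medium_run["traj"])
        pos = np.array([c.center for c in cells])
        grid = np.arange(pos.min() - 100, pos.max() + 101, 10.0)
        cc_raw = sparse_estimate_cc(
            *decode_peak(build_image(spikes, pos, grid)), traj.x)
        profs = [c.temporal_kernel for c in cells]
        both = normalize_occupancy(
            augment_temporal(spikes, pos, profs, grid))
        cc_corr = sparse_estimate_cc(*decode_peak(both), traj.x)
        assert cc_raw < cc_corr < medium_fit.cc_test

    def test_weighted_mean_collapses_with_spread_activity(self, rng):
        """Position-independent background firing across the array
        drowns the rate-weighted mean (it collapses toward the array
        center), while the winner-take-all peak still locks onto the
        sparse informative cells."""
        duration = 240.0
        x = 300.0 * np.sin(2 * np.pi * 0.15
                           * np.arange(int(duration / BIN)) * BIN)
        truth = Trajectory(t0=0.0, dt=BIN, x=x)
        bg_centers = np.arange(-400.0, 401.0, 40.0)
        info_centers = np.linspace(-250.0, 250.0, 9)
        centers = np.concatenate([bg_centers, info_centers])
        rates = [np.full(truth.n, 8.0) for _ in bg_centers]
        rates += [200.0 * (np.abs(x - c) < 40.0) for c in info_centers]
        cells_t = []
        for rate in rates:
            counts = rng.poisson(rate * BIN)
            t = (np.repeat(np.arange(truth.n), counts)
                 + rng.random(counts.sum())) * BIN
            cells_t.append(np.sort(t))
        spikes = SpikeTrainSet(duration=duration, cells=cells_t,
                               ids=list(range(centers.size)))
        grid = np.arange(-420.0, 421.0, 10.0)
        img = build_image(spikes, centers, grid)
        cc_peak = sparse_estimate_cc(*decode_peak(img), truth.x)
        bins, est = decode_weighted_mean(img)
        cc_wm = sparse_estimate_cc(bins, est, truth.x)
        assert cc_wm < cc_peak
        assert np.std(est) < 0.8 * np.std(truth.x)  # collapsed range
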