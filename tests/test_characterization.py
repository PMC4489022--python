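"""Receptive-field mapping, typing, normalized distance, per-cell
decoding vs distance, spike-triggered speed, and group comparisons."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinotrack.characterization import (
    ReceptiveField,
    TypingThresholds,
    checkerboard_stimulus,
    classify_functional_type,
    compare_groups,
    decoding_vs_distance,
    expected_type,
    normalized_distance,
    retinal_magnification,
    spike_triggered_speed,
    sta_receptive_field,
)
from retinotrack.retina import (
    PopulationConfig,
    encode_movie,
    make_population,
    make_temporal_kernel,
)
from retinotrack.trajectory import BarGeometry, Trajectory

BIN = 1.0 / 60.0


@pytest.fixture(scope="module")
def mapped_population():
    """30 cells mapped with a 5-minute flickering checkerboard."""
    frames, grid, dt = checkerboard_stimulus(300.0, span=1500.0, seed=3)
    cells = make_population(PopulationConfig(
        n_cells=30, seed=9,
        type_mix={"biphasic_off": 0.25, "monophasic_off": 0.2,
                  "medium_off": 0.2, "slow_off": 0.15, "on": 0.2}))
    spikes = encode_movie(cells, frames, grid, dt, seed=4,
                          threshold_scale=0.2)
    rfs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(len(cells)):
            rfs.append(sta_receptive_field(spikes.cells[k], frames, grid, dt))
    return cells, rfs


class TestSTA:
    def test_center_recovery_within_one_square(self, mapped_population):
        cells, rfs = mapped_population
        errs = [abs(rf.center_1d - c.center) for c, rf in zip(cells, rfs)]
        assert np.median(errs) < 69.0  # one checkerboard square

    def test_polarity_recovery(self, mapped_population):
        cells, rfs = mapped_population
        ok = sum(rf.polarity == c.polarity for c, rf in zip(cells, rfs))
        assert ok >= 0.9 * len(cells)

    def test_width_recovery(self, mapped_population):
        cells, rfs = mapped_population
        ratios = [rf.width_1d / c.center_sd for c, rf in zip(cells, rfs)
                  if rf.n_spikes > 200]
        assert 0.6 < np.median(ratios) < 1.6

    def test_stimulus_independent_spikes_flat_sta(self, rng):
        frames, grid, dt = checkerboard_stimulus(200.0, span=690.0, seed=1)
        spikes = np.sort(rng.uniform(1.0, 199.0, 600))
        rf = sta_receptive_field(spikes, frames, grid, dt)
        # STA of unrelated spikes: noise at scale 1/sqrt(n)
        assert np.abs(rf.spatial * rf.temporal[:, None].max()).max() < 0.5

    def test_few_spikes_low_confidence(self, rng):
        frames, grid, dt = checkerboard_stimulus(60.0, span=690.0, seed=1)
        with pytest.warns(UserWarning, match="low-confidence"):
            rf = sta_receptive_field(np.array([10.0, 20.0, 30.0]),
                                     frames, grid, dt)
        assert rf.low_confidence


class TestTyping:
    def test_confusion_against_generator_truth(self, mapped_population):
        """>= 90% of cells map to their generator type under
        temporal-dynamics typing."""
        cells, rfs = mapped_population
        ok = sum(classify_functional_type(rf) == expected_type(c.label)
                 for c, rf in zip(cells, rfs))
        assert ok >= 0.9 * len(cells)

    def test_pure_monophasic_kernel(self):
        kern = make_temporal_kernel(0.09, 0.0)
        rf = ReceptiveField(spatial=np.array([1.0]), temporal=-kern,
                            grid=np.array([0.0]), dt=BIN, polarity="off")
        assert classify_functional_type(rf) == "monophasic_off"

    def test_slow_kernel(self):
        kern = make_temporal_kernel(0.24, 0.2)
        rf = ReceptiveField(spatial=np.array([1.0]), temporal=-kern,
                            grid=np.array([0.0]), dt=BIN, polarity="off")
        assert classify_functional_type(rf) == "slow_off"

    def test_degenerate_kernel_unclassified(self):
        rf = ReceptiveField(spatial=np.array([1.0]), temporal=np.zeros(5),
                            grid=np.array([0.0]), dt=BIN, polarity="off")
        assert classify_functional_type(rf) == "unclassified"

    def test_threshold_object_validation(self):
        th = TypingThresholds(lobe_ratio=0.3)
        assert th.lobe_ratio == 0.3


def _gaussian_rf(sd, grid=None):
    grid = np.arange(-600.0, 601.0, 5.0) if grid is None else grid
    return ReceptiveField(spatial=np.exp(-0.5 * (grid / sd) ** 2),
                          temporal=np.array([1.0]), grid=grid,
                          polarity="off", width_1d=sd)


class TestNormalizedDistance:
    def test_worked_example(self):
        """Bar-convolved width 115 um, 3-sigma excursion of 219 um:
        d = 219/115 ~ 1.9."""
        sd_rf = np.sqrt(115.0**2 - 100.0**2 / 12.0)
        nd = normalized_distance(_gaussian_rf(sd_rf), BarGeometry(),
                                 bar_mean=219.0)
        assert nd.s_i == pytest.approx(115.0, rel=0.01)
        assert nd.d == pytest.approx(219.0 / 115.0, rel=0.01)

    def test_zero_at_bar_mean(self):
        nd = normalized_distance(_gaussian_rf(100.0), BarGeometry(), 0.0)
        assert nd.d == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_profile_mean_preserved(self):
        nd = normalized_distance(_gaussian_rf(80.0), BarGeometry(), 50.0)
        assert nd.m_i == pytest.approx(0.0, abs=1e-9)

    def test_blur_invariance(self):
        """A common optical blur applied to the receptive-field
        estimate changes d only marginally (the centers are exact and
        the width grows in quadrature)."""
        from scipy.ndimage import gaussian_filter1d

        sd_rf = np.sqrt(115.0**2 - 100.0**2 / 12.0)
        rf = _gaussian_rf(sd_rf)
        d0 = normalized_distance(rf, BarGeometry(), 219.0).d
        blurred = ReceptiveField(
            spatial=gaussian_filter1d(rf.spatial, 15.0 / 5.0),
            temporal=rf.temporal, grid=rf.grid, polarity="off",
            width_1d=rf.width_1d)
        d1 = normalized_distance(blurred, BarGeometry(), 219.0).d
        assert d1 == pytest.approx(d0, rel=0.05)

    def test_degenerate_profile_rejected(self):
        rf = ReceptiveField(spatial=np.zeros(241),
                            temporal=np.array([1.0]),
                            grid=np.arange(-600.0, 601.0, 5.0),
                            polarity="off")
        with pytest.raises(ValueError, match="zero-mass"):
            normalized_distance(rf, BarGeometry(), 0.0)


class TestDecodingVsDistance:
    def test_negative_slope_and_center_dominance(self, medium_run):
        m = medium_run["model"]
        centers = np.array([c.center for c in medium_run["cells"]])
        per_cell, binned, slope = decoding_vs_distance(m, centers)
        assert slope < 0  # CC falls with distance
        # the best solo decoders sit close to the bar mean
        top = per_cell.nlargest(5, "cc")
        assert top.distance.median() < per_cell.distance.median()

    def test_some_far_cells_still_decode(self, medium_run):
        """Surround coding: cells far beyond their receptive-field
        radius from the bar mean retain solo decoding power."""
        m = medium_run["model"]
        centers = np.array([c.center for c in medium_run["cells"]])
        per_cell, _, _ = decoding_vs_distance(m, centers)
        far = per_cell[per_cell.distance > 400.0]
        assert (far.cc > 0.1).any()

    def test_silent_cell_reported_zero(self, medium_run):
        from retinotrack.decoding import LinearDecoder
        from retinotrack.retina import SpikeTrainSet

        base = medium_run["spikes"]
        spikes = SpikeTrainSet(
            duration=base.duration,
            cells=[base.cells[0], np.array([])],
            ids=[0, 1])
        model = LinearDecoder(spikes, medium_run["traj"])
        per_cell, _, _ = decoding_vs_distance(model, np.array([0.0, 100.0]))
        assert per_cell.loc[per_cell.cell_id == 1, "cc"].iloc[0] == 0.0


class TestSpikeTriggeredSpeed:
    def test_constant_speed_trajectory(self):
        traj = Trajectory(t0=0.0, dt=BIN, x=120.0 * np.arange(600) * BIN)
        sts = spike_triggered_speed(np.array([5.0, 7.0, 9.0]), traj)
        assert np.allclose(sts.mean_speed, 120.0, rtol=1e-6)
        assert sts.baseline == pytest.approx(120.0, rel=1e-6)

    def test_random_spikes_flat_at_baseline(self, medium_run, rng):
        traj = medium_run["traj"]
        spikes = np.sort(rng.uniform(2.0, traj.duration - 1.0, 4000))
        sts = spike_triggered_speed(spikes, traj)
        assert np.abs(sts.mean_speed / sts.baseline - 1).max() < 0.1

    def test_pre_spike_speed_elevated_for_transient_cell(self, medium_run):
        """The encoder fires on drive transients, i.e. after brief
        accelerations: the spike-triggered speed in the ~200 ms before
        a spike exceeds the overall mean speed."""
        cells, spikes = medium_run["cells"], medium_run["spikes"]
        rates = spikes.rates()
        k = int(np.argmax([r if cells[i].label == "biphasic_off" else 0
                           for i, r in enumerate(rates)]))
        sts = spike_triggered_speed(spikes.cells[k], medium_run["traj"])
        band = sts.mean_speed[sts.lags <= 0.2]
        assert band.mean() > 1.05 * sts.baseline

    def test_no_spikes_rejected(self, medium_run):
        with pytest.raises(ValueError, match="no spikes"):
            spike_triggered_speed(np.array([]), medium_run["traj"])


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        u, p = compare_groups(a, a.copy())
        assert p > 0.99

    def test_disjoint_support_exact_p(self):
        """Size-5 groups with disjoint support: the minimal exact
        two-sided p is 2/choose(10,5) = 2/252."""
        a = np.arange(5, dtype=float)
        b = a + 100.0
        _, p = compare_groups(a, b)
        assert p == pytest.approx(2.0 / 252.0, rel=1e-9)

    @given(shift=st.floats(min_value=0.1, max_value=100.0),
           scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_invariance_under_monotone_transform(self, shift, scale):
        a = np.array([1.0, 5.0, 2.5, 7.0])
        b = np.array([2.0, 6.0, 9.0, 4.0])
        _, p0 = compare_groups(a, b)
        _, p1 = compare_groups(scale * a + shift, scale * b + shift)
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0, 4.0])


class TestMagnification:
    def test_salamander_eye_scale(self):
        """2 mm focal length maps ~35 um per degree of visual angle."""
        assert retinal_magnification(2.0) == pytest.approx(35.0, abs=0.5)

    def test_scales_linearly_with_focal_length(self):
        assert retinal_magnification(4.0) == pytest.approx(
            2 * retinal_magnification(2.0))
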