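"""Optimal linear decoding of bar position from population spike trains.

The decoder reconstructs the trajectory as

    p(t) = sum_{i,j} K_i(t - t_ij) + C

where ``t_ij`` is the j-th spike of cell i: each spike adds the cell's
temporal filter to the ongoing reconstruction.  Filters extend 500 ms
before and after the spike (or are restricted to the causal half) and
are fitted by least squares on the first 2/3 of the recording; test
performance is the normalized cross-correlation (CC) between predicted
and true trajectories on the held-out last 1/3, clamped below at 0.

:class:`LinearDecoder` is the model object; its :meth:`~LinearDecoder.fit`
returns a :class:`LinearDecoderResults` carrying filters, performance
and diagnostics.  Because the Gram matrix of the full lagged design is
cached, refitting on arbitrary cell subsets (subset curves, solo-cell
decoders, greedy subset searches) only requires slicing and a small
solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from retinotrack.retina import SpikeTrainSet
from retinotrack.trajectory import Trajectory

__all__ = [
    "LagGrid",
    "DecoderFilters",
    "DecodeResult",
    "LinearDecoder",
    "LinearDecoderResults",
    "build_design",
    "fit_ols",
    "predict",
    "evaluate",
    "subset_curve",
    "normalized_cc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LagGrid:
    """Temporal lag grid of the decoding filters.

    ``bin`` is the decoding bin (default one stimulus frame, 1/60 s);
    filters span ``[lag_min, lag_max]`` around each spike.  With
    ``causal=True`` the grid is restricted to ``[lag_min, 0]``: the
    filter of a spike only extends backward in time, i.e. only the
    stimulus preceding the spike is reconstructed from it.
    """

    bin: float = 1.0 / 60.0
    lag_min: float = -0.5
    lag_max: float = 0.5
    causal: bool = False

    def __post_init__(self) -> None:
        if not (self.lag_min <= 0 <= self.lag_max):
            raise ValueError("require lag_min <= 0 <= lag_max")
        for lag in (self.lag_min, self.lag_max):
            if abs(round(lag / self.bin) - lag / self.bin) > 1e-6:
                raise ValueError("lag bounds must be integer multiples of bin")

    @property
    def lags_bins(self) -> np.ndarray:
        """Integer lags in bins; kernel argument u = lag * bin."""
        lo = int(round(self.lag_min / self.bin))
        hi = 0 if self.causal else int(round(self.lag_max / self.bin))
        return np.arange(lo, hi + 1)

    @property
    def lags(self) -> np.ndarray:
        return self.lags_bins * self.bin

    @property
    def n_lags(self) -> int:
        return self.lags_bins.size


@dataclass
class DecoderFilters:
    """Fitted per-cell temporal kernels K_i (um per spike) plus constant C."""

    filters: dict[int, np.ndarray]
    constant: float
    grid: LagGrid

    def __post_init__(self) -> None:
        for cid, k in self.filters.items():
            k = np.asarray(k, dtype=float)
            if k.shape != (self.grid.n_lags,) or not np.all(np.isfinite(k)):
                raise ValueError(f"bad kernel for cell {cid}")
            self.filters[cid] = k
        if not np.isfinite(self.constant):
            raise ValueError("constant must be finite")

    def norms(self, ord: int = 1) -> pd.Series:
        return pd.Series(
            {cid: np.linalg.norm(k, ord=ord) for cid, k in self.filters.items()},
            name=f"l{ord}_norm",
        )


@dataclass
class DecodeResult:
    """Train/test decoding performance of one prediction."""

    prediction: Trajectory
    cc_train: float
    cc_test: float
    cc_test_raw: float
    mse_test: float
    split: str = "first-2/3-train"


def normalized_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag normalized cross-correlation
    <(x - m_x)(y - m_y)> / (sigma_x sigma_y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance signal in CC computation")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

def build_design(
    spikes: SpikeTrainSet,
    grid: LagGrid,
    duration: float | None = None,
) -> tuple[sparse.csr_matrix, np.ndarray, int]:
    """Lagged spike-count design matrix with intercept column.

    Returns ``(X, rows, n_bins)``: ``X`` has one row per *valid* time
    bin (bins whose full lag window lies inside the recording; edge
    bins are dropped, not zero-padded) and one column block per cell,
    one column per lag, plus a final intercept column of ones.  The
    entry for (bin t, cell i, lag u) is the spike count of cell i in
    bin ``t - u``, so the fitted coefficient of lag u is the kernel
    value K_i(u * bin).  ``rows`` gives the absolute bin index of each
    design row.
    """
    if spikes.total_spikes == 0:
        raise ValueError("empty spike set")
    duration = spikes.duration if duration is None else duration
    n_bins = int(round(duration / grid.bin))
    lags = grid.lags_bins
    row_lo = int(max(lags.max(), 0))
    row_hi = n_bins - 1 + int(min(lags.min(), 0))  # inclusive
    if row_hi < row_lo:
        raise ValueError("recording shorter than the lag window")
    rows = np.arange(row_lo, row_hi + 1)
    n_rows = rows.size
    n_lags = lags.size

    edges = np.arange(n_bins + 1) * grid.bin
    parts = []
    for i, times in enumerate(spikes.cells):
        counts, _ = np.histogram(times, bins=edges)
        nz = np.flatnonzero(counts)
        if nz.size == 0:
            continue
        v = counts[nz].astype(float)
        r = nz[:, None] + lags[None, :]            # absolute row index
        c = np.broadcast_to(np.arange(n_lags) + i * n_lags, r.shape)
        d = np.broadcast_to(v[:, None], r.shape)
        ok = (r >= row_lo) & (r <= row_hi)
        parts.append((r[ok] - row_lo, c[ok], d[ok]))
    r = np.concatenate([p[0] for p in parts])
    c = np.concatenate([p[1] for p in parts])
    d = np.concatenate([p[2] for p in parts])
    # intercept column
    icol = spikes.n_cells * n_lags
    r = np.concatenate([r, np.arange(n_rows)])
    c = np.concatenate([c, np.full(n_rows, icol)])
    d = np.concatenate([d, np.ones(n_rows)])
    X = sparse.coo_matrix((d, (r, c)), shape=(n_rows, icol + 1)).tocsr()
    return X, rows, n_bins


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class LinearDecoder:
    """Linear trajectory decoder fitted to a spike-train recording.

    Parameters
    ----------
    spikes : SpikeTrainSet
        The population recording (decoder input).
    trajectory : Trajectory
        The true bar trajectory (decoder target); resampled onto the
        decoding bin grid if needed.
    grid : LagGrid, optional
        Lag grid of the filters.
    train_frac : float
        Leading fraction of the recording used for fitting (contiguous
        split; the remainder is the test segment).
    """

    def __init__(
        self,
        spikes: SpikeTrainSet,
        trajectory: Trajectory,
        grid: LagGrid | None = None,
        train_frac: float = 2.0 / 3.0,
    ) -> None:
        self.spikes = spikes
        self.grid = grid if grid is not None else LagGrid()
        self.train_frac = float(train_frac)
        if not 0 < self.train_frac <= 1:
            raise ValueError("train_frac must lie in (0, 1]")
        if abs(trajectory.dt - self.grid.bin) > 1e-9:
            trajectory = trajectory.resample(self.grid.bin)
        self.trajectory = trajectory

        X, rows, n_bins = build_design(spikes, self.grid, spikes.duration)
        n_bins = min(n_bins, trajectory.n)
        keep = rows < n_bins
        self._X = X[keep]
        self._rows = rows[keep]
        self._y = trajectory.x[self._rows]
        split_bin = int(round(self.train_frac * n_bins))
        self._is_train = self._rows < split_bin
        self._G: np.ndarray | None = None
        self._Xty: np.ndarray | None = None

    # -- cached train-segment Gram matrix ---------------------------------
    def _normal_eqs(self) -> tuple[np.ndarray, np.ndarray]:
        if self._G is None:
            Xtr = self._X[self._is_train]
            self._G = np.asarray((Xtr.T @ Xtr).todense())
            self._Xty = Xtr.T @ self._y[self._is_train]
        return self._G, self._Xty

    def _col_indices(self, cell_ids: list[int]) -> np.ndarray:
        nl = self.grid.n_lags
        pos = {cid: k for k, cid in enumerate(self.spikes.ids)}
        blocks = [np.arange(nl) + pos[cid] * nl for cid in cell_ids]
        blocks.append(np.array([self.spikes.n_cells * nl]))  # intercept
        return np.concatenate(blocks)

    @property
    def n_cells(self) -> int:
        return self.spikes.n_cells

    def fit(
        self,
        cells: list[int] | None = None,
        ridge: float = 0.0,
    ) -> "LinearDecoderResults":
        """Ordinary-least-squares fit, optionally on a cell subset.

        ``ridge`` adds ``ridge * mean(diag(G))`` to the Gram diagonal
        for conditioning only (logged); the default contract is pure
        OLS, with a minimum-norm pseudoinverse fallback on
        rank-deficient designs.
        """
        cell_ids = list(self.spikes.ids) if cells is None else list(cells)
        idx = self._col_indices(cell_ids)
        G, Xty = self._normal_eqs()
        A = G[np.ix_(idx, idx)].copy()
        b = Xty[idx]
        if ridge > 0:
            lam = ridge * float(np.mean(np.diag(A)))
            A[np.diag_indices_from(A)] += lam
            log.info("ridge conditioning added: %.3e", lam)
        try:
            coef = linalg.solve(A, b, assume_a="pos")
            if not np.all(np.isfinite(coef)):
                raise linalg.LinAlgError("non-finite solution")
        except linalg.LinAlgError:
            log.warning("rank-deficient design; minimum-norm solution used")
            coef = linalg.lstsq(A, b, cond=None)[0]
        return LinearDecoderResults(self, cell_ids, idx, coef)

    def fit_l1(self, lam: float, **kwargs):
        """L1-regularised fit; see :func:`retinotrack.regularized.fit_l1`."""
        from retinotrack.regularized import fit_l1_model

        return fit_l1_model(self, lam, **kwargs)


class LinearDecoderResults:
    """Fitted linear decoder: filters, performance and diagnostics."""

    def __init__(self, model: LinearDecoder, cell_ids, col_idx, coef) -> None:
        self.model = model
        self.cell_ids = list(cell_ids)
        self._col_idx = col_idx
        self.coef = np.asarray(coef, float)
        nl = model.grid.n_lags
        self.constant = float(self.coef[-1])
        self.filters = DecoderFilters(
            filters={cid: self.coef[k * nl:(k + 1) * nl]
                     for k, cid in enumerate(self.cell_ids)},
            constant=self.constant,
            grid=model.grid,
        )
        X = model._X[:, col_idx]
        self._pred = np.asarray(X @ self.coef)
        tr, te = model._is_train, ~model._is_train
        y = model._y

        def _cc(p, t):
            # a constant prediction carries no signal: CC 0, like the
            # negative-CC clamp for useless decoders
            if np.std(p) == 0:
                log.info("constant prediction; CC reported as 0")
                return 0.0
            return normalized_cc(p, t)

        self.cc_train = _cc(self._pred[tr], y[tr])
        if te.any():
            self.cc_test_raw = _cc(self._pred[te], y[te])
            self.mse_test = float(np.mean((self._pred[te] - y[te]) ** 2))
        else:
            self.cc_test_raw = np.nan
            self.mse_test = np.nan
        self.cc_test = self._clamp(self.cc_test_raw)
        self.mse_train = float(np.mean((self._pred[tr] - y[tr]) ** 2))

    @staticmethod
    def _clamp(cc: float) -> float:
        if np.isnan(cc):
            return cc
        if cc < 0:
            log.info("negative test CC %.3f clamped to 0", cc)
            return 0.0
        return float(cc)

    # -- accessors --------------------------------------------------------
    @property
    def prediction(self) -> Trajectory:
        """Predicted trajectory p(t) on the valid-bin grid."""
        m = self.model
        return Trajectory(t0=m._rows[0] * m.grid.bin, dt=m.grid.bin, x=self._pred)

    @property
    def resid(self) -> np.ndarray:
        return self._pred - self.model._y

    @property
    def error(self) -> np.ndarray:
        """Decoding error e(t) = p(t) - x(t) on the valid-bin grid (um)."""
        return self.resid

    def as_decode_result(self) -> DecodeResult:
        return DecodeResult(
            prediction=self.prediction,
            cc_train=self.cc_train,
            cc_test=self.cc_test,
            cc_test_raw=self.cc_test_raw,
            mse_test=self.mse_test,
        )

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured)."""
        m = self.model
        lines = [
            "Linear trajectory decoder",
            "=" * 46,
            f"cells:               {len(self.cell_ids)} / {m.n_cells}",
            f"lag grid:            [{m.grid.lags[0]:+.3f}, {m.grid.lags[-1]:+.3f}] s"
            f" @ {m.grid.bin * 1e3:.1f} ms"
            f"{' (causal)' if m.grid.causal else ''}",
            f"train/test bins:     {int(m._is_train.sum())} / {int((~m._is_train).sum())}",
            f"CC train:            {self.cc_train:.4f}",
            f"CC test (clamped):   {self.cc_test:.4f}",
            f"RMSE test:           {np.sqrt(self.mse_test):.2f} um",
            f"constant C:          {self.constant:.2f} um",
            "-" * 46,
        ]
        norms = self.filters.norms(ord=1).sort_values(ascending=False)
        lines.append("top cells by filter L1 norm (um):")
        for cid, v in norms.head(8).items():
            lines.append(f"  cell {cid:>4}   {v:10.1f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# functional wrappers (module surface)
# --------------------------------------------------------------------------

def fit_ols(
    design: sparse.spmatrix,
    target: np.ndarray,
    grid: LagGrid,
    cell_ids: list[int] | None = None,
) -> DecoderFilters:
    """Least-squares decoder filters from a prebuilt design matrix.

    Solves the normal equations; rank-deficient systems fall back to
    the minimum-norm pseudo-solution (logged).
    """
    y = np.asarray(target, float)
    if design.shape[0] != y.size:
        raise ValueError("design rows must align with target samples")
    G = np.asarray((design.T @ design).todense())
    b = design.T @ y
    try:
        coef = linalg.solve(G, b, assume_a="pos")
        if not np.all(np.isfinite(coef)):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        log.warning("rank-deficient design; minimum-norm solution used")
        coef = linalg.lstsq(G, b, cond=None)[0]
    nl = grid.n_lags
    n_cells = (design.shape[1] - 1) // nl
    ids = list(range(n_cells)) if cell_ids is None else list(cell_ids)
    return DecoderFilters(
        filters={cid: coef[k * nl:(k + 1) * nl] for k, cid in enumerate(ids)},
        constant=float(coef[-1]),
        grid=grid,
    )


def predict(
    filters: DecoderFilters,
    spikes: SpikeTrainSet,
    duration: float | None = None,
) -> Trajectory:
    """Direct kernel-summation prediction: each spike adds its cell's
    filter to the reconstruction at the spike time.

    This is an independent code path from the design-matrix product
    (they agree to machine precision on shared bins).
    """
    grid = filters.grid
    duration = spikes.duration if duration is None else duration
    n_bins = int(round(duration / grid.bin))
    lags = grid.lags_bins
    acc = np.full(n_bins, filters.constant)
    index = {cid: k for k, cid in enumerate(spikes.ids)}
    edges = np.arange(n_bins + 1) * grid.bin
    for cid, kernel in filters.filters.items():
        times = spikes.cells[index[cid]]
        counts, _ = np.histogram(times, bins=edges)
        nz = np.flatnonzero(counts)
        for u, ku in zip(lags, kernel):
            t = nz + u
            ok = (t >= 0) & (t < n_bins)
            acc[t[ok]] += ku * counts[nz[ok]]
    return Trajectory(t0=0.0, dt=grid.bin, x=acc)


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray,
    train_frac: float = 2.0 / 3.0,
) -> tuple[float, float, float]:
    """CC on the contiguous train (leading fraction) and test segments.

    Returns ``(cc_train, cc_test_clamped, cc_test_raw)``; negative test
    CC is reported as 0 (an overfitting artefact, logged).
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must be aligned")
    split = int(round(train_frac * pred.size))
    cc_tr = normalized_cc(pred[:split], truth[:split])
    cc_te = normalized_cc(pred[split:], truth[split:])
    clamped = cc_te
    if clamped < 0:
        log.info("negative test CC %.3f clamped to 0", clamped)
        clamped = 0.0
    return cc_tr, clamped, cc_te


def subset_curve(
    model: LinearDecoder,
    sizes: list[int],
    draws_per_size: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Test CC of random cell subsets of the given sizes.

    Each subset is refitted from scratch (via the cached Gram matrix)
    and evaluated on the test segment.  Returns a tidy frame with
    columns ``size, draw, cc_test``; per-size means via groupby.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(model.spikes.ids)
    rows = []
    for size in sizes:
        if size > ids.size:
            raise ValueError(f"subset size {size} exceeds population {ids.size}")
        n_draws = 1 if size == ids.size else draws_per_size
        for d in range(n_draws):
            chosen = list(rng.choice(ids, size=size, replace=False))
            res = model.fit(cells=chosen)
            rows.append(dict(size=size, draw=d, cc_test=res.cc_test))
    return pd.DataFrame(rows)
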