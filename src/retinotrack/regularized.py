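"""L1-regularised decoding: sparse filter selection, regularisation
strength selection, cell ranking, and disjoint high-performance subsets.

The least-squares objective is augmented with an L1 penalty on the
filters,

    <(p(t) - x(t))^2> + lambda * sum_i ||K_i||_1 ,

which drives the kernels of uninformative cells exactly to zero.  The
regularisation strength is deliberately chosen *larger* than the
MSE-optimal value: the largest lambda whose cross-validated performance
is within a 5% CC drop and a 20% MSE rise of the unregularised
decoder, so that as many filters as possible are zeroed while the
prediction stays good.  Cells ranked by the L1 filter amplitude are
then used to find multiple disjoint subsets that each decode the
trajectory above a target CC — the redundancy of the population made
explicit.

The solver is coordinate descent (scikit-learn); any convex solver
meeting the KKT-residual contract is acceptable, and fits are verified
against the KKT conditions after each solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from retinotrack.decoding import (
    DecoderFilters,
    LinearDecoder,
    LinearDecoderResults,
    normalized_cc,
)

__all__ = [
    "L1Config",
    "SubsetDecomposition",
    "fit_l1",
    "fit_l1_model",
    "L1DecoderResults",
    "lambda_max",
    "kkt_residual",
    "select_lambda",
    "rank_and_group",
    "disjoint_subsets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class L1Config:
    """Regularisation-selection settings.

    ``lambda_grid``: candidate strengths (None = 30 log-spaced values
    spanning [lambda_max/1e4, lambda_max]); ``cc_drop_max`` /
    ``mse_rise_max``: allowed fractional CC decrease / MSE increase
    relative to the unregularised decoder; ``folds``: contiguous
    cross-validation folds on the training segment.
    """

    lambda_grid: np.ndarray | None = None
    cc_drop_max: float = 0.05
    mse_rise_max: float = 0.20
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds <= 0:
            raise ValueError("folds must be positive")
        if self.lambda_grid is not None and np.any(np.asarray(self.lambda_grid) < 0):
            raise ValueError("lambda must be >= 0")


@dataclass
class SubsetDecomposition:
    """Ordered disjoint cell subsets each decoding above ``threshold``."""

    subsets: list[list[int]]
    cc: list[float]
    threshold: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for ids, cc in zip(self.subsets, self.cc):
            if seen & set(ids):
                raise ValueError("subsets are not pairwise disjoint")
            seen |= set(ids)
            if cc < self.threshold:
                raise ValueError("retained subset below threshold")

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(subset_index=k, cell_id=cid, subset_cc=cc)
            for k, (ids, cc) in enumerate(zip(self.subsets, self.cc))
            for cid in ids
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# core solver
# --------------------------------------------------------------------------

def _strip_intercept(X: sparse.spmatrix) -> sparse.spmatrix:
    return X[:, :-1]


def lambda_max(X: sparse.spmatrix, y: np.ndarray) -> float:
    """Smallest lambda for which all kernels are exactly zero:
    lambda_max = (2/n) * max |X^T (y - mean(y))|."""
    n = X.shape[0]
    r = y - y.mean()
    return float(2.0 / n * np.max(np.abs(X.T @ r)))


def kkt_residual(X: sparse.spmatrix, y: np.ndarray, coef: np.ndarray,
                 intercept: float, lam: float) -> float:
    """Maximal violation of the subgradient optimality conditions of
    (1/n)||y - Xw - c||^2 + lambda ||w||_1."""
    n = X.shape[0]
    r = y - X @ coef - intercept
    g = 2.0 / n * (X.T @ r)
    zero = coef == 0
    viol = np.maximum(np.abs(g[zero]) - lam, 0.0) if zero.any() else np.array([0.0])
    active = ~zero
    if active.any():
        viol_a = np.abs(g[active] - lam * np.sign(coef[active]))
        viol = np.concatenate([viol, viol_a])
    # intercept optimality
    viol = np.concatenate([viol, [abs(2.0 / n * r.sum())]])
    return float(viol.max())


def fit_l1(
    design: sparse.spmatrix,
    target: np.ndarray,
    lam: float,
    grid=None,
    cell_ids: list[int] | None = None,
    max_iter: int = 50_000,
    tol: float = 1e-8,
    kkt_tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Minimise (1/n)||y - Xw - C||^2 + lambda sum||K_i||_1.

    ``design`` includes the trailing intercept column (which is not
    penalised).  Returns ``(coef_with_intercept, kkt_residual)``;
    raises on non-convergence (KKT residual above tolerance after a
    retry), with iteration diagnostics.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(target, float)
    X = _strip_intercept(design).tocsc()
    if lam == 0:
        from retinotrack.decoding import fit_ols  # objective identity at 0
        if grid is None:
            raise ValueError("grid required for lambda=0 OLS fallback")
        f = fit_ols(design, y, grid, cell_ids)
        coef = np.concatenate([*f.filters.values(), [f.constant]])
        return coef, 0.0

    scale = max(lam, lambda_max(X, y) * 1e-6)
    est = Lasso(alpha=lam / 2.0, fit_intercept=True, max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
        resid = kkt_residual(X, y, est.coef_, est.intercept_, lam)
        if resid > kkt_tol * scale:
            est = Lasso(alpha=lam / 2.0, fit_intercept=True,
                        max_iter=4 * max_iter, tol=tol / 10)
            est.fit(X, y)
            resid = kkt_residual(X, y, est.coef_, est.intercept_, lam)
    if resid > kkt_tol * scale:
        raise RuntimeError(
            f"L1 solver did not converge: KKT residual {resid:.3e} "
            f"(tol {kkt_tol * scale:.3e}) after {est.n_iter_} iterations "
            f"at lambda={lam:.3e}"
        )
    return np.concatenate([est.coef_, [est.intercept_]]), resid


class L1DecoderResults(LinearDecoderResults):
    """L1 fit results; exact zeros in the kernels are meaningful."""

    def __init__(self, model, cell_ids, col_idx, coef, lam, kkt) -> None:
        super().__init__(model, cell_ids, col_idx, coef)
        self.lam = lam
        self.kkt_residual = kkt

    @property
    def n_active_cells(self) -> int:
        return int(sum(np.any(k != 0) for k in self.filters.filters.values()))

    def amplitude_order(self) -> list[int]:
        """Cell ids by descending L1 filter norm; ties broken by id."""
        norms = self.filters.norms(ord=1)
        return sorted(norms.index, key=lambda cid: (-norms[cid], cid))

    def summary(self) -> str:
        base = super().summary()
        extra = (
            f"\nlambda:              {self.lam:.4e}"
            f"\nactive cells:        {self.n_active_cells} / {len(self.cell_ids)}"
            f"\nKKT residual:        {self.kkt_residual:.2e}"
        )
        return base + extra


def fit_l1_model(model: LinearDecoder, lam: float,
                 cells: list[int] | None = None, **kwargs) -> L1DecoderResults:
    """L1 fit on a :class:`LinearDecoder`'s training segment."""
    cell_ids = list(model.spikes.ids) if cells is None else list(cells)
    idx = model._col_indices(cell_ids)
    Xtr = model._X[model._is_train][:, idx]
    ytr = model._y[model._is_train]
    coef, kkt = fit_l1(Xtr, ytr, lam, grid=model.grid, cell_ids=cell_ids,
                       **kwargs)
    return L1DecoderResults(model, cell_ids, idx, coef, lam, kkt)


# --------------------------------------------------------------------------
# lambda selection
# --------------------------------------------------------------------------

def _default_grid(lmax: float, n: int = 30) -> np.ndarray:
    return np.geomspace(lmax / 1e4, lmax, n)


def select_lambda(
    model: LinearDecoder,
    config: L1Config | None = None,
) -> tuple[float, pd.DataFrame]:
    """Largest admissible regularisation strength under cross-validation.

    Contiguous k-fold CV on the training segment; lambda* is the
    largest grid value whose CV CC is at least ``(1 - cc_drop_max)``
    times the unregularised CV CC *and* whose CV MSE is at most
    ``(1 + mse_rise_max)`` times the unregularised CV MSE.  Returns
    ``(lambda_star, path)`` where the path frame holds the CV curves.
    If no grid point is admissible, returns 0 with a warning.
    """
    config = config or L1Config()
    Xtr = model._X[model._is_train]
    ytr = model._y[model._is_train]
    X = _strip_intercept(Xtr).tocsc()
    lmax = lambda_max(X, ytr)
    grid = (np.sort(np.asarray(config.lambda_grid, float))
            if config.lambda_grid is not None else _default_grid(lmax))

    n = X.shape[0]
    bounds = np.linspace(0, n, config.folds + 1).astype(int)
    folds = [(np.r_[0:bounds[k], bounds[k + 1]:n], np.r_[bounds[k]:bounds[k + 1]])
             for k in range(config.folds)]

    # unregularised baseline per fold (ridgeless normal equations)
    base_cc, base_mse = [], []
    for tr, te in folds:
        from retinotrack.decoding import fit_ols
        f = fit_ols(Xtr[tr], ytr[tr], model.grid, list(model.spikes.ids))
        coef = np.concatenate([*f.filters.values(), [f.constant]])
        pred = Xtr[te] @ coef
        base_cc.append(normalized_cc(pred, ytr[te]))
        base_mse.append(np.mean((pred - ytr[te]) ** 2))
    cc0, mse0 = float(np.mean(base_cc)), float(np.mean(base_mse))

    rows = []
    for lam in grid[::-1]:  # dense warm start direction not needed; sparse first
        ccs, mses = [], []
        for tr, te in folds:
            est = Lasso(alpha=lam / 2.0, fit_intercept=True,
                        max_iter=20_000, tol=1e-7)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(_strip_intercept(Xtr[tr]).tocsc(), ytr[tr])
            pred = _strip_intercept(Xtr[te]) @ est.coef_ + est.intercept_
            sd = np.std(pred)
            ccs.append(normalized_cc(pred, ytr[te]) if sd > 0 else 0.0)
            mses.append(np.mean((pred - ytr[te]) ** 2))
        rows.append(dict(lam=lam, cv_cc=np.mean(ccs), cv_mse=np.mean(mses)))
    path = pd.DataFrame(rows).sort_values("lam").reset_index(drop=True)
    path["cc0"], path["mse0"] = cc0, mse0

    ok = (path.cv_cc >= (1 - config.cc_drop_max) * cc0) & (
        path.cv_mse <= (1 + config.mse_rise_max) * mse0)
    if not ok.any():
        warnings.warn("no admissible lambda on the grid; returning 0")
        return 0.0, path
    return float(path.lam[ok].max()), path


# --------------------------------------------------------------------------
# ranking and disjoint subsets
# --------------------------------------------------------------------------

def rank_and_group(
    l1_results: L1DecoderResults,
    group_size: int = 10,
) -> pd.DataFrame:
    """Cells ordered by descending L1 filter amplitude, split into
    groups of ``group_size``, each group refitted *without*
    regularisation and evaluated on the test segment.

    Returns a frame with one row per group: member ids, mean L1 norm,
    and the group's unregularised test CC.
    """
    order = l1_results.amplitude_order()
    norms = l1_results.filters.norms(ord=1)
    model = l1_results.model
    rows = []
    for g, start in enumerate(range(0, len(order), group_size)):
        ids = order[start:start + group_size]
        refit = model.fit(cells=ids)
        rows.append(dict(group=g, cell_ids=ids,
                         mean_l1=float(norms[ids].mean()),
                         cc_test=refit.cc_test))
    return pd.DataFrame(rows)


def disjoint_subsets(
    model: LinearDecoder,
    threshold: float = 0.85,
    order: list[int] | None = None,
    lam: float | None = None,
) -> SubsetDecomposition:
    """Greedy decomposition of the population into disjoint subsets
    each decoding the trajectory with test CC above ``threshold``.

    Cells are consumed in descending L1-filter-amplitude order (from
    ``order``, or from an L1 fit at ``lam``; default lambda_max/30):
    cells are added one at a time to the current subset, refitting an
    unregularised decoder after each addition, until the subset's test
    CC reaches the threshold; the process restarts on the remaining
    cells.  Terminates when the cells left cannot reach the threshold
    even all together.
    """
    if order is None:
        if lam is None:
            Xtr = _strip_intercept(model._X[model._is_train]).tocsc()
            lam = lambda_max(Xtr, model._y[model._is_train]) / 30.0
        order = fit_l1_model(model, lam).amplitude_order()

    full_cc = model.fit().cc_test
    if threshold > full_cc:
        warnings.warn(
            f"threshold {threshold} above full-population CC {full_cc:.3f}; "
            "empty decomposition")
        return SubsetDecomposition(subsets=[], cc=[], threshold=threshold)

    remaining = list(order)
    subsets: list[list[int]] = []
    ccs: list[float] = []
    while remaining:
        if model.fit(cells=remaining).cc_test < threshold:
            break
        current: list[int] = []
        cc = -np.inf
        for cid in list(remaining):
            current.append(cid)
            cc = model.fit(cells=current).cc_test
            if cc >= threshold:
                break
        if cc < threshold:
            break
        for cid in current:
            remaining.remove(cid)
        subsets.append(current)
        ccs.append(float(cc))
    return SubsetDecomposition(subsets=subsets, cc=ccs, threshold=threshold)
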