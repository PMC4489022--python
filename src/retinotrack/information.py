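"""Coherence-based information rates and population redundancy.

The information rate between the true and decoded trajectories is the
Gaussian-channel lower bound

    I = - integral_0^fmax df log2(1 - gamma^2(f))   [bits/s]

where gamma(f) is the magnitude coherence of the two signals,
estimated by multitaper spectral averaging (windows of 256 samples at
60 Hz, time–bandwidth 3, 5 Slepian tapers) and debiased by the
finite-sample coherence floor of independent signals.  The upper
integration limit fmax is the end of the contiguous low-frequency band
where the coherence is significantly above zero.

Redundancy of a cell subset A is

    R = 1 - MI_A / sum_{i in A} M_i

with MI_A the information of the subset's joint decoder and M_i the
solo-cell informations: R = 0 for independent contributions and
R -> 1 - 1/k for k duplicated cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

__all__ = [
    "CoherenceEstimate",
    "InfoResult",
    "RedundancyResult",
    "CCInfoFit",
    "coherence",
    "info_rate",
    "signal_info_rate",
    "debias_extrapolate",
    "redundancy",
    "subset_info_scaling",
    "cc_info_fit",
]

DEFAULT_FS = 60.0
DEFAULT_WINDOW = 256
DEFAULT_NW = 3.0
DEFAULT_K = 5


@dataclass
class CoherenceEstimate:
    """Multitaper magnitude coherence between two signals.

    ``gamma`` is the debiased magnitude coherence per frequency;
    ``gamma_raw`` the biased estimate; ``n_estimates`` the number of
    independent window x taper spectra averaged (sets both the bias
    floor and the significance threshold for nonzero coherence).
    """

    freqs: np.ndarray
    gamma: np.ndarray = field(repr=False)
    gamma_raw: np.ndarray = field(repr=False)
    n_windows: int = 0
    n_estimates: int = 0
    window_len: float = DEFAULT_WINDOW / DEFAULT_FS
    fs: float = DEFAULT_FS
    significance_p: float = 1e-2

    def __post_init__(self) -> None:
        if np.any(self.gamma < 0) or np.any(self.gamma > 1):
            raise ValueError("coherence must lie in [0, 1]")

    def significance_threshold(self, p: float | None = None) -> float:
        """Magnitude-coherence value exceeded with probability ``p``
        under independence: gamma^2_crit = 1 - p^(1/(n-1))."""
        p = self.significance_p if p is None else p
        return float(np.sqrt(1.0 - p ** (1.0 / (self.n_estimates - 1))))

    def significant_band(self, p: float | None = None) -> int:
        """Index one past the end of the contiguous significant band
        starting at the lowest frequency."""
        thr = self.significance_threshold(p)
        above = self.gamma_raw > thr
        if not above[0]:
            return 0
        stop = np.flatnonzero(~above)
        return int(stop[0]) if stop.size else self.freqs.size


@dataclass
class InfoResult:
    """Information rate in bits/s with the integration band used."""

    info_rate: float
    f_max: float
    error_estimate: float = 0.1
    method: str = "direct"

    def __post_init__(self) -> None:
        if self.info_rate < 0:
            raise ValueError("information rate must be >= 0")


@dataclass
class RedundancyResult:
    subset_ids: list[int]
    mi_subset: float
    sum_individual: float
    redundancy: float


@dataclass
class CCInfoFit:
    """Fit of I = -0.5 alpha log2(1 - CC^2) + beta (per-sample units)."""

    alpha: float
    beta: float
    r2: float


# --------------------------------------------------------------------------
# coherence
# --------------------------------------------------------------------------

def coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = DEFAULT_FS,
    window: int = DEFAULT_WINDOW,
    nw: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_K,
    significance_p: float = 1e-2,
) -> CoherenceEstimate:
    """Multitaper magnitude coherence of two equal-length signals.

    Non-overlapping windows of ``window`` samples, ``n_tapers`` Slepian
    tapers at time–bandwidth ``nw``; cross- and auto-spectra averaged
    over all window x taper estimates.  The debiased squared coherence
    subtracts the 1/n floor expected for independent signals:
    gamma2_db = max(0, (n gamma2 - 1) / (n - 1)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    m = x.size // window
    if m < 1:
        raise ValueError(f"signal shorter than one window ({window} samples)")
    tapers = windows.dpss(window, nw, Kmax=n_tapers)  # (K, window)
    xw = x[: m * window].reshape(m, window)
    yw = y[: m * window].reshape(m, window)
    xw = xw - xw.mean(axis=1, keepdims=True)
    yw = yw - yw.mean(axis=1, keepdims=True)
    # (m, K, nfreq)
    X = np.fft.rfft(xw[:, None, :] * tapers[None, :, :], axis=-1)
    Y = np.fft.rfft(yw[:, None, :] * tapers[None, :, :], axis=-1)
    Sxx = np.mean(np.abs(X) ** 2, axis=(0, 1))
    Syy = np.mean(np.abs(Y) ** 2, axis=(0, 1))
    Sxy = np.mean(X * np.conj(Y), axis=(0, 1))
    denom = Sxx * Syy
    g2 = np.zeros_like(Sxx)
    nz = denom > 0
    g2[nz] = np.abs(Sxy[nz]) ** 2 / denom[nz]
    g2 = np.clip(g2, 0.0, 1.0)
    n_est = m * n_tapers
    g2_db = np.clip((n_est * g2 - 1.0) / (n_est - 1.0), 0.0, 1.0)
    freqs = np.fft.rfftfreq(window, d=1.0 / fs)
    return CoherenceEstimate(
        freqs=freqs, gamma=np.sqrt(g2_db), gamma_raw=np.sqrt(g2),
        n_windows=m, n_estimates=n_est, window_len=window / fs, fs=fs,
        significance_p=significance_p,
    )


# --------------------------------------------------------------------------
# information rate
# --------------------------------------------------------------------------

def info_rate(coh: CoherenceEstimate, significance_p: float | None = None
              ) -> InfoResult:
    """Trapezoidal integral of -log2(1 - gamma^2) over the contiguous
    significant coherence band [0, f_max]."""
    stop = coh.significant_band(significance_p)
    if stop == 0:
        return InfoResult(info_rate=0.0, f_max=0.0)
    g = coh.gamma[:stop].copy()
    if np.any(g >= 1.0):
        warnings.warn("coherence of exactly 1 capped for integration")
        g = np.minimum(g, 1.0 - 1e-12)
    integrand = -np.log2(1.0 - g**2)
    rate = float(np.trapezoid(integrand, coh.freqs[:stop]))
    return InfoResult(info_rate=max(rate, 0.0), f_max=float(coh.freqs[stop - 1]))


def signal_info_rate(x: np.ndarray, y: np.ndarray, fs: float = DEFAULT_FS,
                     **kwargs) -> InfoResult:
    """Convenience: coherence + info_rate in one call."""
    return info_rate(coherence(x, y, fs=fs, **kwargs))


def debias_extrapolate(
    x: np.ndarray,
    y: np.ndarray,
    fractions: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4),
    fs: float = DEFAULT_FS,
    significance_p: float = 1e-1,
    **kwargs,
) -> InfoResult:
    """Finite-data debiasing by extrapolation to infinite sample size.

    The information rate is estimated on nested leading fractions of
    the data and regressed linearly against inverse sample size; the
    intercept is the infinite-data estimate.  Uses the wider
    integration band at the relaxed significance level (default 0.1),
    as appropriate when the bias is removed by extrapolation.
    """
    if len(fractions) < 3:
        raise ValueError("need at least 3 data fractions")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    inv_n, vals = [], []
    for frac in fractions:
        n = int(round(frac * x.size))
        est = info_rate(coherence(x[:n], y[:n], fs=fs, **kwargs),
                        significance_p=significance_p)
        inv_n.append(1.0 / n)
        vals.append(est.info_rate)
    order = np.argsort(inv_n)
    v = np.array(vals)[order]
    if np.any(np.diff(v) > 0):
        warnings.warn("information not monotone in sample size; "
                      "extrapolation may be unreliable")
    slope, intercept = np.polyfit(inv_n, vals, 1)
    return InfoResult(info_rate=max(float(intercept), 0.0),
                      f_max=np.nan, method="extrapolated")


# --------------------------------------------------------------------------
# redundancy and subset scaling
# --------------------------------------------------------------------------

def _test_info(model, cells) -> float:
    """Information rate of a (sub)decoder's test-segment prediction."""
    res = model.fit(cells=cells)
    te = ~model._is_train
    return signal_info_rate(model._y[te], res._pred[te],
                            fs=1.0 / model.grid.bin).info_rate


def redundancy(model, subset_ids: list[int],
               solo_info: dict[int, float] | None = None) -> RedundancyResult:
    """Redundancy R = 1 - MI_A / sum_i M_i for a cell subset.

    ``model`` is a fitted-capable :class:`~retinotrack.decoding.LinearDecoder`;
    solo informations can be passed in to avoid refitting.
    """
    mi_subset = _test_info(model, subset_ids)
    if solo_info is None:
        solo_info = {cid: _test_info(model, [cid]) for cid in subset_ids}
    s = float(sum(solo_info[cid] for cid in subset_ids))
    if s == 0:
        warnings.warn("sum of individual informations is 0; R undefined")
        r = np.nan
    else:
        r = 1.0 - mi_subset / s
    return RedundancyResult(subset_ids=list(subset_ids), mi_subset=mi_subset,
                            sum_individual=s, redundancy=r)


def subset_info_scaling(
    model,
    sizes: list[int],
    draws: int = 5,
    seed: int = 0,
    solo_info: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Joint vs summed-individual information for cell subsets.

    Random subsets of each size, plus the "best" and "worst" subsets
    (top-N / bottom-N cells ranked by solo information).  Returns a
    tidy frame with columns ``size, kind, mi_subset, sum_individual``.
    """
    rng = np.random.default_rng(seed)
    ids = list(model.spikes.ids)
    if solo_info is None:
        solo_info = {cid: _test_info(model, [cid]) for cid in ids}
    by_info = sorted(ids, key=lambda cid: -solo_info[cid])
    rows = []

    def add(subset, kind):
        mi = _test_info(model, subset)
        rows.append(dict(size=len(subset), kind=kind, mi_subset=mi,
                         sum_individual=sum(solo_info[c] for c in subset)))

    for size in sizes:
        for _ in range(draws if size < len(ids) else 1):
            add(list(rng.choice(ids, size=size, replace=False)), "random")
        add(by_info[:size], "best")
        add(by_info[-size:], "worst")
    return pd.DataFrame(rows)


def cc_info_fit(cc: np.ndarray, info: np.ndarray) -> CCInfoFit:
    """Least-squares fit of I = -0.5 alpha log2(1 - CC^2) + beta.

    With no temporal correlation the per-sample information equals
    -0.5 log2(1 - CC^2) exactly (alpha = 1, beta = 0); temporally
    structured signals bend away from it and the linear interpolation
    in the transformed variable captures them empirically.
    """
    cc = np.asarray(cc, float)
    info = np.asarray(info, float)
    if cc.size < 3:
        raise ValueError("need at least 3 (CC, I) pairs")
    if np.any(np.abs(cc) >= 1):
        raise ValueError("|CC| = 1 gives a divergent predictor; rejected")
    u = -0.5 * np.log2(1.0 - cc**2)
    alpha, beta = np.polyfit(u, info, 1)
    pred = alpha * u + beta
    ss_res = np.sum((info - pred) ** 2)
    ss_tot = np.sum((info - info.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CCInfoFit(alpha=float(alpha), beta=float(beta), r2=float(r2))
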