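"""Stimulus-trajectory ensembles for the moving-bar experiments.

Two ensembles are provided:

* a damped Brownian ("spring OU") walk — Langevin dynamics of the bar
  velocity with a linear restoring force pulling the bar back to the
  center, integrated by Euler–Maruyama;
* a low-pass-filtered white-noise positional sequence (independent
  Gaussian draws per stimulus frame, zero-phase Butterworth filtered),
  which puts equal power in a wide frequency band.

Internally the Langevin equation is integrated in SI units (m, s) and
converted to micrometers at the :class:`Trajectory` boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "SpringOUParams",
    "LowpassWhiteParams",
    "Trajectory",
    "BarGeometry",
    "simulate_spring_ou",
    "simulate_lowpass_white",
    "bar_profile",
    "spring_ou_stationary_var",
    "diffusion_constant",
]


@dataclass(frozen=True)
class SpringOUParams:
    """Parameters of the damped, spring-confined random walk.

    The bar velocity obeys ``dv = (-v/tau - omega0^2 x) dt + sigma dW``
    with ``sigma = sqrt(sigma2)``; position integrates the velocity.

    Parameters
    ----------
    sigma2 : float
        Noise intensity sigma^2 in m^2 s^-3.
    tau : float
        Velocity relaxation time in s.
    omega0 : float
        Restoring strength, interpreted as an angular frequency in s^-1.
        Set to 0 for free (unconfined) diffusive motion.
    dt : float
        Integration step in s. Must satisfy ``dt <= tau/10``.
    duration : float
        Total simulated time in s.
    seed : int
        RNG seed; identical parameters and seed give identical paths.
    x0, v0 : float
        Initial position (um) and velocity (um/s).
    """

    sigma2: float = 0.05
    tau: float = 0.050
    omega0: float = 9.42
    dt: float = 0.001
    duration: float = 60.0
    seed: int = 0
    x0: float = 0.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.omega0 < 0:
            raise ValueError("omega0 must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.dt > self.tau / 10:
            raise ValueError(
                f"integration step dt={self.dt} too large for tau={self.tau}: "
                "require dt <= tau/10 (unstable Euler-Maruyama otherwise)"
            )
        # explicit-Euler stability of the oscillatory mode
        if self.omega0 * self.dt > 0.1:
            raise ValueError(
                "unstable configuration: omega0*dt > 0.1; reduce dt"
            )


@dataclass(frozen=True)
class LowpassWhiteParams:
    """White positional noise per stimulus frame, low-pass filtered.

    ``sd`` is the pre-filter standard deviation of the per-frame
    Gaussian position draws (um); ``frame`` the sampling interval (s);
    ``cutoff`` the Butterworth corner frequency (Hz).
    """

    sd: float = 60.0
    frame: float = 1.0 / 60.0
    cutoff: float = 5.0
    order: int = 4
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.frame <= 0 or self.duration <= 0:
            raise ValueError("frame and duration must be > 0")
        nyquist = 0.5 / self.frame
        if not 0 < self.cutoff < nyquist:
            raise ValueError(
                f"cutoff must lie in (0, Nyquist={nyquist:g} Hz), got {self.cutoff}"
            )


@dataclass
class Trajectory:
    """Uniformly sampled 1-D bar position.

    Attributes
    ----------
    t0 : float
        Time of the first sample (s).
    dt : float
        Sample interval (s).
    x : ndarray
        Positions in micrometers.
    """

    t0: float
    dt: float
    x: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ValueError("positions must be a 1-D sequence")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("trajectory contains non-finite positions")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def sample_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of position at arbitrary times."""
        return np.interp(times, self.t, self.x)

    def resample(self, new_dt: float) -> "Trajectory":
        """Linearly interpolate onto a uniform grid of spacing ``new_dt``."""
        if new_dt <= 0:
            raise ValueError("new_dt must be > 0")
        n = int(np.floor(self.duration / new_dt))
        tt = self.t0 + new_dt * np.arange(n)
        return Trajectory(t0=self.t0, dt=new_dt, x=np.interp(tt, self.t, self.x))

    def bin_average(self, bin_dt: float) -> "Trajectory":
        """Down-sample by averaging within consecutive bins of ``bin_dt``."""
        k = int(round(bin_dt / self.dt))
        if k < 1:
            raise ValueError("bin_dt must be >= dt")
        if k == 1:
            return replace(self)
        m = self.n // k
        xb = self.x[: m * k].reshape(m, k).mean(axis=1)
        return Trajectory(t0=self.t0 + 0.5 * (k - 1) * self.dt, dt=k * self.dt, x=xb)


@dataclass(frozen=True)
class BarGeometry:
    """Dark-bar geometry: width/length in um, fractional contrast in (0, 1].

    Contrast is a decrement: 1.0 means a fully dark bar on the gray
    background.
    """

    width: float = 100.0
    length: float = 2300.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("bar width and length must be > 0")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")


def spring_ou_stationary_var(params: SpringOUParams) -> tuple[float, float]:
    """Closed-form stationary variances (Var x in um^2, Var v in (um/s)^2).

    For ``x'' = -x'/tau - omega0^2 x + sigma Gamma(t)`` the stationary
    covariance of the linear SDE is ``Var(x) = sigma^2 tau / (2 omega0^2)``
    and ``Var(v) = sigma^2 tau / 2`` (in SI units).
    """
    if params.omega0 == 0:
        raise ValueError("no stationary position distribution when omega0=0")
    var_x_m2 = params.sigma2 * params.tau / (2 * params.omega0**2)
    var_v_m2 = params.sigma2 * params.tau / 2
    return var_x_m2 * 1e12, var_v_m2 * 1e12


def diffusion_constant(sigma2: float, tau: float) -> float:
    """Effective position diffusion constant D = sigma^2 tau^2 / 2, mm^2/s.

    This is the Green–Kubo integral of the stationary velocity
    autocorrelation, Var(v) * tau, for the spring-free (omega0 = 0)
    process.
    """
    return sigma2 * tau**2 / 2 * 1e6  # m^2/s -> mm^2/s


def simulate_spring_ou(params: SpringOUParams) -> Trajectory:
    """Integrate the spring-confined Langevin dynamics (Euler–Maruyama).

    The two-variable Euler recursion

    ``x[n+1] = x[n] + v[n] dt``
    ``v[n+1] = v[n] + (-v[n]/tau - omega0^2 x[n]) dt + sqrt(sigma2 dt) xi[n]``

    is equivalent to the scalar AR(2)

    ``x[n+2] = (2 - dt/tau) x[n+1] - (1 - dt/tau + omega0^2 dt^2) x[n]
    + sqrt(sigma2 dt) dt xi[n]``

    which is evaluated with a vectorised linear filter.  Positions are
    returned in micrometers on the integration grid.
    """
    p = params
    n = int(round(p.duration / p.dt))
    rng = np.random.default_rng(p.seed)
    dt, tau, w2 = p.dt, p.tau, p.omega0**2
    s = math.sqrt(p.sigma2 * dt)  # velocity kick SD per step, m/s
    x0 = p.x0 * 1e-6
    v0 = p.v0 * 1e-6

    if p.sigma2 == 0 and x0 == 0 and v0 == 0:
        return Trajectory(t0=0.0, dt=dt, x=np.zeros(n))

    xi = rng.standard_normal(max(n - 2, 0))
    a1 = 2.0 - dt / tau
    a2 = -(1.0 - dt / tau + w2 * dt * dt)
    # x[k] = a1 x[k-1] + a2 x[k-2] + (s*dt) xi[k-2]
    a = np.array([1.0, -a1, -a2])
    b = np.array([s * dt])
    x1 = x0 + v0 * dt
    # lfilter initial conditions reproducing x[0]=x0, x[1]=x1 with zero input
    zi = np.array([a1 * x1 + a2 * x0, a2 * x1])
    if n == 1:
        xs = np.array([x0])
    elif n == 2:
        xs = np.array([x0, x1])
    else:
        tail, _ = signal.lfilter(b, a, xi, zi=zi)
        xs = np.concatenate(([x0, x1], tail))
    return Trajectory(t0=0.0, dt=dt, x=xs * 1e6)


def simulate_lowpass_white(params: LowpassWhiteParams) -> Trajectory:
    """i.i.d. Gaussian positions per frame, zero-phase Butterworth filtered."""
    p = params
    n = int(round(p.duration / p.frame))
    rng = np.random.default_rng(p.seed)
    raw = rng.normal(0.0, p.sd, size=n) if p.sd > 0 else np.zeros(n)
    if p.sd == 0:
        return Trajectory(t0=0.0, dt=p.frame, x=raw)
    sos = signal.butter(p.order, p.cutoff, fs=1.0 / p.frame, output="sos")
    x = signal.sosfiltfilt(sos, raw)
    return Trajectory(t0=0.0, dt=p.frame, x=x)


def bar_profile(
    geometry: BarGeometry, position: float, grid: np.ndarray
) -> np.ndarray:
    """1-D luminance cross-section of the dark bar in contrast units.

    Returns 0 (background) everywhere except a contiguous interval of
    width ``geometry.width`` centered on ``position``, where the value
    is ``-contrast`` (a luminance decrement).  Samples whose center
    lies in ``[position - w/2, position + w/2)`` are dark, so a 100-um
    bar on a 1-um grid covers exactly 100 samples.  No wrap-around: the
    bar is clipped at the grid edges.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1:
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform")
    half = geometry.width / 2.0
    dark = (grid >= position - half) & (grid < position + half)
    out = np.zeros_like(grid)
    out[dark] = -geometry.contrast
    return out
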