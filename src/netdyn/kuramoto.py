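"""Noisy Kuramoto phase oscillators on a graph.

Each node i carries a phase θ_i driven by its natural frequency ω_i,
sine coupling to its network neighbours with strength k, and additive
Gaussian noise of amplitude σ that delays full synchronization:

    dθ_i/dt = ω_i + (k/N) Σ_j A_ij sin(θ_j − θ_i) + σ u_i(t)

Integration is Euler–Maruyama with step ``dt`` and √dt noise scaling
(a literal σ·u·dt mode is available for sensitivity checks).  Phases are
accumulated unwrapped.

Functional connectivity is built from the *effective frequency* — a
centred moving average of one-step phase increments over a half-window
Δt — via lagged Pearson correlations:

    FC_ij(δt) = corr_t( Ω_i(t), Ω_j(t+δt) )

δt = 0 captures strict co-activation; a small positive lag (default 2
series steps) captures sequential activation before the effective
frequencies decouple at larger lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graphs import validate_adjacency
from .ser import FCPair

__all__ = [
    "KuramotoParams",
    "kuramoto_simulate",
    "effective_frequency",
    "lagged_correlation_fc",
    "kuramoto_ensemble_fc",
    "order_parameter",
]


@dataclass
class KuramotoParams:
    """Simulation and FC parameters.

    omega_interval
        Natural frequencies are drawn uniformly from this interval, one
        draw per node per run (default (0, 1); the intrinsic-parameter
        sweep widens it symmetrically about its midpoint).
    k
        Coupling strength, scaled by 1/N in the drift (default 10).
    sigma
        Noise amplitude (default 0.25).
    dt, t_max
        Euler step (default 0.1) and total integrated time (default 50),
        giving T = t_max/dt + 1 phase samples.
    window
        Half-window Δt of the effective-frequency moving average, in
        integration steps (default 20, i.e. 2 time units at dt = 0.1).
    stride
        Subsampling stride of the Ω series before correlating, in
        integration steps.  ``None`` (default) uses the window Δt, so
        consecutive series points share half their averaging window:
        lags 0 and 1 then both capture co-activity, lag 2 is the first
        lag whose windows are disjoint (sequential activation), and
        larger lags decouple.  ``stride=1`` keeps the raw grid.
    lag_sim, lag_seq
        Lags (in Ω-series steps after striding) of the co-activation and
        sequential-activation FC matrices (defaults 0 and 2).
    n_runs
        Ensemble size; FC matrices are summed over runs (default 100).
    sqrt_dt_noise
        Euler–Maruyama √dt noise scaling (default True); False uses the
        literal σ·u·dt reading.
    """

    omega_interval: tuple[float, float] = (0.0, 1.0)
    k: float = 10.0
    sigma: float = 0.25
    dt: float = 0.1
    t_max: float = 50.0
    window: int = 20
    stride: int | None = None
    lag_sim: int = 0
    lag_seq: int = 2
    n_runs: int = 100
    sqrt_dt_noise: bool = True

    def __post_init__(self):
        if not np.isfinite([self.k, self.sigma, self.dt, self.t_max]).all():
            raise ValueError("parameters must be finite")
        if self.dt <= 0 or self.t_max < self.dt:
            raise ValueError("need dt > 0 and t_max >= dt")
        if self.window < 1 or self.lag_sim < 0 or self.lag_seq < 0:
            raise ValueError("window must be >= 1 and lags >= 0")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    @property
    def effective_stride(self) -> int:
        return self.window if self.stride is None else self.stride


def kuramoto_simulate(
    A: np.ndarray,
    params: KuramotoParams,
    rng: np.random.Generator,
    omega: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate the noisy phase dynamics; returns unwrapped phases (n, T).

    ``omega`` and ``theta0`` default to fresh uniform draws from
    ``params.omega_interval`` and (−π, π) respectively.
    """
    A = validate_adjacency(A, require_edges=True).astype(float)
    n = A.shape[0]
    if omega is None:
        lo, hi = params.omega_interval
        omega = rng.uniform(lo, hi, size=n)
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (n,):
        raise ValueError("omega length must match node count")
    if theta0 is None:
        theta0 = rng.uniform(-np.pi, np.pi, size=n)
    theta = np.asarray(theta0, dtype=float).copy()
    steps = params.n_steps
    out = np.empty((n, steps + 1))
    out[:, 0] = theta
    noise_scale = (
        params.sigma * np.sqrt(params.dt)
        if params.sqrt_dt_noise
        else params.sigma * params.dt
    )
    kN = params.k / n
    for t in range(1, steps + 1):
        # Σ_j A_ij sin(θ_j − θ_i) = cosθ_i (A sinθ) − sinθ_i (A cosθ)
        s, c = np.sin(theta), np.cos(theta)
        coupling = c * (A @ s) - s * (A @ c)
        theta = theta + params.dt * (omega + kN * coupling)
        if params.sigma > 0:
            theta = theta + noise_scale * rng.standard_normal(n)
        out[:, t] = theta
    return out


def effective_frequency(theta: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average of one-step phase increments.

        Ω_i(t) = 1/(2Δt) Σ_{t'=t−Δt}^{t+Δt−1} [θ_i(t'+1) − θ_i(t')]

    The output is trimmed to the valid support, shape (n, T − 2·window).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("phase raster must be (n, T)")
    n, T = theta.shape
    if window < 1:
        raise ValueError("window must be >= 1")
    if T <= 2 * window:
        raise ValueError(
            f"series too short: need more than {2 * window + 1} samples, got {T}"
        )
    # telescoping: the windowed sum of increments is a phase difference
    out = (theta[:, 2 * window:] - theta[:, : T - 2 * window]) / (2.0 * window)
    return out


def lagged_correlation_fc(series: np.ndarray, lag: int) -> np.ndarray:
    """Pearson correlation matrix at the given lag.

    Entry (i, j) correlates node i's series at time t with node j's at
    t + lag over the overlapping support.  The diagonal is zero by
    convention; zero-variance pairs are recorded as NaN (missing).
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError("series must be (n, T)")
    n, T = X.shape
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if T <= lag + 2:
        raise ValueError(f"series length {T} too short for lag {lag}")
    a = X[:, : T - lag]  # node i at t
    b = X[:, lag:]  # node j at t + lag
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a * a).sum(axis=1))
    sb = np.sqrt((b * b).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (a @ b.T) / np.outer(sa, sb)
    F[~np.isfinite(F)] = np.nan
    if np.isnan(F).all():
        warnings.warn("all FC entries undefined: constant series", stacklevel=2)
    np.fill_diagonal(F, 0.0)
    return F


def _simulate_batch(
    A: np.ndarray, params: KuramotoParams, rng: np.random.Generator, n_runs: int
) -> np.ndarray:
    """Integrate ``n_runs`` independent runs at once; returns (runs, n, T).

    ω and θ(0) are redrawn per run.  Statistically identical to repeated
    :func:`kuramoto_simulate` calls, vectorized across the run axis.
    """
    Af = A.astype(float)
    n = A.shape[0]
    lo, hi = params.omega_interval
    omega = rng.uniform(lo, hi, size=(n, n_runs))
    theta = rng.uniform(-np.pi, np.pi, size=(n, n_runs))
    steps = params.n_steps
    out = np.empty((n_runs, n, steps + 1))
    out[:, :, 0] = theta.T
    noise_scale = (
        params.sigma * np.sqrt(params.dt)
        if params.sqrt_dt_noise
        else params.sigma * params.dt
    )
    kN = params.k / n
    for t in range(1, steps + 1):
        s, c = np.sin(theta), np.cos(theta)
        coupling = c * (Af @ s) - s * (Af @ c)
        theta = theta + params.dt * (omega + kN * coupling)
        if params.sigma > 0:
            theta = theta + noise_scale * rng.standard_normal((n, n_runs))
        out[:, :, t] = theta.T
    return out


def kuramoto_ensemble_fc(
    A: np.ndarray,
    params: KuramotoParams,
    rng: np.random.Generator,
) -> FCPair:
    """Sum lag-``lag_sim`` and lag-``lag_seq`` FC matrices over runs.

    Natural frequencies and initial phases are redrawn independently for
    every run.  Zero-variance (missing) entries are excluded from the sum
    pairwise; an entry missing in *every* run is reported as NaN, and the
    total missing count is surfaced as a warning.
    """
    A = validate_adjacency(A, require_edges=True)
    n = A.shape[0]
    Csum = np.zeros((n, n))
    Ssum = np.zeros((n, n))
    Ccnt = np.zeros((n, n), dtype=int)
    Scnt = np.zeros((n, n), dtype=int)
    n_missing = 0
    rasters = _simulate_batch(A, params, rng, params.n_runs)
    stride = params.effective_stride
    for r in range(params.n_runs):
        om = effective_frequency(rasters[r], params.window)[:, ::stride]
        Fsim = lagged_correlation_fc(om, params.lag_sim)
        Fseq = lagged_correlation_fc(om, params.lag_seq)
        ok_sim, ok_seq = ~np.isnan(Fsim), ~np.isnan(Fseq)
        n_missing += int((~ok_sim).sum() + (~ok_seq).sum())
        Csum[ok_sim] += Fsim[ok_sim]
        Ssum[ok_seq] += Fseq[ok_seq]
        Ccnt += ok_sim
        Scnt += ok_seq
    Csum[Ccnt == 0] = np.nan
    Ssum[Scnt == 0] = np.nan
    if n_missing:
        warnings.warn(
            f"{n_missing} zero-variance FC entries across the ensemble",
            stacklevel=2,
        )
    return FCPair(Csum, Ssum, normalized=False)


def order_parameter(theta: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter r(t) = |⟨e^{iθ}⟩| for each time sample."""
    return np.abs(np.exp(1j * np.asarray(theta)).mean(axis=0))
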