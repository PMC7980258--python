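"""Stochastic model of filopodial growth.

The growth velocity of a filopodium-like structure (FLS) is modelled as a
force produced by fluctuating concentrations of actin regulators at the tip
complex.  Each regulator concentration ``A_i`` relaxes toward a baseline
``Ã_i`` as an independent Ornstein–Uhlenbeck (OU) process

    dA_i = theta * (Ã_i - A_i) dt + dW,     <W(t)W(s)> = 2 theta eta^2 delta(t-s),

so that the deviations ``X_i = A_i - Ã_i`` are stationary Gaussians with
variance ``eta^2`` and relaxation rate ``theta``.  The force (taken equal to
the growth velocity, overdamped limit) is a sum of M products of N such
deviations,

    F_{M,N}(t) = sum_{i=1..M} prod_{j=1..N} X_{N(i-1)+j}(t).

For M = N = 2 the stationary force is exactly Laplace distributed, which is
the empirical hallmark of measured FLS growth velocities.  Lengths follow
dL/dt = F with L clamped at zero from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "GrowthModelParams",
    "RegulatorTraces",
    "VelocitySeries",
    "LengthTrajectory",
    "ReactionNetworkParams",
    "simulate_regulators",
    "compose_force",
    "simulate_length",
    "simulate_length_ensemble",
    "stationary_velocity_sample",
    "laplace_density_check",
    "simulate_reaction_network",
]


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameter bundle for the OU sum-of-products growth model.

    Parameters
    ----------
    M : int
        Number of regulator complexes (sum terms), >= 1.
    N : int
        Number of fluctuating factors per complex (product factors), >= 1.
    theta : float
        OU relaxation rate in 1/min (> 0).
    eta : float
        Stationary fluctuation SD of each regulator, concentration units (>= 0).
    baselines : ndarray or None
        Baseline concentrations ``Ã_i``, length M*N, all >= 0.  ``None``
        means all zero (only deviations matter for the unsigned force).
    dt : float
        Integration step in seconds (> 0).  Default 1 s.
    duration : float
        Total simulated time in minutes.
    seed : int
        Seed for the simulation RNG.
    """

    M: int = 2
    N: int = 2
    theta: float = 11.0
    eta: float = 2.0
    baselines: np.ndarray | None = None
    dt: float = 1.0
    duration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.theta * self.dt_min >= 1.0:
            raise ValueError(
                "theta*dt >= 1 (dt in minutes): explicit scheme unstable; "
                "reduce dt or theta"
            )
        if self.baselines is not None:
            b = np.asarray(self.baselines, dtype=float)
            if b.shape != (self.K,):
                raise ValueError(f"baselines must have length M*N = {self.K}")
            if np.any(b < 0):
                raise ValueError("baselines must be >= 0")
            object.__setattr__(self, "baselines", b)

    @property
    def K(self) -> int:
        """Number of regulator species, M*N."""
        return self.M * self.N

    @property
    def dt_min(self) -> float:
        """Integration step in minutes."""
        return self.dt / 60.0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt_min))

    def baseline_array(self) -> np.ndarray:
        if self.baselines is None:
            return np.zeros(self.K)
        return np.asarray(self.baselines, dtype=float)

    def with_(self, **kw) -> "GrowthModelParams":
        return replace(self, **kw)


@dataclass
class RegulatorTraces:
    """K x T matrix of simulated regulator concentrations.

    ``deviations`` are ``X_i(t) = A_i(t) - Ã_i``; ``concentrations`` are the
    raw ``A_i(t)``.  Times are in minutes.
    """

    times: np.ndarray
    concentrations: np.ndarray
    baselines: np.ndarray

    @property
    def deviations(self) -> np.ndarray:
        return self.concentrations - self.baselines[:, None]

    @property
    def K(self) -> int:
        return self.concentrations.shape[0]


@dataclass
class VelocitySeries:
    """Growth velocity F(t) in length-units per minute; times in minutes."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocity values must be finite")


@dataclass
class LengthTrajectory:
    """Length-vs-time series of one structure.

    times are minutes, lengths are µm (>= 0).  ``source`` records whether the
    series came from a simulation or a measurement.
    """

    id: str
    times: np.ndarray
    lengths: np.ndarray
    source: Literal["simulated", "measured"] = "simulated"
    initiation_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must match")
        if np.any(self.lengths < -1e-12):
            raise ValueError("lengths must be >= 0")

    def velocities(self) -> np.ndarray:
        """Finite-difference velocities (µm/min), same length as times."""
        return np.gradient(self.lengths, self.times)


def simulate_regulators(params: GrowthModelParams, rng: np.random.Generator | None = None) -> RegulatorTraces:
    """Integrate the K = M*N independent OU processes (Euler–Maruyama).

    Update rule: ``A <- A + theta*(Ã - A)*dt + sqrt(2*theta*eta^2*dt)*z`` with
    dt in minutes and z standard normal.  Initial condition A_i(0) = Ã_i.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    K, T = params.K, params.n_steps
    dt = params.dt_min
    base = params.baseline_array()
    a = np.empty((K, T + 1))
    a[:, 0] = base
    noise_amp = np.sqrt(2.0 * params.theta * params.eta**2 * dt)
    drift = params.theta * dt
    z = rng.standard_normal((K, T))
    for t in range(T):
        a[:, t + 1] = a[:, t] + drift * (base - a[:, t]) + noise_amp * z[:, t]
    times = np.arange(T + 1) * dt
    return RegulatorTraces(times=times, concentrations=a, baselines=base)


def compose_force(
    traces: RegulatorTraces, M: int, N: int, signed: bool = False
) -> VelocitySeries:
    """Combine regulator traces into the sum-of-products force.

    Unsigned (default): F(t) = sum_i prod_j X_{N(i-1)+j}(t) over deviations X.
    Signed: each term carries (-1)^i and the factors are the strictly
    positive concentrations (growth complexes vs shrinkage complexes).
    """
    if traces.K != M * N:
        raise ValueError(f"traces have K={traces.K} rows, expected M*N={M * N}")
    if signed:
        factors = traces.concentrations
    else:
        factors = traces.deviations
    prods = factors.reshape(M, N, -1).prod(axis=1)
    if signed:
        signs = (-1.0) ** np.arange(1, M + 1)
        f = (signs[:, None] * prods).sum(axis=0)
    else:
        f = prods.sum(axis=0)
    return VelocitySeries(times=traces.times, values=f)


def _integrate_length(
    times: np.ndarray, force: np.ndarray, dt_min: float, initiation_time: float
) -> np.ndarray:
    """dL/dt = F, L >= 0 (projection), L = 0 before initiation."""
    L = np.zeros_like(force)
    active = times > initiation_time  # L(initiation_time) = 0 exactly
    val = 0.0
    for t in range(1, len(force)):
        if active[t]:
            val = max(0.0, val + force[t - 1] * dt_min)
        L[t] = val
    return L


def simulate_length(
    params: GrowthModelParams,
    initiation_time: float = 0.0,
    rng: np.random.Generator | None = None,
    traj_id: str = "sim-0",
) -> LengthTrajectory:
    """Simulate one length trajectory: OU regulators -> force -> dL/dt = F.

    The length is integrated with the same step as the regulators, clamped at
    zero from below, and held at zero before ``initiation_time`` (minutes).
    """
    if initiation_time >= params.duration:
        raise ValueError("initiation_time must precede duration")
    if initiation_time < 0:
        raise ValueError("initiation_time must be >= 0")
    traces = simulate_regulators(params, rng=rng)
    vel = compose_force(traces, params.M, params.N)
    L = _integrate_length(vel.times, vel.values, params.dt_min, initiation_time)
    return LengthTrajectory(
        id=traj_id,
        times=vel.times,
        lengths=L,
        source="simulated",
        initiation_time=initiation_time,
    )


def simulate_length_ensemble(
    params: GrowthModelParams,
    initiation_times: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorised ensemble of length trajectories; returns (n, T+1) lengths.

    Functionally equivalent to calling :func:`simulate_length` per trajectory
    but integrates all OU systems in one array sweep, which keeps parameter
    scans (theta fitting) tractable.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    init = np.asarray(initiation_times, dtype=float)
    n = init.size
    K, T = params.K, params.n_steps
    dt = params.dt_min
    drift = params.theta * dt
    noise_amp = np.sqrt(2.0 * params.theta * params.eta**2 * dt)
    x = np.zeros((n, K))  # deviations, start at baseline
    L = np.zeros((n, T + 1))
    times = np.arange(T + 1) * dt
    lengths = np.zeros(n)
    for t in range(T):
        f = x.reshape(n, params.M, params.N).prod(axis=2).sum(axis=1)
        active = times[t + 1] > init
        lengths = np.where(active, np.maximum(0.0, lengths + f * dt), 0.0)
        L[:, t + 1] = lengths
        x += -drift * x + noise_amp * rng.standard_normal((n, K))
    return L


def stationary_velocity_sample(
    M: int,
    N: int,
    n: int,
    eta: float = 1.0,
    theta: float = 11.0,
    seed: int | np.random.Generator = 0,
    method: Literal["exact", "euler"] = "exact",
    dt: float = 1.0,
) -> np.ndarray:
    """Draw n samples from the stationary force distribution F_{M,N}.

    ``method="exact"`` samples the OU stationary law directly (i.i.d.
    N(0, eta^2) factors); ``method="euler"`` runs Euler–Maruyama chains with
    a 10/theta burn-in and records decorrelated states (spacing 5/theta),
    which converges to the same distribution and serves as a cross-check.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = M * N
    if method == "exact":
        x = rng.standard_normal((n, K)) * eta
        return x.reshape(n, M, N).prod(axis=2).sum(axis=1)
    if method != "euler":
        raise ValueError("method must be 'exact' or 'euler'")
    dt_min = dt / 60.0
    if theta * dt_min >= 1.0:
        raise ValueError("theta*dt >= 1: unstable")
    burn = int(np.ceil(10.0 / theta / dt_min))
    spacing = max(1, int(np.ceil(5.0 / theta / dt_min)))
    n_chains = min(n, 2000)
    per_chain = int(np.ceil(n / n_chains))
    drift = theta * dt_min
    amp = np.sqrt(2.0 * theta * eta**2 * dt_min)
    x = np.zeros((n_chains, K))
    out = np.empty((per_chain, n_chains))
    step = 0
    collected = 0
    total_steps = burn + per_chain * spacing
    while step < total_steps:
        x += -drift * x + amp * rng.standard_normal(x.shape)
        step += 1
        if step > burn and (step - burn) % spacing == 0 and collected < per_chain:
            out[collected] = x.reshape(n_chains, M, N).prod(axis=2).sum(axis=1)
            collected += 1
    return out.ravel()[:n]


def laplace_density_check(n_samples: int, seed: int = 0) -> dict:
    """Monte-Carlo check that X1*X2 + X3*X4 of i.i.d. standard normals is
    standard Laplace (density 0.5*exp(-|w|)).

    Returns the one-sample KS statistic against Laplace(0, 1) for the sum of
    two products, the same statistic for a single product (which is Bessel-K0
    distributed, not Laplace), and the sample mean.
    """
    from scipy import stats

    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_samples, 4))
    w = x[:, 0] * x[:, 1] + x[:, 2] * x[:, 3]
    single = x[:, 0] * x[:, 1]
    ks_sum = stats.kstest(w, stats.laplace(loc=0.0, scale=1.0).cdf).statistic
    ks_single = stats.kstest(single, stats.laplace(loc=0.0, scale=1.0).cdf).statistic
    return {
        "ks_sum_of_products": float(ks_sum),
        "ks_single_product": float(ks_single),
        "mean": float(w.mean()),
        "n": int(n_samples),
    }


@dataclass(frozen=True)
class ReactionNetworkParams:
    """Mass-action reaction network behind the sum-of-products force.

    2M species A_i are produced at rate sigma, pair into M complexes B_j at
    rate rho, and complexes decay at rate eta_decay:

        0 -> A_i (sigma);  A_2j + A_2j+1 -> B_j (rho);  B_j -> 0 (eta_decay).

    The species steady state is a_i = sqrt(sigma/rho); the velocity is the
    summed complex formation flux, nu = sum_j db_j/dt.
    """

    sigma: float
    rho: float
    eta_decay: float
    M: int = 2

    def __post_init__(self) -> None:
        if min(self.sigma, self.rho, self.eta_decay) <= 0:
            raise ValueError("all rates must be > 0")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @property
    def steady_state_a(self) -> float:
        return float(np.sqrt(self.sigma / self.rho))


def simulate_reaction_network(
    params: ReactionNetworkParams,
    duration: float,
    dt: float = 1.0,
    seed: int = 0,
    fluct_sd: float = 0.0,
    fluct_theta: float = 11.0,
    signed: bool = False,
) -> dict:
    """Simulate the pair-reaction network with OU-fluctuating species.

    Species concentrations a_i fluctuate around the steady state
    sqrt(sigma/rho) as OU processes with SD ``fluct_sd`` and relaxation rate
    ``fluct_theta`` (per minute), reflected at zero so concentrations stay
    non-negative.  Complexes follow db_j/dt = rho*a_2j*a_2j+1 - eta_decay*b_j
    and the growth velocity is nu(t) = sum_j db_j/dt.  With ``signed=True``
    complexes alternate between growth and shrinkage contributions,
    nu(t) = sum_j (-1)^j db_j/dt, which in the large-variance regime
    (fluct_sd >> steady state) gives a symmetric Laplace-like velocity
    distribution.

    Returns dict with times (min), a (2M x T), b (M x T), velocity (T,).
    """
    rng = np.random.default_rng(seed)
    dt_min = dt / 60.0
    T = int(round(duration / dt_min))
    M = params.M
    a_ss = params.steady_state_a
    a = np.full((2 * M, T + 1), a_ss)
    b = np.empty((M, T + 1))
    b[:, 0] = params.rho * a_ss**2 / params.eta_decay  # complex steady state
    vel = np.zeros(T + 1)
    drift = fluct_theta * dt_min
    amp = np.sqrt(2.0 * fluct_theta * fluct_sd**2 * dt_min)
    for t in range(T):
        step = -drift * (a[:, t] - a_ss) + amp * rng.standard_normal(2 * M)
        nxt = a[:, t] + step
        nxt = np.abs(nxt)  # reflective boundary at zero
        a[:, t + 1] = nxt
        flux = params.rho * nxt[0::2] * nxt[1::2]
        bdot = flux - params.eta_decay * b[:, t]
        b[:, t + 1] = b[:, t] + bdot * dt_min
        if signed:
            vel[t + 1] = ((-1.0) ** np.arange(M) * bdot).sum()
        else:
            vel[t + 1] = bdot.sum()
    assert np.all(a >= 0), "reflection must keep concentrations non-negative"
    times = np.arange(T + 1) * dt_min
    return {"times": times, "a": a, "b": b, "velocity": vel}
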