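"""Templated-assembly ladder kinetics.

A genome (template) binds subunits one at a time through the reversible
ladder ``C_N + S <-> C_{N+1}`` for ``N = 0 .. n_max - 1`` with uniform
forward rate constant ``k_plus`` (M^-1 s^-1) and backward rate constant
``k_minus`` (s^-1).  ``C_0`` is the bare genome.  The module provides a
deterministic ODE propagator, an exact stochastic (Gillespie) simulator
acting as an independent oracle, and the self-consistent equilibrium
solution, which is a truncated geometric occupancy distribution with
ratio ``X_S / K_inv`` where ``K_inv = k_minus / k_plus`` is the critical
subunit concentration.

All concentrations are molar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .chemistry import N_A
from .exceptions import (
    ConservationError,
    InfeasibleEquilibriumError,
    SolverError,
    SubcriticalRegimeWarning,
    ValidationError,
)

__all__ = [
    "KineticParameters",
    "MixtureComposition",
    "ComplexDistribution",
    "GillespieResult",
    "default_n_max",
    "propagate_ode",
    "simulate_gillespie",
    "equilibrium_distribution",
    "equilibrium_mean_approx",
    "moments",
    "trajectory_to_dataframe",
]

#: Default relative tolerance for the stiff ODE integrator.
DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and truncation order of the binding ladder.

    Attributes
    ----------
    k_plus : float
        Forward (binding) rate constant, M^-1 s^-1.  Must be positive.
    k_minus : float
        Backward (unbinding) rate constant, s^-1.  Must be non-negative.
    n_max : int
        Largest complex order retained; the ladder is truncated there.
    """

    k_plus: float
    k_minus: float
    n_max: int

    def __post_init__(self) -> None:
        if not self.k_plus > 0:
            raise ValidationError("k_plus must be positive")
        if self.k_minus < 0:
            raise ValidationError("k_minus must be non-negative")
        if int(self.n_max) != self.n_max or self.n_max < 1:
            raise ValidationError("n_max must be a positive integer")

    @property
    def K_inv(self) -> float:
        """Critical subunit concentration ``k_minus / k_plus`` (M)."""
        return self.k_minus / self.k_plus


@dataclass(frozen=True)
class MixtureComposition:
    """Total molar concentrations of subunits and genome.

    ``rho`` is the subunit-to-genome mass ratio and ``m_ratio`` the molar
    ratio per unit mass ratio, so that ``c_S / c_G = rho * m_ratio`` when
    both are provided.
    """

    c_S: float
    c_G: float
    rho: float | None = None
    m_ratio: float | None = None

    def __post_init__(self) -> None:
        if not self.c_S > 0:
            raise ValidationError("c_S must be positive")
        if self.c_G < 0:
            raise ValidationError("c_G must be non-negative")
        if self.rho is not None and self.m_ratio is not None and self.c_G > 0:
            expected = self.rho * self.m_ratio
            if not math.isclose(self.c_S / self.c_G, expected, rel_tol=1e-6):
                raise ValidationError(
                    "c_S/c_G inconsistent with rho * m_ratio "
                    f"({self.c_S / self.c_G:.6g} vs {expected:.6g})"
                )

    @classmethod
    def from_mass_ratio(
        cls, c_S: float, rho: float, m_ratio: float
    ) -> "MixtureComposition":
        """Build a composition from ``c_S`` and a mass ratio."""
        if rho <= 0 or m_ratio <= 0:
            raise ValidationError("rho and m_ratio must be positive")
        return cls(c_S=c_S, c_G=c_S / (rho * m_ratio), rho=rho, m_ratio=m_ratio)


@dataclass
class ComplexDistribution:
    """Molar concentrations of N-th order complexes plus free subunits.

    ``X[N]`` is the concentration of complexes carrying ``N`` subunits
    (``X[0]`` is the bare genome) and ``X_S`` the free-subunit
    concentration.
    """

    X: np.ndarray
    X_S: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 1:
            raise ValidationError("X must be one-dimensional")
        if self.X.size and self.X.min() < 0:
            raise ValidationError("complex concentrations must be non-negative")
        if self.X_S < 0:
            raise ValidationError("free subunit concentration must be non-negative")

    @property
    def n_max(self) -> int:
        return len(self.X) - 1

    @property
    def orders(self) -> np.ndarray:
        return np.arange(len(self.X))

    def total_genome(self) -> float:
        return float(self.X.sum())

    def total_subunit(self) -> float:
        return float(self.X_S + self.orders @ self.X)

    def validate(self, comp: MixtureComposition, rtol: float = 1e-6) -> None:
        """Check both conservation laws against a composition."""
        scale_g = max(comp.c_G, comp.c_S)
        if abs(self.total_genome() - comp.c_G) > rtol * scale_g:
            raise ConservationError(
                f"genome not conserved: sum X = {self.total_genome():.6g}, "
                f"c_G = {comp.c_G:.6g}"
            )
        if abs(self.total_subunit() - comp.c_S) > rtol * comp.c_S:
            raise ConservationError(
                f"subunits not conserved: X_S + sum N X = "
                f"{self.total_subunit():.6g}, c_S = {comp.c_S:.6g}"
            )

    @classmethod
    def bare_genome(
        cls, comp: MixtureComposition, n_max: int
    ) -> "ComplexDistribution":
        """All genome bare, all subunits free."""
        X = np.zeros(n_max + 1)
        X[0] = comp.c_G
        return cls(X=X, X_S=comp.c_S)


def default_n_max(comp: MixtureComposition, cap: int = 500) -> int:
    """Default ladder truncation: 3x the subunit-to-genome molar ratio.

    Far above any realistic mean occupancy, capped to keep the ODE cheap.
    """
    if comp.c_G <= 0:
        return 1
    return int(min(cap, math.ceil(3.0 * comp.c_S / comp.c_G)))


def _rhs_factory(params: KineticParameters, comp: MixtureComposition):
    n = params.n_max
    kp, km = params.k_plus, params.k_minus
    c_S = comp.c_S
    orders = np.arange(n + 1, dtype=float)

    def rhs(_t: float, X: np.ndarray) -> np.ndarray:
        x_s = c_S - orders @ X
        b = kp * x_s
        dX = np.zeros_like(X)
        up = b * X[:-1]
        down = km * X[1:]
        dX[1:] += up
        dX[:-1] -= up
        dX[:-1] += down
        dX[1:] -= down
        return dX

    # structure matrices for the analytic Jacobian
    A = np.zeros((n + 1, n + 1))
    idx = np.arange(n)
    A[idx + 1, idx] += 1.0
    A[idx, idx] -= 1.0
    B = np.zeros((n + 1, n + 1))
    B[idx, idx + 1] += 1.0
    B[idx + 1, idx + 1] -= 1.0

    def jac(_t: float, X: np.ndarray) -> np.ndarray:
        x_s = c_S - orders @ X
        g = A @ X
        return kp * x_s * A + km * B - kp * np.outer(g, orders)

    return rhs, jac


def propagate_ode(
    params: KineticParameters,
    comp: MixtureComposition,
    init: ComplexDistribution,
    times,
    rtol: float = DEFAULT_RTOL,
) -> list[ComplexDistribution]:
    """Integrate the ladder master equation at the requested times.

    ``init`` is taken as the state at ``times[0]``.  Free subunits are
    eliminated through conservation, so the state vector is ``X`` alone
    and ``X_S`` is recomputed at each output.  A stiff (BDF) integrator
    with an analytic Jacobian is used; rate constants in this problem
    span milliseconds to hours.

    Raises
    ------
    ValidationError
        If ``times`` is not strictly increasing / non-negative or the
        initial state violates a conservation law.
    SolverError
        If the integrator does not converge.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing and >= 0")
    if len(init.X) != params.n_max + 1:
        raise ValidationError("init length inconsistent with n_max")
    init.validate(comp)

    orders = np.arange(params.n_max + 1, dtype=float)

    def to_state(X: np.ndarray) -> ComplexDistribution:
        X = np.where(np.abs(X) < 1e-30 * max(comp.c_G, comp.c_S, 1e-300), 0.0, X)
        floor = -1e-6 * max(comp.c_G, comp.c_S)
        if X.min() < floor:
            raise SolverError(
                f"integrator produced a significantly negative concentration "
                f"({X.min():.3g})"
            )
        X = np.clip(X, 0.0, None)
        x_s = comp.c_S - float(orders @ X)
        return ComplexDistribution(X=X, X_S=max(x_s, 0.0))

    if len(times) == 1:
        return [to_state(init.X.copy())]

    rhs, jac = _rhs_factory(params, comp)
    atol = 1e-12 * max(comp.c_S, comp.c_G)
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        init.X,
        method="BDF",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")
    return [to_state(sol.y[:, i]) for i in range(sol.y.shape[1])]


@dataclass
class GillespieResult:
    """Stochastic trajectory of per-genome occupancies.

    ``occupancies`` has shape ``(len(times), n_genome_copies)`` and holds
    the integer number of bound subunits on each genome copy at each
    output time.  ``events`` is optionally a ``(t, genome, +-1)`` record
    of every reaction.
    """

    times: np.ndarray
    occupancies: np.ndarray
    free_subunits: np.ndarray
    volume_litres: float
    n_subunits_total: int
    events: dict | None = None
    seed: int | None = None

    @property
    def mean_occupancy(self) -> np.ndarray:
        return self.occupancies.mean(axis=1)

    @property
    def sem_occupancy(self) -> np.ndarray:
        n = self.occupancies.shape[1]
        return self.occupancies.std(axis=1, ddof=1) / math.sqrt(n)


def simulate_gillespie(
    params: KineticParameters,
    comp: MixtureComposition,
    n_genome_copies: int,
    seed: int,
    t_end: float,
    times=None,
    record_events: bool = False,
) -> GillespieResult:
    """Exact stochastic simulation of the binding ladder.

    A single well-mixed volume is chosen so that ``c_G`` maps exactly to
    ``n_genome_copies``; the total subunit copy number follows from
    ``c_S``.  Unbinding fires at rate ``k_minus`` per occupied genome
    (one channel per complex, matching the master equation), binding at
    rate ``k_plus / (N_A V)`` per free subunit per unsaturated genome.

    Identical seeds give bitwise-identical trajectories.
    """
    if n_genome_copies < 1:
        raise ValidationError("n_genome_copies must be >= 1")
    if comp.c_G <= 0:
        raise ValidationError("stochastic simulation needs c_G > 0")
    if t_end <= 0:
        raise ValidationError("t_end must be positive")

    volume = n_genome_copies / (N_A * comp.c_G)  # litres
    n_subunits = int(round(comp.c_S * N_A * volume))
    if n_subunits < 1:
        raise ValidationError(
            "copy number too small: total subunit count maps to < 1 molecule"
        )
    kb = params.k_plus / (N_A * volume)  # per (free subunit, genome) pair, s^-1
    km = params.k_minus
    n_max = params.n_max

    if times is None:
        times = np.linspace(0.0, t_end, 51)
    times = np.asarray(times, dtype=float)
    if times[0] < 0 or times[-1] > t_end or np.any(np.diff(times) < 0):
        raise ValidationError("output times must lie in [0, t_end], sorted")

    rng = np.random.default_rng(seed)
    occ = np.zeros(n_genome_copies, dtype=np.int64)
    s_free = n_subunits
    n_occupied = 0  # genomes with occ > 0
    n_open = n_genome_copies  # genomes with occ < n_max

    out_occ = np.empty((len(times), n_genome_copies), dtype=np.int64)
    out_free = np.empty(len(times), dtype=np.int64)
    k_out = 0
    ev_t: list[float] = []
    ev_g: list[int] = []
    ev_d: list[int] = []

    t = 0.0
    while True:
        a_bind = kb * s_free * n_open
        a_unb = km * n_occupied
        a_tot = a_bind + a_unb
        t_next = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else math.inf
        # flush snapshots for output times passed before the next event
        while k_out < len(times) and times[k_out] <= min(t_next, t_end):
            out_occ[k_out] = occ
            out_free[k_out] = s_free
            k_out += 1
        if t_next >= t_end or a_tot <= 0:
            break
        t = t_next
        if rng.random() * a_tot < a_bind:
            while True:  # uniform among genomes below n_max
                i = int(rng.integers(n_genome_copies))
                if occ[i] < n_max:
                    break
            occ[i] += 1
            s_free -= 1
            if occ[i] == 1:
                n_occupied += 1
            if occ[i] == n_max:
                n_open -= 1
            delta = 1
        else:
            if 3 * n_occupied >= n_genome_copies:
                while True:  # rejection sampling is cheap when many occupied
                    i = int(rng.integers(n_genome_copies))
                    if occ[i] > 0:
                        break
            else:
                nz = np.flatnonzero(occ)
                i = int(nz[rng.integers(len(nz))])
            if occ[i] == n_max:
                n_open += 1
            occ[i] -= 1
            s_free += 1
            if occ[i] == 0:
                n_occupied -= 1
            delta = -1
        if record_events:
            ev_t.append(t)
            ev_g.append(i)
            ev_d.append(delta)

    while k_out < len(times):  # times at/after t_end or absorbing state
        out_occ[k_out] = occ
        out_free[k_out] = s_free
        k_out += 1

    events = None
    if record_events:
        events = {
            "t": np.asarray(ev_t),
            "genome": np.asarray(ev_g, dtype=np.int64),
            "delta": np.asarray(ev_d, dtype=np.int64),
        }
    return GillespieResult(
        times=times,
        occupancies=out_occ,
        free_subunits=out_free,
        volume_litres=volume,
        n_subunits_total=n_subunits,
        events=events,
        seed=seed,
    )


def _truncated_geometric(ratio: float, n_max: int) -> np.ndarray:
    """Normalized occupancy probabilities p_N proportional to ratio**N."""
    n = np.arange(n_max + 1, dtype=float)
    if ratio <= 0:
        p = np.zeros(n_max + 1)
        p[0] = 1.0
        return p
    logw = n * math.log(ratio)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def equilibrium_distribution(
    params: KineticParameters, comp: MixtureComposition
) -> ComplexDistribution:
    """Self-consistent equilibrium state of the ladder.

    Detailed balance forces ``X[N+1]/X[N] = X_S / K_inv``: the occupancy
    distribution is a (truncated) geometric one.  The free-subunit
    concentration is the unique root of the subunit conservation law,
    found by bracketed root finding on ``(0, c_S)``; the bound-subunit
    total is monotone in ``X_S`` so the root is unique.
    """
    if params.K_inv <= 0:
        raise ValidationError("equilibrium requires K_inv > 0 (k_minus > 0)")
    n_max = params.n_max
    if comp.c_G <= 0:
        return ComplexDistribution(X=np.zeros(n_max + 1), X_S=comp.c_S)

    orders = np.arange(n_max + 1, dtype=float)

    def excess(x_s: float) -> float:
        p = _truncated_geometric(x_s / params.K_inv, n_max)
        return x_s + comp.c_G * float(orders @ p) - comp.c_S

    lo, hi = 0.0, comp.c_S
    if excess(lo) >= 0 or excess(hi) <= 0:
        raise InfeasibleEquilibriumError(
            "no self-consistent free-subunit concentration in (0, c_S)"
        )
    try:
        x_s = brentq(excess, lo, hi, xtol=1e-18 * comp.c_S, rtol=1e-14)
    except RuntimeError as err:  # pragma: no cover - brentq is robust here
        raise InfeasibleEquilibriumError(str(err)) from err
    p = _truncated_geometric(x_s / params.K_inv, n_max)
    return ComplexDistribution(X=comp.c_G * p, X_S=float(x_s))


def distribution_with_mean(
    comp: MixtureComposition, n_max: int, mean: float
) -> ComplexDistribution:
    """Truncated-geometric distribution with a prescribed mean occupancy.

    Used to reconstruct a plausible initial state from a single measured
    occupancy (e.g. the first frame of a dilution experiment, where the
    pre-assembled complexes sat at a ladder equilibrium).
    """
    if not 0 <= mean < n_max:
        raise ValidationError("mean must lie in [0, n_max)")
    bound = comp.c_G * mean
    if bound > comp.c_S:
        raise ValidationError("prescribed mean exceeds the available subunits")
    orders = np.arange(n_max + 1, dtype=float)
    if mean == 0:
        return ComplexDistribution.bare_genome(comp, n_max)

    def gap(log_r: float) -> float:
        p = _truncated_geometric(math.exp(log_r), n_max)
        return float(orders @ p) - mean

    lo, hi = -50.0, 50.0
    root = brentq(gap, lo, hi, rtol=1e-14)
    p = _truncated_geometric(math.exp(root), n_max)
    return ComplexDistribution(X=comp.c_G * p, X_S=comp.c_S - bound)


def equilibrium_mean_approx(c_S: float, c_G: float, K_inv: float) -> float:
    """Linearized equilibrium mean occupancy ``(c_S - K_inv) / c_G``.

    Valid when complexes are far from saturation.  At or below the
    critical concentration the mean is reported as 0 with a warning
    rather than a negative number.
    """
    if c_S <= 0 or c_G <= 0 or K_inv < 0:
        raise ValidationError("concentrations must be positive, K_inv >= 0")
    if c_S <= K_inv:
        warnings.warn(
            "c_S <= K_inv: sub-critical regime, mean occupancy reported as 0",
            SubcriticalRegimeWarning,
            stacklevel=2,
        )
        return 0.0
    return (c_S - K_inv) / c_G


def moments(dist: ComplexDistribution) -> tuple[float, float]:
    """First and second moments of the occupancy distribution.

    Returns ``(<N>, <N^2>)`` with ``<N> = sum N X[N] / sum X[N]``.
    """
    total = dist.X.sum()
    if total <= 0:
        raise ValidationError("moments undefined: total complex concentration is 0")
    n = dist.orders
    p = dist.X / total
    mean = float(n @ p)
    second = float((n.astype(float) ** 2) @ p)
    return mean, second


def trajectory_to_dataframe(times, states: list[ComplexDistribution]):
    """Tabulate an ODE trajectory: time_s, X_0..X_nmax, X_S, mean_N."""
    import pandas as pd

    rows = {}
    rows["time_s"] = np.asarray(times, dtype=float)
    n_max = states[0].n_max
    Xmat = np.stack([s.X for s in states])
    for n in range(n_max + 1):
        rows[f"X_{n}"] = Xmat[:, n]
    rows["X_S"] = np.array([s.X_S for s in states])
    rows["mean_N"] = np.array([moments(s)[0] for s in states])
    return pd.DataFrame(rows)
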