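"""Fitted quantities: relaxation times, critical concentration, binding
free energy, diffusion-limited rate constants, activation energy, and
the kinetic-model fit to forward-intensity traces.

Conventions
-----------
* Weighted fits use 1/sigma^2 weights; points with zero sigma get the
  median positive weight.
* Two-phase exponential fits report time constants sorted ascending;
  the "binding time" convention is the longest one.
* Temperatures are kelvin; energies are reported both in J/mol and in
  units of k_B*T0 with T0 = 298 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .chemistry import N_A, R, T0
from .exceptions import (
    FitConvergenceError,
    SaturatedRegimeError,
    ValidationError,
)
from .kinetics import (
    ComplexDistribution,
    KineticParameters,
    MixtureComposition,
    propagate_ode,
)
from .scattering import ContrastSet, ObservableTrace, forward_intensity

__all__ = [
    "ExponentialFitResult",
    "ArrheniusFitResult",
    "CriticalConcentrationFit",
    "FreeEnergyResult",
    "KineticFit",
    "fit_exponential",
    "fit_critical_concentration",
    "binding_free_energy",
    "diffusion_limited_rate",
    "apparent_diffusion",
    "fit_arrhenius",
    "fit_kinetic_params",
]


@dataclass
class ExponentialFitResult:
    """Single- or double-exponential fit of a rise or decay trace."""

    n_phases: int
    direction: str
    amplitudes: np.ndarray
    taus: np.ndarray
    tau_sems: np.ndarray
    amplitude_sems: np.ndarray
    offset: float
    offset_sem: float
    through_origin: bool
    covariance: np.ndarray
    chi2: float
    aic: float

    @property
    def binding_time(self) -> float:
        """Longest time constant (reporting convention for rises)."""
        return float(self.taus[-1])

    @property
    def fast_time(self) -> float:
        return float(self.taus[0])


def _exp_model(direction: str, n_phases: int, through_origin: bool):
    def model(t, *p):
        amps = p[:n_phases]
        taus = p[n_phases : 2 * n_phases]
        offset = 0.0 if through_origin else p[-1]
        y = np.full_like(t, offset, dtype=float)
        for a, tau in zip(amps, taus):
            if direction == "rise":
                y = y + a * (1.0 - np.exp(-t / tau))
            else:
                y = y + a * np.exp(-t / tau)
        return y

    return model


def _fit_weights(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    pos = sigma > 0
    if not pos.any():
        return np.ones_like(sigma)
    out = sigma.copy()
    out[~pos] = np.median(sigma[pos])
    return out


def fit_exponential(
    trace: ObservableTrace,
    n_phases: int = 1,
    direction: str = "decay",
    through_origin: bool = False,
) -> ExponentialFitResult:
    """Weighted nonlinear least-squares exponential fit.

    Rises are modelled as ``offset + sum_i A_i (1 - exp(-t/tau_i))`` and
    decays as ``offset + sum_i A_i exp(-t/tau_i)``; ``through_origin``
    removes the constant term.  Double exponentials are notoriously
    degenerate, so initialization is a multi-start over a log-spaced
    grid of time-constant candidates with amplitudes profiled linearly.
    """
    if direction not in ("rise", "decay"):
        raise ValidationError("direction must be 'rise' or 'decay'")
    if n_phases not in (1, 2):
        raise ValidationError("n_phases must be 1 or 2")
    n_free = 2 * n_phases + (0 if through_origin else 1)
    if len(trace) < 3 * n_free:
        raise ValidationError(
            f"need at least {3 * n_free} points for {n_free} free parameters"
        )
    t = trace.t
    y = trace.value
    sigma = _fit_weights(trace.sigma)
    model = _exp_model(direction, n_phases, through_origin)

    dt = np.diff(np.unique(t))
    tau_lo = max(dt[dt > 0].min(), 1e-12)
    t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    grid = np.geomspace(tau_lo, 3.0 * t_span, 10)
    candidates = (
        [(tau,) for tau in grid]
        if n_phases == 1
        else list(combinations(grid, 2))
    )

    def profile_amplitudes(taus):
        cols = []
        for tau in taus:
            cols.append(
                1.0 - np.exp(-t / tau) if direction == "rise" else np.exp(-t / tau)
            )
        if not through_origin:
            cols.append(np.ones_like(t))
        A = np.column_stack(cols) / sigma[:, None]
        b = y / sigma
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = A @ coef - b
        return coef, float(resid @ resid)

    best = None
    for taus in candidates:
        try:
            coef, ssr = profile_amplitudes(taus)
        except np.linalg.LinAlgError:
            continue
        if best is None or ssr < best[2]:
            best = (taus, coef, ssr)
    if best is None:
        raise FitConvergenceError("no viable initialization found")

    taus0, coef0, _ = best
    p0 = list(coef0[: n_phases]) + list(taus0)
    if not through_origin:
        p0.append(coef0[-1])
    lower = [-np.inf] * n_phases + [tau_lo / 100.0] * n_phases
    upper = [np.inf] * n_phases + [1e4 * t_span] * n_phases
    if not through_origin:
        lower.append(-np.inf)
        upper.append(np.inf)
    p0 = np.clip(p0, lower, upper)

    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            y,
            p0=p0,
            sigma=sigma,
            absolute_sigma=True,
            bounds=(lower, upper),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as err:
        raise FitConvergenceError(f"exponential fit failed: {err}") from err

    taus = popt[n_phases : 2 * n_phases]
    if np.any(taus >= 0.999e4 * t_span):
        raise FitConvergenceError("time constant hit the upper bound")

    order = np.argsort(taus)
    perm = np.concatenate(
        [order, n_phases + order, [2 * n_phases]] if not through_origin
        else [order, n_phases + order]
    ).astype(int)
    popt = popt[perm]
    pcov = pcov[np.ix_(perm, perm)]
    sems = np.sqrt(np.clip(np.diag(pcov), 0.0, None))

    resid = (model(t, *popt) - y) / sigma
    chi2 = float(resid @ resid)
    aic = chi2 + 2.0 * n_free
    return ExponentialFitResult(
        n_phases=n_phases,
        direction=direction,
        amplitudes=popt[:n_phases],
        taus=popt[n_phases : 2 * n_phases],
        tau_sems=sems[n_phases : 2 * n_phases],
        amplitude_sems=sems[:n_phases],
        offset=0.0 if through_origin else float(popt[-1]),
        offset_sem=0.0 if through_origin else float(sems[-1]),
        through_origin=through_origin,
        covariance=pcov,
        chi2=chi2,
        aic=aic,
    )


@dataclass
class CriticalConcentrationFit:
    """Through-origin fit of equilibrium mean occupancy against mass ratio."""

    slope: float
    slope_sem: float
    K_inv: float
    K_inv_sem: float
    c_S: float
    m_ratio: float


def fit_critical_concentration(
    pairs, c_S: float, m_ratio: float
) -> CriticalConcentrationFit:
    """Estimate the critical concentration from a titration series.

    ``pairs`` is a sequence of ``(rho, n_inf)`` or ``(rho, n_inf, sem)``
    tuples.  At fixed ``c_S`` the ladder model predicts the equilibrium
    mean occupancy to be proportional to rho with slope
    ``m_ratio * (1 - K_inv / c_S)``; a weighted through-origin
    regression inverts that for ``K_inv``.
    """
    if c_S <= 0 or m_ratio <= 0:
        raise ValidationError("c_S and m_ratio must be positive")
    arr = np.atleast_2d(np.asarray(pairs, dtype=float))
    if arr.shape[0] < 2:
        raise ValidationError("need at least 2 (rho, N_inf) pairs")
    rho = arr[:, 0]
    n_inf = arr[:, 1]
    sem = arr[:, 2] if arr.shape[1] > 2 else np.ones_like(rho)
    sem = _fit_weights(sem)
    w = 1.0 / sem**2
    denom = float(w @ rho**2)
    if denom <= 0:
        raise ValidationError("degenerate titration design")
    slope = float(w @ (rho * n_inf)) / denom
    if arr.shape[1] > 2:
        var_slope = 1.0 / denom
    else:  # unweighted: scale by residual variance
        resid = n_inf - slope * rho
        dof = max(len(rho) - 1, 1)
        var_slope = float(resid @ resid) / dof / denom
    if slope > m_ratio:
        raise SaturatedRegimeError(
            f"slope {slope:.4g} exceeds m_ratio {m_ratio:.4g}: "
            "implies a negative critical concentration"
        )
    k_inv = c_S * (1.0 - slope / m_ratio)
    k_inv_sem = c_S * math.sqrt(var_slope) / m_ratio
    return CriticalConcentrationFit(
        slope=slope,
        slope_sem=math.sqrt(var_slope),
        K_inv=k_inv,
        K_inv_sem=k_inv_sem,
        c_S=c_S,
        m_ratio=m_ratio,
    )


@dataclass
class FreeEnergyResult:
    """Binding free energy derived from the critical concentration."""

    g_joule_per_mol: float
    g_kbt0: float
    temperature: float
    reference_conc: float


def binding_free_energy(
    k_inv: float, temperature: float = T0, reference_conc: float = 1.0
) -> FreeEnergyResult:
    """G = R T ln(K_inv / c_ref).

    The reference concentration is an explicit parameter (default the
    conventional 1 M standard state) because reported values depend
    strongly on that convention.
    """
    if k_inv <= 0 or reference_conc <= 0 or temperature <= 0:
        raise ValidationError("k_inv, reference_conc, temperature must be positive")
    g = R * temperature * math.log(k_inv / reference_conc)
    return FreeEnergyResult(
        g_joule_per_mol=g,
        g_kbt0=g / (R * T0),
        temperature=temperature,
        reference_conc=reference_conc,
    )


def diffusion_limited_rate(r_c: float, d_s: float) -> float:
    """Smoluchowski rate constant ``4 pi N_A R_C D_S`` in M^-1 s^-1.

    ``r_c`` is the capture radius in meters and ``d_s`` the diffusion
    coefficient in m^2/s; the litre/molar conversion is handled here.
    """
    if r_c <= 0 or d_s <= 0:
        raise ValidationError("r_c and d_s must be positive")
    return 4.0 * math.pi * N_A * r_c * d_s * 1000.0


def apparent_diffusion(k_plus: float, r_c: float) -> float:
    """Diffusion coefficient implied by a rate constant (inverse of above)."""
    if k_plus <= 0 or r_c <= 0:
        raise ValidationError("k_plus and r_c must be positive")
    return k_plus / (4.0 * math.pi * N_A * r_c * 1000.0)


@dataclass
class ArrheniusFitResult:
    """Linear fit of ln(tau) against 1/T."""

    e_a_joule_per_mol: float
    e_a_kbt0: float
    e_a_sem_joule_per_mol: float
    e_a_sem_kbt0: float
    prefactor: float
    intercept_sem: float


def fit_arrhenius(points) -> ArrheniusFitResult:
    """Activation energy from ``tau proportional to exp(E_a / k_B T)``.

    ``points`` is a sequence of ``(temperature_K, tau_s)`` pairs; a
    linear regression of ln(tau) on 1/T gives ``E_a / R`` as the slope.
    """
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[0] < 3:
        raise ValidationError("need at least 3 temperatures")
    temp = arr[:, 0]
    tau = arr[:, 1]
    if np.any(temp <= 0):
        raise ValidationError("temperatures must be positive kelvin")
    if np.any(tau <= 0):
        raise ValidationError("time constants must be positive")
    res = stats.linregress(1.0 / temp, np.log(tau))
    e_a = res.slope * R
    e_sem = res.stderr * R
    return ArrheniusFitResult(
        e_a_joule_per_mol=e_a,
        e_a_kbt0=e_a / (R * T0),
        e_a_sem_joule_per_mol=e_sem,
        e_a_sem_kbt0=e_sem / (R * T0),
        prefactor=math.exp(res.intercept),
        intercept_sem=res.intercept_stderr,
    )


@dataclass
class KineticFit:
    """Rate constants fitted to a forward-intensity trace."""

    k_plus: float
    k_plus_sem: float
    k_minus: float
    k_minus_sem: float | None
    k_minus_floated: bool
    d_s: float
    r_c: float
    chi2: float
    chi2_reduced: float
    n_points: int


def fit_kinetic_params(
    trace: ObservableTrace,
    comp: MixtureComposition,
    contrast: ContrastSet,
    params0: KineticParameters,
    r_c: float,
    float_k_minus: bool = False,
    init: ComplexDistribution | None = None,
    rtol: float = 1e-8,
) -> KineticFit:
    """Fit the ladder rate constants to an I0(t) trace.

    The model curve is the ODE propagator composed with the forward
    intensity.  ``params0`` provides the starting point and the ladder
    truncation; when ``float_k_minus`` is false, ``k_minus`` is pinned
    to ``params0.k_plus``-scaled critical concentration (i.e. K_inv is
    held at its supplied value while k_plus floats).  The apparent
    diffusion coefficient follows from the Smoluchowski relation at the
    capture radius ``r_c`` (meters).
    """
    t = np.asarray(trace.t, dtype=float)
    if len(t) < (3 if not float_k_minus else 4):
        raise ValidationError("trace too short to constrain the rate constants")
    if np.any(trace.sigma > 0):
        sigma = _fit_weights(trace.sigma)
    else:  # noiseless trace: scale residuals to O(1)
        sigma = np.full(len(t), np.max(np.abs(trace.value)))
    k_inv0 = params0.K_inv
    if init is None:
        init = ComplexDistribution.bare_genome(comp, params0.n_max)

    t_solve = t if t[0] == 0 else np.concatenate([[0.0], t])
    skip = 0 if t[0] == 0 else 1

    def model(theta) -> np.ndarray:
        k_plus = math.exp(theta[0])
        k_minus = math.exp(theta[1]) if float_k_minus else k_plus * k_inv0
        params = KineticParameters(
            k_plus=k_plus, k_minus=k_minus, n_max=params0.n_max
        )
        states = propagate_ode(params, comp, init, t_solve, rtol=rtol)
        return np.array([forward_intensity(s, contrast) for s in states[skip:]])

    def residuals(theta) -> np.ndarray:
        return (model(theta) - trace.value) / sigma

    x0 = [math.log(params0.k_plus)]
    if float_k_minus:
        x0.append(math.log(max(params0.k_minus, 1e-30)))
    result = optimize.least_squares(
        residuals, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not result.success:
        raise FitConvergenceError(f"kinetic fit failed: {result.message}")
    jtj = result.jac.T @ result.jac
    if np.linalg.cond(jtj) > 1e12:
        raise FitConvergenceError("kinetic fit is non-identifiable (flat objective)")
    cov = np.linalg.inv(jtj)
    sems_log = np.sqrt(np.diag(cov))
    k_plus = math.exp(result.x[0])
    k_plus_sem = k_plus * sems_log[0]
    if float_k_minus:
        k_minus = math.exp(result.x[1])
        k_minus_sem = k_minus * sems_log[1]
    else:
        k_minus = k_plus * k_inv0
        k_minus_sem = None
    chi2 = float(result.fun @ result.fun)
    dof = max(len(t) - len(result.x), 1)
    return KineticFit(
        k_plus=k_plus,
        k_plus_sem=k_plus_sem,
        k_minus=k_minus,
        k_minus_sem=k_minus_sem,
        k_minus_floated=float_k_minus,
        d_s=apparent_diffusion(k_plus, r_c),
        r_c=r_c,
        chi2=chi2,
        chi2_reduced=chi2 / dof,
        n_points=len(t),
    )
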