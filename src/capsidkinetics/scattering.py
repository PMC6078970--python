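"""Scattering observables of subunit/genome mixtures.

Maps occupancy distributions to forward intensities, inverts measured
forward intensities to a distribution-free upper bound on the mean
occupancy, and extracts (I0, R_g) from 1-D curves with an iterative
Guinier fit.

The forward intensity of a mixture of free subunits and N-th order
complexes is

    I0 = db_S^2 X_S + sum_N X[N] (db_G + db_S N)^2

with db_G, db_S the excess scattering lengths of genome and subunit.
Because I0 depends on both <N> and <N^2>, the mean cannot be recovered
without distributional assumptions; the quantity

    N_up = sqrt(Gamma^2 + (I0 - I0*) / (db_S^2 c_G)) - Gamma,
    Gamma = db_G / db_S - 1/2,
    I0*   = db_G^2 c_G + db_S^2 c_S   (pre-complexation baseline)

is an upper bound on <N> for any occupancy distribution (Jensen), with
equality exactly when the distribution has zero variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    InconsistentIntensityError,
    NegativeExcessWarning,
    NonGuinierCurveError,
    ValidationError,
)
from .kinetics import (
    ComplexDistribution,
    MixtureComposition,
    _truncated_geometric,
)

__all__ = [
    "ContrastSet",
    "ScatteringCurve",
    "ObservableTrace",
    "ValueWithError",
    "GuinierFit",
    "forward_intensity",
    "baseline_intensity",
    "n_up_from_intensity",
    "guinier_fit",
    "guinier_traces",
    "n_up_trace",
    "form_factor_trace",
    "n_mean_templated_from_intensity",
]

#: Default instrument window (inverse angstroms).
DEFAULT_Q_WINDOW = (3.3e-3, 0.26)


@dataclass(frozen=True)
class ContrastSet:
    """Excess scattering lengths of genome and subunit.

    Units are arbitrary but must be consistent with the absolute
    intensity scale of the curves being analyzed.  ``gamma`` is always
    derived, never stored.
    """

    db_G: float
    db_S: float

    def __post_init__(self) -> None:
        if self.db_S == 0:
            raise ValidationError("db_S must be non-zero")

    @property
    def gamma(self) -> float:
        """Gamma = db_G/db_S - 1/2."""
        return self.db_G / self.db_S - 0.5


@dataclass
class ScatteringCurve:
    """1-D scattering pattern: q (1/A, strictly increasing), I, sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValidationError("q, I, sigma must have equal lengths")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class ObservableTrace:
    """Time-stamped scalar observable with standard errors."""

    t: np.ndarray
    value: np.ndarray
    sigma: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.t) == len(self.value) == len(self.sigma)):
            raise ValidationError("t, value, sigma must have equal lengths")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("t must be non-decreasing")
        if np.any(self.sigma < 0):
            raise ValidationError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ValueWithError:
    value: float
    sigma: float


def forward_intensity(dist: ComplexDistribution, contrast: ContrastSet) -> float:
    """Forward intensity I0 of a complex distribution (exact, no noise)."""
    n = dist.orders.astype(float)
    term = dist.X @ (contrast.db_G + contrast.db_S * n) ** 2
    return float(contrast.db_S**2 * dist.X_S + term)


def baseline_intensity(comp: MixtureComposition, contrast: ContrastSet) -> float:
    """Pre-complexation forward intensity I0* = db_G^2 c_G + db_S^2 c_S."""
    return contrast.db_G**2 * comp.c_G + contrast.db_S**2 * comp.c_S


def n_up_from_intensity(
    i0: float,
    sigma_i0: float,
    comp: MixtureComposition,
    contrast: ContrastSet,
    clip_negative: bool = True,
) -> ValueWithError:
    """Distribution-free upper bound on the mean occupancy from I0.

    Parameters
    ----------
    i0, sigma_i0 : float
        Measured forward intensity and its standard error (absolute
        units consistent with ``contrast``).
    clip_negative : bool
        Clip a small negative intensity excess (within 3 sigma of zero)
        to zero with a warning instead of failing; early-time frames
        routinely sit at the baseline.

    Notes
    -----
    For ``gamma < 0`` (e.g. a contrast-matched genome gives
    gamma = -1/2) the inversion is monotone only for means >= -gamma;
    results below 1/2 are floored at 0 in that case.
    """
    if comp.c_G <= 0:
        raise ValidationError("n_up undefined for c_G = 0")
    if sigma_i0 < 0:
        raise ValidationError("sigma_i0 must be non-negative")
    i0_star = baseline_intensity(comp, contrast)
    excess = (i0 - i0_star) / (contrast.db_S**2 * comp.c_G)
    if excess < 0:
        if i0 < i0_star - 3.0 * sigma_i0 or not clip_negative:
            raise InconsistentIntensityError(
                f"I0 = {i0:.6g} lies more than 3 sigma below the baseline "
                f"I0* = {i0_star:.6g}"
            )
        warnings.warn(
            "negative intensity excess within noise clipped to 0",
            NegativeExcessWarning,
            stacklevel=2,
        )
        excess = 0.0
    gamma = contrast.gamma
    root = math.sqrt(gamma**2 + excess)
    value = root - gamma
    if gamma < 0 and value < 0.5:
        value = 0.0
    sigma = sigma_i0 / (2.0 * contrast.db_S**2 * comp.c_G * root) if root > 0 else 0.0
    return ValueWithError(value=float(value), sigma=float(sigma))


@dataclass
class GuinierFit:
    """Result of an iterative Guinier fit."""

    i0: float
    i0_sigma: float
    rg: float
    rg_sigma: float
    n_points: int
    q_window: tuple[float, float]
    chi2: float


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    s = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    delta = s * sxx - sx * sx
    if delta <= 0:
        raise NonGuinierCurveError("degenerate design matrix in Guinier window")
    slope = (s * sxy - sx * sy) / delta
    intercept = (sxx * sy - sx * sxy) / delta
    var_slope = s / delta
    var_intercept = sxx / delta
    chi2 = float((w * (y - intercept - slope * x) ** 2).sum())
    return slope, intercept, var_slope, var_intercept, chi2


def guinier_fit(
    curve: ScatteringCurve,
    q_rg_max: float = 1.3,
    min_points: int = 5,
    max_iter: int = 100,
) -> GuinierFit:
    """Extract (I0, R_g) from the low-q region of a curve.

    A weighted linear fit of ln I against q^2 is iterated to
    self-consistency over the largest low-q window satisfying
    ``q * R_g <= q_rg_max``.  Weights are ``(I / sigma)^2``, i.e.
    inverse-variance weights of ln I.

    Raises
    ------
    NonGuinierCurveError
        If the fitted slope is non-negative.
    ValidationError
        If fewer than ``min_points`` usable points remain in the window.
    """
    pos = curve.I > 0
    if pos.sum() < min_points:
        raise ValidationError("too few positive-intensity points for a Guinier fit")
    q = curve.q[pos]
    i = curve.I[pos]
    sig = curve.sigma[pos]
    x = q**2
    y = np.log(i)
    w = (i / sig) ** 2

    n0 = max(min_points, len(q) // 5)
    mask = np.zeros(len(q), dtype=bool)
    mask[:n0] = True
    for _ in range(max_iter):
        if mask.sum() < min_points:
            raise ValidationError(
                f"Guinier window contains fewer than {min_points} points"
            )
        slope, intercept, v_s, v_i, chi2 = _wls_line(x[mask], y[mask], w[mask])
        if slope >= 0:
            raise NonGuinierCurveError(
                "non-negative low-q slope: curve has no Guinier regime"
            )
        rg = math.sqrt(-3.0 * slope)
        new_mask = q <= q_rg_max / rg
        if new_mask.sum() < min_points:
            new_mask = np.zeros(len(q), dtype=bool)
            new_mask[:min_points] = True
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    i0 = math.exp(intercept)
    qw = (float(q[mask][0]), float(q[mask][-1]))
    return GuinierFit(
        i0=i0,
        i0_sigma=i0 * math.sqrt(v_i),
        rg=rg,
        rg_sigma=3.0 * math.sqrt(v_s) / (2.0 * rg),
        n_points=int(mask.sum()),
        q_window=qw,
        chi2=chi2,
    )


def guinier_traces(
    times, curves: list[ScatteringCurve], **kwargs
) -> tuple[ObservableTrace, ObservableTrace]:
    """Per-frame Guinier analysis of a curve series: (I0(t), R_g(t))."""
    fits = [guinier_fit(c, **kwargs) for c in curves]
    t = np.asarray(times, dtype=float)
    i0 = ObservableTrace(
        t=t,
        value=np.array([f.i0 for f in fits]),
        sigma=np.array([f.i0_sigma for f in fits]),
        name="I0",
    )
    rg = ObservableTrace(
        t=t,
        value=np.array([f.rg for f in fits]),
        sigma=np.array([f.rg_sigma for f in fits]),
        name="Rg",
    )
    return i0, rg


def n_up_trace(
    i0_trace: ObservableTrace,
    comp: MixtureComposition,
    contrast: ContrastSet,
) -> ObservableTrace:
    """Convert an I0(t) trace into the mean-occupancy upper-bound trace."""
    vals, sigs = [], []
    for i0, s in zip(i0_trace.value, i0_trace.sigma):
        r = n_up_from_intensity(i0, s, comp, contrast)
        vals.append(r.value)
        sigs.append(r.sigma)
    return ObservableTrace(
        t=i0_trace.t, value=np.array(vals), sigma=np.array(sigs), name="N_up"
    )


def form_factor_trace(
    times,
    curves: list[ScatteringCurve],
    q_probe: float = 0.033,
    q_band: float = 0.0,
    background: ScatteringCurve | None = None,
    **guinier_kwargs,
) -> ObservableTrace:
    """Normalized form factor P(q_probe) as a function of time.

    Each frame is normalized by its own Guinier-extrapolated I0 so that
    P(0) = 1, then linearly interpolated at ``q_probe``.  With
    ``q_band > 0`` the probe is instead an inverse-variance-weighted
    average over the relative band ``|q - q_probe| <= q_band * q_probe``,
    which trades q-resolution for counting statistics.  An optional
    background curve (e.g. a model of the free-subunit contribution) is
    subtracted before normalization.
    """
    vals, sigs = [], []
    for c in curves:
        if not (c.q[0] <= q_probe <= c.q[-1]):
            raise ValidationError(
                f"q_probe = {q_probe} outside curve range "
                f"[{c.q[0]:.4g}, {c.q[-1]:.4g}]"
            )
        if background is not None:
            bg = np.interp(c.q, background.q, background.I)
            bg_sig = np.interp(c.q, background.q, background.sigma)
            c = ScatteringCurve(
                q=c.q, I=c.I - bg, sigma=np.hypot(c.sigma, bg_sig)
            )
        fit = guinier_fit(c, **guinier_kwargs)
        if q_band > 0:
            sel = np.abs(c.q - q_probe) <= q_band * q_probe
            if not sel.any():
                raise ValidationError("q_band selects no points")
            w = 1.0 / c.sigma[sel] ** 2
            i_probe = float((w @ c.I[sel]) / w.sum())
            sig_probe = float(math.sqrt(1.0 / w.sum()))
        else:
            i_probe = float(np.interp(q_probe, c.q, c.I))
            sig_probe = float(np.interp(q_probe, c.q, c.sigma))
        p = i_probe / fit.i0
        sig = math.hypot(
            sig_probe / fit.i0, p * fit.i0_sigma / fit.i0
        )
        vals.append(p)
        sigs.append(sig)
    return ObservableTrace(
        t=np.asarray(times, dtype=float),
        value=np.array(vals),
        sigma=np.array(sigs),
        name=f"P(q={q_probe:g})",
    )


def n_mean_templated_from_intensity(
    i0: float,
    comp: MixtureComposition,
    contrast: ContrastSet,
    n_max: int,
) -> float:
    """Mean occupancy implied by I0 under the equilibrium ladder model.

    Assumes the occupancy distribution is the truncated geometric one of
    the templated ladder at equilibrium and solves for its ratio so that
    the model forward intensity matches ``i0``.  This is the
    model-dependent counterpart of the distribution-free upper bound.
    """
    if comp.c_G <= 0:
        raise ValidationError("undefined for c_G = 0")
    orders = np.arange(n_max + 1, dtype=float)

    def model_i0(ratio: float) -> float:
        p = _truncated_geometric(ratio, n_max)
        X = comp.c_G * p
        bound = float(orders @ X)
        x_s = comp.c_S - bound
        if x_s < 0:
            x_s = 0.0
        term = float(X @ (contrast.db_G + contrast.db_S * orders) ** 2)
        return contrast.db_S**2 * x_s + term

    lo, hi = 0.0, 1.0
    # expand hi until the model intensity brackets i0 (monotone in ratio)
    f_lo = model_i0(lo) - i0
    if f_lo >= 0:
        return 0.0
    for _ in range(200):
        if model_i0(hi) - i0 > 0:
            break
        hi *= 2.0
    else:
        raise InconsistentIntensityError(
            "I0 exceeds the saturated-ladder model intensity"
        )
    ratio = brentq(lambda r: model_i0(r) - i0, lo, hi, rtol=1e-13)
    p = _truncated_geometric(ratio, n_max)
    return float(orders @ p)
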