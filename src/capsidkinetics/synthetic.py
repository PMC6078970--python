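"""Synthetic time-resolved scattering data with known ground truth.

Frame series emulate stopped-flow TR-SAXS/SANS acquisitions: the ladder
ODE supplies per-frame occupancy distributions, each scattering species
contributes ``(excess scattering length)^2 * concentration * P(q)`` with
a configurable form factor, and Gaussian photon-counting-like noise with
variance proportional to intensity is added.  The zero-angle limit of
every generated frame equals the forward intensity of its ground-truth
distribution exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .formfactors import (
    core_shell_form_factor,
    gaussian_chain_form_factor,
    smeared_shell_form_factor,
    sphere_form_factor,
)
from .chemistry import sphere_radius_from_rg
from .kinetics import (
    ComplexDistribution,
    KineticParameters,
    MixtureComposition,
    propagate_ode,
)
from .scattering import ContrastSet, ObservableTrace, ScatteringCurve

__all__ = [
    "ContrastModel",
    "SpeciesShapes",
    "StructuralRelaxation",
    "NoiseModel",
    "GeneratorConfig",
    "FrameSeries",
    "generate_frame_series",
    "generate_observable_traces",
    "log_frame_times",
]

#: D2O volume fraction at which ssRNA is contrast matched.
GENOME_MATCH_D2O = 0.68


@dataclass(frozen=True)
class ContrastModel:
    """Excess scattering lengths with optional solvent-deuteration handling.

    When ``d2o_fraction`` is set, each component's excess scattering
    length is scaled linearly towards zero at its match fraction, which
    reproduces contrast matching (the genome term vanishes at 68% D2O).
    """

    db_G: float
    db_S: float
    d2o_fraction: float | None = None
    genome_match: float = GENOME_MATCH_D2O
    subunit_match: float = 0.42

    def effective(self) -> ContrastSet:
        if self.d2o_fraction is None:
            return ContrastSet(db_G=self.db_G, db_S=self.db_S)
        f = self.d2o_fraction
        if not 0 <= f <= 1:
            raise ValidationError("d2o_fraction must lie in [0, 1]")
        db_g = self.db_G * (1.0 - f / self.genome_match)
        db_s = self.db_S * (1.0 - f / self.subunit_match)
        return ContrastSet(db_G=db_g, db_S=db_s)


@dataclass(frozen=True)
class SpeciesShapes:
    """Form-factor geometry of each scattering species (angstroms)."""

    subunit_rg: float = 33.0
    genome_rg: float = 140.0
    npc_r_in: float = 90.0
    npc_r_out: float = 120.0
    npc_fuzz: float = 20.0
    npc_core_contrast: float = 0.0


@dataclass(frozen=True)
class StructuralRelaxation:
    """Mixing weight w(t) between the fuzzy and sharp complex shapes.

    ``w(t) = 1 - sum_i a_i exp(-t / tau_i)``: the complex form factor
    interpolates linearly from a fuzzy shell towards the sharp shell as
    w goes from ``1 - sum a_i`` at t = 0 to 1 at long times.  Weights
    summing to 1 start fully fuzzy; summing to 0 starts (and stays)
    fully relaxed.
    """

    taus: tuple[float, ...] = (48.0,)
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if len(self.taus) != len(self.weights):
            raise ValidationError("taus and weights must have equal lengths")
        if any(tau <= 0 for tau in self.taus):
            raise ValidationError("relaxation times must be positive")
        if any(w < 0 for w in self.weights) or sum(self.weights) > 1.0 + 1e-9:
            raise ValidationError("relaxation weights must be >= 0 and sum to <= 1")

    def mixing(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = np.ones_like(t)
        for a, tau in zip(self.weights, self.taus):
            w = w - a * np.exp(-t / tau)
        return w


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise with variance I/flux (photon-limit approximation)."""

    flux: float = 1e6
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.flux <= 0:
            raise ValidationError("flux must be positive")


@dataclass
class GeneratorConfig:
    """Full description of a synthetic frame-series experiment."""

    params: KineticParameters
    comp: MixtureComposition
    contrast: ContrastModel
    times: np.ndarray
    q: np.ndarray
    shapes: SpeciesShapes = field(default_factory=SpeciesShapes)
    relaxation: StructuralRelaxation = field(default_factory=StructuralRelaxation)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    init: ComplexDistribution | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be positive and strictly increasing")


@dataclass
class FrameSeries:
    """Generated curves plus per-frame ground truth."""

    times: np.ndarray
    curves: list[ScatteringCurve]
    distributions: list[ComplexDistribution]
    true_i0: np.ndarray
    contrast: ContrastSet
    config: GeneratorConfig


def log_frame_times(
    t_end: float, n_frames: int = 50, t_start: float = 5e-3
) -> np.ndarray:
    """Log-spaced frame times from the exposure floor to experiment end."""
    if not 0 < t_start < t_end:
        raise ValidationError("need 0 < t_start < t_end")
    return np.geomspace(t_start, t_end, n_frames)


def _model_intensity(
    q: np.ndarray,
    dist: ComplexDistribution,
    t: float,
    contrast: ContrastSet,
    shapes: SpeciesShapes,
    relaxation: StructuralRelaxation,
) -> np.ndarray:
    """Noise-free mixture intensity at one time point."""
    p_sub = sphere_form_factor(q, sphere_radius_from_rg(shapes.subunit_rg))
    p_gen = gaussian_chain_form_factor(q, shapes.genome_rg)
    p_sharp = core_shell_form_factor(
        q, shapes.npc_r_in, shapes.npc_r_out, shapes.npc_core_contrast
    )
    p_fuzzy = smeared_shell_form_factor(
        q, shapes.npc_r_in, shapes.npc_r_out, shapes.npc_fuzz,
        shapes.npc_core_contrast,
    )
    w = float(relaxation.mixing(t))
    p_npc = (1.0 - w) * p_fuzzy + w * p_sharp

    n = dist.orders.astype(float)
    weights = dist.X * (contrast.db_G + contrast.db_S * n) ** 2
    i_q = contrast.db_S**2 * dist.X_S * p_sub
    i_q = i_q + weights[0] * p_gen  # bare genome scatters as a chain
    i_q = i_q + weights[1:].sum() * p_npc
    return i_q


def model_intensity_at(
    config: GeneratorConfig, dist: ComplexDistribution, t: float, q
) -> np.ndarray:
    """Evaluate the generator's noise-free model at arbitrary q (incl. 0)."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return _model_intensity(
        q, dist, t, config.contrast.effective(), config.shapes, config.relaxation
    )


def generate_frame_series(config: GeneratorConfig) -> FrameSeries:
    """Generate a TR frame series with per-frame ground truth.

    Deterministic for a fixed seed.  Raises if the kinetics solver
    cannot cover the requested times.
    """
    contrast = config.contrast.effective()
    init = config.init
    if init is None:
        init = ComplexDistribution.bare_genome(config.comp, config.params.n_max)
    times = config.times
    t_solve = times if times[0] == 0 else np.concatenate([[0.0], times])
    states = propagate_ode(config.params, config.comp, init, t_solve)
    if times[0] != 0:
        states = states[1:]

    rng = np.random.default_rng(config.seed)
    curves = []
    true_i0 = []
    from .scattering import forward_intensity  # local import avoids a cycle

    for t, dist in zip(times, states):
        i_q = _model_intensity(
            config.q, dist, t, contrast, config.shapes, config.relaxation
        )
        sigma = np.sqrt(np.clip(i_q, 1e-300, None) / config.noise.flux)
        i_obs = i_q + rng.normal(0.0, sigma) if config.noise.enabled else i_q
        curves.append(ScatteringCurve(q=config.q, I=i_obs, sigma=sigma))
        true_i0.append(forward_intensity(dist, contrast))
    return FrameSeries(
        times=times,
        curves=curves,
        distributions=states,
        true_i0=np.asarray(true_i0),
        contrast=contrast,
        config=config,
    )


def generate_observable_traces(
    truth: dict, times, seed: int = 0
) -> tuple[ObservableTrace, dict]:
    """Analytic exponential-phase trace plus seeded Gaussian noise.

    ``truth`` keys: ``phases`` (list of ``(amplitude, tau)``),
    ``baseline`` (constant term, default 0), ``direction`` ("rise" or
    "decay"), and ``noise`` (absolute standard deviation; 0 disables).
    The ground truth is echoed back for recovery studies.
    """
    times = np.asarray(times, dtype=float)
    phases = truth["phases"]
    baseline = float(truth.get("baseline", 0.0))
    direction = truth.get("direction", "rise")
    noise = float(truth.get("noise", 0.0))
    if direction not in ("rise", "decay"):
        raise ValidationError("direction must be 'rise' or 'decay'")
    if noise < 0:
        raise ValidationError("noise must be non-negative")
    y = np.full_like(times, baseline)
    for amp, tau in phases:
        if tau <= 0:
            raise ValidationError("time constants must be positive")
        if direction == "rise":
            y = y + amp * (1.0 - np.exp(-times / tau))
        else:
            y = y + amp * np.exp(-times / tau)
    rng = np.random.default_rng(seed)
    if noise > 0:
        y = y + rng.normal(0.0, noise, size=len(times))
    sigma = np.full_like(times, noise if noise > 0 else 0.0)
    trace = ObservableTrace(t=times, value=y, sigma=sigma, name=truth.get("name", ""))
    return trace, dict(truth)
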