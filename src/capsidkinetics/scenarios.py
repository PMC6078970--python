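"""Canonical synthetic experiment scenarios.

Three scripted scenarios exercise the full pipeline end to end with
known ground truth:

* ``en_masse``     - rapid binding of subunits on the template followed
                     by slow structural reorganization (mass ratio 6).
* ``dilution``     - twofold dilution of pre-assembled complexes
                     releasing subunits.
* ``ph_relaxation``- slow simultaneous binding and structural relaxation
                     after a pH drop (synchronous regime).

Each builder returns a ``GeneratorConfig`` plus a ground-truth dict with
every generating time constant.
"""

from __future__ import annotations

import numpy as np

from .kinetics import (
    ComplexDistribution,
    KineticParameters,
    MixtureComposition,
    default_n_max,
    equilibrium_distribution,
)
from .synthetic import (
    ContrastModel,
    GeneratorConfig,
    NoiseModel,
    SpeciesShapes,
    StructuralRelaxation,
    generate_frame_series,
    log_frame_times,
)

__all__ = ["SCENARIOS", "build_scenario"]

DEFAULT_Q = np.geomspace(3.3e-3, 0.26, 150)


def _flux_for(rel_sigma: float, i0: float) -> float:
    """Flux giving a relative noise ``rel_sigma`` at intensity ``i0``."""
    return 1.0 / (rel_sigma**2 * i0)


def en_masse(seed: int = 0, noise: bool = True, rel_sigma: float = 0.015):
    """Fast en-masse binding (tau ~ 28 ms), slow relaxation (3 s, 48 s)."""
    comp = MixtureComposition.from_mass_ratio(24.6e-6, rho=6.0, m_ratio=25.0)
    tau_bind = 0.028
    k_plus = 1.0 / (tau_bind * comp.c_G)
    k_inv = 13.6e-6
    n_max = default_n_max(comp)
    params = KineticParameters(k_plus=k_plus, k_minus=k_plus * k_inv, n_max=n_max)
    relaxation = StructuralRelaxation(taus=(48.0,), weights=(1.0,))
    times = log_frame_times(300.0, n_frames=48, t_start=5e-3)
    i0_final = 1.6e-3  # order of magnitude of the equilibrium intensity
    config = GeneratorConfig(
        params=params,
        comp=comp,
        contrast=ContrastModel(db_G=3.0, db_S=1.0),
        times=times,
        q=DEFAULT_Q.copy(),
        relaxation=relaxation,
        noise=NoiseModel(flux=_flux_for(rel_sigma, i0_final), enabled=noise),
        seed=seed,
    )
    truth = {
        "scenario": "en_masse",
        "workflow": "assembly",
        "struc_phases": 1,
        "q_probe": 0.044,
        "q_band": 0.2,
        "tau_bind": tau_bind,
        "tau_struc": 48.0,
        "k_plus": k_plus,
        "K_inv": k_inv,
        "pathway": "en_masse",
    }
    return config, truth


def dilution(seed: int = 0, noise: bool = True, rel_sigma: float = 0.02):
    """Unbinding after twofold dilution of pre-assembled complexes."""
    comp_pre = MixtureComposition.from_mass_ratio(24.6e-6, rho=5.5, m_ratio=25.0)
    comp = MixtureComposition.from_mass_ratio(12.3e-6, rho=5.5, m_ratio=25.0)
    tau_unbind = 204.0
    k_plus = 1.0 / (tau_unbind * comp.c_G)
    k_inv = 11.2e-6
    n_max = default_n_max(comp_pre)
    params = KineticParameters(k_plus=k_plus, k_minus=k_plus * k_inv, n_max=n_max)
    pre = equilibrium_distribution(params, comp_pre)
    init = ComplexDistribution(X=pre.X / 2.0, X_S=pre.X_S / 2.0)
    times = log_frame_times(1500.0, n_frames=44, t_start=0.05)
    config = GeneratorConfig(
        params=params,
        comp=comp,
        contrast=ContrastModel(db_G=3.0, db_S=1.0),
        times=times,
        q=DEFAULT_Q.copy(),
        relaxation=StructuralRelaxation(taus=(1.0,), weights=(0.0,)),
        noise=NoiseModel(flux=_flux_for(rel_sigma, 9e-4), enabled=noise),
        seed=seed,
        init=init,
    )
    # complexes start structurally relaxed: weight 0 on the fuzzy shape
    truth = {
        "scenario": "dilution",
        "workflow": "dilution",
        "tau_unbind": tau_unbind,
        "k_plus": k_plus,
        "K_inv": k_inv,
    }
    return config, truth


def ph_relaxation(seed: int = 0, noise: bool = True, rel_sigma: float = 0.015):
    """Slow synchronous binding (3100 s) and relaxation (150 s, 2920 s)."""
    comp = MixtureComposition.from_mass_ratio(21.15e-6, rho=5.5, m_ratio=25.0)
    tau_bind = 3100.0
    k_plus = 1.0 / (tau_bind * comp.c_G)
    n_target = 85.0
    k_inv = comp.c_S - n_target * comp.c_G
    n_max = default_n_max(comp)
    params = KineticParameters(k_plus=k_plus, k_minus=k_plus * k_inv, n_max=n_max)
    # pre-assembled state: equilibrium of the weaker-binding (neutral pH) ladder
    n_init = 75.0
    k_inv_old = comp.c_S - n_init * comp.c_G
    params_old = KineticParameters(
        k_plus=k_plus, k_minus=k_plus * k_inv_old, n_max=n_max
    )
    init = equilibrium_distribution(params_old, comp)
    relaxation = StructuralRelaxation(taus=(150.0, 2920.0), weights=(0.4, 0.6))
    times = log_frame_times(30000.0, n_frames=64, t_start=10.0)
    config = GeneratorConfig(
        params=params,
        comp=comp,
        contrast=ContrastModel(db_G=3.0, db_S=1.0),
        times=times,
        q=DEFAULT_Q.copy(),
        shapes=SpeciesShapes(npc_fuzz=30.0),
        relaxation=relaxation,
        noise=NoiseModel(flux=_flux_for(rel_sigma, 1.5e-3), enabled=noise),
        seed=seed,
        init=init,
    )
    truth = {
        "scenario": "ph_relaxation",
        "workflow": "relaxation",
        "struc_phases": 2,
        "q_probe": 0.044,
        "q_band": 0.2,
        "tau_bind": tau_bind,
        "tau_struc_fast": 150.0,
        "tau_struc": 2920.0,
        "k_plus": k_plus,
        "K_inv": k_inv,
        "pathway": "synchronous",
    }
    return config, truth


SCENARIOS = {
    "en_masse": en_masse,
    "assembly": en_masse,
    "dilution": dilution,
    "ph_relaxation": ph_relaxation,
    "relaxation": ph_relaxation,
}


def build_scenario(name: str, seed: int = 0, noise: bool = True):
    """Build a named scenario; returns (FrameSeries, truth dict)."""
    try:
        builder = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario '{name}'; choose from {sorted(set(SCENARIOS))}"
        ) from None
    config, truth = builder(seed=seed, noise=noise)
    return generate_frame_series(config), truth
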