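"""Workflow orchestration: curve series -> traces -> fitted quantities.

Workflows mirror the experimental analyses:

* ``assembly``   - mixing experiment; single-exponential rise of the
                   occupancy bound from the origin (binding time) plus a
                   two-phase structural relaxation of the form factor.
* ``dilution``   - decay of the occupancy bound (unbinding time).
* ``relaxation`` - slow rise from a pre-assembled state plus form-factor
                   relaxation; binding and structure compared to label
                   the pathway.
* ``titration``  - equilibrium occupancy against mass ratio giving the
                   critical concentration and binding free energy.
* ``arrhenius``  - binding times at several temperatures giving the
                   activation energy.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import sasio
from .estimators import (
    apparent_diffusion,
    binding_free_energy,
    fit_arrhenius,
    fit_critical_concentration,
    fit_exponential,
)
from .estimators import fit_kinetic_params
from .exceptions import ValidationError
from .kinetics import (
    KineticParameters,
    MixtureComposition,
    default_n_max,
    distribution_with_mean,
)
from .scattering import (
    ContrastSet,
    ObservableTrace,
    baseline_intensity,
    form_factor_trace,
    guinier_traces,
    n_mean_templated_from_intensity,
    n_up_trace,
)

logger = logging.getLogger("capsidkinetics")

WORKFLOWS = ("assembly", "dilution", "relaxation", "arrhenius", "titration")


@dataclass
class ExperimentConfig:
    """Declarative description of one analysis run."""

    workflow: str
    data_dir: str | None = None
    c_S: float = 24.6e-6
    c_G: float | None = None
    rho: float | None = None
    m_ratio: float = 25.0
    db_G: float = 3.0
    db_S: float = 1.0
    q_probe: float = 0.033
    q_band: float = 0.0
    n_up_phases: int = 1
    struc_phases: int = 2
    struc_after_factor: float | None = None
    reference_conc: float = 1.0
    r_c: float = 120e-10
    temperature: float = 293.15
    en_masse_ratio: float = 10.0
    synchronous_ratio: float = 3.0
    titration_runs: list = field(default_factory=list)
    tau_points: list = field(default_factory=list)
    temperature_runs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValidationError(
                f"workflow must be one of {WORKFLOWS}, got '{self.workflow}'"
            )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"{path}: unknown config fields {sorted(unknown)}"
            )
        return cls(**raw)

    def composition(self) -> MixtureComposition:
        if self.c_G is not None:
            return MixtureComposition(
                c_S=self.c_S, c_G=self.c_G, rho=self.rho,
                m_ratio=self.m_ratio if self.rho is not None else None,
            )
        if self.rho is None:
            raise ValidationError("config needs either c_G or rho")
        return MixtureComposition.from_mass_ratio(self.c_S, self.rho, self.m_ratio)

    def contrast(self) -> ContrastSet:
        return ContrastSet(db_G=self.db_G, db_S=self.db_S)


def classify_pathway(
    tau_bind: float,
    tau_struc: float,
    en_masse_ratio: float = 10.0,
    synchronous_ratio: float = 3.0,
) -> str:
    """Label the assembly pathway from the two time constants.

    ``en_masse`` when structure lags binding by at least
    ``en_masse_ratio``; ``synchronous`` when the two are within
    ``synchronous_ratio`` of each other; ``indeterminate`` otherwise.
    """
    if tau_bind <= 0 or tau_struc <= 0:
        raise ValidationError("time constants must be positive")
    ratio = tau_struc / tau_bind
    if ratio >= en_masse_ratio:
        return "en_masse"
    if ratio <= synchronous_ratio:
        return "synchronous"
    return "indeterminate"


def _trace_dict(trace: ObservableTrace) -> dict:
    return {
        "t": trace.t.tolist(),
        "value": trace.value.tolist(),
        "sigma": trace.sigma.tolist(),
    }


def _expfit_dict(fit) -> dict:
    return {
        "n_phases": fit.n_phases,
        "direction": fit.direction,
        "amplitudes": fit.amplitudes.tolist(),
        "taus": fit.taus.tolist(),
        "tau_sems": fit.tau_sems.tolist(),
        "offset": fit.offset,
        "offset_sem": fit.offset_sem,
        "through_origin": fit.through_origin,
        "chi2": fit.chi2,
        "aic": fit.aic,
    }


def extract_traces(
    times,
    curves,
    comp: MixtureComposition,
    contrast: ContrastSet,
    q_probe: float = 0.033,
    q_band: float = 0.0,
) -> dict:
    """Guinier, occupancy-bound and form-factor traces for one series."""
    i0, rg = guinier_traces(times, curves)
    traces = {"I0": i0, "Rg": rg, "N_up": n_up_trace(i0, comp, contrast)}
    traces["P_probe"] = form_factor_trace(
        times, curves, q_probe=q_probe, q_band=q_band
    )
    return traces


def _kinetic_model_inversion(
    cfg: ExperimentConfig, comp, contrast, i0_trace, tau_guess: float
) -> dict | None:
    """Fit the ladder model to the I0(t) trace.

    The tail of the trace pins the equilibrium; for mixing experiments
    (bare-genome start) the critical concentration is fixed from the
    tail and only k_plus floats, otherwise the initial state is
    reconstructed from the first frame and k_minus floats as well.
    Returns None when the trace carries no usable excess intensity.
    """
    n_max = default_n_max(comp)
    n_tail = max(3, len(i0_trace) // 4)
    try:
        n_inf = float(np.mean([
            n_mean_templated_from_intensity(v, comp, contrast, n_max)
            for v in i0_trace.value[-n_tail:]
        ]))
    except ValidationError:
        return None
    k_inv_est = comp.c_S - comp.c_G * n_inf
    if k_inv_est <= 0 or n_inf <= 0:
        return None
    k_plus0 = 1.0 / (max(tau_guess, 1e-12) * comp.c_G)
    params0 = KineticParameters(
        k_plus=k_plus0, k_minus=k_plus0 * k_inv_est, n_max=n_max
    )
    if cfg.workflow == "assembly":
        init = None  # bare genome
        float_k_minus = False
    else:
        n_0 = n_mean_templated_from_intensity(
            float(i0_trace.value[0]), comp, contrast, n_max
        )
        init = distribution_with_mean(comp, n_max, n_0)
        float_k_minus = True
    fit = fit_kinetic_params(
        i0_trace, comp, contrast, params0, cfg.r_c,
        float_k_minus=float_k_minus, init=init,
    )
    return {
        "k_plus_per_M_s": fit.k_plus,
        "k_plus_sem_per_M_s": fit.k_plus_sem,
        "k_minus_per_s": fit.k_minus,
        "k_minus_floated": fit.k_minus_floated,
        "K_inv_M": fit.k_minus / fit.k_plus,
        "tau_model_s": 1.0 / (fit.k_plus * comp.c_G),
        "d_s_m2_s": fit.d_s,
        "chi2_reduced": fit.chi2_reduced,
    }


def _analyze_binding_and_structure(cfg: ExperimentConfig, times, curves) -> dict:
    comp = cfg.composition()
    contrast = cfg.contrast()
    traces = extract_traces(
        times, curves, comp, contrast, cfg.q_probe, cfg.q_band
    )
    logger.info(
        "workflow=%s frames=%d baseline=%.4g",
        cfg.workflow, len(curves), baseline_intensity(comp, contrast),
    )

    rise_origin = cfg.workflow == "assembly"
    n_up_fit = fit_exponential(
        traces["N_up"],
        n_phases=cfg.n_up_phases,
        direction="rise" if cfg.workflow != "dilution" else "decay",
        through_origin=rise_origin,
    )
    report = {
        "workflow": cfg.workflow,
        "traces": {k: _trace_dict(v) for k, v in traces.items()},
        "fits": {"n_up": _expfit_dict(n_up_fit)},
        "derived": {},
    }
    model = _kinetic_model_inversion(
        cfg, comp, contrast, traces["I0"], n_up_fit.binding_time
    )
    if model is not None:
        report["fits"]["kinetic_model"] = model

    if cfg.workflow == "dilution":
        report["derived"]["tau_unbind_s"] = n_up_fit.binding_time
        if model is not None:
            report["derived"]["tau_unbind_model_s"] = model["tau_model_s"]
        return report

    tau_bind = n_up_fit.binding_time
    report["derived"]["tau_bind_s"] = tau_bind
    if model is not None:
        report["derived"]["tau_bind_model_s"] = model["tau_model_s"]
        report["derived"]["k_plus_model_per_M_s"] = model["k_plus_per_M_s"]
        report["derived"]["d_s_model_m2_s"] = model["d_s_m2_s"]
    k_plus_apparent = 1.0 / (tau_bind * comp.c_G)
    report["derived"]["k_plus_apparent_per_M_s"] = k_plus_apparent
    report["derived"]["d_s_apparent_m2_s"] = apparent_diffusion(
        k_plus_apparent, cfg.r_c
    )

    p_trace = traces["P_probe"]
    factor = cfg.struc_after_factor
    if factor is None:
        factor = 20.0 if cfg.workflow == "assembly" else 0.0
    if factor > 0:
        keep = p_trace.t >= factor * tau_bind
        if keep.sum() >= 3 * (2 * cfg.struc_phases):
            p_trace = ObservableTrace(
                t=p_trace.t[keep], value=p_trace.value[keep],
                sigma=p_trace.sigma[keep], name=p_trace.name,
            )
    struc_fit = fit_exponential(
        p_trace, n_phases=cfg.struc_phases, direction="decay",
        through_origin=False,
    )
    report["fits"]["form_factor"] = _expfit_dict(struc_fit)
    tau_struc = struc_fit.binding_time
    report["derived"]["tau_struc_s"] = tau_struc
    if struc_fit.n_phases == 2:
        report["derived"]["tau_struc_fast_s"] = struc_fit.fast_time
    report["classification"] = classify_pathway(
        tau_bind, tau_struc, cfg.en_masse_ratio, cfg.synchronous_ratio
    )
    return report


def _equilibrium_occupancy(cfg, rho, times, curves) -> tuple[float, float]:
    """Templated-model occupancy near equilibrium (tail of the series)."""
    comp = MixtureComposition.from_mass_ratio(cfg.c_S, rho, cfg.m_ratio)
    contrast = cfg.contrast()
    i0, _ = guinier_traces(times, curves)
    n_tail = max(3, len(times) // 4)
    n_max = default_n_max(comp)
    vals = [
        n_mean_templated_from_intensity(v, comp, contrast, n_max)
        for v in i0.value[-n_tail:]
    ]
    return float(np.mean(vals)), float(np.std(vals, ddof=1) / np.sqrt(len(vals)))


def run_workflow(
    config: ExperimentConfig,
    series: dict | None = None,
) -> dict:
    """Execute a workflow and return a JSON-serializable report.

    ``series`` optionally supplies pre-loaded data instead of reading
    from ``config.data_dir``: for single-series workflows a dict with
    ``times`` and ``curves``; for titration a mapping
    ``{rho: (times, curves)}``; for arrhenius a mapping
    ``{temperature_K: (times, curves)}``.
    """
    cfg = config
    if cfg.workflow in ("assembly", "dilution", "relaxation"):
        if series is not None:
            times, curves = series["times"], series["curves"]
        else:
            if cfg.data_dir is None:
                raise ValidationError("config.data_dir is required")
            times, curves = sasio.read_series(cfg.data_dir)
        return _analyze_binding_and_structure(cfg, times, curves)

    if cfg.workflow == "titration":
        pairs = []
        if series:
            runs = [(rho, data) for rho, data in sorted(series.items())]
        else:
            runs = []
            for entry in cfg.titration_runs:
                rho = float(entry["rho"])
                runs.append((rho, sasio.read_series(entry["data_dir"])))
        for rho, (times, curves) in runs:
            n_inf, sem = _equilibrium_occupancy(cfg, rho, times, curves)
            pairs.append((rho, n_inf, sem if sem > 0 else 1.0))
        fit = fit_critical_concentration(pairs, cfg.c_S, cfg.m_ratio)
        energy = binding_free_energy(
            fit.K_inv, temperature=cfg.temperature,
            reference_conc=cfg.reference_conc,
        )
        return {
            "workflow": "titration",
            "pairs": [list(p) for p in pairs],
            "fits": {"critical_concentration": dataclasses.asdict(fit)},
            "derived": {
                "K_inv_M": fit.K_inv,
                "K_inv_sem_M": fit.K_inv_sem,
                "G_bind_joule_per_mol": energy.g_joule_per_mol,
                "G_bind_kbt0": energy.g_kbt0,
                "reference_conc_M": energy.reference_conc,
            },
        }

    # arrhenius
    points = [(float(t), float(tau)) for t, tau in cfg.tau_points]
    if series:
        for temp, (times, curves) in sorted(series.items()):
            sub = dataclasses.replace(cfg, workflow="relaxation")
            rep = run_workflow(sub, series={"times": times, "curves": curves})
            points.append((float(temp), rep["derived"]["tau_bind_s"]))
    elif cfg.temperature_runs:
        for entry in cfg.temperature_runs:
            times, curves = sasio.read_series(entry["data_dir"])
            sub = dataclasses.replace(cfg, workflow="relaxation")
            rep = run_workflow(sub, series={"times": times, "curves": curves})
            points.append((float(entry["temperature_K"]), rep["derived"]["tau_bind_s"]))
    fit = fit_arrhenius(points)
    return {
        "workflow": "arrhenius",
        "points": [list(p) for p in points],
        "fits": {"arrhenius": dataclasses.asdict(fit)},
        "derived": {
            "E_a_joule_per_mol": fit.e_a_joule_per_mol,
            "E_a_kbt0": fit.e_a_kbt0,
            "E_a_sem_kbt0": fit.e_a_sem_kbt0,
        },
    }
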