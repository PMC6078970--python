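import math
import warnings

import numpy as np
import pytest

from capsidkinetics.exceptions import (
    InconsistentIntensityError,
    NegativeExcessWarning,
    NonGuinierCurveError,
    ValidationError,
)
from capsidkinetics.formfactors import (
    core_shell_form_factor,
    smeared_shell_form_factor,
    sphere_form_factor,
)
from capsidkinetics.kinetics import ComplexDistribution, MixtureComposition, moments
from capsidkinetics.scattering import (
    ContrastSet,
    ObservableTrace,
    ScatteringCurve,
    baseline_intensity,
    form_factor_trace,
    forward_intensity,
    guinier_fit,
    n_mean_templated_from_intensity,
    n_up_from_intensity,
    n_up_trace,
)


def _point_mass(n: int, c_g: float, x_s: float, n_max: int = 30):
    X = np.zeros(n_max + 1)
    X[n] = c_g
    return ComplexDistribution(X=X, X_S=x_s)


class TestContrastSet:
    def test_gamma_derived(self):
        assert ContrastSet(db_G=3.0, db_S=1.0).gamma == pytest.approx(2.5)
        assert ContrastSet(db_G=0.0, db_S=1.0).gamma == pytest.approx(-0.5)

    def test_zero_db_s_rejected(self):
        with pytest.raises(ValidationError):
            ContrastSet(db_G=1.0, db_S=0.0)


class TestForwardIntensity:
    def test_bare_mixture_is_baseline(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        dist = _point_mass(0, c_g=1.0, x_s=12.0)
        assert forward_intensity(dist, simple_contrast) == pytest.approx(
            baseline_intensity(comp, simple_contrast)
        )

    def test_contrast_matched_genome(self):
        con = ContrastSet(db_G=0.0, db_S=2.0)
        dist = _point_mass(5, c_g=1.5, x_s=0.5)
        # db_S^2 (X_S + sum N^2 X_N)
        assert forward_intensity(dist, con) == pytest.approx(
            4.0 * (0.5 + 25 * 1.5)
        )

    def test_degenerate_example(self, simple_contrast):
        dist = _point_mass(10, c_g=1.0, x_s=2.0)
        assert forward_intensity(dist, simple_contrast) == pytest.approx(171.0)


class TestBaselineIntensity:
    def test_no_genome(self, simple_contrast):
        comp = MixtureComposition(c_S=5.0, c_G=0.0)
        assert baseline_intensity(comp, simple_contrast) == pytest.approx(5.0)

    def test_matched_genome(self):
        comp = MixtureComposition(c_S=5.0, c_G=2.0)
        con = ContrastSet(db_G=0.0, db_S=1.0)
        assert baseline_intensity(comp, con) == pytest.approx(5.0)

    def test_arithmetic(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        assert baseline_intensity(comp, simple_contrast) == pytest.approx(21.0)


class TestNUpBound:
    def test_baseline_gives_zero(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        res = n_up_from_intensity(21.0, 0.1, comp, simple_contrast)
        assert res.value == pytest.approx(0.0)

    def test_zero_variance_is_tight(self, simple_contrast):
        # degenerate distribution at N=10: I0 = 171, I0* = 21, Gamma = 2.5
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        res = n_up_from_intensity(171.0, 0.0, comp, simple_contrast)
        assert res.value == pytest.approx(10.0, rel=1e-12)

    def test_geometric_strictly_above_mean(self, simple_contrast):
        r = 0.9
        n = np.arange(1001)
        comp_cg = 1.0
        X = comp_cg * (1 - r) * r**n
        dist = ComplexDistribution(X=X, X_S=0.5)
        comp = MixtureComposition(
            c_S=dist.total_subunit(), c_G=dist.total_genome()
        )
        i0 = forward_intensity(dist, simple_contrast)
        res = n_up_from_intensity(i0, 0.0, comp, simple_contrast)
        mean = moments(dist)[0]
        assert mean == pytest.approx(9.0, rel=1e-6)
        assert res.value > mean

    def test_bound_property_random_distributions(self, simple_contrast, rng):
        # brute-force oracle: build 1000 random occupancy distributions,
        # push them through the exact intensity formula, invert, and check
        # the bound; equality only at zero variance.
        for _ in range(1000):
            n_max = int(rng.integers(1, 120))
            support = rng.random(n_max + 1) < 0.4
            support[int(rng.integers(n_max + 1))] = True
            X = np.where(support, rng.random(n_max + 1), 0.0)
            x_s = float(rng.random())
            dist = ComplexDistribution(X=X, X_S=x_s)
            db_s = float(rng.uniform(0.2, 3.0))
            db_g = float(rng.uniform(0.5, 4.0)) * db_s  # Gamma >= -1/2... keep >= 0
            con = ContrastSet(db_G=db_g, db_S=db_s)
            if con.gamma < 0:
                continue
            comp = MixtureComposition(
                c_S=dist.total_subunit(), c_G=dist.total_genome()
            )
            i0 = forward_intensity(dist, con)
            res = n_up_from_intensity(i0, 0.0, comp, con)
            mean, m2 = moments(dist)
            var = m2 - mean**2
            assert res.value >= mean - 1e-9
            if var > 1e-9:
                assert res.value > mean
            else:
                assert res.value == pytest.approx(mean, abs=1e-9)

    def test_monotone_in_intensity(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        i0s = np.linspace(21.0, 400.0, 50)
        vals = [
            n_up_from_intensity(i, 0.0, comp, simple_contrast).value for i in i0s
        ]
        assert np.all(np.diff(vals) > 0)

    def test_contrast_match_reduction(self):
        # db_G = 0: bound reduces to sqrt(1/4 + excess) + 1/2
        comp = MixtureComposition(c_S=10.0, c_G=1.0)
        con = ContrastSet(db_G=0.0, db_S=1.0)
        i0 = baseline_intensity(comp, con) + 30.0
        res = n_up_from_intensity(i0, 0.0, comp, con)
        assert res.value == pytest.approx(math.sqrt(0.25 + 30.0) + 0.5)

    def test_negative_excess_clipped_with_warning(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        with pytest.warns(NegativeExcessWarning):
            res = n_up_from_intensity(20.9, 0.1, comp, simple_contrast)
        assert res.value == 0.0

    def test_far_below_baseline_rejected(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        with pytest.raises(InconsistentIntensityError):
            n_up_from_intensity(15.0, 0.1, comp, simple_contrast)

    def test_no_genome_rejected(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=0.0)
        with pytest.raises(ValidationError):
            n_up_from_intensity(21.0, 0.1, comp, simple_contrast)

    def test_sigma_propagation(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        sig = 2.0
        res = n_up_from_intensity(171.0, sig, comp, simple_contrast)
        # d N_up / d I0 = 1 / (2 db_S^2 c_G sqrt(Gamma^2 + excess))
        expected = sig / (2.0 * math.sqrt(2.5**2 + 150.0))
        assert res.sigma == pytest.approx(expected, rel=1e-12)


def _gaussian_curve(i0=7.0, rg=50.0, rel_sigma=1e-8, n=80, qmax=0.26):
    q = np.geomspace(3.3e-3, qmax, n)
    I = i0 * np.exp(-(q**2) * rg**2 / 3.0)
    return ScatteringCurve(q=q, I=I, sigma=np.maximum(rel_sigma * I, 1e-300))


class TestGuinier:
    def test_exact_gaussian(self):
        fit = guinier_fit(_gaussian_curve())
        assert fit.i0 == pytest.approx(7.0, rel=1e-9)
        assert fit.rg == pytest.approx(50.0, rel=1e-9)

    def test_sphere_within_2_percent(self):
        radius = 120.0
        q = np.geomspace(3.3e-3, 0.26, 200)
        I = 5.0 * sphere_form_factor(q, radius)
        curve = ScatteringCurve(q=q, I=I, sigma=np.maximum(1e-6 * I, 1e-300))
        fit = guinier_fit(curve)
        assert fit.rg == pytest.approx(math.sqrt(3.0 / 5.0) * radius, rel=0.02)
        assert fit.i0 == pytest.approx(5.0, rel=0.02)

    def test_subunit_scale_noisy_recovery(self, rng):
        # 33 A scatterer with photon-like noise: recovery within a few sem
        rg = 33.0
        q = np.geomspace(3.3e-3, 0.26, 150)
        I = 2e-5 * np.exp(-(q**2) * rg**2 / 3.0)
        sigma = np.sqrt(I / 5e9)
        curve = ScatteringCurve(q=q, I=I + rng.normal(0, sigma), sigma=sigma)
        fit = guinier_fit(curve)
        assert abs(fit.rg - rg) < 4 * fit.rg_sigma
        assert abs(fit.i0 - 2e-5) < 4 * fit.i0_sigma

    def test_window_criterion(self):
        fit = guinier_fit(_gaussian_curve(rg=100.0), q_rg_max=1.3)
        assert fit.q_window[1] * fit.rg <= 1.3 * 1.0001

    def test_flat_curve_rejected(self):
        q = np.geomspace(1e-3, 0.1, 50)
        curve = ScatteringCurve(q=q, I=np.ones(50), sigma=np.ones(50) * 0.01)
        with pytest.raises(NonGuinierCurveError):
            guinier_fit(curve)

    def test_too_few_points_rejected(self):
        q = np.array([0.01, 0.02, 0.03])
        curve = ScatteringCurve(q=q, I=np.exp(-q**2), sigma=np.full(3, 0.01))
        with pytest.raises(ValidationError):
            guinier_fit(curve)


class TestCurveValidation:
    def test_decreasing_q_rejected(self):
        with pytest.raises(ValidationError):
            ScatteringCurve(
                q=np.array([0.2, 0.1]), I=np.ones(2), sigma=np.ones(2)
            )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            ScatteringCurve(
                q=np.array([0.1, 0.2]), I=np.ones(2), sigma=np.array([1.0, 0.0])
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ScatteringCurve(q=np.array([0.1]), I=np.ones(2), sigma=np.ones(2))


class TestObservableTrace:
    def test_time_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ObservableTrace(
                t=np.array([1.0, 0.5]), value=np.ones(2), sigma=np.ones(2)
            )


class TestFormFactorTrace:
    @staticmethod
    def _shell_series(weights, rel_sigma=1e-7):
        q = np.geomspace(3.3e-3, 0.26, 150)
        sharp = core_shell_form_factor(q, 90.0, 120.0)
        fuzzy = smeared_shell_form_factor(q, 90.0, 120.0, 25.0)
        curves = []
        for w in weights:
            I = 3e-3 * ((1 - w) * fuzzy + w * sharp)
            curves.append(
                ScatteringCurve(q=q, I=I, sigma=np.maximum(rel_sigma * I, 1e-300))
            )
        return curves

    def test_constant_series_constant_trace(self):
        curves = self._shell_series([0.3, 0.3, 0.3, 0.3, 0.3])
        trace = form_factor_trace([0, 1, 2, 3, 4], curves, q_probe=0.044)
        assert np.ptp(trace.value) < 1e-6 * abs(trace.value[0])

    def test_linear_in_mixing_coefficient(self):
        ws = np.linspace(0.0, 1.0, 6)
        curves = self._shell_series(ws)
        trace = form_factor_trace(np.arange(6.0), curves, q_probe=0.044)
        coeffs = np.polyfit(ws, trace.value, 1)
        fitted = np.polyval(coeffs, ws)
        # small residual curvature comes only from the per-frame Guinier
        # normalization (window shifts with the changing apparent R_g)
        resid = np.abs(trace.value - fitted)
        assert resid.max() < 0.02 * np.ptp(trace.value)

    def test_slow_constant_recovery_double_exponential(self, rng):
        # exponential relaxation between fuzzy and sharp shells: a
        # two-phase fit of the probe trace recovers the slow constant,
        # mirroring the structural-relaxation analysis (tau ~ 2920 s)
        tau_fast, tau_slow = 150.0, 2920.0
        t = np.geomspace(10.0, 30000.0, 60)
        w = 1.0 - 0.4 * np.exp(-t / tau_fast) - 0.6 * np.exp(-t / tau_slow)
        curves = self._shell_series(w, rel_sigma=5e-3)
        noisy = [
            ScatteringCurve(
                q=c.q, I=c.I + rng.normal(0, c.sigma), sigma=c.sigma
            )
            for c in curves
        ]
        trace = form_factor_trace(t, noisy, q_probe=0.044, q_band=0.2)
        from capsidkinetics.estimators import fit_exponential

        fit = fit_exponential(trace, n_phases=2, direction="decay")
        assert fit.binding_time == pytest.approx(tau_slow, rel=0.10)

    def test_probe_outside_range_rejected(self):
        curves = self._shell_series([0.5])
        with pytest.raises(ValidationError):
            form_factor_trace([0.0], curves, q_probe=0.5)

    def test_background_subtraction(self):
        curves = self._shell_series([0.5, 0.5])
        bg = ScatteringCurve(
            q=curves[0].q,
            I=np.full_like(curves[0].q, 1e-5),
            sigma=np.full_like(curves[0].q, 1e-12),
        )
        raised = [
            ScatteringCurve(q=c.q, I=c.I + 1e-5, sigma=c.sigma) for c in curves
        ]
        t_clean = form_factor_trace([0, 1], curves, q_probe=0.044)
        t_corr = form_factor_trace([0, 1], raised, q_probe=0.044, background=bg)
        np.testing.assert_allclose(t_corr.value, t_clean.value, rtol=1e-4)


class TestTemplatedInversion:
    def test_round_trip_through_equilibrium_shape(self, simple_contrast):
        from capsidkinetics.kinetics import _truncated_geometric

        comp = MixtureComposition(c_S=24.6e-6, c_G=0.164e-6)
        n_max = 300
        p = _truncated_geometric(0.98, n_max)
        X = comp.c_G * p
        orders = np.arange(n_max + 1, dtype=float)
        dist = ComplexDistribution(
            X=X, X_S=comp.c_S - float(orders @ X)
        )
        i0 = forward_intensity(dist, simple_contrast)
        mean = n_mean_templated_from_intensity(i0, comp, simple_contrast, n_max)
        assert mean == pytest.approx(moments(dist)[0], rel=1e-9)

    def test_baseline_maps_to_zero(self, simple_contrast):
        comp = MixtureComposition(c_S=24.6e-6, c_G=0.164e-6)
        i0 = baseline_intensity(comp, simple_contrast)
        assert n_mean_templated_from_intensity(
            i0, comp, simple_contrast, 300
        ) == pytest.approx(0.0, abs=1e-9)


class TestNUpTrace:
    def test_maps_i0_trace(self, simple_contrast):
        comp = MixtureComposition(c_S=12.0, c_G=1.0)
        i0 = ObservableTrace(
            t=np.array([0.0, 1.0]),
            value=np.array([21.0, 171.0]),
            sigma=np.array([0.0, 0.0]),
        )
        trace = n_up_trace(i0, comp, simple_contrast)
        assert trace.value[0] == pytest.approx(0.0)
        assert trace.value[1] == pytest.approx(10.0)
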