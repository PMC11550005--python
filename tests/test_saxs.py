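"""Scattering stack against closed-form sphere/Gaussian oracles."""

import math
import warnings

import numpy as np
import pytest

import sbpconf.saxs as saxs_module
from sbpconf import saxs, structio, synthetic
from sbpconf.errors import FitError
from testutil import sphere_curve, sphere_form_factor, sphere_pr

R_SPHERE = 30.0
RG_SPHERE = math.sqrt(3.0 / 5.0) * R_SPHERE


@pytest.fixture(scope="module")
def sphere_data():
    return sphere_curve(R_SPHERE)


class TestDebye:
    def test_single_point_scatterer_flat(self):
        m = synthetic.make_sphere_cloud(1, 1.0, seed=0)
        q = np.linspace(0.01, 0.5, 20)
        np.testing.assert_allclose(saxs.debye_intensity(m, q).I, 1.0)

    def test_two_point_closed_form(self):
        m = synthetic.make_sphere_cloud(2, 30.0, seed=0)
        c = m.coords()
        d = float(np.linalg.norm(c[0] - c[1]))
        q = np.array([0.03, 0.1, 0.33])
        I = saxs.debye_intensity(m, q).I
        np.testing.assert_allclose(I, 2.0 * (1.0 + np.sin(q * d) / (q * d)), rtol=1e-12)

    def test_uniform_sphere_matches_analytic(self, sphere_model_2000):
        q = np.linspace(0.01, 4.0 / R_SPHERE, 25)
        I = saxs.debye_intensity(sphere_model_2000, q).I
        analytic = sphere_form_factor(q, R_SPHERE)
        # normalized by forward intensity; 2000-point Monte Carlo sampling noise
        dev = np.abs(I / 2000 ** 2 - analytic).max() / analytic.max()
        assert dev < 0.01

    def test_forward_limit_is_total_scattering_squared(self, sphere_model_2000):
        q = np.array([1e-4])
        I0 = saxs.debye_intensity(sphere_model_2000, q).I[0]
        assert I0 == pytest.approx(2000 ** 2, rel=1e-4)

    def test_histogram_path_agrees_with_exact(self, sphere_model_2000, monkeypatch):
        q = np.linspace(0.006, 0.5, 60)
        exact = saxs.debye_intensity(sphere_model_2000, q).I
        monkeypatch.setattr(saxs_module, "EXACT_PAIR_LIMIT", 1)
        hist = saxs.debye_intensity(sphere_model_2000, q).I
        assert np.abs((hist - exact) / exact).max() < 0.005

    def test_intensity_positive(self, sphere_model_2000):
        q = np.linspace(0.006, 0.5, 60)
        assert np.all(saxs.debye_intensity(sphere_model_2000, q).I > 0)


class TestGuinier:
    def test_sphere_rg_within_one_percent(self, sphere_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = saxs.guinier_fit(sphere_data)
        assert g.rg == pytest.approx(RG_SPHERE, rel=0.01)
        assert g.qmax_rg <= 1.3 + 1e-9
        assert g.n_points >= 10

    def test_exact_gaussian_recovered(self):
        q = np.linspace(0.006, 0.2, 120)
        curve = structio.ScatteringCurve(q=q, I=7.0 * np.exp(-q ** 2 * 21.31 ** 2 / 3.0))
        g = saxs.guinier_fit(curve)
        assert g.rg == pytest.approx(21.31, abs=1e-9)
        assert g.i0 == pytest.approx(7.0, rel=1e-12)

    def test_no_guinier_region_raises(self):
        q = np.linspace(0.01, 0.2, 50)
        curve = structio.ScatteringCurve(q=q, I=np.exp(+q ** 2 * 100))
        with pytest.raises(FitError):
            saxs.guinier_fit(curve)

    def test_consistent_with_coordinate_rg(self, sphere_model_2000):
        q = np.linspace(0.006, 0.15, 80)
        curve = saxs.debye_intensity(sphere_model_2000, q)
        g = saxs.guinier_fit(curve)
        assert g.rg == pytest.approx(saxs.coordinate_rg(sphere_model_2000), rel=0.02)


class TestPrTransform:
    def test_sphere_pr_recovered(self, sphere_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = saxs.pr_transform(sphere_data, dmax=2.0 * R_SPHERE)
        analytic = sphere_pr(dist.r, R_SPHERE)
        analytic /= np.trapezoid(analytic, dist.r)
        recovered = dist.p / np.trapezoid(dist.p, dist.r)
        assert np.abs(recovered - analytic).max() / analytic.max() < 0.05
        # peak near 0.525 * Dmax for a uniform sphere
        assert dist.r[np.argmax(dist.p)] == pytest.approx(0.525 * 2 * R_SPHERE, rel=0.06)
        assert dist.p[0] == 0.0 and dist.p[-1] == 0.0

    def test_rg_consistent_with_guinier(self):
        q = np.linspace(0.006, 0.3, 150)
        curve = structio.ScatteringCurve(q=q, I=5.0 * np.exp(-q ** 2 * 20.0 ** 2 / 3.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = saxs.pr_transform(curve, dmax=70.0)
        g = saxs.guinier_fit(curve)
        assert dist.rg == pytest.approx(g.rg, rel=0.02)

    def test_zero_curve_gives_zero_p(self):
        q = np.linspace(0.01, 0.3, 60)
        curve = structio.ScatteringCurve(q=q, I=np.zeros(60), sigma=np.ones(60))
        dist = saxs.pr_transform(curve, dmax=50.0)
        assert np.all(dist.p == 0.0)

    def test_forward_transform_reproduces_input(self, sphere_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = saxs.pr_transform(sphere_data, dmax=2.0 * R_SPHERE)
        A = saxs._ift_system(sphere_data.q, dist.r)
        resid = sphere_data.I - A @ dist.p
        rel = np.linalg.norm(resid) / np.linalg.norm(sphere_data.I)
        assert rel < 0.01
        assert dist.fit_chi2 <= 1.2  # unit-weight reduced chi2 on noiseless input


class TestEstimateDmax:
    def test_sphere_dmax_near_2r(self, sphere_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dmax = saxs.estimate_dmax(sphere_data)
        rg = saxs.guinier_fit(sphere_data).rg
        grid_step = (4.0 - 1.5) * rg / 20.0
        assert abs(dmax - 2.0 * R_SPHERE) <= 1.5 * grid_step

    def test_open_larger_than_closed(self):
        closed, _ = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=5.0, seed=12))
        opened, _ = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=60.0, seed=12))
        q = np.linspace(0.006, 0.4, 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_closed = saxs.estimate_dmax(saxs.debye_intensity(closed, q))
            d_open = saxs.estimate_dmax(saxs.debye_intensity(opened, q))
        assert d_open > d_closed


class TestPorod:
    def test_sphere_volume_within_ten_percent(self, sphere_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = saxs.guinier_fit(sphere_data)
            v = saxs.porod_volume(sphere_data, g)
        v_true = 4.0 / 3.0 * math.pi * R_SPHERE ** 3
        assert v == pytest.approx(v_true, rel=0.10)

    def test_scale_invariance(self, sphere_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g1 = saxs.guinier_fit(sphere_data)
            v1 = saxs.porod_volume(sphere_data, g1)
            scaled = structio.ScatteringCurve(q=sphere_data.q, I=5.0 * sphere_data.I)
            g5 = saxs.guinier_fit(scaled)
            v5 = saxs.porod_volume(scaled, g5)
        assert v5 == pytest.approx(v1, rel=1e-6)


class TestChi2Fit:
    def test_exact_match_zero_chi2(self, sphere_data):
        curve = structio.ScatteringCurve(q=sphere_data.q, I=sphere_data.I,
                                         sigma=np.ones(len(sphere_data)))
        fit = saxs.chi2_fit(curve, sphere_data)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
        assert fit.scale == pytest.approx(1.0)

    def test_recovers_scale_with_unit_noise(self, rng):
        q = np.linspace(0.01, 0.4, 400)
        base = np.exp(-q ** 2 * 150) + 0.01
        sigma = 0.02 * base
        noisy = 3.7 * base + rng.normal(0.0, sigma)
        exp = structio.ScatteringCurve(q=q, I=noisy, sigma=sigma)
        model = structio.ScatteringCurve(q=q, I=base)
        fit = saxs.chi2_fit(exp, model)
        assert fit.scale == pytest.approx(3.7, rel=0.02)
        assert abs(fit.chi2 - 1.0) < 3.0 / math.sqrt(len(q))

    def test_scale_equivariance(self, sphere_data, rng):
        sigma = np.full(len(sphere_data), 0.01)
        noisy = sphere_data.I + rng.normal(0, 0.01, len(sphere_data))
        exp = structio.ScatteringCurve(q=sphere_data.q, I=noisy, sigma=sigma)
        fit1 = saxs.chi2_fit(exp, sphere_data)
        exp_k = structio.ScatteringCurve(q=sphere_data.q, I=7.0 * noisy, sigma=7.0 * sigma)
        fit_k = saxs.chi2_fit(exp_k, sphere_data)
        assert fit_k.chi2 == pytest.approx(fit1.chi2, rel=1e-9)
        assert fit_k.scale == pytest.approx(7.0 * fit1.scale, rel=1e-9)

    def test_interpolation_onto_experimental_grid(self):
        qe = np.linspace(0.02, 0.3, 50)
        qm = np.linspace(0.01, 0.4, 500)
        exp = structio.ScatteringCurve(q=qe, I=np.exp(-qe ** 2 * 100),
                                       sigma=np.full(50, 1e-3))
        model = structio.ScatteringCurve(q=qm, I=np.exp(-qm ** 2 * 100))
        fit = saxs.chi2_fit(exp, model)
        assert fit.chi2 < 0.1


class TestRankModels:
    def test_identical_models_tie_in_input_order(self, sphere_model_2000):
        q = np.linspace(0.01, 0.3, 60)
        curve = saxs.debye_intensity(sphere_model_2000, q)
        exp = structio.ScatteringCurve(q=q, I=curve.I, sigma=0.01 * curve.I)
        table = saxs.rank_models(exp, [sphere_model_2000, sphere_model_2000],
                                 names=["first", "second"])
        assert list(table["model"]) == ["first", "second"]

    def test_generating_model_ranked_first(self):
        a, _ = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=10.0, seed=13))
        b, _ = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=40.0, seed=13))
        curve = synthetic.simulate_scattering_curve(a, counts_scale=1e4, seed=99)
        table = saxs.rank_models(curve, [b, a], names=["open", "generator"])
        assert table.iloc[0]["model"] == "generator"
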