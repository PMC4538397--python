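import numpy as np
import pytest
import statsmodels.api as sm

from toptrees import (
    GenericModel,
    PowerModel,
    fit_generic_model,
    fit_power_model,
    fit_richness_model,
    loocv_by_site,
    plot_pairs,
    predict_agb_tot,
)

from conftest import make_plot, power_law_plot


class TestFitPowerModel:
    def test_noise_free_recovery(self):
        x = np.linspace(50_000, 300_000, 30)
        y = 1.3 * x**0.95
        m = fit_power_model(x, y, 20)
        assert m.alpha == pytest.approx(1.3, abs=1e-6)
        assert m.beta == pytest.approx(0.95, abs=1e-6)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_identity_limit_when_topn_is_total(self):
        x = np.linspace(100_000, 400_000, 12)
        m = fit_power_model(x, x.copy(), 10_000)
        assert m.alpha == pytest.approx(1.0, abs=1e-9)
        assert m.beta == pytest.approx(1.0, abs=1e-9)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_plots(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_power_model(np.ones(4), np.ones(4), 20)

    def test_noisy_recovery_within_own_confidence_interval(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(12, 0.4, 175)
        y = 1.3 * x**0.95 * np.exp(rng.normal(0, 0.15, 175))
        m = fit_power_model(x, y, 20)
        assert abs(m.beta - 0.95) < 1.96 * m.beta_se
        assert abs(m.alpha - 1.3) < 1.96 * m.alpha_se * 3  # alpha CI is log-skewed
        # independent oracle: log-log OLS on the same draws
        ols = sm.OLS(np.log(y), sm.add_constant(np.log(x))).fit()
        assert m.beta == pytest.approx(ols.params[1], abs=3 * ols.bse[1])

    def test_rser_is_relative_to_mean_response(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(12, 0.3, 50)
        y = 2 * x**0.9 * np.exp(rng.normal(0, 0.1, 50))
        m = fit_power_model(x, y, 20)
        assert m.rser == pytest.approx(m.rse / y.mean())
        assert 0 < m.rser < 1


class TestGenericModel:
    def _models(self, alpha_fn, beta_fn):
        return [
            PowerModel(n=n, alpha=alpha_fn(n), beta=beta_fn(n), r2=1.0,
                       rse=0.0, rser=0.0, n_plots=30)
            for n in range(5, 101, 5)
        ]

    def test_exact_alpha_meta_fit(self):
        g = fit_generic_model(self._models(lambda n: 2 * n**-0.3, lambda n: 1.0))
        assert g.alpha_coeffs[0] == pytest.approx(2.0, abs=1e-6)
        assert g.alpha_coeffs[1] == pytest.approx(-0.3, abs=1e-6)

    def test_constant_beta_reproduced(self):
        g = fit_generic_model(self._models(lambda n: 2 * n**-0.3, lambda n: 1.0))
        for n in range(5, 101, 5):
            assert g.beta(n) == pytest.approx(1.0, abs=1e-3)

    def test_meta_predictions_track_per_n_values(self):
        # smooth per-N coefficients with mild deterministic wiggle
        alpha_fn = lambda n: 1.5 * n**-0.2 * (1 + 0.02 * np.sin(n))
        beta_fn = lambda n: 1.05 * (1 - np.exp(-0.3 * n**0.8)) * (1 + 0.01 * np.cos(n))
        models = self._models(alpha_fn, beta_fn)
        g = fit_generic_model(models)
        for m in models:
            assert g.alpha(m.n) == pytest.approx(m.alpha, rel=0.05)
            assert g.beta(m.n) == pytest.approx(m.beta, rel=0.05)

    def test_needs_enough_distinct_n(self):
        models = self._models(lambda n: 1.0, lambda n: 1.0)[:5]
        with pytest.raises(ValueError, match="10 distinct"):
            fit_generic_model(models)


class TestPredict:
    def test_identity_power_model(self):
        m = PowerModel(n=20, alpha=1.0, beta=1.0, r2=1, rse=0, rser=0, n_plots=9)
        assert predict_agb_tot(200_000.0, 20, m) == pytest.approx(200_000.0)

    def test_forced_arithmetic(self):
        m = PowerModel(n=20, alpha=2.0, beta=0.5, r2=1, rse=0, rser=0, n_plots=9)
        assert predict_agb_tot(10_000.0, 20, m) == pytest.approx(200.0)

    def test_generic_model_validity_range(self):
        g = GenericModel(alpha_coeffs=(2.0, -0.3), beta_coeffs=(1.0, 0.3, 0.8))
        with pytest.raises(ValueError, match="validity range"):
            predict_agb_tot(10_000.0, 3, g)
        assert predict_agb_tot(10_000.0, 20, g) > 0

    def test_generic_json_round_trip(self, tmp_path):
        g = GenericModel(alpha_coeffs=(2.0, -0.3), beta_coeffs=(1.0, 0.3, 0.8),
                         alpha_r2=0.99, beta_r2=0.98)
        p = tmp_path / "model.json"
        g.to_json(p)
        back = GenericModel.from_json(p)
        assert back.alpha(20) == pytest.approx(g.alpha(20))
        assert back.beta(20) == pytest.approx(g.beta(20))


def exact_law_sites(alpha=1.5, beta=0.98, n_sites=4, plots=8):
    sites = {}
    x0 = 150_000.0
    for s in range(n_sites):
        site = f"site{s}"
        sites[site] = [
            power_law_plot(x0 * (1 + 0.08 * s + 0.1 * j), alpha, beta,
                           plot_id=f"{site}-p{j}", site_id=site)
            for j in range(plots)
        ]
    return sites


class TestLOOCV:
    def test_perfect_model_limit(self):
        cv = loocv_by_site(exact_law_sites(), 20)
        per_site = cv[cv["site"] != "average"]
        assert np.allclose(per_site["pearson_r"], 1.0, atol=1e-9)
        assert np.all(per_site["bias"] < 1e-6)

    def test_two_sites_rejected(self):
        sites = exact_law_sites(n_sites=2)
        with pytest.raises(ValueError, match=">= 3 sites"):
            loocv_by_site(sites, 20)

    def test_small_site_excluded_with_warning(self):
        sites = exact_law_sites(n_sites=4)
        sites["tiny"] = sites["site0"][:1]
        with pytest.warns(UserWarning, match="tiny"):
            cv = loocv_by_site(sites, 20)
        assert "tiny" not in set(cv["site"])

    def test_shifted_site_has_largest_bias(self):
        # site2's totals are inflated x1.5 at identical top-20 sums, so the
        # cross-validated model underpredicts it by exactly 1/3
        sites = exact_law_sites(n_sites=5)
        sites["site2"] = [
            power_law_plot(150_000.0 * (1 + 0.16 + 0.1 * j), 1.5 * 1.5, 0.98,
                           plot_id=f"site2-p{j}", site_id="site2")
            for j in range(8)
        ]
        cv = loocv_by_site(sites, 20).set_index("site")
        per_site = cv.drop(index="average")
        assert per_site["bias"].idxmax() == "site2"
        assert cv.loc["site2", "bias"] == pytest.approx(1 / 3, abs=1e-6)
        assert cv.loc["site2", "signed_bias"] == pytest.approx(-1 / 3, abs=1e-6)


class TestRichnessModel:
    @staticmethod
    def richness_plot(k_top, s_total, plot_id, site_id):
        # k_top distinct species among the 20 largest stems, s_total overall
        agbs, species = [], []
        for i in range(20):
            agbs.append(1000.0 - i)
            species.append(f"Genus{i % k_top:03d} big{i % k_top:03d}")
        extra = s_total - k_top
        for i in range(extra):
            agbs.append(10.0 + 0.01 * i)
            species.append(f"Genus900 small{i:03d}")
        return make_plot(agbs, species=species, plot_id=plot_id, site_id=site_id)

    def test_exact_line_recovered(self):
        plots = [
            self.richness_plot(k, 2 * k + 10, f"p{k}", "s1") for k in range(3, 12)
        ]
        fit = fit_richness_model({"s1": plots}, 20)
        row = fit[fit["site"] == "s1"].iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["intercept"] == pytest.approx(10.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_constant_predictor_flagged_degenerate(self):
        plots = [self.richness_plot(5, 30 + k, f"p{k}", "s1") for k in range(6)]
        fit = fit_richness_model({"s1": plots}, 20)
        assert fit[fit["site"] == "s1"]["degenerate"].iloc[0]

    def test_per_site_slopes_recovered_with_noise(self):
        rng = np.random.default_rng(9)
        sites = {}
        for s, slope in enumerate((1.5, 2.5, 3.5)):
            plots = []
            for j, k in enumerate(range(3, 15)):
                s_tot = int(round(slope * k + 12 + rng.integers(-1, 2)))
                plots.append(self.richness_plot(k, s_tot, f"p{j}", f"s{s}"))
            sites[f"s{s}"] = plots
            fit = fit_richness_model(sites, 20)
            got = fit[fit["site"] == f"s{s}"]["slope"].iloc[0]
            assert got == pytest.approx(slope, rel=0.10)


def test_plot_pairs_match_manual_sums(small_region):
    plots, _ = small_region
    x, y = plot_pairs(plots[:3], 10)
    for i, p in enumerate(plots[:3]):
        agbs = sorted((t.agb for t in p.trees), reverse=True)
        assert x[i] == pytest.approx(sum(agbs[:10]))
        assert y[i] == pytest.approx(sum(agbs))
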