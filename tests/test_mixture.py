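import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screenmix.io import make_guide_table
from screenmix.mixture import (
    QPrior,
    call_at_fdr,
    em_fit_marginal,
    fit_screen,
    gene_posterior,
    global_fdr,
    score_genes,
)
from screenmix.null_model import NullFit
from screenmix.simulate import FullSimConfig, simulate_full


def _f1_normal(mu, sigma):
    return lambda x: stats.norm.logpdf(np.asarray(x, float), mu, sigma)


class TestEmFitMarginal:
    def test_pure_null_drives_tau_to_zero(self, std_normal_null):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        fit = em_fit_marginal(x, std_normal_null)
        assert fit.tau <= 0.02

    def test_recovers_generating_mixture(self, std_normal_null):
        rng = np.random.default_rng(2)
        n, tau = 10_000, 0.10
        labels = rng.random(n) < tau
        x = np.where(labels, rng.normal(-3.0, 1.0, n), rng.normal(0.0, 1.0, n))
        fit = em_fit_marginal(x, std_normal_null)
        assert 0.08 <= fit.tau <= 0.12
        assert -3.2 <= fit.f1_params["mu"] <= -2.8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_em_trace_non_decreasing(self, std_normal_null, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(size=900), rng.normal(-2.5, 1.2, 100)])
        fit = em_fit_marginal(x, std_normal_null)
        assert np.all(np.diff(fit.em_trace) >= -1e-8)
        assert np.all((fit.responsibilities >= 0) & (fit.responsibilities <= 1))

    def test_no_controls_variant_estimates_normal_null(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.2, 1.1, 4500), rng.normal(-3, 1, 500)])
        fit = em_fit_marginal(x, None)
        assert fit.f0.family == "normal"
        mu0, sd0 = fit.f0.params
        assert abs(mu0 - 0.2) < 0.15 and abs(sd0 - 1.1) < 0.15

    def test_bimodal_f1_splits_sides(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.normal(0, 1, 4000), rng.normal(-3, 1, 300), rng.normal(3, 1, 300)]
        )
        f0 = NullFit("normal", (0.0, 1.0), 0.0, 4000)
        fit = em_fit_marginal(x, f0, f1_mode="bimodal")
        assert fit.f1_params["mu_neg"] < -2 and fit.f1_params["mu_pos"] > 2
        assert 0.3 < fit.f1_params["w_neg"] < 0.7

    def test_non_finite_input_errors(self, std_normal_null):
        with pytest.raises(ValueError):
            em_fit_marginal([0.0, np.nan], std_normal_null)


class TestGenePosterior:
    def test_point_mass_at_one_collapses_to_two_groups(self, std_normal_null):
        # single guide with density ratio f1/f0 = 9 and tau = 0.1:
        # posterior = 0.1*9 / (0.1*9 + 0.9) = 1/2
        mu = -3.0
        x = (np.log(9.0) + mu**2 / 2.0) / mu  # solves N(x;mu,1)/N(x;0,1) = 9
        post = gene_posterior(
            [x], std_normal_null, _f1_normal(mu, 1.0), 0.1,
            QPrior(kind="point_mass", point=1.0),
        )
        assert post == pytest.approx(0.5, abs=1e-12)

    def test_point_mass_equals_flat_two_groups_every_gene(self, small_screen, std_normal_null):
        table, _ = small_screen
        tau = 0.12
        f1 = _f1_normal(-3.0, 1.25)
        rng = np.random.default_rng(0)
        genes = rng.choice(table["gene_id"].unique(), 25, replace=False)
        for g in genes:
            if g == "negative_control":
                continue
            x = table.loc[table["gene_id"] == g, "lfc"].to_numpy()
            post = gene_posterior(
                x, std_normal_null, f1, tau, QPrior(kind="point_mass", point=1.0)
            )
            log_num = np.log(tau) + f1(x).sum()
            log_den = np.log(1 - tau) + std_normal_null.logpdf(x).sum()
            flat = 1.0 / (1.0 + np.exp(log_den - log_num))
            assert post == pytest.approx(flat, abs=1e-12)

    def test_closed_form_when_f1_equals_f0(self, std_normal_null):
        # f1 == f0 on every guide: integrand is tau/q, uniform psi on
        # [tau, 1] gives tau * ln(1/tau) / (1 - tau)
        tau = 0.1
        x = np.array([0.3, -0.7, 1.1])
        post = gene_posterior(
            x, std_normal_null, std_normal_null.logpdf, tau, QPrior(), n_nodes=100
        )
        expect = tau * np.log(1 / tau) / (1 - tau)
        assert post == pytest.approx(expect, abs=1e-9)

    def test_quadrature_matches_brute_force_integration(self, std_normal_null):
        rng = np.random.default_rng(9)
        x = rng.normal(-1.0, 1.5, size=6)
        tau = 0.07
        f1 = _f1_normal(-2.5, 1.0)
        post = gene_posterior(x, std_normal_null, f1, tau, QPrior(), n_nodes=100)

        # dense trapezoid oracle on 1e5 points, endpoints included
        # (at q=lo=tau the integrand is exactly 1, at q=1 the f0 branch
        # of the within-gene mixture vanishes)
        lo = max(tau, 0.01)
        q = np.linspace(lo, 1.0, 100_001)
        lf0 = std_normal_null.logpdf(x)
        lf1 = f1(x)
        integrand = np.empty_like(q)
        for i, qk in enumerate(q):
            if qk >= 1.0:
                s = lf1.sum()
            else:
                s = np.logaddexp(np.log(qk) + lf1, np.log(1 - qk) + lf0).sum()
            if tau / qk >= 1.0:
                integrand[i] = 1.0
                continue
            log_a = np.log(tau / qk) + s
            log_b = np.log(1 - tau / qk) + lf0.sum()
            integrand[i] = 1.0 / (1.0 + np.exp(log_b - log_a))
        oracle = np.trapezoid(integrand, q) / (1.0 - lo)
        assert post == pytest.approx(oracle, abs=1e-6)

    def test_adding_supportive_guide_raises_posterior(self, std_normal_null):
        f1 = _f1_normal(-2.5, 1.0)
        rng = np.random.default_rng(12)
        for prior in (QPrior(kind="point_mass", point=1.0), QPrior()):
            for _ in range(10):
                x = list(rng.normal(-0.5, 1.0, size=4))
                base = gene_posterior(x, std_normal_null, f1, 0.1, prior)
                extra = -3.0  # strongly f1-favoured (ratio > 1)
                more = gene_posterior(x + [extra], std_normal_null, f1, 0.1, prior)
                assert more >= base - 1e-12

    def test_invalid_inputs(self, std_normal_null):
        f1 = _f1_normal(-2.5, 1.0)
        with pytest.raises(ValueError):
            gene_posterior([], std_normal_null, f1, 0.1)
        with pytest.raises(ValueError):
            gene_posterior([0.0], std_normal_null, f1, 1.5)
        with pytest.raises(ValueError, match="p > 1"):
            gene_posterior([0.0], std_normal_null, f1, 0.5, QPrior(kind="point_mass", point=0.3))


class TestScoreGenes:
    def test_likelihood_ratio_direction(self, std_normal_null):
        table = make_guide_table(
            [f"g{i}" for i in range(8)],
            ["hit"] * 4 + ["dud"] * 4,
            [-3.1, -2.9, -3.0, -2.8, 0.1, -0.1, 0.2, 0.0],
            [False] * 8,
        )
        fit = _fixed_fit(std_normal_null, tau=0.2)
        scores = score_genes(table, fit).set_index("gene_id")
        assert scores.loc["hit", "locfdr"] < 0.05
        assert scores.loc["dud", "locfdr"] > 0.8

    def test_guide_order_within_genes_irrelevant(self, small_screen, true_skew_t_null):
        table, _ = small_screen
        targeting = table.loc[~table.is_negative_control]
        fit = _fixed_fit(true_skew_t_null, tau=0.15)
        a = score_genes(targeting, fit)
        shuffled = targeting.sample(frac=1.0, random_state=0)
        b = score_genes(shuffled, fit)
        pd.testing.assert_frame_equal(a, b)

    def test_true_genes_score_better_than_null_genes(self, small_screen, true_skew_t_null):
        table, truth = small_screen
        fit = em_fit_marginal(
            table.loc[~table.is_negative_control, "lfc"].to_numpy(), true_skew_t_null
        )
        scores = score_genes(table, fit).set_index("gene_id")["locfdr"]
        null_mean = scores[truth.gene[truth.gene == 0].index].mean()
        true_mean = scores[truth.gene[truth.gene == 1].index].mean()
        assert null_mean >= true_mean

    def test_mean_locfdr_tracks_null_proportion(self, small_screen, true_skew_t_null):
        # with the efficiency prior matched to the generative q, the mean
        # posterior mass equals the interesting-gene fraction (here 1/4);
        # the hard bound mean locfdr >= 1 - tau_hat/lo holds for any prior
        table, truth = small_screen
        fit = em_fit_marginal(
            table.loc[~table.is_negative_control, "lfc"].to_numpy(), true_skew_t_null
        )
        scores = score_genes(table, fit, q_prior=QPrior(kind="point_mass", point=0.9))
        null_prop = (truth.gene == 0).mean()
        assert scores["locfdr"].mean() == pytest.approx(null_prop, abs=0.05)
        uniform_scores = score_genes(table, fit)
        lo = max(fit.tau, 0.01)
        assert uniform_scores["locfdr"].mean() >= 1.0 - fit.tau / lo - 1e-9


def _fixed_fit(f0, tau):
    from screenmix.mixture import MixtureFit

    return MixtureFit(
        f0=f0,
        f1_mode="unimodal",
        f1_params={"mu": -3.0, "sigma": 1.25},
        tau=tau,
        responsibilities=np.array([]),
        em_trace=[0.0],
        converged=True,
        n_iter=1,
    )


class TestGlobalFdr:
    def test_worked_example(self):
        fdr = global_fdr([0.01, 0.05, 0.20])
        assert np.allclose(fdr, [0.01, 0.03, 0.26 / 3])
        scores = pd.DataFrame(
            {"gene_id": list("abc"), "locfdr": [0.01, 0.05, 0.20], "fdr_cummean": fdr}
        )
        assert len(call_at_fdr(scores, 0.05)) == 2
        assert len(call_at_fdr(scores, 0.1)) == 3

    def test_all_ones_calls_nothing(self):
        fdr = global_fdr(np.ones(10))
        scores = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "locfdr": 1.0, "fdr_cummean": fdr}
        )
        assert len(call_at_fdr(scores, 0.99)) == 0

    def test_matches_brute_force_at_every_rank(self, rng):
        s = np.sort(rng.random(200))
        fdr = global_fdr(s)
        brute = np.array([s[: k + 1].mean() for k in range(200)])
        assert np.allclose(fdr, brute)
        assert np.all(np.diff(fdr) >= -1e-12)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            global_fdr([])
        with pytest.raises(ValueError):
            global_fdr([0.5, 0.2])  # not sorted


class TestFitScreen:
    def test_no_controls_requires_normal_em(self, small_screen):
        table, _ = small_screen
        no_ctrl = table.loc[~table.is_negative_control]
        with pytest.raises(ValueError, match="normal-em"):
            fit_screen(no_ctrl, null="skewt")
        fit, scores = fit_screen(no_ctrl, null="normal-em")
        assert fit.f0.family == "normal"
        assert len(scores) == no_ctrl["gene_id"].nunique()

    def test_global_null_screen_calls_nothing(self):
        called = []
        for seed in (0, 1, 2):
            cfg = FullSimConfig(
                n_genes_null=400, n_genes_pos=1, guides_per_gene=5,
                efficiency=0.0, n_controls=400, seed=seed,
            )
            table, _ = simulate_full(cfg)
            _, scores = fit_screen(table, null="skewt", seed=seed)
            called.append(len(call_at_fdr(scores, 0.1)))
        assert np.mean(called) <= 2

    def test_deterministic_given_input_and_seed(self, small_screen):
        table, _ = small_screen
        _, a = fit_screen(table, seed=5)
        _, b = fit_screen(table, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_enriched_direction_mirrors_depleted(self, small_screen):
        table, _ = small_screen
        flipped = table.copy()
        flipped["lfc"] = -flipped["lfc"]
        _, dep = fit_screen(table, direction="depleted", null="skewt", seed=0)
        _, enr = fit_screen(flipped, direction="enriched", null="skewt", seed=0)
        pd.testing.assert_frame_equal(dep, enr)

    def test_tau_recovery_round_trip(self):
        # generative tau = p_genes * efficiency (guides split evenly)
        cfg = FullSimConfig(
            n_genes_null=1500, n_genes_pos=500, guides_per_gene=10,
            efficiency=0.8, n_controls=959, seed=99,
        )
        table, _ = simulate_full(cfg)
        fit, _ = fit_screen(table, null="skewt", seed=0)
        gen_tau = (500 / 2000) * 0.8
        assert fit.tau == pytest.approx(gen_tau, abs=0.03)
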