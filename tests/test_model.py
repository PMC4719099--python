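import dataclasses
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pwibayes as pw
from pwibayes.model import _sweep


class TestGammaMomentMatching:
    def test_published_hyperparameters(self):
        # mean 5.0e-05 and SD 33 of the observed cell precisions
        shape, rate = pw.gamma_from_mean_sd(5.0e-05, 33.0)
        assert f"{shape:.0e}" == "2e-12"
        assert f"{rate:.1e}" == "4.6e-08"

    def test_unit_case_is_exponential(self):
        assert pw.gamma_from_mean_sd(1.0, 1.0) == (1.0, 1.0)

    @given(mean=st.floats(1e-8, 1e6), sd=st.floats(1e-8, 1e6))
    def test_round_trip_identity(self, mean, sd):
        shape, rate = pw.gamma_from_mean_sd(mean, sd)
        assert shape / rate == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(shape) / rate == pytest.approx(sd, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pw.gamma_from_mean_sd(0.0, 1.0)


def synthetic_median_table(seed=11, n_controls=13, n_patients=6):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_controls):
        rows.append((f"c{i}", "control", *(800 + rng.normal(0, 60, 4))))
    for i in range(n_patients):
        rows.append((f"p{i}", "patient", *(1200 + rng.normal(0, 150, 4))))
    return pd.DataFrame(rows, columns=["participant_id", "group", *pw.DEFAULT_CONDITIONS])


class TestBuildPriors:
    def test_matches_hand_computation(self):
        med = synthetic_median_table(seed=11)
        priors = pw.build_priors(med)
        # independent arithmetic with the statistics module
        pooled = [med.loc[i, c] for i in med.index for c in pw.DEFAULT_CONDITIONS]
        assert priors.baseline_mean == pytest.approx(statistics.fmean(pooled), rel=1e-12)
        pooled_var = statistics.variance(pooled)
        assert priors.baseline_precision == pytest.approx(1e-6 / pooled_var, rel=1e-12)
        assert priors.sd_lower == pytest.approx(np.sqrt(pooled_var) / 1000, rel=1e-12)
        assert priors.sd_upper == pytest.approx(np.sqrt(pooled_var) * 1000, rel=1e-12)
        precisions = [
            1.0 / statistics.variance(med.loc[med["group"] == g, c].tolist())
            for g in ("control", "patient")
            for c in pw.DEFAULT_CONDITIONS
        ]
        m = statistics.fmean(precisions)
        s = 1e6 * statistics.stdev(precisions)
        assert priors.deflection_precision_shape == pytest.approx(m * m / (s * s), rel=1e-9)
        assert priors.deflection_precision_rate == pytest.approx(m / (s * s), rel=1e-9)
        assert priors.nu_prior_mean == 29.0

    def test_scaling_law(self):
        med = synthetic_median_table(seed=12)
        scaled = med.copy()
        scaled[list(pw.DEFAULT_CONDITIONS)] *= 2.0
        p1, p2 = pw.build_priors(med), pw.build_priors(scaled)
        assert p2.baseline_mean == pytest.approx(2 * p1.baseline_mean)
        assert p2.sd_lower == pytest.approx(2 * p1.sd_lower)
        assert p2.sd_upper == pytest.approx(2 * p1.sd_upper)
        assert p2.baseline_precision == pytest.approx(p1.baseline_precision / 4)

    def test_degenerate_data_rejected(self):
        med = synthetic_median_table()
        med[list(pw.DEFAULT_CONDITIONS)] = 900.0
        with pytest.raises(ValueError):
            pw.build_priors(med)


class TestMcmcConfig:
    def test_defaults_follow_published_settings(self):
        cfg = pw.McmcConfig()
        assert (cfg.n_samples, cfg.thin, cfg.burn_in) == (100_000, 50, 2_000)

    @pytest.mark.parametrize("kwargs", [{"n_samples": 0}, {"thin": 0}, {"n_samples": 1001, "n_chains": 2}])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pw.McmcConfig(**kwargs)


class TestFit:
    def test_seed_determinism(self, paper_medians):
        mcmc = pw.McmcConfig(n_samples=400, thin=1, burn_in=100, n_chains=2, seed=3)
        a = pw.fit_model(paper_medians, mcmc=mcmc)
        b = pw.fit_model(paper_medians, mcmc=mcmc)
        assert np.array_equal(a.baseline, b.baseline)
        assert np.array_equal(a.interaction_deflection, b.interaction_deflection)
        c = pw.fit_model(paper_medians, mcmc=dataclasses.replace(mcmc, seed=4))
        assert not np.array_equal(a.baseline, c.baseline)

    def test_retained_draw_count_and_chain_layout(self, paper_posterior, small_mcmc):
        assert paper_posterior.n_draws == small_mcmc.n_samples
        assert np.bincount(paper_posterior.chain).tolist() == [small_mcmc.per_chain] * 2

    def test_sum_to_zero_in_every_draw(self, paper_posterior):
        scale = np.abs(paper_posterior.baseline).max()
        tol = 1e-8 * scale
        assert np.abs(paper_posterior.group_deflection.sum(axis=1)).max() < tol
        assert np.abs(paper_posterior.distractor_deflection.sum(axis=1)).max() < tol
        inter = paper_posterior.interaction_deflection
        assert np.abs(inter.sum(axis=1)).max() < tol
        assert np.abs(inter.sum(axis=2)).max() < tol

    def test_sigma_within_prior_bounds_and_nu_positive(self, paper_medians, paper_posterior):
        priors = pw.build_priors(paper_medians)
        assert (paper_posterior.sigma >= priors.sd_lower).all()
        assert (paper_posterior.sigma <= priors.sd_upper).all()
        assert (paper_posterior.nu > 0).all()

    def test_diagnostics_reported_and_converged(self, paper_posterior):
        assert set(paper_posterior.rhat) >= {"baseline", "sigma", "cell_mean"}
        assert paper_posterior.converged
        assert max(paper_posterior.rhat.values()) < 1.05

    def test_cell_mean_sum_corollary(self, paper_posterior):
        cm = paper_posterior.cell_means()
        dev = (cm - paper_posterior.baseline[:, None, None]).sum(axis=(1, 2))
        assert np.abs(dev).max() < 1e-8 * np.abs(paper_posterior.baseline).max()

    def test_null_truth_contrasts_include_zero(self):
        # no group gap, no condition effects: every named contrast's HDI
        # should (and, at this seed, does) contain zero
        effects = {(g, c): 0.0 for g in ("control", "patient") for c in pw.DEFAULT_CONDITIONS}
        cfg = pw.paper_like_config(seed=31, effect_ms=effects, patient_slowing_ms=0.0)
        trials, _ = pw.simulate_dataset(cfg)
        retained, _ = pw.exclude_trials(trials)
        med = pw.condition_medians(retained)
        post = pw.fit_model(med, mcmc=pw.McmcConfig(n_samples=4000, thin=1, burn_in=400, n_chains=2, seed=5))
        for name, res in pw.named_contrasts(post).items():
            assert res.includes_zero(), name

    def test_vague_posterior_with_minimal_data(self):
        # 2 participants x 2 conditions: sigma and nu stay essentially at
        # their priors (nu near its prior mean 29, sigma spanning decades)
        med = pd.DataFrame(
            [("a", "control", 700.0, 780.0), ("b", "patient", 1100.0, 1460.0)],
            columns=["participant_id", "group", "neutral", "unrelated"],
        )
        priors = pw.PriorSpec(
            baseline_mean=1000.0, baseline_precision=1e-11,
            sd_lower=0.3, sd_upper=300_000.0,
        )
        post = pw.fit_model(
            med, priors=priors,
            mcmc=pw.McmcConfig(n_samples=20_000, thin=1, burn_in=1_000, n_chains=2, seed=8),
        )
        assert 10.0 < post.nu.mean() < 60.0
        q1, q99 = np.quantile(post.sigma, [0.01, 0.99])
        assert q99 / q1 > 10.0

    def test_unknown_backend_rejected(self, paper_medians):
        with pytest.raises(ValueError, match="backend"):
            pw.fit_model(paper_medians, backend="nuts")


class TestContrasts:
    def test_cell_means_identity_when_deflections_zero(self):
        s = 200
        post = pw.PosteriorSamples(
            groups=("control", "patient"),
            conditions=pw.DEFAULT_CONDITIONS,
            baseline=np.full(s, 900.0),
            group_deflection=np.zeros((s, 2)),
            distractor_deflection=np.zeros((s, 4)),
            interaction_deflection=np.zeros((s, 2, 4)),
            sigma=np.full(s, 50.0),
            nu=np.full(s, 20.0),
            chain=np.zeros(s, dtype=int),
        )
        assert (post.cell_means() == 900.0).all()
        res = post.contrast({("control", "neutral"): 1.0})
        assert res.mean == 900.0

    def test_self_contrast_rejected(self, paper_posterior):
        # +1 and -1 on the same cell net to all-zero coefficients
        coefs = np.zeros((2, 4))
        coefs[0, 0] = 1.0
        coefs[0, 0] -= 1.0
        with pytest.raises(ValueError, match="all zero"):
            pw.contrast(paper_posterior, coefs)

    def test_degenerate_contrast_flagged(self):
        s = 300
        post = pw.PosteriorSamples(
            groups=("control", "patient"),
            conditions=pw.DEFAULT_CONDITIONS,
            baseline=np.linspace(880, 920, s),
            group_deflection=np.zeros((s, 2)),
            distractor_deflection=np.zeros((s, 4)),
            interaction_deflection=np.zeros((s, 2, 4)),
            sigma=np.full(s, 50.0),
            nu=np.full(s, 20.0),
            chain=np.zeros(s, dtype=int),
        )
        # cells are identical within a draw: their difference is exactly zero
        res = post.contrast({("control", "neutral"): 1.0, ("control", "related"): -1.0})
        assert res.degenerate
        assert res.hdi_low == res.hdi_high == 0.0

    def test_group_difference_sign_convention(self, paper_posterior):
        cm = paper_posterior.cell_means()
        conds = paper_posterior.conditions
        lex = lambda g: cm[:, g, conds.index("unrelated")] - cm[:, g, conds.index("neutral")]
        expected = lex(0) - lex(1)  # control - patient
        res = paper_posterior.named_contrasts()["groupdiff_lexical"]
        assert np.allclose(res.draws, expected)
        # patients show larger lexical interference: difference below zero
        assert res.mean < 0

    def test_tail_percentages_sum_to_100(self, paper_posterior):
        for res in paper_posterior.named_contrasts().values():
            assert res.pct_above_zero + res.pct_below_zero + res.pct_at_zero == pytest.approx(100.0)

    def test_group_contrast_recovers_truth(self, paper_posterior, paper_trials):
        _, truth = paper_trials
        res = paper_posterior.named_contrasts()["group"]
        assert res.decision == "credible_positive"
        assert res.mean == pytest.approx(truth["group_gap_overall_ms"], abs=60.0)


class TestSweep:
    @given(
        b0=st.floats(-1000, 1000),
        seed=st.integers(0, 1000),
    )
    def test_recentring_preserves_cell_means_and_constraints(self, b0, seed):
        rng = np.random.default_rng(seed)
        bg, bc = rng.normal(0, 50, 2), rng.normal(0, 50, 4)
        bgc = rng.normal(0, 50, (2, 4))
        base, g, c, inter = _sweep(b0, bg, bc, bgc)
        original = b0 + bg[:, None] + bc[None, :] + bgc
        recon = base + g[:, None] + c[None, :] + inter
        assert np.allclose(original, recon, atol=1e-9)
        assert abs(g.sum()) < 1e-9
        assert abs(c.sum()) < 1e-9
        assert np.abs(inter.sum(axis=0)).max() < 1e-9
        assert np.abs(inter.sum(axis=1)).max() < 1e-9


def batch_se(draws, n_batches=10):
    batches = np.array_split(draws, n_batches)
    means = [b.mean() for b in batches]
    return np.std(means, ddof=1) / np.sqrt(n_batches)


class TestBackendAgreement:
    def test_gibbs_and_emcee_agree_on_contrast_means(self, paper_medians):
        mcmc_g = pw.McmcConfig(n_samples=8000, thin=2, burn_in=800, n_chains=2, seed=19)
        mcmc_e = pw.McmcConfig(n_samples=8000, thin=10, burn_in=4000, n_chains=1, seed=19)
        post_g = pw.fit_model(paper_medians, mcmc=mcmc_g)
        post_e = pw.fit_model(paper_medians, mcmc=mcmc_e, backend="emcee")
        res_g = pw.named_contrasts(post_g)
        res_e = pw.named_contrasts(post_e)
        for name in res_g:
            # batch means absorb the residual autocorrelation of both chains
            se = np.hypot(batch_se(res_g[name].draws, 8), batch_se(res_e[name].draws, 8))
            diff = abs(res_g[name].mean - res_e[name].mean)
            # 3x combined MC standard error, with a 2 ms numerical floor
            assert diff < 3.0 * se + 2.0, f"{name}: diff {diff:.2f} vs se {se:.2f}"


class TestModelClass:
    def test_fit_stores_priors_and_posterior(self, paper_medians):
        mcmc = pw.McmcConfig(n_samples=600, thin=1, burn_in=150, n_chains=2, seed=2)
        model = pw.RobustSplitPlotAnova(mcmc=mcmc)
        post = model.fit(paper_medians)
        assert post is model.posterior_
        assert isinstance(model.priors_, pw.PriorSpec)
        assert post.n_draws == 600
        # the draws table round-trips every parameter column
        df = post.to_dataframe()
        assert len(df) == 600
        assert "interaction[patient,phonological]" in df.columns


class TestFrequentistConcordance:
    def test_decisions_match_strong_ttest_results(self, paper_posterior, paper_medians):
        effects = pw.compute_effects(paper_medians)
        ttests = pw.effect_ttests(effects)
        bayes = paper_posterior.named_contrasts()
        for _, row in ttests.iterrows():
            if not np.isfinite(row["p"]) or row["p"] >= 0.005:
                continue
            if row["group"] == "between":
                # Welch tests patient - control; the posterior group-difference
                # contrast is signed control - patient
                res = bayes[f"groupdiff_{row['effect']}"]
                expected = "credible_negative" if row["t"] > 0 else "credible_positive"
            else:
                res = bayes[f"{row['group']}_{row['effect']}"]
                expected = "credible_positive" if row["t"] > 0 else "credible_negative"
            assert res.decision == expected, row["comparison"]
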