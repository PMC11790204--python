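"""Ordinal regression, LOO, and the acceptance/threshold/reason logits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gutsgof import inference as inf
from gutsgof import synthetic_survey as ss


def simple_records(n, coef_gof, seed, sd_evaluator=0.0, cutpoints=(-3.9, -3.1, -2.2, -1.3, -0.4)):
    """Records with a uniform gof covariate scored by a known ordinal truth."""
    rng = np.random.default_rng(seed)
    truth = ss.TrueScoreModel(
        coef_gof=coef_gof,
        coef_validation=0.0,
        coef_experience=0.0,
        coef_gof_x_validation=0.0,
        coef_gof_x_experience=0.0,
        cutpoints=tuple(np.array(cutpoints) - 0.0),
        sd_evaluator=sd_evaluator,
    )
    df = pd.DataFrame(
        {
            "evaluator_id": [f"E{i % 20}" for i in range(n)],
            "affiliation": "academia",
            "experience": 3,
            "role": "calibration",
            "avg_gof": rng.uniform(0, 1, size=n),
        }
    )
    if coef_gof == 0.0:
        truth = ss.TrueScoreModel(
            coef_gof=0.0, coef_validation=0.0, coef_experience=0.0,
            coef_gof_x_validation=0.0, coef_gof_x_experience=0.0,
            cutpoints=(-1.5, -0.8, 0.0, 0.8, 1.5), sd_evaluator=sd_evaluator,
        )
    return ss.sample_scores(df, truth, seed=seed + 1), truth


class TestFitCumulative:
    def test_category_probabilities_normalized(self):
        rec, _ = simple_records(300, -4.0, seed=0)
        fit = inf.fit_cumulative(rec, terms=("gof",), seed=1, config=inf.OrdinalConfig(n_draws=500))
        probs = fit.category_probabilities(np.linspace(-6, 0, 11))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()

    def test_null_effect_interval_contains_zero(self):
        hits = 0
        for rep in range(10):
            rec, _ = simple_records(400, 0.0, seed=100 + rep)
            fit = inf.fit_cumulative(
                rec, terms=("gof",), seed=rep, config=inf.OrdinalConfig(n_draws=800)
            )
            lo, hi = fit.coef_interval("gof")
            hits += lo <= 0.0 <= hi
        assert hits >= 9

    def test_negative_effect_recovery(self):
        inside = 0
        for rep in range(10):
            rec, truth = simple_records(600, -4.0, seed=200 + rep)
            fit = inf.fit_cumulative(
                rec, terms=("gof",), seed=rep, config=inf.OrdinalConfig(n_draws=800)
            )
            draws = fit.coef_draws("gof")
            assert (draws < 0).mean() > 0.99
            lo, hi = fit.coef_interval("gof")
            inside += lo <= -4.0 <= hi
        assert inside >= 9

    def test_logit_link_also_recovers(self):
        rng = np.random.default_rng(3)
        n = 800
        df = pd.DataFrame(
            {
                "evaluator_id": [f"E{i % 10}" for i in range(n)],
                "affiliation": "academia",
                "experience": 3,
                "role": "calibration",
                "avg_gof": rng.uniform(0, 1, n),
            }
        )
        truth = ss.TrueScoreModel(
            link="logit", coef_gof=-6.0, coef_validation=0.0, coef_experience=0.0,
            coef_gof_x_validation=0.0, coef_gof_x_experience=0.0, sd_evaluator=0.0,
            cutpoints=(-6.5, -5.2, -4.0, -2.6, -1.2),
        )
        rec = ss.sample_scores(df, truth, seed=4)
        fit = inf.fit_cumulative(rec, terms=("gof",), link="logit", seed=5)
        lo, hi = fit.coef_interval("gof")
        assert lo <= -6.0 <= hi

    def test_constant_predictor_rejected(self):
        rec, _ = simple_records(100, -4.0, seed=6)
        rec["avg_gof"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            inf.fit_cumulative(rec, terms=("gof",), seed=0)

    def test_mcmc_and_laplace_agree(self):
        rec, _ = simple_records(500, -4.0, seed=7)
        lap = inf.fit_cumulative(
            rec, terms=("gof",), seed=1, config=inf.OrdinalConfig(n_draws=1000)
        )
        mc = inf.fit_cumulative(
            rec,
            terms=("gof",),
            seed=1,
            config=inf.OrdinalConfig(
                method="mcmc", n_draws=1000, mcmc_burn=1500, mcmc_keep=250
            ),
        )
        m_lap = np.median(lap.coef_draws("gof"))
        m_mc = np.median(mc.coef_draws("gof"))
        sd = np.std(lap.coef_draws("gof"))
        assert abs(m_lap - m_mc) < 3 * sd

    def test_random_effect_sd_recovered(self):
        rec, truth = simple_records(1200, -4.0, seed=8, sd_evaluator=0.8)
        fit = inf.fit_cumulative(
            rec, terms=("gof",), random_effect="evaluator_id", seed=2,
            config=inf.OrdinalConfig(n_draws=1000),
        )
        assert fit.sd is not None
        med = float(np.median(fit.sd))
        assert abs(med - 0.8) / 0.8 < 0.5


class TestElpdLoo:
    def test_noise_predictor_does_not_win(self):
        wins = 0
        for rep in range(10):
            rec, _ = simple_records(300, -4.0, seed=300 + rep)
            rng = np.random.default_rng(rep)
            rec["noise"] = rng.uniform(0, 1, len(rec))
            cfg = inf.OrdinalConfig(n_draws=800)
            base = inf.elpd_loo(
                inf.fit_cumulative(rec, terms=("gof",), seed=rep, config=cfg)
            )
            rec2 = rec.copy()
            rec2["avg_gof"] = rec2["noise"]
            noisy = inf.elpd_loo(
                inf.fit_cumulative(rec2, terms=("gof",), seed=rep, config=cfg)
            )
            wins += noisy.elpd <= base.elpd + base.se
        assert wins >= 9

    def test_pareto_k_well_behaved(self):
        rec, _ = simple_records(500, -4.0, seed=9)
        fit = inf.fit_cumulative(rec, terms=("gof",), seed=0)
        res = inf.elpd_loo(fit)
        assert (res.pareto_k < 0.7).all()
        assert not res.warning


class TestRankPredictors:
    def test_candidate_count_and_duplicates(self, survey_records):
        ts = survey_records[survey_records["representation"] == "TS"]
        cfg = inf.OrdinalConfig(n_draws=400)
        table = inf.rank_predictors(ts, method="average", config=cfg, seed=0)
        assert len(table) == 31
        assert table["size"].value_counts().to_dict() == {1: 5, 2: 10, 3: 10, 4: 5, 5: 1}
        assert table["converged"].all()
        # ranking consistent with elpd ordering
        ranked = table.dropna(subset=["rank"]).sort_values("rank")
        assert (np.diff(ranked["elpd"]) <= 1e-9).all()

    def test_minimum_combination_rule(self, survey_records):
        ts = survey_records[survey_records["representation"] == "TS"].head(400)
        cfg = inf.OrdinalConfig(n_draws=300)
        table = inf.rank_predictors(ts, method="minimum", config=cfg, seed=1)
        assert len(table) == 31


class TestAcceptanceLogit:
    def make_accept_records(self, n, a, b, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 1, n)
        accept = rng.uniform(size=n) < expit(a + b * g)
        return pd.DataFrame({"avg_gof": g, "score": np.where(accept, 2, 5)})

    def test_recovery_of_known_coefficients(self):
        rec = self.make_accept_records(1000, -7.4, 10.0, seed=0)
        fit = inf.fit_acceptance_logit(rec, "avg_gof")
        se = np.sqrt(np.diag(fit.cov))
        assert abs(fit.intercept + 7.4) < 2 * se[0]
        assert abs(fit.slope - 10.0) < 2 * se[1]
        assert ((fit.predicted(np.linspace(0, 1, 9)) > 0) &
                (fit.predicted(np.linspace(0, 1, 9)) < 1)).all()

    def test_null_slope_interval_contains_zero(self):
        rec = self.make_accept_records(500, 0.0, 0.0, seed=1)
        fit = inf.fit_acceptance_logit(rec, "avg_gof")
        t = fit.table().set_index("coefficient")
        assert t.loc["avg_gof", "ci_lower"] <= 0 <= t.loc["avg_gof", "ci_upper"]

    def test_single_outcome_rejected(self):
        rec = pd.DataFrame({"avg_gof": [0.1, 0.9], "score": [2, 2]})
        with pytest.raises(ValueError, match="both acceptance outcomes"):
            inf.fit_acceptance_logit(rec, "avg_gof")


class TestThreshold:
    def test_analytic_root(self):
        fit = inf.LogitFit(
            params=np.array([-3.0, 5.0]), cov=np.eye(2) * 1e-4,
            names=["intercept", "g"], predictor="g", n=100, data_range=(0.0, 1.0),
        )
        res = inf.acceptance_threshold(fit)
        assert res.threshold == pytest.approx(0.6, abs=1e-10)
        assert not res.flagged

    def test_scale_invariance(self):
        for c in (0.5, 2.0, 7.0):
            fit = inf.LogitFit(
                params=np.array([-3.0 * c, 5.0 * c]), cov=np.eye(2) * 1e-6,
                names=["intercept", "g"], predictor="g", n=100, data_range=(0.0, 1.0),
            )
            assert inf.acceptance_threshold(fit).threshold == pytest.approx(0.6, abs=1e-10)

    def test_recovery_of_true_threshold(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0, 1, 1000)
        accept = rng.uniform(size=1000) < expit(10.0 * (g - 0.74))
        rec = pd.DataFrame({"avg_gof": g, "score": np.where(accept, 1, 6)})
        fit = inf.fit_acceptance_logit(rec, "avg_gof")
        res = inf.acceptance_threshold(fit)
        assert abs(res.threshold - 0.74) < 0.05
        assert res.lower < res.threshold < res.upper

    def test_wrong_sign_flagged(self):
        fit = inf.LogitFit(
            params=np.array([3.0, -5.0]), cov=np.eye(2) * 1e-4,
            names=["intercept", "g"], predictor="g", n=100, data_range=(0.0, 1.0),
        )
        res = inf.acceptance_threshold(fit, positive_slope_expected=True)
        assert res.flagged and "slope" in res.message


class TestRejectionReasonModel:
    def make_reason_records(self, n, seed, truth=None):
        """Independent uniform metrics so coefficients are identifiable."""
        truth = truth or ss.TrueScoreModel()
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "s_sppe_min": rng.uniform(0, 1, n),
                "s_sppe_max": rng.uniform(0, 1, n),
                "s_nrmse": rng.uniform(0, 1, n),
                "s_ppc": rng.uniform(0, 1, n),
                "representation": "TS",
                "score": 5,
            }
        )
        return ss.sample_rejection_reasons(df, truth, seed=seed + 1)

    def test_sign_recovery(self):
        truth = ss.TrueScoreModel()
        expected_signs = {"s_sppe_min": -1, "s_sppe_max": -1, "s_nrmse": 1, "s_ppc": 1}
        ok = 0
        for rep in range(10):
            rec = self.make_reason_records(800, seed=400 + rep, truth=truth)
            fit = inf.fit_rejection_reason_model(rec)
            t = fit.table().set_index("coefficient")
            ok += all(
                np.sign(t.loc[k, "estimate"]) == s for k, s in expected_signs.items()
            )
        assert ok >= 9

    def test_accepted_scores_excluded(self):
        rec = self.make_reason_records(300, seed=3)
        spiked = pd.concat(
            [rec, rec.assign(score=2, reasons="")], ignore_index=True
        )
        a = inf.fit_rejection_reason_model(rec)
        b = inf.fit_rejection_reason_model(spiked)
        np.testing.assert_allclose(a.params, b.params, atol=1e-8)

    def test_constant_metric_rejected(self):
        rec = self.make_reason_records(200, seed=4)
        rec["s_ppc"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            inf.fit_rejection_reason_model(rec)

    def test_single_group_rejected(self):
        rec = self.make_reason_records(100, seed=5)
        rec["reasons"] = "a"
        with pytest.raises(ValueError, match="both reason groups"):
            inf.fit_rejection_reason_model(rec)


class TestRepresentationAcceptance:
    def make_rep_records(self, n, p_ts, p_drc, seed):
        rng = np.random.default_rng(seed)
        rep = np.where(rng.uniform(size=n) < 0.5, "TS", "DRC")
        p = np.where(rep == "TS", p_ts, p_drc)
        accept = rng.uniform(size=n) < p
        return pd.DataFrame({"representation": rep, "score": np.where(accept, 2, 5)})

    def test_null_difference(self):
        rec = self.make_rep_records(800, 0.6, 0.6, seed=0)
        fit = inf.fit_representation_acceptance(rec)
        t = fit.table().set_index("coefficient")
        assert t.loc["DRC", "ci_lower"] <= 0 <= t.loc["DRC", "ci_upper"]

    def test_drc_advantage_recovered(self):
        rec = self.make_rep_records(1500, 0.5, 0.75, seed=1)
        fit = inf.fit_representation_acceptance(rec)
        t = fit.table().set_index("coefficient")
        assert t.loc["DRC", "estimate"] > 0
        assert t.loc["DRC", "ci_lower"] > 0

    def test_missing_representation_rejected(self):
        rec = pd.DataFrame({"representation": ["TS"] * 4, "score": [1, 2, 5, 6]})
        with pytest.raises(ValueError, match="both representations"):
            inf.fit_representation_acceptance(rec)
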