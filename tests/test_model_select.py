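"""Design coding, information criteria, stepwise search, OLS inference, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortivoc.cohort import CohortConfig, generate_cohort
from cortivoc.model_select import (
    aicc,
    bh_adjust,
    bic,
    build_design,
    compare_models,
    exhaustive_best_subset,
    fit_ols,
    stepwise,
)
from cortivoc.preprocess import preprocess_pipeline


def tiny_meta():
    rows = [
        ("s0", "A", "female", "evening"),
        ("s1", "B", "male", "morning"),
        ("s2", "C", "female", "afternoon"),
        ("s3", "D", "male", "evening"),
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "sex", "timepoint"]
    ).set_index("sample_id", drop=False)


class TestBuildDesign:
    def setup_method(self):
        self.meta = tiny_meta()
        self.z = pd.DataFrame(
            {"g1": [0.5, 1.0, -1.0, 2.0], "g2": [1.0, -2.0, 0.0, 0.5]},
            index=self.meta.index,
        )

    def test_reference_cell_all_zero(self):
        d = build_design(self.z, self.meta, ["g1", "g2"], ("sex", "time"))
        ref = d.loc["s0"]
        for c in d.columns:
            if c not in ("g1", "g2"):
                assert ref[c] == 0.0

    def test_product_coding(self):
        d = build_design(self.z, self.meta, ["g1"], ("sex", "time"))
        row = d.loc["s1"]  # male morning, g1 = 1.0
        assert row["Male"] == 1.0 and row["Morning"] == 1.0 and row["Afternoon"] == 0.0
        assert row["g1:Male"] == 1.0 and row["g1:Morning"] == 1.0
        assert d.loc["s2", "g1:Afternoon"] == -1.0

    def test_column_count(self):
        d = build_design(self.z, self.meta, ["g1", "g2"], ("sex", "time"))
        # 2 mains + 3 dummies + 2*3 products
        assert d.shape[1] == 11

    def test_factor_subset(self):
        d = build_design(self.z, self.meta, ["g1"], ("sex",))
        assert set(d.columns) == {"g1", "Male", "g1:Male"}

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            build_design(self.z, self.meta, ["g1"], ("weather",))


class TestInformationCriteria:
    def test_closed_form_value(self):
        # intercept only, n=100, rss=100: aic = 100*ln(1) + 2 = 2; aicc adds 4/98
        assert aicc(100.0, 100, 1) == pytest.approx(2.0 + 4.0 / 98.0)
        assert bic(100.0, 100, 1) == pytest.approx(math.log(100))

    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_aicc_exceeds_aic(self, k):
        n = 50
        aic = n * math.log(2.0 / n) + 2 * k
        assert aicc(2.0, n, k) > aic

    def test_aicc_converges_to_aic(self):
        n, k = 10**7, 5
        aic = n * math.log(1.0) + 2 * k
        assert abs(aicc(float(n), n, k) - aic) < 1e-3

    def test_undefined_small_n(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 5)
        with pytest.raises(ValueError):
            aicc(0.0, 100, 2)


class TestFitOLS:
    def test_textbook_single_predictor(self):
        # hand-computable instance: y = 1 + 2x plus small perturbations
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.9, 5.2, 6.8, 9.0])
        design = pd.DataFrame({"x": x})
        fit = fit_ols(design, y)
        # oracle: closed-form simple regression
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = (resid**2).sum() / 3
        se_slope = math.sqrt(s2 / sxx)
        tcrit = stats.t.ppf(0.975, 3)
        assert fit.beta["x"] == pytest.approx(slope)
        assert fit.beta["Intercept"] == pytest.approx(intercept)
        assert fit.se["x"] == pytest.approx(se_slope)
        assert fit.ci95_low["x"] == pytest.approx(slope - tcrit * se_slope)
        assert fit.ci95_high["x"] == pytest.approx(slope + tcrit * se_slope)
        t_stat = slope / se_slope
        assert fit.p_raw["x"] == pytest.approx(2 * stats.t.sf(abs(t_stat), 3))

    def test_intercept_only(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fit = fit_ols(pd.DataFrame(index=range(4)), y)
        assert fit.beta["Intercept"] == pytest.approx(y.mean())
        assert fit.adj_r2 == pytest.approx(0.0)

    def test_perfect_fit_guarded(self):
        x = np.arange(6, dtype=float)
        y = 2.0 + 0.5 * x
        fit = fit_ols(pd.DataFrame({"x": x}), y)
        assert fit.adj_r2 == 1.0
        assert fit.p_raw["x"] <= 1e-12

    def test_matches_qr_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        design = pd.DataFrame(X, columns=[f"c{j}" for j in range(5)])
        fit = fit_ols(design, y)
        Xi = np.column_stack([np.ones(40), X])
        q, r = np.linalg.qr(Xi)
        beta = np.linalg.solve(r, q.T @ y)
        got = np.array([fit.beta["Intercept"]] + [fit.beta[f"c{j}"] for j in range(5)])
        assert np.allclose(got, beta, atol=1e-8)

    def test_rank_deficiency_names_terms(self):
        x = np.arange(8, dtype=float)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(design, x)

    def test_ci_brackets_beta_and_k_counts_intercept(self):
        rng = np.random.default_rng(12)
        design = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        y = rng.standard_normal(30)
        fit = fit_ols(design, y)
        assert fit.k == 4
        for t in ["Intercept", "a", "b", "c"]:
            assert fit.ci95_low[t] <= fit.beta[t] <= fit.ci95_high[t]
            assert fit.p_bh[t] >= fit.p_raw[t] - 1e-15


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_hand_step_up_mixed(self):
        # oracle: p_bh(i) = min_{j: p(j) >= p(i)} min(1, m p(j)/rank(j))
        p = np.array([0.005, 0.04, 0.03, 0.9])
        expected = np.array([0.02, 0.0533333333, 0.0533333333, 0.9])
        assert np.allclose(bh_adjust(p), expected)

    def test_equal_and_single(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        assert np.allclose(bh_adjust([0.07]), [0.07])

    def test_monotone_and_rank_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (np.argsort(np.argsort(p)) <= np.argsort(np.argsort(adj + 1e-12 * p))).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def random_instance(rng, n=40, p=8, k_true=3, snr=3.0):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.zeros(p)
    support = rng.choice(p, size=k_true, replace=False)
    beta[support] = snr * rng.uniform(0.3, 1.0, k_true) * rng.choice([-1, 1], k_true)
    y = X @ beta + rng.standard_normal(n)
    return pd.DataFrame(X, columns=[f"t{j}" for j in range(p)]), y


class TestStepwise:
    def test_criterion_never_beats_exhaustive_and_usually_matches(self):
        """On small instances the greedy search never finds a better criterion
        than full enumeration, and matches it most of the time."""
        rng = np.random.default_rng(17)
        matches, total = 0, 50
        for _ in range(total):
            design, y = random_instance(rng, n=35, p=8)
            fit = stepwise(design, y, direction="both", criterion="aicc", hierarchy=False)
            _, best_crit = exhaustive_best_subset(design, y, "aicc")
            assert fit.aicc >= best_crit - 1e-8
            matches += abs(fit.aicc - best_crit) < 1e-8
        assert matches >= 0.8 * total

    def test_null_design_bic_selects_intercept_only(self):
        """Pure-noise candidates: BIC keeps the intercept-only model in the
        majority of replicates."""
        rng = np.random.default_rng(23)
        empty = 0
        for _ in range(50):
            X = rng.standard_normal((45, 6))
            design = pd.DataFrame(X, columns=[f"n{j}" for j in range(6)])
            y = rng.standard_normal(45)
            fit = stepwise(design, y, direction="forward", criterion="bic")
            empty += len(fit.terms) == 0
        assert empty > 25

    def test_high_snr_recovery_including_interaction(self):
        """A planted sparse model with interactions is fully recovered at
        high signal-to-noise by backward elimination.  (Forward addition can
        stall when an interaction cancels its main effect's marginal signal,
        which is why both directions are provided.)"""
        cfg = CohortConfig(
            n_subjects=40, n_features=30, n_informative=3, effect_scale=0.5,
            noise_sd=0.03, subject_sd=0.0, missing_rate=0.0, outlier_rate=0.0,
            n_sex_interactions=1, n_time_interactions=1, seed=71,
        )
        meta, table, truth = generate_cohort(cfg)
        proc, kept = preprocess_pipeline(table, meta)
        design = build_design(proc, kept, truth.support, ("sex", "time"))
        y = np.log10(kept["cortisol_ug"].to_numpy())
        fit = stepwise(design, y, direction="backward", criterion="aicc")
        selected = set(fit.terms)
        planted = set(truth.support) | {f"{f}:{d}" for f, d in truth.interactions}
        assert planted <= selected

    def test_criterion_trace_non_increasing(self):
        rng = np.random.default_rng(29)
        design, y = random_instance(rng, n=50, p=10)
        fit = stepwise(design, y, direction="both", criterion="aicc", hierarchy=False)
        crits = [c for _, c in fit.stepwise_trace]
        assert all(b <= a + 1e-12 for a, b in zip(crits, crits[1:]))

    def test_hierarchy_constraint(self):
        """An interaction never appears without its main effect."""
        cfg = CohortConfig(
            n_subjects=25, n_features=12, n_informative=3, effect_scale=0.4,
            noise_sd=0.1, subject_sd=0.0, missing_rate=0.0, outlier_rate=0.0,
            n_sex_interactions=2, n_time_interactions=2, seed=73,
        )
        meta, table, truth = generate_cohort(cfg)
        proc, kept = preprocess_pipeline(table, meta)
        design = build_design(proc, kept, list(proc.z.columns[:8]), ("sex", "time"))
        y = np.log10(kept["cortisol_ug"].to_numpy())
        fit = stepwise(design, y, direction="both", criterion="aicc", hierarchy=True)
        terms = set(fit.terms)
        for t in terms:
            if ":" in t and not t.split(":")[0] in ("Male", "Morning", "Afternoon"):
                assert t.split(":")[0] in terms

    def test_log_response_changes_only_the_response(self):
        rng = np.random.default_rng(31)
        design, _ = random_instance(rng, n=30, p=4)
        y = np.exp(rng.standard_normal(30))
        f_raw = fit_ols(design, y)
        f_log = fit_ols(design, np.log10(y))
        assert f_raw.terms == f_log.terms
        assert f_raw.beta != f_log.beta


class TestCompareModels:
    def test_bic_breaks_aicc_tie(self):
        rng = np.random.default_rng(41)
        design, y = random_instance(rng, n=40, p=6)
        f1 = fit_ols(design[["t0", "t1"]], y)
        f2 = fit_ols(design[["t2", "t3"]], y)
        f1.aicc = f2.aicc = 10.0
        f1.bic, f2.bic = 14.0, 12.0
        report = compare_models([f1, f2], names=["a", "b"])
        assert report.iloc[0]["name"] == "b"

    def test_overfit_flag(self):
        rng = np.random.default_rng(43)
        design, y = random_instance(rng, n=24, p=10)
        fit = fit_ols(design, y)  # k = 11 > 24/3
        report = compare_models([fit])
        assert bool(report.iloc[0]["overfit_flag"])

    def test_single_fit_ranked_first(self):
        rng = np.random.default_rng(47)
        design, y = random_instance(rng, n=30, p=3)
        report = compare_models([fit_ols(design, y)], names=["only"])
        assert list(report["name"]) == ["only"]

    def test_differing_sample_sets_rejected(self):
        rng = np.random.default_rng(53)
        design, y = random_instance(rng, n=30, p=3)
        f1 = fit_ols(design, y)
        f2 = fit_ols(design.iloc[:-2], y[:-2])
        with pytest.raises(ValueError, match="sample sets"):
            compare_models([f1, f2])
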