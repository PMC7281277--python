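"""PQN, filters and standardization: oracles, boundaries, invariants."""

import numpy as np
import pandas as pd
import pytest

from cortivoc.cohort import CohortConfig, generate_cohort
from cortivoc.preprocess import (
    blank_and_early_filter,
    log_standardize,
    outlier_filter,
    pqn_normalize,
    preprocess_pipeline,
    presence_filter,
)
from tests.conftest import make_table


class TestPQN:
    def test_identical_samples_unchanged(self):
        row = [10.0, 20.0, 30.0, 40.0]
        table = make_table([row, row, row])
        out, q = pqn_normalize(table)
        assert np.allclose(q, 1.0)
        pd.testing.assert_frame_equal(out.abundance, table.abundance)

    def test_doubled_sample_gets_quotient_two(self):
        base = np.array([10.0, 20.0, 30.0, 40.0])
        table = make_table([base, base, 2 * base])
        out, q = pqn_normalize(table)
        assert q.iloc[2] == pytest.approx(2.0)
        assert np.allclose(out.abundance.iloc[2], base)

    def test_matches_median_of_ratios_oracle(self):
        x = np.array(
            [[2.0, 8.0, 5.0, 1.0], [4.0, 2.0, 10.0, 3.0], [6.0, 4.0, 20.0, 9.0]]
        )
        table = make_table(x)
        _, q = pqn_normalize(table)
        ref = np.median(x, axis=0)
        expected = [np.median(x[i] / ref) for i in range(3)]
        assert np.allclose(q, expected)

    def test_idempotent_on_dilution_family(self):
        """Exact idempotence where it holds exactly: samples that are scalar
        multiples of one spectrum normalize once and stay fixed."""
        rng = np.random.default_rng(4)
        spectrum = rng.uniform(1.0, 100.0, size=30)
        d = rng.uniform(0.3, 3.0, size=11)
        table = make_table(np.outer(d, spectrum))
        once, q1 = pqn_normalize(table)
        twice, q2 = pqn_normalize(once)
        assert np.allclose(q1, d / np.median(d))
        assert np.allclose(q2, 1.0, atol=1e-10)
        pd.testing.assert_frame_equal(once.abundance, twice.abundance)

    def test_approximately_idempotent_on_generic_table(self, default_cohort):
        """On generic tables the re-computed median reference shifts slightly;
        second-pass quotients stay within ~1% of unity."""
        _, table, _ = default_cohort
        once, _ = pqn_normalize(table)
        _, q2 = pqn_normalize(once)
        assert np.allclose(q2, 1.0, atol=0.02)

    def test_undoes_synthetic_dilution(self):
        """Diluting each sample of a common-spectrum table is exactly undone
        up to one global factor."""
        rng = np.random.default_rng(5)
        spectrum = rng.uniform(1.0, 100.0, size=40)
        d0 = rng.uniform(0.5, 2.0, size=15)
        base = np.outer(d0, spectrum)
        normalized, _ = pqn_normalize(make_table(base))
        d = rng.uniform(0.5, 2.0, size=15)
        recovered, q = pqn_normalize(make_table(normalized.abundance.mul(d, axis=0)))
        ratio = q.to_numpy() / d
        assert np.allclose(ratio, ratio[0], rtol=1e-10)
        common = recovered.abundance / normalized.abundance
        assert np.allclose(common, common.iloc[0, 0], rtol=1e-10)

    def test_dilution_recovery_on_generic_cohort(self, default_cohort):
        """On a realistic cohort, per-sample dilution is reverted to within
        the reference-shift error (~2%)."""
        _, table, _ = default_cohort
        normalized, _ = pqn_normalize(table)
        rng = np.random.default_rng(0)
        d = rng.uniform(0.5, 2.0, size=table.n_samples)
        diluted = make_table(normalized.abundance.mul(d, axis=0).set_axis(
            normalized.abundance.index, axis=0))
        recovered, q = pqn_normalize(diluted)
        ratio = q.to_numpy() / d
        assert np.allclose(ratio / np.median(ratio), 1.0, atol=0.05)

    def test_missing_stays_missing(self):
        x = pd.DataFrame([[1.0, np.nan, 3.0], [2.0, 4.0, 6.0], [1.5, 3.0, 4.5]])
        out, _ = pqn_normalize(make_table(x))
        assert out.mask.to_numpy().sum() == 1
        assert np.isnan(out.abundance.iloc[0, 1])

    def test_all_zero_reference_rejected(self):
        # sample s0 observes only feature f0, whose reference median is 0
        x = pd.DataFrame(
            [[0.0, np.nan, np.nan], [0.0, 5.0, 6.0], [0.0, 7.0, 8.0]]
        )
        with pytest.raises(ValueError, match="s0"):
            pqn_normalize(make_table(x))


class TestPresenceFilter:
    def test_boundary_at_half(self):
        x = np.ones((6, 2))
        x[3:, 0] = np.nan  # f0 observed in 3/6 = 50%
        x[2:, 1] = np.nan  # f1 observed in 2/6
        out = presence_filter(make_table(x), 0.5)
        assert list(out.abundance.columns) == ["f0"]

    def test_full_presence_required(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        x[1, 1] = np.nan
        x[2, 2] = np.nan
        out = presence_filter(make_table(x), 1.0)
        assert out.n_features == 0

    def test_matches_counting_oracle_on_cohort(self):
        meta, table, _ = generate_cohort(
            CohortConfig(seed=17, n_subjects=20, n_features=80, missing_rate=0.5)
        )
        out = presence_filter(table, 0.5)
        counts = table.abundance.notna().sum(axis=0)
        expected = counts[counts >= 0.5 * table.n_samples].index.tolist()
        assert list(out.abundance.columns) == expected
        assert 0 < out.n_features < 80

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            presence_filter(make_table(np.ones((3, 2))), 0.0)


class TestBlankAndEarlyFilter:
    def test_rt_boundary(self):
        table = make_table(np.ones((3, 2)), rt1=[357.9, 358.0])
        out = blank_and_early_filter(table)
        assert list(out.abundance.columns) == ["f1"]

    def test_blank_flag_dropped_regardless_of_rt(self):
        table = make_table(np.ones((3, 2)), rt1=[1000.0, 1000.0], blank=[True, False])
        out = blank_and_early_filter(table)
        assert list(out.abundance.columns) == ["f1"]

    def test_identity_when_clean(self):
        table = make_table(np.ones((3, 3)), rt1=[358.0, 500.0, 2000.0])
        out = blank_and_early_filter(table)
        assert out.n_features == 3

    def test_commutes_with_presence_filter(self, default_cohort):
        _, table, _ = default_cohort
        fm = table.feature_meta.copy()
        fm.loc[fm.index[:40], "rt1_s"] = 100.0  # force some early peaks
        t = make_table(table.abundance, rt1=fm["rt1_s"].to_numpy())
        a = presence_filter(blank_and_early_filter(t), 0.5)
        b = blank_and_early_filter(presence_filter(t, 0.5))
        pd.testing.assert_frame_equal(a.abundance, b.abundance)


class TestOutlierFilter:
    def make_meta(self, values):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "cortisol_ug": values,
            }
        )

    def test_above_ceiling_dropped(self):
        kept, dropped = outlier_filter(self.make_meta([5.0, 97.0, 12.0]))
        assert list(dropped["cortisol_ug"]) == [97.0]

    def test_borderline_value_kept_unless_excluded(self):
        meta = self.make_meta([44.3, 10.0])
        kept, dropped = outlier_filter(meta)
        assert len(dropped) == 0
        kept, dropped = outlier_filter(meta, exclude=["s0"])
        assert list(dropped["sample_id"]) == ["s0"]

    def test_no_outliers(self):
        kept, dropped = outlier_filter(self.make_meta([1.0, 2.0, 3.0]))
        assert len(dropped) == 0 and len(kept) == 3


class TestLogStandardize:
    def test_columns_mean_zero_sd_one(self, default_cohort):
        _, table, _ = default_cohort
        proc = log_standardize(presence_filter(table))
        assert np.allclose(proc.z.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(proc.z.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_matches_hand_computation(self):
        table = make_table(np.array([[10.0], [100.0], [1000.0]]))
        proc = log_standardize(table)
        expected = np.array([-1.0, 0.0, 1.0])  # log10 -> {1,2,3}, sd = 1
        assert np.allclose(proc.z["f0"], expected)
        assert proc.feature_mean["f0"] == pytest.approx(2.0)
        assert proc.feature_sd["f0"] == pytest.approx(1.0)

    def test_half_min_imputation(self):
        x = pd.DataFrame({"f0": [8.0, 16.0, np.nan], "f1": [1.0, 2.0, 4.0]})
        proc = log_standardize(make_table(x))
        # imputed value 4 enters the log step: z reconstructs from log10(4)
        z_expected = (np.log10(4.0) - proc.feature_mean["f0"]) / proc.feature_sd["f0"]
        assert proc.z.loc["s2", "f0"] == pytest.approx(z_expected)

    def test_zero_variance_feature_named(self):
        x = pd.DataFrame({"flat": [5.0, 5.0, 5.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            log_standardize(make_table(x))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            log_standardize(make_table(np.ones((3, 2))), impute="magic")


def test_pipeline_composition(default_cohort):
    meta, table, truth = default_cohort
    proc, kept = preprocess_pipeline(table, meta)
    assert proc.z.shape[0] == len(kept) == 180 - len(truth.outlier_samples)
    assert set(proc.dropped_samples) == set(truth.outlier_samples)
    assert np.allclose(proc.z.mean(axis=0), 0.0, atol=1e-8)
    assert set(truth.support) <= set(proc.retained)
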