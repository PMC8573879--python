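"""Normality gate, transform policy, ROUT, ANCOVA, BH-FDR, categorical."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aminoflux import (InputError, ModelError, StatsConfig, ancova, bh_fdr,
                       categorical_compare, dagostino_pearson,
                       percent_difference, percent_difference_ci,
                       rout_outliers, transform_policy)
from aminoflux.stats import compare_endpoints, group_mean_ci

CFG = StatsConfig()


class TestNormality:
    def test_normal_sample_passes(self, rng):
        res = dagostino_pearson(rng.normal(0, 1, 5000))
        assert res.testable and res.p > 0.001

    def test_lognormal_sample_fails(self, rng):
        res = dagostino_pearson(rng.lognormal(0, 1, 5000))
        assert res.p < 1e-6

    def test_small_sample_untestable(self):
        res = dagostino_pearson([1.0, 2.0, 3.0, 4.0, 5.0])
        assert not res.testable and np.isnan(res.p)


class TestTransformPolicy:
    def test_normal_sample_unchanged(self, rng):
        x = rng.normal(10, 1, 200)
        out, flag, status = transform_policy(x, CFG)
        assert not flag and status == "normal"
        np.testing.assert_array_equal(out, x)

    def test_lognormal_sample_ln_transformed(self, rng):
        x = rng.lognormal(0, 1, 200)
        out, flag, status = transform_policy(x, CFG)
        assert flag and status == "transformed"
        np.testing.assert_allclose(out, np.log(x))

    def test_nonpositive_nonnormal_left_untransformed(self, rng):
        x = np.concatenate([rng.lognormal(0, 1, 199), [0.0]])
        out, flag, status = transform_policy(x, CFG)
        assert not flag and status == "non_transformable"


class TestROUT:
    def test_planted_outlier_exactly_flagged(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 20), [10.0]])
        kept, out = rout_outliers(x, 0.05)
        assert list(out) == [20]
        assert kept.size == 20

    def test_false_flag_dataset_rate_bounded(self, rng):
        """Clean N(0,1) samples: share of datasets with any flag stays
        near the nominal Q."""
        flagged = sum(
            rout_outliers(rng.normal(0, 1, 30), 0.05)[1].size > 0
            for _ in range(1000))
        assert flagged / 1000 <= 2 * 0.05

    def test_small_sample_untouched(self):
        x = np.arange(8.0)
        kept, out = rout_outliers(x, 0.05)
        np.testing.assert_array_equal(kept, x)
        assert out.size == 0


class TestAncova:
    @staticmethod
    def _sim(rng, n=25, effect=0.0):
        age = rng.uniform(46, 76, 2 * n)
        bmi = rng.normal(30, 6, 2 * n)
        g = np.array(["CN"] * n + ["CD"] * n)
        y = 0.05 * age + 0.1 * bmi + rng.normal(0, 1, 2 * n)
        y[g == "CD"] += effect
        return y, g, pd.DataFrame({"age": age, "bmi": bmi})

    def test_null_rejection_rate_calibrated(self, rng):
        rej = sum(ancova(*self._sim(rng), CFG).p < 0.05
                  for _ in range(2000))
        assert 0.04 <= rej / 2000 <= 0.06

    def test_planted_effect_recovered_unbiased(self, rng):
        ests = np.array([ancova(*self._sim(rng, effect=1.0), CFG).estimate
                         for _ in range(300)])
        mc_se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 1.0) < 3 * mc_se

    def test_constant_group_label_rejected(self, rng):
        y, g, cov = self._sim(rng)
        g[:] = "CN"
        with pytest.raises(ModelError):
            ancova(y, g, cov, CFG)

    def test_constant_covariate_rejected(self, rng):
        y, g, cov = self._sim(rng)
        cov["bmi"] = 30.0
        with pytest.raises(ModelError):
            ancova(y, g, cov, CFG)


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_ties_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.5, 0.5, 0.5]), [0.5] * 3)
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_properties(self, ps):
        """q >= p elementwise, q <= 1, and step-up formula agreement."""
        q = bh_fdr(ps)
        p = np.asarray(ps)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)
        order = np.argsort(p)
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        expect = np.minimum.accumulate(ranked[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(expect, 1.0),
                                   atol=1e-12)


class TestCategorical:
    def test_sleep_disordered_breathing_association(self):
        # CN 7 yes / 44 no vs CD 12 yes / 15 no
        p = categorical_compare([[7, 44], [12, 15]])
        assert p <= 0.01

    def test_identical_proportions(self):
        assert categorical_compare([[10, 10], [10, 10]]) == 1.0

    def test_empty_margin_undefined(self):
        assert np.isnan(categorical_compare([[0, 0], [5, 5]]))


class TestPercentDifference:
    def test_arithmetic(self):
        assert percent_difference(100.0, 85.0) == pytest.approx(-15.0)
        assert percent_difference(42.0, 42.0) == 0.0
        with pytest.raises(InputError):
            percent_difference(0.0, 1.0)

    def test_bootstrap_ci_covers_truth(self, rng):
        """Nominal 95% bootstrap CI covers the true -15% in >= 90% of
        simulated cohorts."""
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            cn = rng.normal(100, 12, 40)
            cd = rng.normal(85, 12, 25)
            _, (lo, hi) = percent_difference_ci(cn, cd, n_boot=400,
                                               rng=rng)
            cover += lo <= -15.0 <= hi
        assert cover / n_rep >= 0.90


class TestCompareEndpoints:
    def test_geometric_mean_reporting_iff_transformed(self, rng):
        n = 40
        subjects = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(2 * n)],
            "group": ["CN"] * n + ["CD"] * n,
            "age": rng.uniform(46, 76, 2 * n),
            "bmi": rng.normal(30, 5, 2 * n),
        })
        skewed = rng.lognormal(3.0, 0.9, 2 * n)
        normal = rng.normal(50, 5, 2 * n)
        long = pd.concat([
            pd.DataFrame({"subject_id": subjects["subject_id"],
                          "endpoint": "conc_A", "value": skewed}),
            pd.DataFrame({"subject_id": subjects["subject_id"],
                          "endpoint": "conc_B", "value": normal}),
        ])
        out = compare_endpoints(long, subjects).set_index("endpoint")
        assert bool(out.loc["conc_A", "transformed"])
        assert not bool(out.loc["conc_B", "transformed"])
        # geometric mean bracketed by its back-transformed CI
        assert (out.loc["conc_A", "ci_cn_low"]
                <= out.loc["conc_A", "mean_cn"]
                <= out.loc["conc_A", "ci_cn_high"])
        # q >= p wherever both are defined
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_rout_disabled_identical_when_nothing_removed(self, rng):
        n = 20
        subjects = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(2 * n)],
            "group": ["CN"] * n + ["CD"] * n,
            "age": rng.uniform(46, 76, 2 * n),
            "bmi": rng.normal(30, 5, 2 * n),
        })
        long = pd.DataFrame({
            "subject_id": list(subjects["subject_id"]) * 2,
            "endpoint": ["conc_A"] * 2 * n + ["conc_B"] * 2 * n,
            "value": rng.normal(100, 10, 4 * n),
        })
        with_rout = compare_endpoints(long, subjects, apply_rout=True)
        without = compare_endpoints(long, subjects, apply_rout=False)
        clean = with_rout["outliers_removed"] == 0
        for col in ("p", "q", "mean_cn", "mean_cd",
                    "estimated_difference"):
            np.testing.assert_allclose(
                with_rout.loc[clean, col], without.loc[clean, col],
                rtol=1e-12)


def test_group_mean_ci_brackets_point():
    m, (lo, hi) = group_mean_ci([1.0, 2.0, 3.0, 4.0])
    assert lo <= m <= hi
    gm, (glo, ghi) = group_mean_ci(np.log([10.0, 20.0, 40.0]),
                                   geometric=True)
    assert glo <= gm <= ghi
    assert gm == pytest.approx((10 * 20 * 40) ** (1 / 3))
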