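"""Survival curves and tests, concordance, exact differentials, tertiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from stadsub.characterize import (
    bh_adjust,
    categorize_omics,
    clinical_table,
    concordance,
    differential_category_test,
    differential_mutation_test,
    fisher_exact_2x2,
    fisher_exact_2xc,
    km_estimator,
    logrank_test,
    median_survival,
    tertile_survival,
)

from conftest import make_layer


def surv_df(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": samples, "os_days": times, "os_event": events})


def labels_series(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=samples)


class TestKaplanMeier:
    def test_uniform_deaths_drop_by_quarter(self):
        km = km_estimator(surv_df([1, 2, 3, 4], [1, 1, 1, 1]), labels_series(["a"] * 4))
        s = km["a"].set_index("time")["survival"]
        assert np.allclose(s.loc[[1, 2, 3, 4]], [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_one(self):
        km = km_estimator(surv_df([5, 6, 7], [0, 0, 0]), labels_series(["a"] * 3))
        assert (km["a"]["survival"] == 1.0).all()

    def test_mixed_case_matches_hand_product(self):
        # times 1+,2,3+,4,5,6 (+ censored): S(2)=4/5, S(4)=4/5*2/3, S(5)=4/5*2/3*1/2
        km = km_estimator(surv_df([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 1, 0]), labels_series(["a"] * 6))
        s = km["a"].set_index("time")["survival"]
        assert s.loc[2] == pytest.approx(4 / 5)
        assert s.loc[4] == pytest.approx(4 / 5 * 2 / 3)
        assert s.loc[5] == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)

    def test_median_survival_helper(self):
        km = km_estimator(surv_df([1, 2, 3, 4], [1, 1, 1, 1]), labels_series(["a"] * 4))
        assert median_survival(km["a"]) == 2.0


class TestLogrankTest:
    def test_identical_groups_null(self):
        surv = surv_df([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        chi2, df, p = logrank_test(surv, labels_series(["a", "a", "a", "b", "b", "b"]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(surv_df([1, 2], [1, 1]), labels_series(["a", "a"]))

    def test_three_group_df(self):
        rng = np.random.default_rng(0)
        surv = surv_df(rng.exponential(10, 30), rng.integers(0, 2, 30))
        _, df, _ = logrank_test(surv, labels_series(list("abc") * 10))
        assert df == 2


class TestConcordance:
    def test_identical_labelings(self):
        a = labels_series([1] * 20 + [2] * 20 + [3] * 20)
        out = concordance(a, a)
        assert out["ari"] == 1.0
        assert out["p"] < 1e-5

    def test_shuffled_labels_near_zero_ari(self):
        rng = np.random.default_rng(0)
        a = labels_series(rng.integers(1, 4, 300))
        b = pd.Series(rng.permutation(a.to_numpy()), index=a.index)
        out = concordance(a, b)
        assert abs(out["ari"]) < 0.05

    def test_diagonal_2x2_closed_form(self):
        # [[20, 0], [0, 20]] without continuity correction:
        # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2) = 40
        a = labels_series([1] * 20 + [2] * 20)
        out = concordance(a, a)
        assert out["chi2"] == pytest.approx(40.0)
        assert out["p"] < 1e-5
        assert out["ari"] == 1.0

    def test_degenerate_single_class(self):
        a = labels_series([1, 1, 1, 1])
        b = labels_series([1, 2, 1, 2])
        out = concordance(a, b)
        assert np.isnan(out["chi2"])


class TestCategorize:
    def test_cnv_categories(self):
        layer = make_layer(np.array([[0.5, -0.5, 0.0, 0.3]]), kind="CNV", centered=True)
        out = categorize_omics(layer)
        assert out.to_numpy().tolist() == [["Gain", "Loss", "Normal", "Normal"]]

    def test_met_categories(self):
        layer = make_layer(np.array([[0.1, 0.9, 0.5]]), kind="MET", centered=False)
        out = categorize_omics(layer)
        assert out.to_numpy().tolist() == [["HypoMethy", "HyperMethy", "Normal"]]

    def test_partition_conservation(self):
        rng = np.random.default_rng(1)
        layer = make_layer(rng.normal(0, 0.5, (30, 10)), kind="CNV", centered=True)
        out = categorize_omics(layer)
        counts = out.apply(pd.Series.value_counts).fillna(0).sum().sum()
        assert counts == 300


def enumerate_fisher_2x2(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def logp(x):
        return (
            gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(n - r1 + 1) - gammaln(c1 - x + 1) - gammaln(n - r1 - c1 + x + 1)
            + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ps = {x: np.exp(logp(x)) for x in range(lo, hi + 1)}
    obs = ps[a]
    return min(1.0, sum(p for p in ps.values() if p <= obs * (1 + 1e-9)))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table", [[[3, 1], [1, 3]], [[10, 2], [3, 15]], [[0, 5], [5, 0]], [[7, 7], [7, 7]]]
    )
    def test_matches_enumeration(self, table):
        assert fisher_exact_2x2(table) == pytest.approx(enumerate_fisher_2x2(table), abs=1e-12)

    def test_known_value(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(0.485714285714, abs=1e-9)

    def test_2xc_reduces_to_2x2(self):
        t = [[10, 2], [3, 15]]
        assert fisher_exact_2xc(t) == pytest.approx(fisher_exact_2x2(t), abs=1e-9)

    def test_2x3_enumeration_vs_monte_carlo(self):
        t = [[8, 3, 1], [2, 6, 9]]
        exact = fisher_exact_2xc(t)
        mc = fisher_exact_2xc(t, max_total=5, n_mc=40_000, seed=1)  # force MC path
        assert mc == pytest.approx(exact, abs=0.01)

    def test_identical_distributions_p_one(self):
        assert fisher_exact_2xc([[5, 5, 5], [5, 5, 5]]) == pytest.approx(1.0)


class TestBH:
    def test_equal_pvalues_unchanged(self):
        p = np.full(10, 0.03)
        assert np.allclose(bh_adjust(p), 0.03)

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_qvalues_monotone_in_p_order(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0 + 1e-12))


class TestDifferentialTests:
    def test_identical_category_distributions_p_one(self):
        cats = pd.DataFrame(
            [["Gain"] * 4 + ["Normal"] * 4], index=["g1"],
            columns=[f"s{i}" for i in range(8)],
        )
        labels = labels_series([1, 1, 2, 2, 1, 1, 2, 2])
        out = differential_category_test(cats, labels, (1, 2))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_mutation_table_oracle(self):
        # group 1: 10 mutated / 2 wild; group 2: 3 mutated / 15 wild
        mut = pd.DataFrame(
            [[1] * 10 + [0] * 2 + [1] * 3 + [0] * 15], index=["TP53"],
            columns=[f"s{i}" for i in range(30)],
        )
        labels = labels_series([1] * 12 + [2] * 18)
        out = differential_mutation_test(mut, labels, (1, 2))
        expected = enumerate_fisher_2x2([[10, 2], [3, 15]])
        assert out["p"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["direction"].iloc[0] == "1"

    def test_never_mutated_gene_skipped(self):
        mut = pd.DataFrame(
            np.zeros((1, 10), dtype=int), index=["GENE0"], columns=[f"s{i}" for i in range(10)]
        )
        labels = labels_series([1] * 5 + [2] * 5)
        out = differential_mutation_test(mut, labels, (1, 2))
        assert len(out) == 0

    def test_planted_rate_difference_detected(self):
        rng = np.random.default_rng(0)
        n = 150
        mat = np.vstack(
            [np.concatenate([rng.random(n) < 0.4, rng.random(n) < 0.05]) for _ in range(5)]
        ).astype(int)
        mut = pd.DataFrame(mat, index=[f"m{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(2 * n)])
        labels = labels_series([1] * n + [2] * n)
        out = differential_mutation_test(mut, labels, (1, 2))
        assert (out["q"] < 0.1).all()
        assert (out["direction"] == "1").all()


class TestTertiles:
    def test_nine_distinct_values_split_evenly(self):
        expr = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        surv = surv_df(np.arange(1.0, 10.0), [1] * 9)
        lab, km, p = tertile_survival(expr, surv)
        assert lab.value_counts().tolist() == [3, 3, 3]

    def test_constant_expression_falls_back(self, caplog):
        expr = pd.Series(np.ones(12), index=[f"s{i}" for i in range(12)])
        surv = surv_df(np.arange(1.0, 13.0), [1] * 12)
        with caplog.at_level("WARNING"):
            lab, _, p = tertile_survival(expr, surv)
        assert sorted(lab.value_counts().tolist()) == [4, 4, 4]
        assert any("rank-based" in r.message for r in caplog.records)

    def test_monotone_hazard_orders_medians(self):
        rng = np.random.default_rng(3)
        n = 300
        expr = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        tert = pd.qcut(expr, 3, labels=False)
        lam = 0.002 * 2.0**tert  # hazard doubles per tertile
        t = rng.exponential(1.0 / lam)
        surv = surv_df(t, [1] * n, samples=list(expr.index))
        lab, km, p = tertile_survival(expr, surv)
        med = [median_survival(km[g]) for g in ["L1", "L2", "L3"]]
        assert med[0] > med[1] > med[2]
        assert p < 0.05


def test_clinical_table_counts_and_detection():
    rng = np.random.default_rng(1)
    n = 200
    labels = labels_series(rng.integers(1, 4, n))
    stage = np.where(labels.to_numpy() == 2, "III", "I")
    flip = rng.random(n) < 0.2
    stage = np.where(flip, np.where(stage == "I", "III", "I"), stage)
    clinical = pd.DataFrame({"sample_id": labels.index, "stage": stage,
                             "sex": rng.choice(["m", "f"], n)})
    out = clinical_table(labels, clinical)
    assert out["stage"]["table"].to_numpy().sum() == n
    assert out["stage"]["p"] < 0.05
    assert out["sex"]["p"] > 0.001  # unrelated covariate rarely significant
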