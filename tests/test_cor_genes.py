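"""Correlation screening, Fisher Z, skewness, survival filter, selections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as ll_logrank

from stadsub.corgenes import (
    arm_proportions,
    correlate_layers,
    cpg_region_breakdown,
    fisher_z,
    logrank_2group,
    logrank_expression_filter,
    select_cor_genes,
    skewness_with_test,
)

from conftest import make_layer


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_equals_half_log_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


class TestCorrelateLayers:
    def test_matches_naive_covariance_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 10))
        B = rng.normal(size=(20, 10))
        exp = make_layer(A)
        cnv = make_layer(B, kind="CNV")
        out = correlate_layers(exp, cnv)

        for i, g in enumerate(exp.feature_ids):
            a, b = A[i], B[i]
            num = ((a - a.mean()) * (b - b.mean())).sum()
            den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
            assert out.at[g, "r"] == pytest.approx(num / den, abs=1e-12)

    def test_hand_case(self):
        out = correlate_layers(
            make_layer(np.array([[1.0, 2, 3, 4]])), make_layer(np.array([[2.0, 4, 5, 9]]), kind="CNV")
        )
        a = np.array([1.0, 2, 3, 4]); b = np.array([2.0, 4, 5, 9])
        r = np.corrcoef(a, b)[0, 1]
        assert out["r"].iloc[0] == pytest.approx(r, abs=1e-12)

    def test_perfect_anticorrelation(self):
        A = np.array([[1.0, 2, 3, 4, 5]])
        out = correlate_layers(make_layer(A), make_layer(-A, kind="CNV"))
        assert out["r"].iloc[0] == -1.0
        assert np.isnan(out["z"].iloc[0])  # |r| = 1 excluded from the z distribution
        assert out["p_cor"].iloc[0] == 0.0

    def test_zero_variance_row_excluded(self):
        A = np.array([[1.0, 2, 3, 4], [1.0, 1, 1, 1]])
        out = correlate_layers(make_layer(A), make_layer(A[::-1], kind="CNV"))
        assert "g1" not in out.index


class TestSkewness:
    def test_symmetric_vector_zero(self):
        g1, _ = skewness_with_test(np.tile([1.0, 2.0, 3.0], 5))
        assert g1 == pytest.approx(0.0, abs=1e-12)

    def test_mirror_negates(self):
        x = np.random.default_rng(2).exponential(size=50)
        g1, _ = skewness_with_test(x)
        g1m, _ = skewness_with_test(-x)
        assert g1m == pytest.approx(-g1, abs=1e-12)

    def test_exponential_population_skewness(self):
        x = np.random.default_rng(3).exponential(size=10_000)
        g1, p = skewness_with_test(x)
        assert g1 == pytest.approx(2.0, abs=0.1)
        assert p < 1e-5

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            skewness_with_test(np.ones(20))


class TestLogrank2Group:
    def test_identical_groups_give_null(self):
        t = np.array([1.0, 2, 3, 1, 2, 3]); d = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([True, True, True, False, False, False])
        chi2, p = logrank_2group(t, d, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, size=40)
        d = rng.integers(0, 2, size=40)
        d[:4] = 1
        g = rng.random(40) < 0.5
        chi2, p = logrank_2group(t, d, g)
        ref = ll_logrank(t[g], t[~g], event_observed_A=d[g], event_observed_B=d[~g])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)


def test_expression_filter_flags_degenerate_genes():
    exp = make_layer(np.vstack([np.ones(12), np.arange(12.0)]))
    surv = pd.DataFrame(
        {"sample_id": [f"s{j}" for j in range(12)],
         "os_days": np.arange(1.0, 13.0), "os_event": [1] * 12}
    )
    out = logrank_expression_filter(exp, surv)
    assert out.at["g0", "degenerate"] and out.at["g0", "p_logrank"] == 1.0
    assert not out.at["g1", "degenerate"]


class TestSelectCorGenes:
    def _tables(self):
        cnv = pd.DataFrame(
            {"r": [0.6, -0.5, 0.3], "p_cor": [0.001, 0.001, 0.2], "p_logrank": [0.01, 0.01, 0.01]},
            index=["a", "b", "c"],
        )
        met = pd.DataFrame(
            {"r": [-0.5, 0.4, -0.2], "p_cor": [0.001, 0.001, 0.3], "p_logrank": [0.01, 0.2, 0.01]},
            index=["a", "b", "c"],
        )
        return cnv, met

    def test_directional_definition(self):
        cnv, met = self._tables()
        sets = select_cor_genes(cnv, met)
        assert sets.cnvcor == {"a"}  # r > 0, both filters pass
        assert sets.metcor == {"a"}  # r < 0, both filters pass
        assert sets.overlap == {"a"}

    def test_negative_r_never_in_cnvcor(self):
        cnv, met = self._tables()
        cnv.loc["b", "p_cor"] = 1e-30
        assert "b" not in select_cor_genes(cnv, met).cnvcor

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {"r": rng.uniform(-1, 1, 200), "p_cor": rng.random(200), "p_logrank": rng.random(200)},
            index=[f"g{i}" for i in range(200)],
        )
        small = select_cor_genes(tab, tab, alpha_cor=0.02, alpha_surv=0.03)
        large = select_cor_genes(tab, tab, alpha_cor=0.2, alpha_surv=0.3)
        assert small.cnvcor <= large.cnvcor and small.metcor <= large.metcor


class TestArmProportions:
    def _ann(self):
        return pd.DataFrame(
            {"chromosome": ["17"] * 12 + ["1"] * 4,
             "arm": ["p"] * 12 + ["q"] * 4,
             "start": 1, "end": 2, "coding": True},
            index=[f"g{i}" for i in range(16)],
        )

    def test_empty_set_all_zero(self):
        out = arm_proportions(set(), self._ann())
        assert (out["fraction"] == 0).all()

    def test_full_set_all_one(self):
        ann = self._ann()
        out = arm_proportions(set(ann.index), ann)
        assert (out["fraction"] == 1).all()

    def test_counted_fraction(self):
        out = arm_proportions({"g0", "g1", "g2"}, self._ann())
        assert out.set_index("arm").at["17p", "fraction"] == pytest.approx(3 / 12)


def test_cpg_breakdown_conserves_counts():
    manifest = pd.DataFrame(
        {"probe_id": ["p1", "p2", "p3"],
         "gene_symbol": ["a", "b", "c"],
         "region_class": ["Island", "Island", "Shore"],
         "gene_relation": ["Promoter", "Body", "Promoter"]}
    )
    chosen = pd.Series({"a": "p1", "b": "p2", "c": "p3"})
    out = cpg_region_breakdown(["a", "b", "c"], manifest, chosen)
    assert sum(out["region_class"].values()) == 3
    assert out["region_class"] == {"Island": 2, "Shore": 1}
    assert out["gene_relation"] == {"Promoter": 2, "Body": 1}
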