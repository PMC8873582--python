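"""Synthetic cohort generator: determinism, planted effects, round-trips."""

import numpy as np
import pandas as pd
import pytest

from stadsub.io import map_segments_to_genes, read_layer, read_segments
from stadsub.synthetic import CohortConfig, generate_cohort, write_cohort

SMALL = dict(n_samples=40, n_genes=100)


def test_same_seed_is_bit_identical():
    a, ta = generate_cohort(CohortConfig(seed=9, **SMALL))
    b, tb = generate_cohort(CohortConfig(seed=9, **SMALL))
    pd.testing.assert_frame_equal(a.exp.data, b.exp.data)
    pd.testing.assert_frame_equal(a.met_probes.data, b.met_probes.data)
    pd.testing.assert_frame_equal(a.maf, b.maf)
    assert (ta.labels == tb.labels).all()


def test_different_seed_differs():
    a, _ = generate_cohort(CohortConfig(seed=1, **SMALL))
    b, _ = generate_cohort(CohortConfig(seed=2, **SMALL))
    assert not np.allclose(a.exp.data, b.exp.data)


def test_noise_free_limit_collapses_subtypes():
    cfg = CohortConfig(
        seed=0, n_samples=30, n_genes=60,
        sigma_cnv=0.0, sigma_met=0.0, sigma_exp=0.0, sigma_inst=0.0,
        sigma_probe_noise=0.0, dosage_slope=0.0, silencing_slope=0.0,
    )
    cohort, truth = generate_cohort(cfg)
    for layer in (cohort.exp, cohort.cnv):
        vals = layer.data.T.groupby(truth.labels).nunique()
        assert int(vals.to_numpy().max()) == 1  # within a subtype every sample identical


def test_value_ranges():
    cohort, _ = generate_cohort(CohortConfig(seed=3, **SMALL))
    beta = cohort.met_probes.data.to_numpy()
    assert beta.min() > 0.0 and beta.max() < 1.0
    assert (cohort.survival["os_days"] > 0).all()
    assert set(cohort.survival["os_event"].unique()) <= {0, 1}
    assert set(np.unique(cohort.mutations.to_numpy())) <= {0, 1}


def test_planted_sets_disjoint_by_default_and_overlap_optional():
    _, truth = generate_cohort(CohortConfig(seed=0, **SMALL))
    assert not set(truth.dosage_genes) & set(truth.silenced_genes)
    _, t2 = generate_cohort(CohortConfig(seed=0, overlap_fraction=0.4, **SMALL))
    overlap = set(t2.dosage_genes) & set(t2.silenced_genes)
    assert len(overlap) == round(0.4 * len(t2.silenced_genes))


def test_dosage_correlation_matches_attenuation_formula():
    # r = a*sd(c) / sqrt(a^2 var(c) + sigma_e^2), per dosage gene
    cfg = CohortConfig(seed=4, n_samples=300, n_genes=200, dosage_slope=1.0, sigma_exp=0.1)
    cohort, truth = generate_cohort(cfg)
    e = cohort.exp.data.loc[truth.dosage_genes].to_numpy()
    c = cohort.cnv.data.loc[truth.dosage_genes].to_numpy()
    r_obs = np.array(
        [np.corrcoef(e[i], c[i])[0, 1] for i in range(len(truth.dosage_genes))]
    )
    assert (r_obs >= 0.9).all()  # near-deterministic dosage at small noise

    cfg2 = CohortConfig(seed=5, n_samples=300, n_genes=200)
    cohort2, truth2 = generate_cohort(cfg2)
    e2 = cohort2.exp.data.loc[truth2.dosage_genes].to_numpy()
    c2 = cohort2.cnv.data.loc[truth2.dosage_genes].to_numpy()
    a, se = cfg2.dosage_slope, cfg2.sigma_exp
    for i in range(0, len(truth2.dosage_genes), 7):
        sc = c2[i].std()
        r_pred = a * sc / np.sqrt(a**2 * sc**2 + se**2)
        r_obs = np.corrcoef(e2[i], c2[i])[0, 1]
        assert r_obs == pytest.approx(r_pred, abs=0.12)  # Monte-Carlo error at n=300


def test_roles_partition_gene_universe():
    _, truth = generate_cohort(CohortConfig(seed=0, **SMALL))
    cfg = truth.config
    n_roles = (
        len(truth.dosage_genes) + len(truth.silenced_genes) + len(truth.cnv_balance_genes)
        + len(truth.met_balance_genes) + len(truth.exp_struct_genes) + len(truth.null_genes)
    )
    assert n_roles == cfg.n_genes
    assert set(truth.prognostic_genes) <= set(truth.dosage_genes) | set(truth.silenced_genes)


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    cohort, truth = generate_cohort(CohortConfig(seed=6, n_samples=30, n_genes=80))
    paths = write_cohort(cohort, truth, d)
    return d, cohort, truth, paths


class TestWriteCohort:

    def test_matrix_round_trip(self, written):
        d, cohort, _, _ = written
        exp = read_layer(d / "exp.tsv", "EXP", centered=True)
        assert np.allclose(exp.data.to_numpy(), cohort.exp.data.to_numpy(), atol=1e-10)
        met = read_layer(d / "met_probes.tsv", "MET")
        assert np.allclose(met.data.to_numpy(), cohort.met_probes.data.to_numpy(), atol=1e-10)

    def test_seg_remaps_to_original_cnv(self, written):
        d, cohort, _, _ = written
        seg = read_segments(d / "cnv.seg")
        remapped = map_segments_to_genes(seg, cohort.gene_annotation)
        got = remapped.data.loc[cohort.cnv.data.index, cohort.cnv.data.columns]
        assert np.allclose(got.to_numpy(), cohort.cnv.data.to_numpy(), atol=1e-12)

    def test_truth_tables_list_planted_sets(self, written):
        d, _, truth, _ = written
        roles = pd.read_csv(d / "truth_genes.tsv", sep="\t")
        dosage = set(roles.loc[roles["role"].str.contains("dosage"), "gene"])
        assert dosage == set(truth.dosage_genes)
        samples = pd.read_csv(d / "truth_samples.tsv", sep="\t")
        assert (samples.set_index("sample_id")["subtype"] == truth.labels).all()
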