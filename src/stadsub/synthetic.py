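"""Synthetic matched multi-omics cohort with planted subtype structure.

The generator emulates a ~300-sample gastric-tumor cohort profiled on three
platforms (expression, gene-level copy number, 450K-style methylation) plus
survival and a somatic-mutation panel, with three latent molecular subtypes.
Every planted effect is recorded in a :class:`SyntheticTruth` so each
pipeline stage has an exact recovery oracle.

Generative model (all draws from one seeded generator, in a fixed order):

1. subtype label ``g_i`` from the mixing proportions; genomic-instability
   factor ``u_i ~ |Normal(0, sigma_inst)|``.
2. CNV: gene-level log2 ratio ``c_ij = mu_cnv[j, g_i] * (1 + u_i) +
   Normal(0, sigma_cnv) * (1 + u_i)`` — instability scales both the planted
   regional means and the genome-wide dispersion, which is what couples the
   per-sample CNV and MET aberration frequencies.
3. MET: M-value ``m_ij = M0_j + mu_met[j, g_i] * (1 + u_i) +
   Normal(0, sigma_met) * (1 + u_i)``; beta = 2^m / (2^m + 1), so beta stays
   in (0, 1) by construction.  ``M0_j`` is the per-gene normal-tissue
   baseline, also emitted as the normal reference for centring.
4. EXP (log2 fold change): ``e_ij = mu_exp[j, g_i] + a * c_ij`` for dosage
   genes, ``- b * (m_ij - M0_j)`` for silenced genes, plus
   ``Normal(0, sigma_exp)``.
5. survival: ``T ~ Exponential(lambda_{g_i})`` with an independent uniform
   censoring horizon.
6. mutations: per panel gene, ``Bernoulli(rate[g_i, gene])``.

Planted subtype mean patterns form the symmetric cyclic triple
``A = (+1, -1, 0)``, ``D = (0, +1, -1)``, ``E = (-1, 0, +1)`` over the three
subtypes, assigned to interleaved thirds of the planted gene sets.  The
three subtype centroids are therefore equidistant, and each subtype carries
the same expected number of gained, lost, hyper- and hypomethylated genes —
with ``sigma_inst = 0`` the per-sample aberration frequencies of the two
platforms are uncorrelated, while any ``sigma_inst > 0`` induces the
positive coupling seen in unstable tumor genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OmicsLayer

# Subtype-space mean patterns (entries = subtypes 1..3).  The cyclic triple
# is symmetric: the three subtype centroids are equidistant, and each subtype
# carries exactly one gained and one lost gene group per platform, so the
# expected aberration load is identical across subtypes.  With hazards
# (1, 3, 1.1) patterns A and D contrast prognostically distinct subtypes
# (survival-informative), while pattern E separates the two good-prognosis
# subtypes and is therefore prognosis-neutral by construction.
PATTERN_A = np.array([+1.0, -1.0, 0.0])
PATTERN_D = np.array([0.0, +1.0, -1.0])
PATTERN_E = np.array([-1.0, 0.0, +1.0])
PATTERN_C = np.array([0.0, 0.0, -1.0])  # optional extra-structure pattern

#: mutation panel: ten genes recurrently mutated in gastric tumors with
#: subtype-differential rates, plus two background genes with a flat rate.
DIFFERENTIAL_PANEL = (
    "ARID1A", "PIK3CA", "ZFHX3", "SPECC1", "OBSCN",
    "KMT2D", "FSIP2", "ZBTB20", "TTN", "RANBP2",
)
BACKGROUND_PANEL = ("TP53", "CDH1")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference cohort: 300 samples, 2,000 genes, three
    subtypes, 15% dosage genes whose expression tracks copy number with an
    attenuated correlation near 0.6, 15% methylation-silenced genes, and a
    genomic-instability scale that couples CNV and MET aberration rates.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_subtypes: int = 3
    proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    dosage_gene_fraction: float = 0.15
    silenced_gene_fraction: float = 0.15
    balance_gene_fraction: float = 0.0  # optional per-platform null-expression structure
    exp_struct_gene_fraction: float = 0.15
    dosage_slope: float = 1.2  # a: expression per unit log2 copy ratio
    silencing_slope: float = 0.55  # b: expression per unit M-value, applied negatively
    delta_cnv: float = 0.5  # planted log2-ratio shift
    delta_met: float = 1.6  # planted M-value shift
    delta_exp: float = 1.0  # planted expression shift for EXP-structure genes
    sigma_cnv: float = 0.15
    sigma_met: float = 0.5
    sigma_exp: float = 1.0
    sigma_probe_offset: float = 0.3  # constant probe-level offset (M scale)
    sigma_probe_noise: float = 0.2  # per-cell probe noise (M scale)
    sigma_inst: float = 0.5  # genomic-instability scale; 0 decouples platforms
    baseline_m_sd: float = 1.2  # normal-tissue M-value spread (0.8 for silenced genes)
    base_hazard: float = 1.0 / 1000.0  # events per day for the best-prognosis subtype
    hazard_multipliers: tuple = (1.0, 3.0, 1.1)
    censor_horizon: float = 5000.0  # days; censoring time ~ Uniform(1, horizon)
    mutation_rates_differential: tuple = (0.40, 0.05, 0.20)  # per subtype
    mutation_rate_background: float = 0.30
    synonymous_rate: float = 0.05  # decoy records the MAF reader must discard
    overlap_fraction: float = 0.0  # fraction of silenced genes also made dosage genes
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if self.n_subtypes != 3:
            raise ValueError("the planted pattern set is defined for 3 subtypes")
        for name in ("dosage_gene_fraction", "silenced_gene_fraction", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma_inst < 0:
            raise ValueError("sigma_inst must be >= 0")
        if any(m <= 0 for m in self.hazard_multipliers) or self.base_hazard <= 0:
            raise ValueError("hazard rates must be positive")


@dataclass
class SyntheticTruth:
    """Planted structure: the oracle for recovery tests."""

    labels: pd.Series  # sample -> subtype 1..K
    instability: pd.Series  # sample -> u_i
    hazard: pd.Series  # sample -> event rate per day
    dosage_genes: list
    silenced_genes: list
    prognostic_genes: list  # planted genes whose subtype contrast implies a hazard contrast
    cnv_balance_genes: list
    met_balance_genes: list
    exp_struct_genes: list
    null_genes: list
    mutation_rates: pd.DataFrame  # gene x subtype Bernoulli rates
    config: CohortConfig


@dataclass
class Cohort:
    """Matched synthetic multi-omics cohort (gene-level except MET probes)."""

    exp: OmicsLayer  # centered log2 fold change
    cnv: OmicsLayer  # gene-level log2 segment ratios
    met_probes: OmicsLayer  # raw probe beta values
    met_normal: pd.Series  # probe -> normal-tissue reference beta
    gene_annotation: pd.DataFrame
    probe_manifest: pd.DataFrame
    survival: pd.DataFrame  # sample_id, os_days, os_event
    clinical: pd.DataFrame  # sample_id, stage, sex
    mutations: pd.DataFrame  # binary gene x sample matrix
    maf: pd.DataFrame  # MAF-lite records incl. synonymous decoys


def _m_to_beta(m: np.ndarray) -> np.ndarray:
    return np.exp2(m) / (np.exp2(m) + 1.0)


def _gene_annotation(gene_ids, rng) -> pd.DataFrame:
    """Lay genes out over 22 autosomes with size-proportional gene counts."""
    n = len(gene_ids)
    weights = np.array([24.0 - 0.9 * c for c in range(1, 23)])
    counts = np.floor(weights / weights.sum() * n).astype(int)
    counts[: n - counts.sum()] += 1
    chroms, arms, starts, ends = [], [], [], []
    for c, cnt in enumerate(counts, start=1):
        pos = 1_000_000
        for j in range(cnt):
            length = int(rng.integers(5_000, 50_000))
            chroms.append(str(c))
            arms.append("p" if j < 0.4 * cnt else "q")
            starts.append(pos)
            ends.append(pos + length)
            pos += length + int(rng.integers(50_000, 150_000))
    return pd.DataFrame(
        {
            "symbol": gene_ids,
            "chromosome": chroms[:n],
            "arm": arms[:n],
            "start": starts[:n],
            "end": ends[:n],
            "coding": rng.random(n) < 0.9,
        }
    ).set_index("symbol")


def _stage_probs(subtype: int) -> np.ndarray:
    # stage shifts towards III/IV in the aggressive subtype 2
    table = {
        1: [0.25, 0.40, 0.30, 0.05],
        2: [0.05, 0.20, 0.45, 0.30],
        3: [0.15, 0.30, 0.40, 0.15],
    }
    return np.array(table[subtype])


def generate_cohort(config: CohortConfig | None = None) -> tuple[Cohort, SyntheticTruth]:
    """Draw one cohort plus its planted truth from the generative model."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n, G, K = cfg.n_samples, cfg.n_genes, cfg.n_subtypes
    samples = [f"S{i + 1:04d}" for i in range(n)]
    genes = [f"G{j + 1:05d}" for j in range(G)]

    # ---- sample-level latents -------------------------------------------
    labels = rng.choice(np.arange(1, K + 1), size=n, p=np.asarray(cfg.proportions))
    u = np.abs(rng.normal(0.0, cfg.sigma_inst, size=n)) if cfg.sigma_inst > 0 else np.zeros(n)
    amp = 1.0 + u

    # ---- gene roles ------------------------------------------------------
    nd = int(round(cfg.dosage_gene_fraction * G))
    ns = int(round(cfg.silenced_gene_fraction * G))
    nb = int(round(cfg.balance_gene_fraction * G))
    ne = int(round(cfg.exp_struct_gene_fraction * G))
    if nd + ns + 2 * nb + ne > G:
        raise ValueError("gene-role fractions exceed the gene count")
    idx = np.arange(G)
    dosage = idx[:nd]
    silenced = idx[nd : nd + ns]
    if cfg.overlap_fraction > 0:
        n_overlap = int(round(cfg.overlap_fraction * ns))
        silenced = np.concatenate([dosage[:n_overlap], silenced[: ns - n_overlap]])
    cnv_balance = idx[nd + ns : nd + ns + nb]
    met_balance = idx[nd + ns + nb : nd + ns + 2 * nb]
    exp_struct = idx[nd + ns + 2 * nb : nd + ns + 2 * nb + ne]
    structured = set(dosage) | set(silenced) | set(cnv_balance) | set(met_balance) | set(exp_struct)
    null = np.array([j for j in idx if j not in structured], dtype=int)

    def split_groups(members, n_groups):
        return [members[i::n_groups] for i in range(n_groups)]

    def pattern_matrix(members, patterns):
        """(G, K) subtype-mean matrix assigning patterns to interleaved thirds of members."""
        mu = np.zeros((G, K))
        for part, pat in zip(split_groups(members, len(patterns)), patterns):
            mu[part] = pat
        return mu

    cyclic = (PATTERN_A, PATTERN_D, PATTERN_E)
    mu_cnv = cfg.delta_cnv * pattern_matrix(dosage, cyclic)
    mu_cnv[cnv_balance] = cfg.delta_cnv * PATTERN_C
    mu_met = cfg.delta_met * pattern_matrix(silenced, cyclic)
    mu_met[met_balance] = cfg.delta_met * PATTERN_C
    mu_exp = cfg.delta_exp * pattern_matrix(exp_struct, (PATTERN_A, PATTERN_D))
    # planted genes on the A/D axes contrast subtypes with distinct hazards;
    # the E axis separates the two good-prognosis subtypes (prognosis-neutral)
    prognostic = np.concatenate(
        [np.concatenate(split_groups(members, 3)[:2]) for members in (dosage, silenced)]
    )

    # ---- CNV -------------------------------------------------------------
    lab0 = labels - 1
    c = mu_cnv[:, lab0] * amp + rng.normal(0.0, cfg.sigma_cnv, size=(G, n)) * amp

    # ---- MET (M scale, then beta) ---------------------------------------
    m0 = rng.normal(0.0, cfg.baseline_m_sd, size=G)
    m0[silenced] = rng.normal(0.0, 0.8, size=len(silenced))
    m = m0[:, None] + mu_met[:, lab0] * amp + rng.normal(0.0, cfg.sigma_met, size=(G, n)) * amp

    # ---- EXP -------------------------------------------------------------
    e = mu_exp[:, lab0] + rng.normal(0.0, cfg.sigma_exp, size=(G, n))
    e[dosage] += cfg.dosage_slope * c[dosage]
    e[silenced] -= cfg.silencing_slope * (m[silenced] - m0[silenced, None])

    # ---- survival --------------------------------------------------------
    mult = np.asarray(cfg.hazard_multipliers)
    hazard = cfg.base_hazard * mult[lab0]
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(1.0, cfg.censor_horizon, size=n)
    os_days = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    # ---- mutations -------------------------------------------------------
    panel = list(DIFFERENTIAL_PANEL) + list(BACKGROUND_PANEL)
    rates = pd.DataFrame(
        {
            f"subtype_{k}": [cfg.mutation_rates_differential[k - 1]] * len(DIFFERENTIAL_PANEL)
            + [cfg.mutation_rate_background] * len(BACKGROUND_PANEL)
            for k in range(1, K + 1)
        },
        index=panel,
    )
    rate_mat = rates.to_numpy()[:, lab0]
    mut = (rng.random((len(panel), n)) < rate_mat).astype(int)
    records = []
    for gi, gene in enumerate(panel):
        for si in np.flatnonzero(mut[gi]):
            vclass = "missense" if rng.random() < 0.7 else "nonsense"
            records.append((samples[si], gene, vclass))
    syn_mask = rng.random((len(panel), n)) < cfg.synonymous_rate
    for gi, gene in enumerate(panel):
        for si in np.flatnonzero(syn_mask[gi]):
            records.append((samples[si], gene, "synonymous"))
    maf = pd.DataFrame(records, columns=["sample_id", "gene_symbol", "variant_class"])

    # ---- probes ----------------------------------------------------------
    n_probes = 1 + (idx % 3 == 0).astype(int) + (idx % 7 == 0).astype(int)
    probe_rows, probe_gene_idx, offsets = [], [], []
    region_probs = {
        "silenced": ([0.70, 0.20, 0.05, 0.05], [0.45, 0.15, 0.10, 0.25, 0.05]),
        "other": ([0.30, 0.25, 0.15, 0.30], [0.20, 0.10, 0.10, 0.45, 0.15]),
    }
    regions, relations = [], []
    silenced_set = set(silenced)
    region_names = ["Island", "Shore", "Shelf", "OpenSea"]
    relation_names = ["Promoter", "5'UTR", "FirstExon", "Body", "Other"]
    for j in idx:
        p_reg, p_rel = region_probs["silenced" if j in silenced_set else "other"]
        for t in range(n_probes[j]):
            probe_rows.append(f"cg{j + 1:05d}_{t + 1}")
            probe_gene_idx.append(j)
            offsets.append(rng.normal(0.0, cfg.sigma_probe_offset))
            regions.append(region_names[rng.choice(4, p=p_reg)])
            relations.append(relation_names[rng.choice(5, p=p_rel)])
    probe_gene_idx = np.array(probe_gene_idx)
    offsets = np.array(offsets)
    probe_m = (
        m[probe_gene_idx]
        + offsets[:, None]
        + rng.normal(0.0, cfg.sigma_probe_noise, size=(len(probe_rows), n))
    )
    probe_beta = _m_to_beta(probe_m)
    normal_beta = pd.Series(
        _m_to_beta(m0[probe_gene_idx] + offsets), index=probe_rows, name="normal_beta"
    )
    manifest = pd.DataFrame(
        {
            "probe_id": probe_rows,
            "gene_symbol": [genes[j] for j in probe_gene_idx],
            "region_class": regions,
            "gene_relation": relations,
        }
    )

    # ---- clinical --------------------------------------------------------
    stages = np.array(["I", "II", "III", "IV"])
    stage = np.array([stages[rng.choice(4, p=_stage_probs(int(k)))] for k in labels])
    sex = np.where(rng.random(n) < 0.65, "male", "female")

    annotation = _gene_annotation(genes, rng)
    cohort = Cohort(
        exp=OmicsLayer("EXP", pd.DataFrame(e, index=genes, columns=samples), centered=True),
        cnv=OmicsLayer("CNV", pd.DataFrame(c, index=genes, columns=samples), centered=True),
        met_probes=OmicsLayer(
            "MET", pd.DataFrame(probe_beta, index=probe_rows, columns=samples), centered=False
        ),
        met_normal=normal_beta,
        gene_annotation=annotation,
        probe_manifest=manifest,
        survival=pd.DataFrame(
            {"sample_id": samples, "os_days": os_days, "os_event": os_event}
        ),
        clinical=pd.DataFrame({"sample_id": samples, "stage": stage, "sex": sex}),
        mutations=pd.DataFrame(mut, index=panel, columns=samples),
        maf=maf,
    )
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=samples, name="subtype"),
        instability=pd.Series(u, index=samples, name="instability"),
        hazard=pd.Series(hazard, index=samples, name="hazard"),
        dosage_genes=[genes[j] for j in dosage],
        silenced_genes=[genes[j] for j in silenced],
        prognostic_genes=[genes[j] for j in prognostic],
        cnv_balance_genes=[genes[j] for j in cnv_balance],
        met_balance_genes=[genes[j] for j in met_balance],
        exp_struct_genes=[genes[j] for j in exp_struct],
        null_genes=[genes[j] for j in null],
        mutation_rates=rates,
        config=cfg,
    )
    return cohort, truth


def centered_met(cohort: Cohort) -> OmicsLayer:
    """Probe-level tumor-minus-normal beta differences (values in [-1, 1])."""
    diff = cohort.met_probes.data.sub(cohort.met_normal, axis=0)
    return OmicsLayer("MET", diff, centered=True)


def write_cohort(cohort: Cohort, truth: SyntheticTruth, directory) -> dict:
    """Write every file format the readers consume, plus the truth tables.

    The SEG file is reconstructed from the gene-level CNV matrix with one
    segment per gene per sample, so mapping it back through
    ``map_segments_to_genes`` reproduces the matrix exactly.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    paths = {}

    def _write(df, name, **kw):
        p = d / name
        df.to_csv(p, sep="\t", float_format=fmt, **kw)
        paths[name] = p
        return p

    exp = cohort.exp.data.copy()
    exp.index.name = "gene"
    _write(exp, "exp.tsv", na_rep="NA")
    met = cohort.met_probes.data.copy()
    met.index.name = "probe_id"
    _write(met, "met_probes.tsv", na_rep="NA")
    _write(cohort.met_normal.to_frame(), "met_normal.tsv")
    ann = cohort.gene_annotation
    _write(ann.reset_index(), "gene_annotation.tsv", index=False)
    _write(cohort.probe_manifest, "probe_manifest.tsv", index=False)
    surv = cohort.survival.merge(cohort.clinical, on="sample_id")
    _write(surv, "clinical.tsv", index=False)
    _write(cohort.maf, "mutations.maf.tsv", index=False)

    seg_rows = []
    cnv = cohort.cnv.data
    for gene in cnv.index:
        row = ann.loc[gene]
        for sample in cnv.columns:
            seg_rows.append(
                (sample, row["chromosome"], row["start"], row["end"], cnv.at[gene, sample])
            )
    seg = pd.DataFrame(
        seg_rows, columns=["Sample", "Chromosome", "Start", "End", "Segment_Mean"]
    )
    _write(seg, "cnv.seg", index=False)

    roles = {}
    for role, members in [
        ("dosage", truth.dosage_genes),
        ("silenced", truth.silenced_genes),
        ("prognostic", truth.prognostic_genes),
        ("cnv_balance", truth.cnv_balance_genes),
        ("met_balance", truth.met_balance_genes),
        ("exp_struct", truth.exp_struct_genes),
        ("background", truth.null_genes),
    ]:
        for g in members:
            roles.setdefault(g, []).append(role)
    truth_genes = pd.DataFrame(
        {"gene": list(cnv.index), "role": ["+".join(roles.get(g, ["background"])) for g in cnv.index]}
    )
    _write(truth_genes, "truth_genes.tsv", index=False)
    truth_samples = pd.concat([truth.labels, truth.instability, truth.hazard], axis=1)
    truth_samples.index.name = "sample_id"
    _write(truth_samples.reset_index(), "truth_samples.tsv", index=False)
    _write(truth.mutation_rates.rename_axis("gene").reset_index(), "truth_mutation_rates.tsv", index=False)
    (d / "config.json").write_text(json.dumps(truth.config.__dict__, default=list, indent=1))
    paths["config.json"] = d / "config.json"
    return paths
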