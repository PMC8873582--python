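"""Config-driven orchestration of the full subtyping workflow.

Stages run in the fixed order

    load -> cor_genes -> nmf (CNVcor and METcor separately) ->
    integrative -> aberrations -> characterize

writing every declared TSV artifact plus a machine-readable run manifest.
A single global seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, in stage order, so any stage can
be re-run standalone and reproduce its output exactly.  All randomness in a
run derives from the config seed; identical config and seed give
byte-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aberrations import (
    AberrationThresholds,
    call_aberrations,
    frequency_profile,
    pairwise_frequency_correlation,
)
from .characterize import (
    categorize_omics,
    clinical_table,
    concordance,
    differential_category_test,
    differential_mutation_test,
    km_estimator,
    logrank_test,
    multi_level_screen,
    tertile_survival,
)
from .corgenes import (
    arm_proportions,
    correlate_layers,
    cpg_region_breakdown,
    logrank_expression_filter,
    select_cor_genes,
    skewness_with_test,
)
from .icluster import icluster_fit
from .io import (
    OmicsLayer,
    filter_features,
    knn_impute,
    map_segments_to_genes,
    match_samples,
    read_gene_annotation,
    read_layer,
    read_mutations,
    read_probe_manifest,
    read_segments,
    read_survival,
    select_representative_probe,
)
from .nmf import select_k, to_nonnegative
from .synthetic import Cohort, CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("load", "cor_genes", "nmf", "integrative", "aberrations", "characterize")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Every knob of the workflow, round-trippable through YAML."""

    outdir: str = "stadsub_run"
    seed: int = 0
    # input: either a synthetic cohort config or a directory of input files
    synthetic: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    input_dir: str | None = None
    # preprocessing
    max_missing_fraction: float = 0.3
    knn_k: int = 10
    probe_rule: str = "mean_r"
    # correlated-gene selection
    alpha_cor: float = 0.05
    alpha_surv: float = 0.05
    # NMF
    k_min: int = 2
    k_max: int = 10
    nmf_runs: int = 50
    nmf_max_iter: int = 500
    # integrative clustering
    icluster_k: int = 3
    icluster_lambda: float = 0.2
    icluster_restarts: int = 20
    nmf_min_features: int = 10  # floor on the feature-set size fed to NMF
    # aberrations
    thresholds: dict = field(
        default_factory=lambda: {"gain": 0.3, "loss": -0.3, "hyper": 0.8, "hypo": 0.2}
    )
    fdr_alpha: float = 0.1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def stage_seeds(seed: int) -> dict:
    """Expand the global seed into one deterministic child seed per stage."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(STAGES, children)}


class StageError(RuntimeError):
    pass


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA", index=index)


def _load_cohort_from_dir(d: Path, cfg: PipelineConfig):
    exp = read_layer(d / "exp.tsv", "EXP", centered=True)
    met_probes = read_layer(d / "met_probes.tsv", "MET", centered=False)
    met_normal = pd.read_csv(d / "met_normal.tsv", sep="\t", index_col=0).iloc[:, 0]
    manifest = read_probe_manifest(d / "probe_manifest.tsv")
    annotation = read_gene_annotation(d / "gene_annotation.tsv")
    segments = read_segments(d / "cnv.seg")
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t")
    survival = read_survival(d / "clinical.tsv")[["sample_id", "os_days", "os_event"]]
    maf_path = d / "mutations.maf.tsv"
    mutations = (
        read_mutations(maf_path, samples=exp.sample_ids) if maf_path.exists() else pd.DataFrame()
    )
    cnv = map_segments_to_genes(segments, annotation)
    cohort = Cohort(
        exp=exp,
        cnv=cnv,
        met_probes=met_probes,
        met_normal=met_normal,
        gene_annotation=annotation,
        probe_manifest=manifest,
        survival=survival,
        clinical=clinical.drop(columns=[c for c in ("os_days", "os_event") if c in clinical]),
        mutations=mutations,
        maf=pd.DataFrame(),
    )
    return cohort


def _order_by_survival(labels: pd.Series, survival: pd.DataFrame) -> pd.Series:
    """Relabel clusters by prognosis: 1 = best, 2 = worst, 3.. = intermediate.

    The per-cluster severity score is the constant-hazard estimate
    events / total follow-up time.  The 1/2 convention matches the usual
    reporting of integrative subtypes, where the headline comparison is the
    best- versus poorest-prognosis group.
    """
    surv = survival.set_index("sample_id").loc[labels.index]
    scores = []
    for g in pd.unique(labels):
        sub = surv[labels == g]
        scores.append((float(sub["os_event"].sum() / sub["os_days"].sum()), g))
    ranked = [g for _, g in sorted(scores)]  # ascending hazard: best first
    order = [ranked[0], ranked[-1], *ranked[1:-1]]
    mapping = {g: i + 1 for i, g in enumerate(order)}
    return labels.map(mapping).astype(int)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    t0 = time.time()
    results: dict = {"seeds": seeds}
    thresholds = AberrationThresholds(**config.thresholds)

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except Exception as err:  # noqa: BLE001 - stage-tagged re-raise
                raise StageError(f"[{name}] {err}") from err

        return deco

    # ---- load -----------------------------------------------------------
    @stage("load")
    def _load():
        if config.synthetic:
            cohort_cfg = CohortConfig(**{"seed": seeds["load"], **config.cohort})
            cohort, truth = generate_cohort(cohort_cfg)
            write_cohort(cohort, truth, out / "cohort")
            results["truth"] = truth
        else:
            if not config.input_dir or not Path(config.input_dir).exists():
                raise FileNotFoundError(f"input directory not found: {config.input_dir}")
            cohort = _load_cohort_from_dir(Path(config.input_dir), config)
            results["truth"] = None
        met_probe_filtered = filter_features(
            cohort.met_probes, max_missing_fraction=config.max_missing_fraction
        )
        if met_probe_filtered.n_missing:
            met_probe_filtered = knn_impute(met_probe_filtered, k=config.knn_k)
        exp = cohort.exp if not cohort.exp.n_missing else knn_impute(cohort.exp, k=config.knn_k)
        met_centered_probes = OmicsLayer(
            "MET",
            met_probe_filtered.data.sub(cohort.met_normal.reindex(met_probe_filtered.feature_ids), axis=0),
            centered=True,
        )
        met_gene_centered, chosen = select_representative_probe(
            met_centered_probes, exp, cohort.probe_manifest, rule=config.probe_rule
        )
        met_gene_beta = OmicsLayer(
            "MET", met_probe_filtered.data.loc[chosen.to_numpy()].set_axis(chosen.index, axis=0),
            centered=False,
        )
        exp, cnv, met_gene_centered, met_gene_beta, survival, clinical = match_samples(
            exp, cohort.cnv, met_gene_centered, met_gene_beta, cohort.survival, cohort.clinical
        )
        results.update(
            cohort=cohort,
            exp=exp,
            cnv=cnv,
            met_centered=met_gene_centered,
            met_beta=met_gene_beta,
            chosen_probes=chosen,
            survival=survival,
            clinical=clinical,
            mutations=cohort.mutations,
        )

    # ---- correlated genes ----------------------------------------------
    @stage("cor_genes")
    def _cor():
        exp, cnv, met = results["exp"], results["cnv"], results["met_centered"]
        cnv_cor = correlate_layers(exp, cnv)
        met_cor = correlate_layers(exp, met)
        lr = logrank_expression_filter(exp, results["survival"])
        cnv_cor = cnv_cor.join(lr["p_logrank"], how="left")
        met_cor = met_cor.join(lr["p_logrank"], how="left")
        sets = select_cor_genes(
            cnv_cor, met_cor, alpha_cor=config.alpha_cor, alpha_surv=config.alpha_surv
        )
        skew_cnv = skewness_with_test(cnv_cor["z"].dropna())
        skew_met = skewness_with_test(met_cor["z"].dropna())
        ann = results["cohort"].gene_annotation
        arms_cnv = arm_proportions(sets.cnvcor, ann, universe=cnv_cor.index)
        arms_met = arm_proportions(sets.metcor, ann, universe=met_cor.index)
        cpg = cpg_region_breakdown(
            sets.metcor, results["cohort"].probe_manifest, results["chosen_probes"], ann
        )
        for name, df in [("cor_cnv.tsv", cnv_cor), ("cor_met.tsv", met_cor)]:
            d = df.copy()
            d.insert(0, "layer", "CNV" if name == "cor_cnv.tsv" else "MET")
            _write(d, out / name)
        _write(arms_cnv, out / "arm_proportions_cnvcor.tsv", index=False)
        _write(arms_met, out / "arm_proportions_metcor.tsv", index=False)
        pd.Series(sorted(sets.cnvcor)).to_csv(out / "cnvcor_genes.txt", index=False, header=False)
        pd.Series(sorted(sets.metcor)).to_csv(out / "metcor_genes.txt", index=False, header=False)
        (out / "cpg_breakdown.json").write_text(json.dumps(cpg, indent=1, sort_keys=True))
        results.update(
            cnv_cor=cnv_cor, met_cor=met_cor, sets=sets, skew_cnv=skew_cnv, skew_met=skew_met
        )

    # ---- NMF consensus ---------------------------------------------------
    @stage("nmf")
    def _nmf():
        sets = results["sets"]
        nmf_out = {}
        for tag, layer, genes, table, positive in [
            ("cnvcor", results["cnv"], sorted(sets.cnvcor), results["cnv_cor"], True),
            ("metcor", results["met_centered"], sorted(sets.metcor), results["met_cor"], False),
        ]:
            if len(genes) < config.nmf_min_features:
                # small cohorts can leave the double-filtered set too sparse to
                # cluster on; extend with the best correlation-ranked genes of
                # the correct sign so the stage stays well-posed
                sign_ok = table["r"] > 0 if positive else table["r"] < 0
                ranked = table[sign_ok].sort_values("p_cor").index
                extra = [g for g in ranked if g not in set(genes)]
                need = config.nmf_min_features - len(genes)
                logger.warning(
                    "nmf: only %d %s genes passed both filters; adding %d "
                    "correlation-ranked genes", len(genes), tag, min(need, len(extra)),
                )
                genes = sorted(set(genes) | set(extra[:need]))
            if len(genes) < 5:
                raise ValueError(f"too few {tag} genes ({len(genes)}) for NMF")
            V, _ = to_nonnegative(layer.subset_features(genes))
            best_k, table, res = select_k(
                V,
                k_range=range(config.k_min, config.k_max + 1),
                n_runs=config.nmf_runs,
                seed=seeds["nmf"],
                max_iter=config.nmf_max_iter,
                sample_ids=layer.sample_ids,
            )
            labels = pd.Series(
                res[best_k].labels, index=layer.sample_ids, name=f"nmf_{tag}"
            )
            _write(table, out / f"nmf_{tag}_diagnostics.tsv", index=False)
            _write(labels.to_frame(), out / f"nmf_{tag}_labels.tsv")
            _write(
                pd.DataFrame(
                    res[best_k].consensus, index=layer.sample_ids, columns=layer.sample_ids
                ),
                out / f"nmf_{tag}_consensus.tsv",
            )
            nmf_out[tag] = {"best_k": best_k, "table": table, "labels": labels, "res": res}
        results["nmf"] = nmf_out

    # ---- integrative clustering -----------------------------------------
    @stage("integrative")
    def _integrative():
        sets = results["sets"]
        genes = sorted(sets.cnvcor | sets.metcor)
        layers = []
        for layer in (results["exp"], results["cnv"], results["met_centered"]):
            keep = [g for g in genes if g in set(layer.feature_ids)]
            layers.append(layer.subset_features(keep))
        fit = icluster_fit(
            layers,
            k=config.icluster_k,
            lam=config.icluster_lambda,
            n_init=config.icluster_restarts,
            seed=seeds["integrative"],
        )
        labels = pd.Series(fit.labels, index=layers[0].sample_ids, name="icluster")
        labels = _order_by_survival(labels, results["survival"])
        labels.name = "icluster"
        _write(labels.to_frame(), out / "icluster_labels.tsv")
        summary = pd.DataFrame(
            {
                "layer": ["EXP", "CNV", "MET"],
                "n_features": [w.shape[0] for w in fit.W],
                "nonzero_loadings": [int((w != 0).sum()) for w in fit.W],
            }
        )
        summary["objective"] = fit.objective[-1]
        _write(summary, out / "icluster_summary.tsv", index=False)
        results["icluster"] = {"fit": fit, "labels": labels}

    # ---- aberration statistics ------------------------------------------
    @stage("aberrations")
    def _aberrations():
        calls = call_aberrations(results["cnv"], results["met_beta"], thresholds)
        profile = frequency_profile(calls)
        corr = pairwise_frequency_correlation(profile)
        prof = profile.copy()
        prof.index.name = "sample_id"
        _write(prof, out / "aberration_frequencies.tsv")
        _write(corr, out / "aberration_correlations.tsv", index=False)
        results.update(aberration_profile=profile, aberration_corr=corr)

    # ---- subtype characterization ---------------------------------------
    @stage("characterize")
    def _characterize():
        survival = results["survival"]
        labels = results["icluster"]["labels"]
        km = km_estimator(survival, labels)
        chi2, df_, p = logrank_test(survival, labels)
        km_rows = []
        for g, tab in km.items():
            t = tab.copy()
            t.insert(0, "group", g)
            km_rows.append(t)
        _write(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv", index=False)
        conc = {
            "icluster_vs_nmf_cnvcor": concordance(labels, results["nmf"]["cnvcor"]["labels"]),
            "icluster_vs_nmf_metcor": concordance(labels, results["nmf"]["metcor"]["labels"]),
            "nmf_cnvcor_vs_metcor": concordance(
                results["nmf"]["cnvcor"]["labels"], results["nmf"]["metcor"]["labels"]
            ),
        }
        conc_df = pd.DataFrame(
            [
                {"comparison": k, "chi2": v["chi2"], "p": v["p"], "ari": v["ari"]}
                for k, v in conc.items()
            ]
        )
        _write(conc_df, out / "label_concordance.tsv", index=False)

        groups = (1, 2)  # best- vs worst-prognosis subtypes after relabeling
        cats_cnv = categorize_omics(results["cnv"], thresholds)
        cats_met = categorize_omics(results["met_beta"], thresholds)
        diff_cnv = differential_category_test(
            cats_cnv, labels, groups, seed=seeds["characterize"]
        )
        diff_met = differential_category_test(
            cats_met, labels, groups, seed=seeds["characterize"]
        )
        _write(diff_cnv, out / "differential_cnv.tsv", index=False)
        _write(diff_met, out / "differential_met.tsv", index=False)
        screen = multi_level_screen(
            diff_cnv, diff_met, results["exp"], labels, groups, alpha=config.fdr_alpha
        )
        _write(screen, out / "multi_level_genes.tsv", index=False)
        tert_rows = []
        for gene in screen["gene"].head(5) if len(screen) else []:
            lab, _, p_t = tertile_survival(results["exp"].data.loc[gene], survival)
            tert_rows.append({"gene": gene, "p_logrank_tertiles": p_t})
        _write(pd.DataFrame(tert_rows), out / "tertile_survival.tsv", index=False)
        mut = results["mutations"]
        if len(mut):
            diff_mut = differential_mutation_test(mut, labels, groups)
            _write(diff_mut, out / "differential_mutations.tsv", index=False)
        else:
            diff_mut = pd.DataFrame()
        clin = clinical_table(labels, results["clinical"])
        clin_df = pd.DataFrame(
            [{"covariate": c, "p_chi2": v["p"]} for c, v in clin.items()]
        )
        _write(clin_df, out / "clinical_tests.tsv", index=False)
        results.update(
            km=km,
            logrank=(chi2, df_, p),
            concordance=conc,
            diff_cnv=diff_cnv,
            diff_met=diff_met,
            diff_mut=diff_mut,
            screen=screen,
            clinical_tests=clin,
        )

    manifest = {
        "package": "stadsub",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": dataclasses.asdict(config),
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_yaml(out / "config_used.yaml")
    return results
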