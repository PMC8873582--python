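"""CNV-correlated and MET-correlated gene discovery.

Per gene, the Pearson correlation between expression and a second omics
layer (gene-level copy number, or normal-centred methylation) is computed,
variance-stabilized with Fisher's Z transform, and combined with a per-gene
log-rank survival screen.  Genes with a positive expression~CNV correlation
form the CNVcor set; genes with a negative expression~MET correlation the
METcor set (copy-number dosage raises transcription, promoter methylation
silences it).  Summaries by chromosome arm and by CpG-region class follow
the usual genomic-landscape reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsLayer

logger = logging.getLogger(__name__)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = float(r)
    if not abs(r) < 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


#: correlations this close to +-1 are clamped before atanh so z stays finite
_R_CLAMP = 1.0 - 1e-15


def correlate_layers(exp: OmicsLayer, other: OmicsLayer) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with a second layer.

    Returns a DataFrame indexed by gene with columns ``r``, ``z`` (Fisher Z,
    NaN for |r| = 1 exactly) and ``p_cor`` (two-sided, from the t
    distribution on n-2 df).  Requires identical sample order and at least 4
    samples.  Zero-variance rows are excluded and logged.
    """
    if list(exp.sample_ids) != list(other.sample_ids):
        raise ValueError("sample ids/order differ between layers; run match_samples first")
    genes = [g for g in exp.feature_ids if g in set(other.feature_ids)]
    n = len(exp.sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples")
    A = exp.data.loc[genes].to_numpy(dtype=float)
    B = other.data.loc[genes].to_numpy(dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    va = (Ac**2).sum(axis=1)
    vb = (Bc**2).sum(axis=1)
    ok = (va > 0) & (vb > 0)
    if (~ok).any():
        logger.info("correlate_layers: %d zero-variance genes excluded", int((~ok).sum()))
    r = np.full(len(genes), np.nan)
    r[ok] = (Ac[ok] * Bc[ok]).sum(axis=1) / np.sqrt(va[ok] * vb[ok])
    r = np.clip(r, -1.0, 1.0)
    z = np.where(np.abs(r) < 1.0, np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame({"r": r, "z": z, "p_cor": p}, index=pd.Index(genes, name="gene"))
    return out[ok]


def skewness_with_test(values) -> tuple[float, float]:
    """Adjusted Fisher-Pearson sample skewness with the D'Agostino test p-value."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValueError("skewness test needs at least 8 values")
    if np.ptp(x) == 0:
        raise ValueError("constant vector has undefined skewness")
    g1 = float(stats.skew(x, bias=False))
    p = float(stats.skewtest(x).pvalue)
    return g1, p


def logrank_2group(times, events, in_group1) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic and p-value.

    Standard observed-minus-expected accumulation over distinct event times
    with hypergeometric variance; ties handled canonically.  A degenerate
    comparison (zero variance) yields statistic 0 and p = 1.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(in_group1, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, d, g = t[order], d[order], g[order]
    n = len(t)
    event_times = np.unique(t[d == 1])
    if len(event_times) == 0:
        return 0.0, 1.0
    lo = np.searchsorted(t, event_times, side="left")
    hi = np.searchsorted(t, event_times, side="right")
    cg = np.concatenate([[0], np.cumsum(g)])
    cd = np.concatenate([[0], np.cumsum(d)])
    cgd = np.concatenate([[0], np.cumsum(g & (d == 1))])
    n_t = n - lo
    n1_t = int(g.sum()) - cg[lo]
    d_t = cd[hi] - cd[lo]
    d1_t = cgd[hi] - cgd[lo]
    O1 = float(d1_t.sum())
    frac = n1_t / n_t
    E1 = float((d_t * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = np.where(
            n_t > 1, d_t * frac * (1 - frac) * (n_t - d_t) / np.maximum(n_t - 1, 1), 0.0
        )
    V = float(v_terms.sum())
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_expression_filter(
    exp: OmicsLayer, survival: pd.DataFrame, split: str = "median"
) -> pd.DataFrame:
    """Per-gene survival screen: log-rank p after expression dichotomization.

    Samples above the per-gene median form one group, the rest the other.
    A degenerate split (all values equal) is recorded with p = 1 and flagged.
    Returns columns ``p_logrank`` and ``degenerate``.
    """
    if split != "median":
        raise ValueError("only median dichotomization is implemented")
    surv = survival.set_index("sample_id").loc[list(exp.sample_ids)]
    t = surv["os_days"].to_numpy(dtype=float)
    d = surv["os_event"].to_numpy(dtype=int)
    X = exp.data.to_numpy(dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    ps, flags = np.ones(X.shape[0]), np.zeros(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        hi = X[i] > med[i, 0]
        if hi.sum() == 0 or hi.sum() == len(hi):
            flags[i] = True
            continue
        _, ps[i] = logrank_2group(t, d, hi)
    if flags.any():
        logger.info("logrank_expression_filter: %d degenerate splits (p=1)", int(flags.sum()))
    return pd.DataFrame(
        {"p_logrank": ps, "degenerate": flags}, index=pd.Index(exp.feature_ids, name="gene")
    )


@dataclass
class CorGeneSets:
    cnvcor: set
    metcor: set

    @property
    def overlap(self) -> set:
        return self.cnvcor & self.metcor


def select_cor_genes(
    cnv_cor: pd.DataFrame,
    met_cor: pd.DataFrame,
    alpha_cor: float = 0.05,
    alpha_surv: float = 0.05,
) -> CorGeneSets:
    """Directional selection of CNVcor and METcor genes.

    CNVcor: r > 0, correlation p < ``alpha_cor`` and (when a ``p_logrank``
    column is present) log-rank p < ``alpha_surv``.  METcor: the same with
    r < 0 on the methylation comparison.  Enlarging either alpha can only
    grow the sets.
    """

    def _pick(tab: pd.DataFrame, positive: bool) -> set:
        sign_ok = tab["r"] > 0 if positive else tab["r"] < 0
        sel = sign_ok & (tab["p_cor"] < alpha_cor)
        if "p_logrank" in tab.columns:
            sel &= tab["p_logrank"] < alpha_surv
        return set(tab.index[sel])

    return CorGeneSets(cnvcor=_pick(cnv_cor, True), metcor=_pick(met_cor, False))


def arm_proportions(gene_set, annotation: pd.DataFrame, universe=None) -> pd.DataFrame:
    """Fraction of analyzed genes per chromosome arm that belong to ``gene_set``.

    ``universe`` defaults to every annotated gene; arms without analyzed
    genes are omitted.
    """
    universe = list(universe) if universe is not None else list(annotation.index)
    ann = annotation.loc[universe]
    arm = ann["chromosome"].astype(str) + ann["arm"].astype(str)
    in_set = pd.Series([g in set(gene_set) for g in universe], index=ann.index)
    grp = pd.DataFrame({"arm": arm, "in_set": in_set}).groupby("arm")
    out = grp["in_set"].agg(["sum", "count"]).rename(columns={"sum": "n_set", "count": "n_total"})
    out["fraction"] = out["n_set"] / out["n_total"]
    return out.reset_index()


def cpg_region_breakdown(
    metcor_genes,
    manifest: pd.DataFrame,
    chosen_probes: pd.Series,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Tally the representative probes of METcor genes by CpG context.

    Returns counts by ``region_class`` (Island/Shore/Shelf/OpenSea), by
    ``gene_relation`` (Promoter/5'UTR/FirstExon/Body/Other) and, when a gene
    annotation is supplied, coding vs non-coding gene counts.  Each tally
    sums to the number of METcor genes with a chosen probe.
    """
    genes = [g for g in metcor_genes if g in chosen_probes.index]
    pairs = pd.DataFrame({"gene_symbol": genes, "probe_id": chosen_probes.loc[genes].to_numpy()})
    merged = pairs.merge(manifest, on=["probe_id", "gene_symbol"], how="left")
    out = {
        "region_class": merged["region_class"].value_counts().to_dict(),
        "gene_relation": merged["gene_relation"].value_counts().to_dict(),
    }
    if annotation is not None:
        coding = annotation["coding"].reindex(genes)
        out["coding"] = {
            "coding": int(coding.fillna(False).sum()),
            "non_coding": int((~coding.fillna(False).astype(bool)).sum()),
        }
    return out
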