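"""Matched multi-omics data model: matrix containers, readers, and feature mapping.

The central container is :class:`OmicsLayer`, one feature-by-sample real matrix
carrying expression (EXP, log2 fold change vs. normal), gene-level copy number
(CNV, log2 segment ratios) or DNA methylation (MET, beta values or
normal-centred beta differences).  Helper functions cover the standard
preprocessing steps of an integrative tumor-omics analysis: missingness
filtering, k-nearest-neighbour imputation, SEG-segment-to-gene mapping, and
representative-probe selection for genes covered by several methylation
probes.

All tables are plain TSV; ``NA`` (or an empty cell) marks a missing value.
Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYER_KINDS = ("EXP", "CNV", "MET")

#: autosomes only; features elsewhere are dropped when sex chromosomes are excluded
AUTOSOMES = frozenset(str(c) for c in range(1, 23))

REGION_CLASSES = ("Island", "Shore", "Shelf", "OpenSea")
GENE_RELATIONS = ("Promoter", "5'UTR", "FirstExon", "Body", "Other")


class LayerError(ValueError):
    """Raised on malformed omics input (duplicate ids, wrong scale, bad cells)."""


@dataclass
class OmicsLayer:
    """One omics matrix: rows are features (genes or probes), columns samples.

    Parameters
    ----------
    kind
        One of ``EXP``, ``CNV``, ``MET``.
    data
        Float DataFrame, index = feature ids, columns = sample ids, NaN = missing.
    centered
        True when values are tumor minus the matched-normal mean.  Uncentred
        MET values must be beta values in [0, 1]; centred MET differences lie
        in [-1, 1].
    """

    kind: str
    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise LayerError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise LayerError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise LayerError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if self.kind == "MET":
            finite = vals[np.isfinite(vals)]
            if not self.centered and finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise LayerError("uncentred MET layer must contain beta values in [0, 1]")
            if self.centered and finite.size and (finite.min() < -1.0 or finite.max() > 1.0):
                raise LayerError("centred MET layer must lie in [-1, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_features(self, features) -> "OmicsLayer":
        return replace(self, data=self.data.loc[list(features)])

    def subset_samples(self, samples) -> "OmicsLayer":
        return replace(self, data=self.data[list(samples)])


# ---------------------------------------------------------------------------
# readers


def _read_matrix_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        seen, dups = set(), []
        for s in samples:
            if s in seen:
                dups.append(s)
            seen.add(s)
        raise LayerError(f"duplicate sample ids in header: {sorted(set(dups))[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        raise LayerError(
            f"duplicate feature ids: {raw.index[raw.index.duplicated()].unique().tolist()[:5]}"
        )
    num = raw.apply(lambda col: pd.to_numeric(col.replace({"NA": None, "": None}), errors="coerce"))
    bad = num.isna() & ~raw.isin(["NA", ""])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LayerError(
            f"non-numeric cell at feature {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    num.index.name = raw.index.name
    return num.astype(float)


def read_layer(path, kind: str, centered: bool = False) -> OmicsLayer:
    """Read a feature-by-sample TSV matrix into an :class:`OmicsLayer`.

    The first column holds feature ids, the header row sample ids.  ``NA``
    and empty cells become missing values (never zero).  Duplicate ids or a
    non-numeric cell are hard errors.
    """
    return OmicsLayer(kind=kind, data=_read_matrix_tsv(path), centered=centered)


def write_layer(layer: OmicsLayer, path, float_format: str = "%.10g") -> None:
    df = layer.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=float_format)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: symbol, chromosome, arm, start, end, coding."""
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"symbol", "chromosome", "arm", "start", "end"}
    missing = required - set(ann.columns)
    if missing:
        raise LayerError(f"gene annotation missing columns {sorted(missing)}")
    if ann["symbol"].duplicated().any():
        raise LayerError("duplicate gene symbols in annotation")
    if (ann["start"] > ann["end"]).any():
        raise LayerError("gene annotation has start > end")
    if "coding" not in ann.columns:
        ann["coding"] = True
    return ann.set_index("symbol")


def read_probe_manifest(path) -> pd.DataFrame:
    """Probe manifest TSV: one row per probe-gene pair.

    Columns: probe_id, gene_symbol, region_class, gene_relation.  A probe
    mapped to several genes appears once per gene.
    """
    man = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_symbol", "region_class", "gene_relation"}
    missing = required - set(man.columns)
    if missing:
        raise LayerError(f"probe manifest missing columns {sorted(missing)}")
    if man.duplicated(["probe_id", "gene_symbol"]).any():
        raise LayerError("duplicate probe-gene pairs in manifest")
    return man


def read_segments(path, dialect: str = "one_based") -> pd.DataFrame:
    """Read a SEG file (Sample, Chromosome, Start, End, Segment_Mean).

    ``dialect='one_based'`` treats coordinates as 1-based inclusive (the
    internal convention); ``'zero_based_half_open'`` converts BED-style
    coordinates on the fly.
    """
    seg = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    required = {"Sample", "Chromosome", "Start", "End", "Segment_Mean"}
    missing = required - set(seg.columns)
    if missing:
        raise LayerError(f"SEG file missing columns {sorted(missing)}")
    seg = seg.rename(
        columns={
            "Sample": "sample_id",
            "Chromosome": "chromosome",
            "Start": "start",
            "End": "end",
            "Segment_Mean": "segment_mean",
        }
    )
    if dialect == "zero_based_half_open":
        seg["start"] = seg["start"] + 1
    elif dialect != "one_based":
        raise ValueError(f"unknown SEG dialect {dialect!r}")
    if (seg["start"] > seg["end"]).any():
        raise LayerError("segment with start > end")
    return seg


def read_survival(path) -> pd.DataFrame:
    """Clinical TSV with sample_id, os_days, os_event (1 = death, 0 = censored)."""
    cl = pd.read_csv(path, sep="\t")
    required = {"sample_id", "os_days", "os_event"}
    missing = required - set(cl.columns)
    if missing:
        raise LayerError(f"clinical table missing columns {sorted(missing)}")
    if (cl["os_days"] <= 0).any():
        raise LayerError("survival times must be positive")
    if not cl["os_event"].isin([0, 1]).all():
        raise LayerError("os_event must be 0/1")
    return cl


#: somatic variant classes retained when building the binary mutation matrix;
#: synonymous (and any other) records are discarded.
NONSYNONYMOUS = ("missense", "nonsense")


def read_mutations(path, samples=None) -> pd.DataFrame:
    """Build a binary gene-by-sample mutation matrix from MAF-lite records.

    Only missense and nonsense records count; synonymous mutations are
    eliminated.  ``samples`` optionally fixes the column universe so samples
    without any retained mutation still appear as all-zero columns.
    """
    maf = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "gene_symbol", "variant_class"}
    missing = required - set(maf.columns)
    if missing:
        raise LayerError(f"MAF-lite file missing columns {sorted(missing)}")
    keep = maf[maf["variant_class"].isin(NONSYNONYMOUS)]
    mat = (
        pd.crosstab(keep["gene_symbol"], keep["sample_id"]).clip(upper=1)
        if len(keep)
        else pd.DataFrame()
    )
    if samples is not None:
        mat = mat.reindex(columns=list(samples), fill_value=0)
    return mat.fillna(0).astype(int)


# ---------------------------------------------------------------------------
# filtering / imputation


def filter_features(
    layer: OmicsLayer,
    annotation: pd.DataFrame | None = None,
    max_missing_fraction: float = 0.3,
    drop_sex_chromosomes: bool = False,
) -> OmicsLayer:
    """Drop features with too many missing values and (optionally) off-autosome features.

    A feature is removed when its missing fraction is *strictly greater* than
    ``max_missing_fraction`` ("over 30%" semantics: exactly 30% is retained).
    With ``drop_sex_chromosomes`` every annotated feature whose chromosome is
    not 1..22 is removed; unannotated features are kept.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = layer.data.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    if drop_sex_chromosomes:
        if annotation is None:
            raise ValueError("drop_sex_chromosomes requires an annotation")
        chrom = annotation["chromosome"].astype(str)
        on_sex = layer.feature_ids.map(
            lambda f: f in chrom.index and chrom.loc[f] not in AUTOSOMES
        )
        keep &= ~np.asarray(on_sex, dtype=bool)
    if not keep.any():
        raise LayerError("all features removed by filtering")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_features: removed %d/%d features", dropped, len(keep))
    return replace(layer, data=layer.data.loc[keep])


def knn_impute(layer: OmicsLayer, k: int = 10) -> OmicsLayer:
    """Impute missing cells from the k nearest features.

    Distance between two features is the root-mean-square difference over
    their jointly observed samples (so features with different missingness
    patterns are comparable).  A missing cell (feature i, sample s) becomes
    the mean of the values at s of the k nearest features observed at s.
    When fewer than k such neighbours exist the feature's own observed mean
    is used and a warning is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = layer.data.to_numpy(dtype=float).copy()
    obs = np.isfinite(X)
    if not obs.any(axis=1).all():
        bad = layer.feature_ids[~obs.any(axis=1)].tolist()
        raise LayerError(f"features with no observed value: {bad[:5]}")
    if obs.all():
        return replace(layer, data=layer.data.copy())
    rows_missing = np.flatnonzero(~obs.all(axis=1))
    row_means = np.nanmean(X, axis=1)
    out = X.copy()
    for i in rows_missing:
        shared = obs & obs[i]  # (n_features, n_samples) joint observation mask
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X - X[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.where(n_shared > 0, (diff**2).sum(axis=1) / n_shared, np.inf))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for s in np.flatnonzero(~obs[i]):
            eligible = np.flatnonzero(obs[:, s] & np.isfinite(dist))
            if len(eligible) < k:
                logger.warning(
                    "knn_impute: feature %s sample %s has %d < k=%d usable neighbours; "
                    "falling back to the feature mean",
                    layer.feature_ids[i], layer.sample_ids[s], len(eligible), k,
                )
                out[i, s] = row_means[i]
            else:
                nearest = eligible[np.argsort(dist[eligible], kind="stable")[:k]]
                out[i, s] = X[nearest, s].mean()
    return replace(layer, data=pd.DataFrame(out, index=layer.feature_ids, columns=layer.sample_ids))


# ---------------------------------------------------------------------------
# probe / segment -> gene mapping


def map_segments_to_genes(segments: pd.DataFrame, annotation: pd.DataFrame) -> OmicsLayer:
    """Length-weighted mean segment log2 ratio per gene per sample.

    For every gene the overlapping segments of a sample contribute their
    segment mean weighted by the number of overlapping base pairs (1-based
    inclusive intervals).  Genes without any overlapping segment are missing
    for that sample.  Splitting a segment into adjacent pieces with the same
    mean leaves the result unchanged.
    """
    genes = annotation[["chromosome", "start", "end"]].copy()
    genes["chromosome"] = genes["chromosome"].astype(str)
    samples = pd.unique(segments["sample_id"])
    out = pd.DataFrame(np.nan, index=genes.index, columns=samples)
    for chrom, gsub in genes.groupby("chromosome", sort=False):
        seg_c = segments[segments["chromosome"].astype(str) == chrom]
        if seg_c.empty:
            continue
        for sample, ssub in seg_c.groupby("sample_id", sort=False):
            ssub = ssub.sort_values("start")
            starts = ssub["start"].to_numpy()
            ends = ssub["end"].to_numpy()
            means = ssub["segment_mean"].to_numpy(dtype=float)
            # segments of one sample/chromosome are non-overlapping, so the
            # overlap set of a gene is a contiguous run
            lo = np.searchsorted(ends, gsub["start"].to_numpy(), side="left")
            hi = np.searchsorted(starts, gsub["end"].to_numpy(), side="right")
            for gi, (gene, gs, ge) in enumerate(
                zip(gsub.index, gsub["start"].to_numpy(), gsub["end"].to_numpy())
            ):
                a, b = lo[gi], hi[gi]
                if a >= b:
                    continue
                ov = np.minimum(ends[a:b], ge) - np.maximum(starts[a:b], gs) + 1
                ov = np.clip(ov, 0, None)
                w = ov.sum()
                if w > 0:
                    out.at[gene, sample] = float(np.dot(ov, means[a:b]) / w)
    return OmicsLayer(kind="CNV", data=out, centered=True)


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def select_representative_probe(
    probe_layer: OmicsLayer,
    exp_layer: OmicsLayer,
    manifest: pd.DataFrame,
    rule: str = "mean_r",
) -> tuple[OmicsLayer, pd.Series]:
    """Collapse a probe-level MET layer to gene level, one probe per gene.

    For genes with several probes the representative is, under ``mean_r``
    (the default), the probe whose Pearson correlation with the gene's
    expression is closest to the per-gene mean correlation; under ``min_r``
    the probe with the smallest (most negative) correlation.  ``min_r``
    mirrors a common convention but carries a winner's-curse bias: picking
    the extreme of several noisy correlation estimates drags null genes
    towards negative r, which inflates downstream false discoveries.  Returns the gene-level layer plus the
    chosen probe id per gene (provenance for the CpG-region breakdown).
    Genes without any probe in the manifest are excluded and logged.
    """
    if rule not in ("min_r", "mean_r"):
        raise ValueError(f"unknown rule {rule!r}")
    samples = [s for s in exp_layer.sample_ids if s in set(probe_layer.sample_ids)]
    if len(samples) < 4:
        raise LayerError("need at least 4 shared samples for probe selection")
    man = manifest[
        manifest["probe_id"].isin(probe_layer.feature_ids)
        & manifest["gene_symbol"].isin(exp_layer.feature_ids)
    ]
    skipped = set(exp_layer.feature_ids) - set(man["gene_symbol"])
    if skipped:
        logger.info("select_representative_probe: %d genes without probes excluded", len(skipped))
    P = probe_layer.data[samples]
    E = exp_layer.data[samples]
    rows, chosen = {}, {}
    for gene, sub in man.groupby("gene_symbol", sort=False):
        probes = sub["probe_id"].tolist()
        if len(probes) == 1:
            pick = probes[0]
        else:
            r = _row_pearson(
                P.loc[probes].to_numpy(dtype=float),
                np.tile(E.loc[gene].to_numpy(dtype=float), (len(probes), 1)),
            )
            if rule == "min_r":
                pick = probes[int(np.nanargmin(r))]
            else:
                pick = probes[int(np.nanargmin(np.abs(r - np.nanmean(r))))]
        rows[gene] = P.loc[pick]
        chosen[gene] = pick
    gene_met = pd.DataFrame(rows).T
    gene_met = gene_met.loc[[g for g in exp_layer.feature_ids if g in rows]]
    layer = OmicsLayer(kind="MET", data=gene_met, centered=probe_layer.centered)
    return layer, pd.Series(chosen, name="probe_id").loc[layer.feature_ids]


def match_samples(*tables, min_samples: int = 3):
    """Restrict every input to the shared samples, in a common column order.

    Accepts any mix of :class:`OmicsLayer` (samples = columns) and DataFrames
    with a ``sample_id`` column (clinical, survival) or sample columns
    (mutation matrix).  Order follows the first input.  Fewer than
    ``min_samples`` shared samples is an error.
    """
    if len(tables) < 2:
        raise ValueError("need at least two inputs to match")

    def ids(t):
        if isinstance(t, OmicsLayer):
            return list(t.sample_ids)
        if isinstance(t, pd.DataFrame) and "sample_id" in t.columns:
            return t["sample_id"].tolist()
        return list(t.columns)

    common = None
    for t in tables:
        s = set(ids(t))
        common = s if common is None else common & s
    order = [s for s in ids(tables[0]) if s in common]
    if len(order) < min_samples:
        raise LayerError(f"only {len(order)} shared samples (< {min_samples})")
    out = []
    for t in tables:
        if isinstance(t, OmicsLayer):
            out.append(t.subset_samples(order))
        elif isinstance(t, pd.DataFrame) and "sample_id" in t.columns:
            sub = t.set_index("sample_id").loc[order].reset_index()
            out.append(sub)
        else:
            out.append(t[order])
    return tuple(out)
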