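"""Directional CNV/MET aberration calls and per-sample frequency coupling.

Copy-number gain/loss is called on gene-level log2 segment ratios
(gain > 0.3, loss < -0.3); hyper-/hypomethylation on raw beta values
(hyper > 0.8, hypo < 0.2).  Note the two scales are different even though
both thresholds are conventionally quoted as cutoffs on "beta": the CNV
cutoff is a log2 ratio, the MET cutoffs are methylation fractions.  All
inequalities are strict, so a value exactly at a threshold is Normal.

Per-sample aberration frequencies (fraction of analyzed genes called in
each direction) quantify genomic instability; their pairwise Pearson
correlations across samples measure how tightly CNV and MET abnormality
loads are coupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsLayer


@dataclass(frozen=True)
class AberrationThresholds:
    gain: float = 0.3
    loss: float = -0.3
    hyper: float = 0.8
    hypo: float = 0.2


DIRECTIONS = ("gain", "loss", "hyper", "hypo")


def call_aberrations(
    cnv: OmicsLayer | None,
    met_beta: OmicsLayer | None,
    thresholds: AberrationThresholds = AberrationThresholds(),
) -> dict:
    """Boolean per-gene-per-sample call matrices for each direction.

    ``met_beta`` must hold raw (uncentred) beta values in [0, 1]; centred
    values are rejected as a wrong-scale error.  Either layer may be None
    when only one platform is analyzed.
    """
    calls = {}
    if cnv is not None:
        C = cnv.data
        calls["gain"] = C > thresholds.gain
        calls["loss"] = C < thresholds.loss
    if met_beta is not None:
        if met_beta.centered:
            raise ValueError("aberration calling needs raw beta values, got centred MET")
        B = met_beta.data
        vals = B.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("MET values outside [0, 1]: wrong scale supplied")
        calls["hyper"] = B > thresholds.hyper
        calls["hypo"] = B < thresholds.hypo
    return calls


def frequency_profile(calls: dict) -> pd.DataFrame:
    """Per-sample fraction of analyzed genes called in each direction.

    Missing cells do not count as analyzed genes for their direction.
    """
    cols = {}
    for direction, mat in calls.items():
        analyzed = mat.notna() if mat.isna().any().any() else None
        frac = mat.fillna(False).sum(axis=0) / (
            analyzed.sum(axis=0) if analyzed is not None else mat.shape[0]
        )
        cols[f"f_{direction}"] = frac
    return pd.DataFrame(cols)


def pairwise_frequency_correlation(profile: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation (with two-sided p) for every unordered frequency pair.

    Zero-variance frequency vectors are flagged and their r omitted (NaN).
    """
    cols = list(profile.columns)
    if len(profile) < 4:
        raise ValueError("need at least 4 samples")
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x = profile[cols[i]].to_numpy(dtype=float)
            y = profile[cols[j]].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"pair": f"{cols[i]}~{cols[j]}", "r": np.nan, "p": np.nan,
                             "degenerate": True})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"pair": f"{cols[i]}~{cols[j]}", "r": float(r), "p": float(p),
                         "degenerate": False})
    return pd.DataFrame(rows)
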