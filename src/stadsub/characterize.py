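"""Subtype characterization: survival, label concordance, and differential tests.

Kaplan-Meier curves and the g-group log-rank test compare overall survival
across subtypes; cross-tabulation with a chi-square independence test and
the adjusted Rand index quantify agreement between two labelings; per-gene
Fisher-exact tests on categorized copy-number / methylation states and on
binary mutation status identify subtype-differential genes, with
Benjamini-Hochberg control of the false discovery rate; and per-gene
expression tertiles (L1-L3) stratify survival for candidate markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .aberrations import AberrationThresholds
from .io import OmicsLayer

logger = logging.getLogger(__name__)

CNV_CATEGORIES = ("Normal", "Gain", "Loss")
MET_CATEGORIES = ("Normal", "HyperMethy", "HypoMethy")


# ---------------------------------------------------------------------------
# survival


def km_estimator(survival: pd.DataFrame, labels: pd.Series) -> dict:
    """Product-limit survival estimate per label group.

    Returns ``{group: DataFrame(time, at_risk, survival)}``; empty groups
    are omitted and logged.
    """
    surv = survival.set_index("sample_id")
    out = {}
    for group in pd.unique(labels):
        members = labels.index[labels == group]
        sub = surv.loc[[s for s in members if s in surv.index]]
        if sub.empty:
            logger.warning("km_estimator: group %r has no samples with survival data", group)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_days"], sub["os_event"])
        table = kmf.event_table
        sf = kmf.survival_function_.iloc[:, 0]
        out[group] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=float),
                "survival": sf.reindex(table.index).to_numpy(dtype=float),
            }
        )
    return out


def logrank_test(survival: pd.DataFrame, labels: pd.Series) -> tuple[float, int, float]:
    """g-group log-rank test: (chi-square, df = g - 1, p-value)."""
    surv = survival.set_index("sample_id").loc[labels.index]
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(surv["os_days"], labels.to_numpy(), surv["os_event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def median_survival(km: pd.DataFrame) -> float:
    """First time the product-limit curve drops to <= 0.5 (inf if it never does)."""
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("inf")


# ---------------------------------------------------------------------------
# concordance


def concordance(labels_a: pd.Series, labels_b: pd.Series) -> dict:
    """Agreement of two labelings of the same samples.

    Returns the cross-tabulation, the chi-square independence p (no
    continuity correction; omitted for a degenerate single-class labeling)
    and the adjusted Rand index.
    """
    common = [s for s in labels_a.index if s in set(labels_b.index)]
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    table = pd.crosstab(a, b)
    ari = float(adjusted_rand_score(a, b))
    if table.shape[0] < 2 or table.shape[1] < 2:
        logger.warning("concordance: degenerate labeling, chi-square omitted")
        return {"table": table, "chi2": np.nan, "p": np.nan, "ari": ari}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "chi2": float(chi2), "p": float(p), "ari": ari}


# ---------------------------------------------------------------------------
# categorical omics states


def categorize_omics(
    layer: OmicsLayer, thresholds: AberrationThresholds = AberrationThresholds()
) -> pd.DataFrame:
    """Exactly one category per cell: Normal/Gain/Loss (CNV) or Normal/HyperMethy/HypoMethy (MET)."""
    X = layer.data
    if layer.kind == "CNV":
        out = np.where(X > thresholds.gain, "Gain", np.where(X < thresholds.loss, "Loss", "Normal"))
    elif layer.kind == "MET":
        if layer.centered:
            raise ValueError("categorize_omics needs raw beta values for MET")
        vals = X.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("MET values outside [0, 1]: wrong scale supplied")
        out = np.where(
            X > thresholds.hyper, "HyperMethy", np.where(X < thresholds.hypo, "HypoMethy", "Normal")
        )
    else:
        raise ValueError("categorize_omics applies to CNV or MET layers")
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability rule)."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def _log_table_prob(row1, colsums, n, r1) -> float:
    # log P(table | margins) for a 2 x C table under the hypergeometric null
    row1 = np.asarray(row1)
    colsums = np.asarray(colsums)
    return float(
        (gammaln(colsums + 1) - gammaln(row1 + 1) - gammaln(colsums - row1 + 1)).sum()
        + gammaln(r1 + 1)
        + gammaln(n - r1 + 1)
        - gammaln(n + 1)
    )


def fisher_exact_2xc(table, max_total: int = 200, n_mc: int = 100_000, seed: int = 0) -> float:
    """Two-sided exact p for a 2 x C contingency table.

    Full enumeration of tables with the observed margins when the total is
    at most ``max_total`` (p = sum of probabilities of tables no more likely
    than the observed one); otherwise a seeded Monte-Carlo estimate over
    ``n_mc`` tables drawn from the conditional null.
    """
    T = np.asarray(table, dtype=int)
    if T.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    keep = T.sum(axis=0) > 0
    T = T[:, keep]
    C = T.shape[1]
    if C < 2:
        return 1.0
    n = int(T.sum())
    r1 = int(T[0].sum())
    colsums = T.sum(axis=0)
    logp_obs = _log_table_prob(T[0], colsums, n, r1)
    tol = 1e-7
    if n <= max_total:
        total = 0.0
        # enumerate the first C-1 cells of row 1; the last is determined
        def rec(idx, remaining, cells):
            nonlocal total
            if idx == C - 1:
                last = remaining
                if 0 <= last <= colsums[-1]:
                    lp = _log_table_prob(cells + [last], colsums, n, r1)
                    if lp <= logp_obs + tol:
                        total += np.exp(lp)
                return
            lo = max(0, remaining - int(colsums[idx + 1 :].sum()))
            hi = min(int(colsums[idx]), remaining)
            for a in range(lo, hi + 1):
                rec(idx + 1, remaining - a, cells + [a])

        rec(0, r1, [])
        return float(min(total, 1.0))
    # Monte Carlo: permute group membership, tabulate
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(C), colsums)
    hits = 0
    batch = 2000
    done = 0
    while done < n_mc:
        b = min(batch, n_mc - done)
        for _ in range(b):
            pick = rng.permutation(pool)[:r1]
            row1 = np.bincount(pick, minlength=C)
            if _log_table_prob(row1, colsums, n, r1) <= logp_obs + tol:
                hits += 1
        done += b
    return float((hits + 1) / (n_mc + 1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    gene: str
    test: str
    p: float
    q: float
    direction: str


def differential_category_test(
    categories: pd.DataFrame,
    labels: pd.Series,
    groups: tuple,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene exact test of category distribution between two subtypes.

    ``categories`` is a per-gene-per-sample state matrix (e.g. from
    :func:`categorize_omics`); ``groups`` names the two subtype labels to
    compare.  Empty category columns are collapsed before testing; p-values
    are BH-adjusted across genes.  Direction reports the group with the
    higher non-Normal rate.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    members = {g: labels.index[labels == g] for g in groups}
    sub = categories[
        [s for g in groups for s in members[g] if s in categories.columns]
    ]
    cats = sorted(pd.unique(sub.to_numpy().ravel()))
    rows = []
    for gene in sub.index:
        vals = sub.loc[gene]
        tab = np.array(
            [
                [int((vals[[s for s in members[g] if s in vals.index]] == c).sum()) for c in cats]
                for g in groups
            ]
        )
        p = fisher_exact_2xc(tab, seed=seed)
        aberrant = [c for c in cats if c != "Normal"]
        rates = [
            float((vals[[s for s in members[g] if s in vals.index]].isin(aberrant)).mean())
            for g in groups
        ]
        direction = str(groups[0]) if rates[0] >= rates[1] else str(groups[1])
        rows.append({"gene": gene, "test": "fisher_2xC", "p": p, "direction": direction})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out[["gene", "test", "p", "q", "direction"]]


def differential_mutation_test(
    mutations: pd.DataFrame, labels: pd.Series, groups: tuple
) -> pd.DataFrame:
    """Per-gene 2x2 Fisher exact test of mutation rate between two subtypes.

    Genes never mutated in the compared samples are skipped (logged);
    BH adjustment across tested genes; direction = group with the higher
    mutation rate.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    members = {
        g: [s for s in labels.index[labels == g] if s in mutations.columns] for g in groups
    }
    rows = []
    skipped = 0
    for gene in mutations.index:
        counts = []
        for g in groups:
            m = mutations.loc[gene, members[g]]
            counts.append([int(m.sum()), int(len(m) - m.sum())])
        tab = np.array(counts)
        if tab[:, 0].sum() == 0:
            skipped += 1
            continue
        p = fisher_exact_2x2(tab)
        rate = [tab[i, 0] / tab[i].sum() for i in range(2)]
        rows.append(
            {
                "gene": gene,
                "test": "fisher_2x2",
                "p": p,
                "direction": str(groups[0]) if rate[0] >= rate[1] else str(groups[1]),
            }
        )
    if skipped:
        logger.info("differential_mutation_test: %d never-mutated genes skipped", skipped)
    out = pd.DataFrame(rows, columns=["gene", "test", "p", "direction"])
    out["q"] = bh_adjust(out["p"]) if len(out) else np.zeros(0)
    return out[["gene", "test", "p", "q", "direction"]]


# ---------------------------------------------------------------------------
# tertile survival


def tertile_survival(
    expression: pd.Series, survival: pd.DataFrame
) -> tuple[pd.Series, dict, float]:
    """Split one gene's expression into tertiles L1-L3 and test survival.

    Cuts at the 1/3 and 2/3 empirical quantiles; when ties empty a tertile
    the split falls back to rank-based thirds (logged).  Returns the tertile
    labels, the per-group Kaplan-Meier tables and the 3-group log-rank p.
    """
    x = expression.dropna()
    if len(x) < 9:
        raise ValueError("tertile analysis needs at least 9 samples")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    lab = pd.Series(
        np.where(x <= q1, "L1", np.where(x <= q2, "L2", "L3")), index=x.index, name="tertile"
    )
    if len(set(lab)) < 3:
        logger.warning("tertile_survival: ties collapsed a tertile; using rank-based split")
        order = x.sort_values(kind="stable").index
        lab = pd.Series(index=x.index, dtype=object, name="tertile")
        third = len(order) // 3
        lab[order[:third]] = "L1"
        lab[order[third : 2 * third]] = "L2"
        lab[order[2 * third :]] = "L3"
    km = km_estimator(survival, lab)
    if len(set(lab)) < 2:
        return lab, km, 1.0
    _, _, p = logrank_test(survival, lab)
    return lab, km, p


# ---------------------------------------------------------------------------
# clinical summary


def clinical_table(labels: pd.Series, clinical: pd.DataFrame, covariates=None) -> dict:
    """Per-subtype counts for each categorical covariate plus a chi-square p.

    Mirrors the usual "Table 1" of a subtyping study; samples missing a
    covariate are dropped for that covariate only.
    """
    cl = clinical.set_index("sample_id").loc[[s for s in labels.index if s in set(clinical["sample_id"])]]
    covariates = covariates or [c for c in cl.columns if c not in ("os_days", "os_event")]
    out = {}
    for cov in covariates:
        sub = cl[cov].dropna()
        tab = pd.crosstab(sub, labels.loc[sub.index])
        if tab.shape[0] > 1 and tab.shape[1] > 1:
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
        else:
            p = np.nan
        out[cov] = {"table": tab, "p": float(p) if np.isfinite(p) else np.nan}
    return out


def multi_level_screen(
    diff_cnv: pd.DataFrame,
    diff_met: pd.DataFrame,
    exp: OmicsLayer,
    labels: pd.Series,
    groups: tuple,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Genes different between two subtypes at all three molecular levels.

    Intersects the CNV and MET categorical differentials (q < alpha) with a
    per-gene expression rank-sum test between the two subtypes (BH q <
    alpha).  The expression test is a nonparametric stand-in for a count
    model: this screen consumes already-normalized expression, not raw
    counts.
    """
    members = {g: [s for s in labels.index[labels == g] if s in exp.sample_ids] for g in groups}
    genes = sorted(
        set(diff_cnv.loc[diff_cnv["q"] < alpha, "gene"])
        & set(diff_met.loc[diff_met["q"] < alpha, "gene"])
        & set(exp.feature_ids)
    )
    rows = []
    for gene in genes:
        a = exp.data.loc[gene, members[groups[0]]].to_numpy(dtype=float)
        b = exp.data.loc[gene, members[groups[1]]].to_numpy(dtype=float)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"gene": gene, "p_exp": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_exp"] = bh_adjust(out["p_exp"])
        out = out[out["q_exp"] < alpha].reset_index(drop=True)
    return out
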