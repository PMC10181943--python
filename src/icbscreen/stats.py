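"""The statistical harness.

Gene-wise differential expression with the published filters (a Welch test
standing in for the moderated linear model), the univariate logistic
response screen with Benjamini-Hochberg tiers, one-sided hypergeometric
over-representation, Mann-Whitney comparison of gene-set significance,
the bivariate cytokine linear model, survival stratification and the
integrative cross-correlation clustering of top features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, mannwhitneyu, spearmanr, ttest_ind
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --- Differential expression --------------------------------------------------


def expression_filter(
    expr: ExpressionMatrix,
    coding_genes: set[str] | list[str],
    min_log2tpm: float = 0.5,
    min_fraction: float = 0.30,
) -> list[str]:
    """Protein-coding genes expressed at log2TPM >= ``min_log2tpm`` in at
    least ``min_fraction`` of samples (both inclusive)."""
    coding = set(coding_genes)
    if not coding:
        raise ValueError("coding gene list is empty")
    V = expr.values
    frac = np.nanmean(np.where(np.isnan(V), np.nan, V >= min_log2tpm), axis=1)
    return [
        g
        for g, f in zip(expr.gene_ids, frac)
        if g in coding and f >= min_fraction
    ]


def differential_expression(
    expr: ExpressionMatrix, response: pd.Series
) -> pd.DataFrame:
    """Gene-wise two-group comparison of responders vs nonresponders.

    Log-fold-change is the responder-minus-nonresponder group mean
    difference on the log2 scale; p-values come from Welch's
    unequal-variance t-test with BH adjustment across genes.  This is a
    documented stand-in for a moderated linear model.
    """
    response = response.reindex(expr.sample_ids)
    groups = response.to_numpy(dtype=float)
    mask1 = groups == 1
    mask0 = groups == 0
    if mask1.sum() < 3 or mask0.sum() < 3:
        raise ValueError("each response group needs at least 3 samples")
    V = expr.values
    x1, x0 = V[:, mask1], V[:, mask0]
    lfc = np.nanmean(x1, axis=1) - np.nanmean(x0, axis=1)
    res = ttest_ind(x1, x0, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {"gene": expr.gene_ids, "lfc": lfc, "p": p, "p_adj": bh_adjust(p)}
    ).set_index("gene")


# --- Logistic response screen -------------------------------------------------

FEATURE_KINDS = ("binary", "continuous", "burden")


def prevalence_filter(
    features: pd.DataFrame,
    kinds: dict[str, str],
    min_prevalence: float = 0.05,
) -> pd.DataFrame:
    """Drop binary features present in fewer than ``min_prevalence`` of
    samples (inclusive); continuous/burden features pass through."""
    keep = []
    for col in features.columns:
        if kinds.get(col, "continuous") == "binary":
            prev = features[col].fillna(0).astype(float).mean()
            if prev < min_prevalence:
                continue
        keep.append(col)
    return features[keep]


@dataclass
class AssociationResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float = np.nan
    tier: str = "ns"
    n: int = 0
    separated: bool = False


def logistic_screen(
    features: pd.DataFrame,
    response: pd.Series,
    fdr_significant: float = 0.1,
    fdr_near_significant: float = 0.25,
) -> pd.DataFrame:
    """Univariate logistic regression of binary response on each feature.

    OR = exp(slope) with Wald 95% CI and two-sided Wald p; BH adjustment
    across the screened set with tiers significant (q < 0.1) and
    near-significant (q < 0.25).  Perfectly separated features are flagged,
    given infinite-CI sentinels, and excluded from the BH family.
    """
    y_all = response
    rows: list[AssociationResult] = []
    for col in features.columns:
        x = features[col]
        mask = x.notna() & y_all.reindex(x.index).notna()
        x_val = x[mask].to_numpy(dtype=float)
        y_val = y_all.reindex(x.index)[mask].to_numpy(dtype=float)
        n = int(mask.sum())
        if n < 3 or len(np.unique(y_val)) < 2 or np.ptp(x_val) == 0:
            rows.append(
                AssociationResult(col, np.nan, np.nan, np.nan, np.nan, n=n, separated=True)
            )
            continue
        X = sm.add_constant(x_val)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y_val, X).fit(disp=False, maxiter=200)
            beta = fit.params[1]
            se = fit.bse[1]
            separated = not np.isfinite(se) or se > 50 or not fit.mle_retvals.get(
                "converged", True
            )
        except Exception:  # numerical failure == separation sentinel
            separated = True
        if separated:
            rows.append(
                AssociationResult(
                    col, np.nan, 0.0, np.inf, np.nan, n=n, separated=True
                )
            )
            continue
        ci = beta + np.array([-1.0, 1.0]) * 1.959963984540054 * se
        rows.append(
            AssociationResult(
                col,
                float(np.exp(beta)),
                float(np.exp(ci[0])),
                float(np.exp(ci[1])),
                float(fit.pvalues[1]),
                n=n,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")
    ok = ~out["separated"] & out["p"].notna()
    out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["tier"] = "ns"
    out.loc[ok & (out["q"] < fdr_near_significant), "tier"] = "near-significant"
    out.loc[ok & (out["q"] < fdr_significant), "tier"] = "significant"
    return out


# --- Gene-set statistics ------------------------------------------------------


def hypergeometric_ora(
    query: GeneSet,
    reference_sets: list[GeneSet],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided (upper-tail) hypergeometric over-representation of the query
    set's overlap with each reference set, with BH adjustment."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not set(query.members) <= universe:
        raise ValueError("query set must be contained in the universe")
    M = len(universe)
    q = len(set(query.members))
    rows = []
    for ref in reference_sets:
        ref_in = set(ref.members) & universe
        k = len(ref_in & set(query.members))
        p = float(hypergeom.sf(k - 1, M, len(ref_in), q))
        rows.append({"set": ref.name, "overlap": k, "set_size": len(ref_in), "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def compare_set_significance(
    de: pd.DataFrame,
    set_a: GeneSet,
    set_b: GeneSet,
    signed: bool = False,
) -> dict:
    """Two-sided Mann-Whitney U comparing per-gene significance scores
    (-log10 nominal p, optionally signed by fold-change direction) between
    two gene sets; overlapping genes are excluded from both."""
    genes_a = set(set_a.members) & set(de.index)
    genes_b = set(set_b.members) & set(de.index)
    overlap = genes_a & genes_b
    if overlap:
        logger.info("excluding %d overlapping genes from the comparison", len(overlap))
        genes_a -= overlap
        genes_b -= overlap
    if len(genes_a) < 3 or len(genes_b) < 3:
        raise ValueError("each set needs at least 3 non-overlapping genes with DE results")

    def score(genes):
        sub = de.loc[sorted(genes)]
        s = -np.log10(sub["p"].to_numpy())
        if signed:
            s = s * np.sign(sub["lfc"].to_numpy())
        return s

    a, b = score(genes_a), score(genes_b)
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": len(a),
        "n_b": len(b),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def bivariate_expression_model(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> dict:
    """OLS of y on 1 + x1 + x2 with the two univariate fits for comparison."""
    y, x1, x2 = (np.asarray(v, dtype=float) for v in (y, x1, x2))
    if y.size < 4:
        raise ValueError("need at least 4 samples")
    if abs(np.corrcoef(x1, x2)[0, 1]) >= 1.0 - 1e-12:
        raise ValueError("x1 and x2 are collinear")

    def fit(*xs):
        X = sm.add_constant(np.column_stack(xs))
        res = sm.OLS(y, X).fit()
        return res

    full = fit(x1, x2)
    return {
        "coefficients": dict(zip(["intercept", "x1", "x2"], full.params)),
        "r2_combined": float(full.rsquared),
        "r2_x1": float(fit(x1).rsquared),
        "r2_x2": float(fit(x2).rsquared),
    }


# --- Survival -----------------------------------------------------------------

BIN_KINDS = ("zscore", "cluster", "burden", "alteration")


def bin_feature(values: pd.Series, kind: str, cluster: str | None = None) -> pd.Series:
    """High/low binning for survival: z-scores cut at 0, burdens at the
    cohort median (ties to low), cluster features as membership-vs-rest,
    alterations as presence/absence."""
    if kind not in BIN_KINDS:
        raise ValueError(f"unknown binning kind {kind!r}")
    if kind == "zscore":
        high = values.astype(float) > 0
    elif kind == "burden":
        high = values.astype(float) > values.astype(float).median()
    elif kind == "cluster":
        if cluster is None:
            raise ValueError("cluster binning needs the target cluster label")
        high = values.astype(str) == cluster
    else:
        high = values.astype(float) > 0
    return pd.Series(np.where(high, "high", "low"), index=values.index, name=values.name)


def km_logrank(
    pfs_time: pd.Series, pfs_event: pd.Series, groups: pd.Series
) -> dict:
    """Two-group log-rank test with per-group Kaplan-Meier medians."""
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("log-rank comparison needs exactly two nonempty groups")
    masks = {lv: groups == lv for lv in levels}
    if pfs_event[groups.notna()].sum() == 0:
        raise ValueError("no events in either group")
    a, b = levels
    res = logrank_test(
        pfs_time[masks[a]],
        pfs_time[masks[b]],
        event_observed_A=pfs_event[masks[a]],
        event_observed_B=pfs_event[masks[b]],
    )
    medians = {}
    for lv in levels:
        km = KaplanMeierFitter().fit(pfs_time[masks[lv]], pfs_event[masks[lv]])
        medians[lv] = float(km.median_survival_time_)
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "median_high": medians.get("high", np.nan),
        "median_low": medians.get("low", np.nan),
        "medians": medians,
        "n": {lv: int(masks[lv].sum()) for lv in levels},
    }


def survival_screen(
    clinical: pd.DataFrame,
    binned_features: pd.DataFrame,
) -> pd.DataFrame:
    """Log-rank screen over pre-binned features with BH across the screen."""
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    rows = []
    for col in binned_features.columns:
        groups = binned_features[col].reindex(clin.index)
        res = km_logrank(clin["pfs_time"], clin["pfs_event"], groups)
        rows.append(
            {
                "feature": col,
                "statistic": res["statistic"],
                "p": res["p"],
                "median_high": res["median_high"],
                "median_low": res["median_low"],
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# --- Integrative clustering ---------------------------------------------------


def cross_correlation_cluster(
    features: pd.DataFrame, n_blocks: int
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Spearman cross-correlation of features with average-linkage
    hierarchical blocks; returns the (ordered) correlation matrix, block
    assignments, and the dendrogram leaf order."""
    usable = []
    for col in features.columns:
        v = features[col].astype(float)
        if v.dropna().nunique() <= 1:
            logger.warning("dropping constant feature %s from correlation clustering", col)
            continue
        usable.append(col)
    if len(usable) < n_blocks:
        raise ValueError("fewer usable features than requested blocks")
    sub = features[usable].astype(float)
    if (sub.notna().sum(axis=0) < 3).any():
        raise ValueError("need >= 3 pairwise-complete observations per feature")
    corr = np.atleast_2d(spearmanr(sub.to_numpy(), nan_policy="omit").statistic)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    blocks = sch.fcluster(Z, t=n_blocks, criterion="maxclust")
    leaves = sch.leaves_list(Z)
    order = [usable[i] for i in leaves]
    corr_df = pd.DataFrame(corr, index=usable, columns=usable).loc[order, order]
    assignments = pd.Series(blocks, index=usable, name="block")
    return corr_df, assignments, order
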