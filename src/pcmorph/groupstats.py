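"""Nonparametric group comparisons and distribution summaries for feature tables.

The comparison recipe for shape features is the Kruskal–Wallis omnibus test
followed by Dunn's post-hoc test with Benjamini–Hochberg adjustment of the
pairwise p-values; convex/concave flank intensities are compared with a
Welch t-test.  Summaries report median, mean, sample SD and a normal-
approximation 95% confidence interval of the mean — the quantities violin
plots of such data conventionally show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "PairwiseResult",
    "FeatureSummary",
    "kruskal_wallis",
    "dunn_posthoc",
    "bh_adjust",
    "welch_t_test",
    "summarize_feature",
    "area_distribution",
    "compare_feature_table",
    "comparisons_table",
    "summaries_table",
]


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    raw_p: float
    adjusted_p: float = np.nan


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    h_statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    adjustment: str = "benjamini-hochberg"


@dataclass(frozen=True)
class FeatureSummary:
    group: str
    n: int
    median: float
    mean: float
    sd: float  # NaN when n == 1
    ci95_low: float
    ci95_high: float


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p with k−1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    groups: list[np.ndarray], names: list[str] | None = None
) -> list[PairwiseResult]:
    """Dunn's post-hoc z tests on pooled ranks, with tie correction.

    For each unordered pair (i, j):
    ``z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) · (1/n_i + 1/n_j))`` where
    ``T = Σ(t³−t) / (12(N−1))`` sums over tie groups; two-sided normal p.
    Returned ``adjusted_p`` is NaN — adjustment is applied by the caller.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group in Dunn's test")
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0, *sizes])
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:  # all observations tied
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
            results.append(
                PairwiseResult(names[i], names[j], float(z), min(float(p), 1.0))
            )
    return results


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def summarize_feature(values: np.ndarray, group: str = "") -> FeatureSummary:
    """Median, mean, sample SD and normal 95% CI of the mean (mean ± 1.96·SD/√n)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one observation")
    mean = float(v.mean())
    if len(v) == 1:
        return FeatureSummary(group, 1, float(v[0]), mean, np.nan, np.nan, np.nan)
    sd = float(v.std(ddof=1))
    half = 1.96 * sd / np.sqrt(len(v))
    return FeatureSummary(
        group, len(v), float(np.median(v)), mean, sd, mean - half, mean + half
    )


def area_distribution(
    areas: np.ndarray, bin_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Relative frequency of cell areas per bin; frequencies sum to 1 exactly."""
    areas = np.asarray(areas, dtype=float)
    if len(areas) == 0:
        raise ValueError("no areas given")
    counts, edges = np.histogram(areas, bins=bin_edges)
    return counts / counts.sum(), edges


def compare_feature_table(
    df: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "genotype",
    adjust_scope: str = "per_feature",
) -> list[GroupComparison]:
    """KW + Dunn + BH for every feature column of a long feature table.

    ``adjust_scope``: 'per_feature' applies BH across the pairwise
    comparisons of each feature separately (the default); 'global' pools all
    features' pairwise p-values into one BH family.
    """
    if adjust_scope not in ("per_feature", "global"):
        raise ValueError("adjust_scope must be 'per_feature' or 'global'")
    if df[group_col].isna().any():
        raise ValueError("missing group labels")
    names = sorted(df[group_col].unique().tolist())
    comparisons = []
    all_raw: list[float] = []
    for feat in feature_cols:
        vals = df[feat].astype(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in feature {feat!r}")
        groups = [vals[df[group_col] == g].to_numpy() for g in names]
        h, p = kruskal_wallis(groups)
        pw = dunn_posthoc(groups, names)
        comparisons.append(GroupComparison(feat, h, p, pw))
        all_raw.extend(r.raw_p for r in pw)
    if adjust_scope == "per_feature":
        adjusted = [bh_adjust([r.raw_p for r in c.pairwise]) for c in comparisons]
    else:
        flat = bh_adjust(all_raw)
        adjusted, k = [], 0
        for c in comparisons:
            adjusted.append(flat[k : k + len(c.pairwise)])
            k += len(c.pairwise)
    out = []
    for c, adj in zip(comparisons, adjusted):
        pw = [
            PairwiseResult(r.group_a, r.group_b, r.z, r.raw_p, float(q))
            for r, q in zip(c.pairwise, adj)
        ]
        out.append(GroupComparison(c.feature, c.h_statistic, c.p_value, pw))
    return out


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons to one row per feature × group pair."""
    rows = []
    for c in comparisons:
        for r in c.pairwise:
            rows.append(
                {
                    "feature": c.feature,
                    "kw_h": c.h_statistic,
                    "kw_p": c.p_value,
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "dunn_z": r.z,
                    "raw_p": r.raw_p,
                    "adjusted_p": r.adjusted_p,
                    "adjustment": c.adjustment,
                }
            )
    cols = [
        "feature", "kw_h", "kw_p", "group_a", "group_b",
        "dunn_z", "raw_p", "adjusted_p", "adjustment",
    ]
    return pd.DataFrame(rows, columns=cols)


def summaries_table(
    df: pd.DataFrame, feature_cols: list[str], group_col: str = "genotype"
) -> pd.DataFrame:
    """Per feature × group summary statistics (violin-plot companion data)."""
    rows = []
    for feat in feature_cols:
        for g in sorted(df[group_col].unique().tolist()):
            s = summarize_feature(df.loc[df[group_col] == g, feat].to_numpy(), str(g))
            rows.append(
                {
                    "feature": feat,
                    "group": s.group,
                    "n": s.n,
                    "median": s.median,
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci95_low": s.ci95_low,
                    "ci95_high": s.ci95_high,
                }
            )
    cols = ["feature", "group", "n", "median", "mean", "sd", "ci95_low", "ci95_high"]
    return pd.DataFrame(rows, columns=cols)
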