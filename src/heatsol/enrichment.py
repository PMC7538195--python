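"""Shared categorical statistics: hypergeometric term enrichment,
per-category Fisher tests, and the Shapiro-Wilk-gated group comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import bh_adjust
from .disaggregation import assess_normality

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, then member ids."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms[fields[0]] = {g for g in fields[2:] if g}
    return terms


def hypergeom_enrichment(foreground: Iterable[str],
                         background: Iterable[str],
                         term_map: Mapping[str, set[str]],
                         alpha: float = 0.05,
                         include_empty: bool = False) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a foreground set.

    For each term: N = |background|, K = |term intersect background|,
    n = |foreground|, k = |term intersect foreground|; p = P(X >= k).
    Terms with k = 0 are excluded from testing (and from the BH family)
    unless ``include_empty``.  Foreground must be a subset of background.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    N, n = len(bg), len(fg)
    rows = []
    for term, members in term_map.items():
        members = members & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        if k == 0 and not include_empty:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N) if n and K else np.nan
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k,
                     "p_raw": p, "enrichment_ratio": ratio})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.set_index("term")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values("p_raw")


def category_fisher(calls: pd.DataFrame,
                    categories: pd.Series) -> pd.DataFrame:
    """Per-category Fisher exact test of aggregator occurrence.

    Builds, per category, the 2x2 table (aggregator, soluble) x (in
    category, not in category).  Multi-label inputs are allowed (a protein
    may carry several categories), so category fractions can sum above 1.
    Returns odds ratios (inf reported as inf), two-sided p, BH-adjusted p,
    and the per-class fraction difference used for display.
    """
    is_agg = calls["class"] == "aggregator"
    n_agg, n_sol = int(is_agg.sum()), int((~is_agg).sum())
    shared = calls.index.intersection(categories.index)
    cats = categories.loc[shared]
    if cats.nunique() < 2:
        raise ValueError("need >= 2 categories")
    rows = []
    for cat in sorted(cats.unique()):
        members = set(cats.index[cats == cat])
        if not members:
            logger.info("category %s empty, skipped", cat)
            continue
        a = int(sum(1 for p in members if is_agg.get(p, False)))
        c = len(members) - a
        table = np.array([[a, n_agg - a], [c, n_sol - c]])
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        frac_agg = a / n_agg if n_agg else np.nan
        frac_sol = c / n_sol if n_sol else np.nan
        rows.append({"category": cat, "n_aggregator": a, "n_soluble": c,
                     "odds_ratio": float(odds), "p_raw": float(p),
                     "frac_aggregator": frac_agg, "frac_soluble": frac_sol,
                     "frac_difference": frac_agg - frac_sol})
    out = pd.DataFrame(rows).set_index("category")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


@dataclass
class GroupComparison:
    """Two-group test with box/violin-ready summary statistics."""

    test: str                     # "t" or "wilcoxon"
    p_value: float
    summary: pd.DataFrame         # per group: n, median, q1, q3, whiskers


def _box_summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 interpolation
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return {"n": x.size, "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo, "whisker_high": hi}


def group_compare(values: pd.Series, labels: pd.Series) -> GroupComparison:
    """Compare two groups with the normality-gated test choice.

    Both groups normal by Shapiro-Wilk (p >= 0.05) -> two-sample t-test;
    otherwise Wilcoxon rank-sum.  Groups need >= 3 values each.
    """
    groups = {}
    for g in labels.unique():
        x = values[labels == g].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"group {g!r} has < 3 values")
        groups[g] = x
    if len(groups) != 2:
        raise ValueError("group_compare expects exactly 2 groups")
    (ga, xa), (gb, xb) = groups.items()
    normal = (assess_normality(xa[: min(len(xa), 5000)])
              and assess_normality(xb[: min(len(xb), 5000)]))
    if normal:
        test = "t"
        p = float(stats.ttest_ind(xa, xb).pvalue)
    else:
        test = "wilcoxon"
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(
                xa, xb, alternative="two-sided").pvalue)
    summary = pd.DataFrame({ga: _box_summary(xa), gb: _box_summary(xb)}).T
    return GroupComparison(test=test, p_value=p, summary=summary)
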