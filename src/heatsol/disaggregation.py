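"""Disaggregation kinetics: per-protein recovery slopes and their
correlation with aggregation-associated sequence/structure features.

The disaggregation rate of a protein is the slope of an ordinary
least-squares line through its mean solubility (log2 heat/mock) over the
recovery time course, including the post-shock anchor at t = 0.  Feature
correlations use Pearson when both vectors pass a Shapiro-Wilk normality
gate (p >= 0.05) and Spearman otherwise, with BH adjustment across the
tested feature set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import bh_adjust
from .preprocess import SolubilityProfiles

logger = logging.getLogger(__name__)


def fit_slopes(profiles: SolubilityProfiles) -> pd.DataFrame:
    """OLS slope and intercept of mean solubility vs recovery time.

    Proteins with fewer than 3 quantified time points get no fit (NaN,
    count logged).  Columns: slope (solubility-units/h), intercept,
    n_points.
    """
    mean_s = profiles.mean_s
    t = np.asarray(mean_s.columns, dtype=float)
    y = mean_s.to_numpy()
    n_points = np.isfinite(y).sum(axis=1)

    slope = np.full(len(mean_s), np.nan)
    intercept = np.full(len(mean_s), np.nan)
    complete = np.isfinite(y).all(axis=1)
    if complete.any():
        # vectorised closed form for the (common) complete-profile case
        tbar = t.mean()
        sxx = ((t - tbar) ** 2).sum()
        yc = y[complete]
        ybar = yc.mean(axis=1)
        slope[complete] = ((t - tbar) * (yc - ybar[:, None])).sum(axis=1) / sxx
        intercept[complete] = ybar - slope[complete] * tbar
    for i in np.flatnonzero(~complete & (n_points >= 3)):
        m = np.isfinite(y[i])
        b, a = np.polyfit(t[m], y[i, m], 1)
        slope[i], intercept[i] = b, a
    n_unfit = int((n_points < 3).sum())
    if n_unfit:
        logger.info("slope fitting: %d proteins with < 3 time points "
                    "left unfitted", n_unfit)
    return pd.DataFrame({"slope": slope, "intercept": intercept,
                         "n_points": n_points}, index=mean_s.index)


def assess_normality(sample, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk gate: True when the sample looks normal (p >= alpha).

    Degenerate (constant) samples are not testable and are reported as
    non-normal.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return False
    return bool(stats.shapiro(x).pvalue >= alpha)


def correlate_features(slopes: pd.Series,
                       features: pd.DataFrame) -> pd.DataFrame:
    """Correlate disaggregation slopes with each feature column.

    Test choice per feature: Pearson if both the slope vector and the
    feature pass :func:`assess_normality`, Spearman otherwise.  Constant
    features are reported with NaN coefficients and excluded from the BH
    adjustment.  Output is volcano-ready: feature, method, coefficient,
    p_raw, p_adj, n.
    """
    rows = []
    for feat in features.columns:
        joined = pd.concat([slopes.rename("slope"), features[feat]],
                           axis=1, join="inner").dropna()
        n = len(joined)
        if n < 10:
            raise ValueError(f"feature {feat!r}: need >= 10 proteins, "
                             f"got {n}")
        x = joined["slope"].to_numpy()
        f = joined[feat].to_numpy()
        if np.ptp(f) == 0 or np.ptp(x) == 0:
            logger.info("feature %s: constant vector, correlation "
                        "undefined", feat)
            rows.append({"feature": feat, "method": "none",
                         "coefficient": np.nan, "p_raw": np.nan, "n": n})
            continue
        n_test = min(n, 5000)
        if assess_normality(x[:n_test]) and assess_normality(f[:n_test]):
            r, p = stats.pearsonr(x, f)
            method = "pearson"
        else:
            r, p = stats.spearmanr(x, f)
            method = "spearman"
        rows.append({"feature": feat, "method": method,
                     "coefficient": float(r), "p_raw": float(p), "n": n})
    out = pd.DataFrame(rows).set_index("feature")
    tested = out["p_raw"].notna()
    out["p_adj"] = np.nan
    out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_raw"].to_numpy())
    return out


def tag_deciles(slopes: pd.Series) -> pd.Series:
    """Tag aggregators as bottom10 / middle80 / top10 by slope rank.

    The slowest ``ceil(0.1 n)`` are bottom10, the fastest ``ceil(0.1 n)``
    top10; ties break by protein identifier (stable).
    """
    s = slopes.dropna()
    n = len(s)
    if n < 10:
        raise ValueError("need >= 10 aggregators for decile tagging")
    k = int(np.ceil(0.1 * n))
    order = s.reset_index()
    order.columns = ["protein_id", "slope"]
    order = order.sort_values(["slope", "protein_id"],
                              kind="stable").set_index("protein_id")
    tags = pd.Series("middle80", index=order.index)
    tags.iloc[:k] = "bottom10"
    tags.iloc[-k:] = "top10"
    out = pd.Series("none", index=slopes.index)
    out.loc[tags.index] = tags
    return out
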