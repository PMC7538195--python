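"""Aggregator calling by empirical-Bayes moderated testing.

A protein is called an aggregator when its solubility -- the log2
heat/mock ratio of soluble-fraction intensity directly after heat shock --
is significantly reduced: BH-adjusted p < 0.05 in a moderated one-sample
t-test on replicate-paired heat-minus-mock differences AND mean solubility
below log2(2/3).  Both cut-offs are strict.

The moderation follows the standard empirical-Bayes treatment of gene-wise
variances: a scaled inverse-chi-square prior with ``d0`` degrees of freedom
and scale ``s0_sq`` is fitted to the observed variances by the method of
moments on the log scale (digamma/trigamma matching), and each protein's
variance is shrunk toward the prior before computing the t-statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import SolubilityProfiles

logger = logging.getLogger(__name__)

FC_CUT = float(np.log2(2.0 / 3.0))


@dataclass(frozen=True)
class ModerationParams:
    """Prior of the variance model: s_g^2 ~ s0_sq * inv-chi-square(d0)."""

    d0: float          # prior degrees of freedom; inf = complete shrinkage
    s0_sq: float       # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log scale)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # good starting point: trigamma(x) ~ 1/x for large x
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(sample_variances: np.ndarray,
                        df: int) -> ModerationParams:
    """Method-of-moments fit of the variance prior on the log scale.

    With z_g = log(s_g^2): under the model, Var(z) = trigamma(df/2) +
    trigamma(d0/2) and E(z) = log(s0_sq) + [digamma(df/2) - log(df/2)] -
    [digamma(d0/2) - log(d0/2)].  If the empirical variance of z does not
    exceed trigamma(df/2), the prior is degenerate: d0 = inf and all
    proteins share s0_sq.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError("need >= 10 positive finite variances")
    if df < 1:
        raise ValueError("residual df must be >= 1")
    z = np.log(s2)
    zbar = z.mean()
    zvar = z.var(ddof=1)
    bias_d = special.digamma(df / 2.0) - np.log(df / 2.0)
    excess = zvar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # degenerate prior: all true variances equal; the raw-scale mean is
        # unbiased for s0_sq (the log-scale mean would carry a chi-square
        # bias of exp(digamma(d/2) - log(d/2)))
        return ModerationParams(d0=np.inf, s0_sq=float(s2.mean()))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    bias_d0 = special.digamma(half_d0) - np.log(half_d0)
    s0_sq = float(np.exp(zbar - bias_d + bias_d0))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(values: np.ndarray,
                params: ModerationParams) -> tuple[float, float]:
    """Moderated one-sample t-test of the replicate values against 0.

    The posterior variance is ``(d0 s0_sq + d s_g^2) / (d0 + d)`` with
    d = n - 1; the statistic is referred to a t distribution with
    ``d0 + d`` degrees of freedom (normal when d0 is infinite).  With
    d0 = 0 this is the ordinary one-sample t-test.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 replicates")
    d = n - 1
    s_g2 = x.var(ddof=1)
    if np.isinf(params.d0):
        s_post2 = params.s0_sq
        t = x.mean() / np.sqrt(s_post2 / n)
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        d0 = params.d0
        s_post2 = (d0 * params.s0_sq + d * s_g2) / (d0 + d)
        if s_post2 == 0:
            return (0.0, 1.0) if x.mean() == 0 else (np.inf, 0.0)
        t = x.mean() / np.sqrt(s_post2 / n)
        p = 2.0 * stats.t.sf(abs(t), d0 + d)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_aggregators(profiles: SolubilityProfiles, alpha: float = 0.05,
                     fc_cut: float = FC_CUT,
                     d0_override: float | None = None) -> pd.DataFrame:
    """Classify proteins as aggregator vs soluble from t = 0 solubility.

    Fits the variance prior across all proteins with complete replicates at
    the heat-shock time point, computes moderated t-statistics and BH-
    adjusted p-values, and applies the conjunction rule (adjusted p below
    ``alpha`` AND mean solubility below ``fc_cut``; both strict).

    ``d0_override`` replaces the fitted prior df (0 recovers the ordinary
    t-test) -- used for oracle comparisons.
    """
    s0 = profiles.at_time(0.0)
    n_reps = s0.notna().sum(axis=1)
    usable = n_reps >= 2
    skipped = (~usable).sum()
    if skipped:
        logger.info("aggregator calling: %d proteins with < 2 replicates "
                    "skipped", skipped)
    data = s0[usable]
    df = int(data.notna().sum(axis=1).mode()[0]) - 1
    variances = data.var(axis=1, ddof=1).to_numpy()
    params = estimate_moderation(variances, df)
    if d0_override is not None:
        if d0_override == 0:
            params = None  # ordinary t
        else:
            params = ModerationParams(d0=d0_override, s0_sq=params.s0_sq)

    # vectorised moderated t over all proteins
    arr = data.to_numpy(dtype=float)
    n = np.isfinite(arr).sum(axis=1)
    mean = np.nanmean(arr, axis=1)
    s_g2 = np.nanvar(arr, axis=1, ddof=1)
    d = n - 1
    if params is None:
        s_post2 = s_g2
        df_tot = d.astype(float)
    elif np.isinf(params.d0):
        s_post2 = np.full_like(s_g2, params.s0_sq)
        df_tot = np.full(len(data), np.inf)
    else:
        s_post2 = (params.d0 * params.s0_sq + d * s_g2) / (params.d0 + d)
        df_tot = params.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = mean / np.sqrt(s_post2 / n)
    finite_df = np.isfinite(df_tot)
    p_raw = np.where(
        finite_df,
        2.0 * stats.t.sf(np.abs(t_mod), np.where(finite_df, df_tot, 1.0)),
        2.0 * stats.norm.sf(np.abs(t_mod)))
    degenerate = np.isnan(t_mod)  # 0/0: zero mean with zero variance
    t_mod[degenerate] = 0.0
    p_raw[degenerate] = 1.0
    p_adj = bh_adjust(p_raw)
    mean_s = data.mean(axis=1)
    is_agg = (p_adj < alpha) & (mean_s.to_numpy() < fc_cut)
    calls = pd.DataFrame({
        "solubility_hs": mean_s,
        "t_mod": t_mod,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "class": np.where(is_agg, "aggregator", "soluble"),
    }, index=data.index)
    logger.info("called %d aggregators / %d soluble",
                int(is_agg.sum()), int((~is_agg).sum()))
    return calls


def flag_insoluble_subpop(total_solubility: pd.DataFrame,
                          cut: float = -0.6,
                          condition: str = "preshock") -> pd.Series:
    """Flag proteins with a pre-stress insoluble sub-population.

    True iff the pre-shock NP-40/SDS log2 ratio is strictly below ``cut``.
    Proteins without a pre-shock value get NA (count logged).
    """
    if condition not in total_solubility.columns:
        raise ValueError(f"no {condition!r} column in total solubility")
    ts = total_solubility[condition]
    n_missing = int(ts.isna().sum())
    if n_missing:
        logger.info("insoluble-subpopulation flag: %d proteins without "
                    "pre-shock total solubility", n_missing)
    flags = ts < cut
    return flags.mask(ts.isna())
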