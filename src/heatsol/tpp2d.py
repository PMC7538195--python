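"""Two-dimensional thermal-proteome-profiling stability score.

After heat or mock shock, aliquots are exposed to a 12-point temperature
gradient and the soluble remnants are quantified.  The per-protein analysis:

1.  Normalize each temperature's channels separately (variance
    stabilisation) and express every curve as log2 fold change against the
    37.0 degC sample of the same condition and replicate.
2.  Score a (heat, mock) curve pair by summing the per-temperature
    differences, after subtracting the mean difference at the two
    sub-shock temperatures (37.0, 37.8 degC) -- a baseline that absorbs
    aggregation that already happened during the shock itself.
3.  Bootstrap over replicates: in each of 500 rounds, one heat and one mock
    replicate are drawn independently per temperature, composite curves are
    assembled and scored.
4.  Within each round, scores are z-standardised across proteins; each
    protein's mean standardised score is tested against zero (one-sample
    t over the rounds) giving a BH-adjusted "local FDR"; the across-protein
    z-transform of the means is the final score, on which an empirical
    Gaussian null yields tail-area q-values ("global FDR").
5.  A protein is a hit when both FDRs are below 0.01 and it was quantified
    at 6 or more temperatures; the sign of the final score separates
    stabilized from destabilized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import bh_adjust
from .io import IntensityTable
from .preprocess import normalize_vs

logger = logging.getLogger(__name__)

BASELINE_TEMPS = 2          # number of sub-shock gradient temperatures
MIN_TEMPS_FOR_HIT = 6
REF_TEMP = 37.0


def normalize_tpp(table: IntensityTable) -> IntensityTable:
    """Variance-stabilise each temperature's channels separately."""
    meta = table.channel_meta.loc[table.values.columns]
    pieces = []
    for T in sorted(meta["temperature_C"].dropna().unique()):
        sub = table.select_channels(temperature_C=T)
        norm, _ = normalize_vs(sub)
        pieces.append(norm.values)
    values = pd.concat(pieces, axis=1)[table.values.columns]
    return replace(table, values=values, scale="log2")


@dataclass
class TPPCurves:
    """Per-condition, per-replicate log2 fold-change curves vs 37.0 degC."""

    proteins: pd.Index
    temperatures: np.ndarray            # the gradient, ascending
    heat: np.ndarray                    # (n_proteins, n_heat_reps, n_temps)
    mock: np.ndarray                    # (n_proteins, n_mock_reps, n_temps)
    n_temps_quantified: np.ndarray      # per protein

    @property
    def n_heat_reps(self) -> int:
        return self.heat.shape[1]

    @property
    def n_mock_reps(self) -> int:
        return self.mock.shape[1]


def fold_changes(table: IntensityTable) -> TPPCurves:
    """log2 fold change of each channel against the matched 37.0 degC one.

    The reference channel (37.0 degC) must be present for every
    (condition, replicate); fold changes at the reference are 0 by
    construction.  A protein counts as quantified at temperature T when it
    has a finite fold change in at least one replicate of each condition.
    """
    if table.scale == "raw":
        raise ValueError("fold_changes expects a log2 table")
    meta = table.channel_meta.loc[table.values.columns]
    temps = np.sort(meta["temperature_C"].dropna().unique())
    if REF_TEMP not in temps:
        raise ValueError(f"no {REF_TEMP} degC reference channel")
    stacks = {}
    for cond in ("heat", "mock"):
        sel = meta[meta["condition"] == cond]
        reps = sorted(sel["replicate"].unique())
        arr = np.full((len(table.proteins), len(reps), len(temps)), np.nan)
        for j, rep in enumerate(reps):
            sub = sel[sel["replicate"] == rep]
            by_temp = {row["temperature_C"]: cid
                       for cid, row in sub.iterrows()}
            if REF_TEMP not in by_temp:
                raise ValueError(
                    f"missing {REF_TEMP} degC channel for {cond} rep {rep}")
            ref = table.values[by_temp[REF_TEMP]].to_numpy()
            for k, T in enumerate(temps):
                if T in by_temp:
                    arr[:, j, k] = table.values[by_temp[T]].to_numpy() - ref
        stacks[cond] = arr
    heat, mock = stacks["heat"], stacks["mock"]
    quant = (np.isfinite(heat).any(axis=1)
             & np.isfinite(mock).any(axis=1)).sum(axis=1)
    return TPPCurves(proteins=table.proteins, temperatures=temps,
                     heat=heat, mock=mock, n_temps_quantified=quant)


def stability_score(heat_fc: np.ndarray, mock_fc: np.ndarray) -> float:
    """Baseline-corrected summed difference between one curve pair.

    ``d_T = heat_fc(T) - mock_fc(T)``; the baseline is the mean of d at the
    first two gradient temperatures; the score sums ``d_T - baseline`` over
    all quantified temperatures.  Invariant to adding a constant to every
    d_T.  NaN when the baseline temperatures are not quantified.
    """
    d = np.asarray(heat_fc, dtype=float) - np.asarray(mock_fc, dtype=float)
    base = d[:BASELINE_TEMPS]
    if not np.isfinite(base).any():
        return float("nan")
    b = np.nanmean(base)
    resid = d - b
    return float(np.nansum(resid[np.isfinite(resid)]))


def bootstrap_scores(curves: TPPCurves, n_rounds: int = 500, *,
                     seed: int) -> np.ndarray:
    """Replicate-resampled stability scores, (n_proteins, n_rounds).

    Per round and per temperature, one heat and one mock replicate are
    drawn uniformly and independently for every protein; the composite
    curves are scored with :func:`stability_score`'s arithmetic
    (vectorised).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_prot, n_heat, n_temps = curves.heat.shape
    n_mock = curves.mock.shape[1]
    if n_heat < 1 or n_mock < 1:
        raise ValueError("need >= 1 replicate per condition")
    scores = np.empty((n_prot, n_rounds))
    for r in range(n_rounds):
        hidx = rng.integers(0, n_heat, size=(n_prot, 1, n_temps))
        midx = rng.integers(0, n_mock, size=(n_prot, 1, n_temps))
        h = np.take_along_axis(curves.heat, hidx, axis=1)[:, 0, :]
        m = np.take_along_axis(curves.mock, midx, axis=1)[:, 0, :]
        d = h - m
        base = d[:, :BASELINE_TEMPS]
        n_base = np.isfinite(base).sum(axis=1)
        with np.errstate(invalid="ignore"):
            b = np.where(n_base > 0,
                         np.nansum(np.nan_to_num(base), axis=1)
                         / np.maximum(n_base, 1), np.nan)
        resid = d - b[:, None]
        s = np.nansum(np.where(np.isfinite(resid), resid, 0.0), axis=1)
        s[~np.isfinite(b)] = np.nan
        scores[:, r] = s
    return scores


def zscore_and_test(boot_scores: np.ndarray,
                    proteins: pd.Index) -> pd.DataFrame:
    """Round-wise z-standardisation, per-protein test and final score.

    Within each bootstrap round, raw scores are standardised across
    proteins (rounds whose across-protein SD is zero are dropped).  Per
    protein: ``mean_z`` is the mean of its standardised scores, ``p_raw``
    a two-sided one-sample t-test of those values against zero,
    ``p_adj_local`` the BH adjustment across proteins, and
    ``final_score`` the across-protein z-transform of ``mean_z``.
    """
    B = np.asarray(boot_scores, dtype=float)
    n_prot, n_rounds = B.shape
    if n_prot < 10:
        raise ValueError("need >= 10 proteins for across-protein z-scores")
    mu = np.nanmean(B, axis=0)
    sd = np.nanstd(B, axis=0, ddof=1)
    ok_rounds = np.isfinite(sd) & (sd > 0)
    n_dropped = int((~ok_rounds).sum())
    if n_dropped:
        logger.info("z-scoring: %d rounds with zero across-protein SD "
                    "dropped", n_dropped)
    if not ok_rounds.any():
        raise ValueError("no usable bootstrap rounds")
    Z = (B[:, ok_rounds] - mu[ok_rounds]) / sd[ok_rounds]
    fin = np.isfinite(Z)
    n_eff = fin.sum(axis=1)
    Z0 = np.where(fin, Z, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_z = np.where(n_eff > 0,
                          Z0.sum(axis=1) / np.maximum(n_eff, 1), np.nan)
        ss = (np.where(fin, Z - mean_z[:, None], 0.0) ** 2).sum(axis=1)
        sd_z = np.sqrt(ss / np.maximum(n_eff - 1, 1))
        t = mean_z / (sd_z / np.sqrt(n_eff))
    p_raw = 2.0 * stats.t.sf(np.abs(t), np.maximum(n_eff - 1, 1))
    degenerate = np.isnan(t) & (n_eff > 0)
    p_raw[degenerate] = np.where(mean_z[degenerate] == 0, 1.0, 0.0)
    valid = np.isfinite(mean_z) & (n_eff >= 2)
    p_raw[~valid] = np.nan
    p_adj = np.full(n_prot, np.nan)
    p_adj[valid] = bh_adjust(p_raw[valid])
    final = np.full(n_prot, np.nan)
    final[valid] = ((mean_z[valid] - mean_z[valid].mean())
                    / mean_z[valid].std(ddof=1))
    return pd.DataFrame({
        "mean_z": mean_z, "p_raw": p_raw, "p_adj_local": p_adj,
        "final_score": final, "n_rounds_used": n_eff,
    }, index=proteins)


def global_fdr(final_scores: np.ndarray) -> tuple[np.ndarray, dict]:
    """Empirical-null tail-area q-values on the final scores.

    The null is Normal(0, sigma0) with sigma0 = MAD / 0.6745; the null
    proportion pi0 is the fraction of scores within one null SD divided by
    the standard-normal central mass, clipped to [0, 1].  Returns q-values
    (input order) and the fitted null parameters.
    """
    x = np.asarray(final_scores, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < 50:
        raise ValueError("need >= 50 proteins for the empirical null")
    mad = np.median(np.abs(obs - np.median(obs)))
    sigma0 = mad / 0.6745
    if sigma0 <= 0:
        raise ValueError("degenerate final-score distribution")
    p = 2.0 * stats.norm.sf(np.abs(x) / sigma0)
    central = float(np.mean(np.abs(obs) <= sigma0))
    pi0 = float(np.clip(central / 0.6826894921370859, 0.0, 1.0))
    q = np.full_like(x, np.nan)
    valid = np.isfinite(p)
    q[valid] = np.clip(pi0 * bh_adjust(p[valid]), 0.0, 1.0)
    return q, {"sigma0": float(sigma0), "pi0": pi0}


def call_hits(results: pd.DataFrame, fdr_cut: float = 0.01,
              min_temps: int = MIN_TEMPS_FOR_HIT) -> pd.Series:
    """Dual-FDR hit calling: stabilized / destabilized / none.

    Hit iff local (BH) and global (empirical-null) FDR are both below
    ``fdr_cut`` and the protein was quantified at >= ``min_temps``
    temperatures; the sign of the final score gives the direction.
    """
    needed = {"p_adj_local", "global_fdr", "final_score",
              "n_temps_quantified"}
    missing = needed - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    is_hit = ((results["p_adj_local"] < fdr_cut)
              & (results["global_fdr"] < fdr_cut)
              & (results["n_temps_quantified"] >= min_temps))
    direction = np.where(results["final_score"] > 0,
                         "stabilized", "destabilized")
    return pd.Series(np.where(is_hit, direction, "none"),
                     index=results.index, name="hit")


def tpp2d_pipeline(raw_table: IntensityTable, n_rounds: int = 500, *,
                   seed: int, normalize: bool = True) -> pd.DataFrame:
    """Full stability-score pipeline on a raw melting-gradient table."""
    table = normalize_tpp(raw_table) if normalize else raw_table
    curves = fold_changes(table)
    boot = bootstrap_scores(curves, n_rounds, seed=seed)
    res = zscore_and_test(boot, curves.proteins)
    res["n_temps_quantified"] = curves.n_temps_quantified
    q, null_fit = global_fdr(res["final_score"].to_numpy())
    res["global_fdr"] = q
    res["hit"] = call_hits(res)
    res.attrs["null_fit"] = null_fit
    return res
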