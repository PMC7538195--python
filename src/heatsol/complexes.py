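"""Protein-complex membership enrichment and aggregation coherence.

Tests whether aggregators are over-represented among complex members
(Fisher exact test on the 2x2 membership table) and whether members of the
same complex aggregate and disaggregate coherently.  Coherence of a complex
is the mean over all unordered pairs of its aggregator members of the
Euclidean distance between their solubility vectors; the null reference is
a set of scrambled complexes built by re-assigning pooled aggregators to
complexes while maintaining the empirical frequency distribution of
per-complex aggregator counts.  Real and scrambled coherence values are
compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


def membership_enrichment(calls: pd.DataFrame,
                          complex_db: dict[str, set[str]]
                          ) -> tuple[float, float, np.ndarray]:
    """Fisher exact test of aggregator status vs complex membership.

    Returns (odds_ratio, two_sided_p, table) for the 2x2 table of
    (aggregator, soluble) x (member of >= 1 complex, not a member).
    """
    members = set().union(*complex_db.values()) if complex_db else set()
    is_agg = calls["class"] == "aggregator"
    in_cpx = calls.index.to_series().isin(members)
    table = np.array([
        [int((is_agg & in_cpx).sum()), int((is_agg & ~in_cpx).sum())],
        [int((~is_agg & in_cpx).sum()), int((~is_agg & ~in_cpx).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("Fisher test needs non-zero margins")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def coherence_distance(vectors: np.ndarray | pd.DataFrame) -> float:
    """Mean pairwise Euclidean distance between member solubility vectors.

    With one time point this reduces to the mean absolute difference.
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 members for a pairwise distance")
    return float(pdist(arr, metric="euclidean").mean())


def normalize_recovery(mean_s: pd.DataFrame,
                       mode: str = "divide") -> pd.DataFrame:
    """Normalize recovery trajectories to the initial loss of solubility.

    For each protein with strictly negative solubility at t = 0, the value
    at each recovery time point t > 0 becomes ``mean_s(t) / mean_s(0)``
    (1 = still fully aggregated, 0 = fully recovered).  ``mode="subtract"``
    uses ``mean_s(t) - mean_s(0)`` instead.  Proteins with non-negative
    t = 0 solubility are excluded (count logged).
    """
    if 0.0 not in mean_s.columns:
        raise ValueError("profiles must include the t = 0 anchor")
    s0 = mean_s[0.0]
    ok = s0 < 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("recovery normalization: %d proteins with "
                    "non-negative t=0 solubility excluded", n_excluded)
    rec_cols = [t for t in mean_s.columns if t > 0]
    sub = mean_s.loc[ok, rec_cols]
    if mode == "divide":
        return sub.div(s0[ok], axis=0)
    if mode == "subtract":
        return sub.sub(s0[ok], axis=0)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CoherenceResult:
    """Coherence of one real complex."""

    complex_id: str
    n_members: int
    n_quantified: int
    n_aggregators: int
    eligible: bool
    mean_pairwise_distance: float  # NaN when not eligible


@dataclass
class CoherenceAnalysis:
    """Real vs scrambled coherence comparison."""

    results: list[CoherenceResult]
    real_distances: np.ndarray      # per eligible complex
    null_distances: np.ndarray      # per scrambled complex
    slot_counts: np.ndarray         # aggregator counts of eligible complexes
    wilcoxon_p: float

    @property
    def eligible_ids(self) -> list[str]:
        return [r.complex_id for r in self.results if r.eligible]


def _eligibility(complex_db, quantified, aggregator_vectors,
                 min_quantified_frac=0.75, min_aggregators=2):
    results = []
    for cid, members in complex_db.items():
        members = set(members)
        n_q = len(members & quantified)
        agg_members = [m for m in members if m in aggregator_vectors.index]
        eligible = (n_q >= min_quantified_frac * len(members)
                    and len(agg_members) >= min_aggregators)
        dist = np.nan
        if eligible:
            dist = coherence_distance(aggregator_vectors.loc[agg_members])
        results.append(CoherenceResult(
            complex_id=cid, n_members=len(members), n_quantified=n_q,
            n_aggregators=len(agg_members), eligible=eligible,
            mean_pairwise_distance=dist))
    return results


def scramble_complexes(slot_counts: np.ndarray,
                       pooled_vectors: pd.DataFrame, n_perm: int = 10000, *,
                       seed: int) -> np.ndarray:
    """Null coherence distances from scrambled complexes.

    Each scrambled complex draws its aggregator-slot count from the
    empirical distribution of real per-complex counts and fills the slots
    by sampling aggregators without replacement from the pooled set;
    the coherence distance is computed exactly as for real complexes.
    Deterministic under ``seed``.
    """
    slot_counts = np.asarray(slot_counts, dtype=int)
    if slot_counts.size < 2:
        raise ValueError("need >= 2 eligible complexes to scramble")
    pool = pooled_vectors.to_numpy(dtype=float)
    if pool.ndim == 1:
        pool = pool[:, None]
    if pool.shape[0] < slot_counts.max():
        raise ValueError("pooled aggregator set smaller than the largest "
                         "slot count")
    rng = np.random.default_rng(seed)
    counts = rng.choice(slot_counts, size=n_perm, replace=True)
    null = np.empty(n_perm)
    n_pool = pool.shape[0]
    for i, c in enumerate(counts):
        idx = rng.choice(n_pool, size=c, replace=False)
        null[i] = pdist(pool[idx], metric="euclidean").mean()
    return null


def coherence_test(real: np.ndarray, null: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p for real vs scrambled coherence.

    Exact enumeration when both samples have n <= 10, the tie-corrected
    normal approximation otherwise.  All-tied input gives p = 1.
    """
    real = np.asarray(real, dtype=float)
    null = np.asarray(null, dtype=float)
    if real.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([real, null])
    if np.ptp(combined) == 0:
        return 1.0
    method = "exact" if (real.size <= 10 and null.size <= 10) else "asymptotic"
    res = stats.mannwhitneyu(real, null, alternative="two-sided",
                             method=method)
    return float(res.pvalue)


def analyze_coherence(complex_db: dict[str, set[str]],
                      quantified: set[str],
                      aggregator_vectors: pd.DataFrame,
                      n_perm: int = 10000, *, seed: int,
                      min_quantified_frac: float = 0.75,
                      min_aggregators: int = 2) -> CoherenceAnalysis:
    """Full real-vs-scrambled coherence analysis.

    ``aggregator_vectors`` holds one solubility vector per aggregator
    (rows = proteins, columns = time points); a complex is eligible when at
    least 75% of its members are quantified and at least two members are
    aggregators with solubility data.
    """
    results = _eligibility(complex_db, quantified, aggregator_vectors,
                           min_quantified_frac, min_aggregators)
    eligible = [r for r in results if r.eligible]
    if len(eligible) < 2:
        raise ValueError("fewer than 2 eligible complexes")
    slot_counts = np.array([r.n_aggregators for r in eligible])
    real = np.array([r.mean_pairwise_distance for r in eligible])
    null = scramble_complexes(slot_counts, aggregator_vectors,
                              n_perm, seed=seed)
    p = coherence_test(real, null)
    return CoherenceAnalysis(results=results, real_distances=real,
                             null_distances=null, slot_counts=slot_counts,
                             wilcoxon_p=p)


def select_display_complexes(calls: pd.DataFrame,
                             complex_db: dict[str, set[str]],
                             solubility_hs: pd.Series,
                             min_quantified_frac: float = 0.75,
                             min_aggregator_frac: float = 0.60
                             ) -> dict[str, pd.DataFrame]:
    """Complexes dominated by aggregators, with member distance matrices.

    Selects complexes with at least 75% of members quantified and at least
    60% of members called aggregators; for each, returns the symmetric
    matrix of pairwise absolute differences in heat-shock solubility over
    all quantified members.
    """
    quantified = set(calls.index)
    aggregators = set(calls.index[calls["class"] == "aggregator"])
    out = {}
    for cid, members in complex_db.items():
        members = set(members)
        quant = sorted(members & quantified)
        if len(quant) < min_quantified_frac * len(members):
            continue
        if len(members & aggregators) < min_aggregator_frac * len(members):
            continue
        vals = solubility_hs.loc[quant].to_numpy()
        mat = np.abs(vals[:, None] - vals[None, :])
        out[cid] = pd.DataFrame(mat, index=quant, columns=quant)
    return out
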