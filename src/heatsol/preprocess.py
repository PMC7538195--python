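"""Quality filtering, batch correction, normalization, imputation and the
ratio-type summaries consumed downstream.

Order of operations for the recovery assay: quality filter (unique-peptide
support), log2 transform, per-protein batch correction, variance-stabilising
normalization of the light fraction with coefficient transfer to the heavy
fraction, left-censored imputation, then solubility / total-solubility /
synthesis ratios.

The variance-stabilising step is a quantile-matched affine calibration
followed by a glog2 transform, ``glog2(u) = log2(u + sqrt(u**2 + 1))``:
each channel's 10th-90th percentile quantiles are regressed on a reference
channel's, and the fitted affine map is inverted before the glog.  This
keeps the defining contract of variance stabilisation (monotone transform,
variance approximately independent of the mean, log2-like for large
intensities, since glog2(u) ~ log2(2u)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import IntensityTable

logger = logging.getLogger(__name__)

TIMEPOINTS_H = (0.0, 1.0, 2.0, 3.0, 5.0)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_quality(table: IntensityTable, min_unique_peptides: int = 2,
                   min_replicates: int = 2) -> IntensityTable:
    """Keep proteins with enough unique-peptide support.

    A protein is retained when it has at least ``min_unique_peptides``
    unique peptides in at least ``min_replicates`` replicates.  Row order
    is preserved.
    """
    if table.peptide_support is None:
        raise ValueError("peptide_support is required for quality filtering")
    support = table.peptide_support.reindex(table.proteins)
    ok = (support >= min_unique_peptides).sum(axis=1) >= min_replicates
    keep = table.proteins[ok.to_numpy()]
    return replace(table, values=table.values.loc[keep],
                   peptide_support=support.loc[keep])


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def correct_batches(table: IntensityTable,
                    batches: pd.Series | None = None) -> IntensityTable:
    """Remove additive per-protein batch offsets from a log2 table.

    Fits, per protein, the additive two-way model (protein mean + batch
    effect) by least squares and subtracts the batch offsets; the per-
    protein grand mean over channels is preserved exactly.  With a single
    batch the table is returned unchanged.
    """
    if table.scale == "raw":
        raise ValueError("batch correction expects a log2-scale table")
    if batches is None:
        batches = table.channel_meta.loc[table.values.columns, "batch"]
    batches = batches.reindex(table.values.columns)
    if batches.isna().any():
        raise ValueError("every channel needs a batch label")
    labels = batches.unique()
    if len(labels) < 2:
        return table
    vals = table.values
    grand = vals.mean(axis=1)
    corrected = vals.copy()
    for b in labels:
        cols = batches.index[batches == b]
        if len(cols) == 0:
            raise ValueError(f"batch {b!r} has no channels")
        offset = vals[cols].mean(axis=1) - grand
        corrected[cols] = vals[cols].sub(offset, axis=0)
    return replace(table, values=corrected)


# ---------------------------------------------------------------------------
# variance-stabilising normalization
# ---------------------------------------------------------------------------

def glog2(u):
    """Generalised log2: log2(u + sqrt(u^2 + 1)); ~ log2(2u) for large u."""
    u = np.asarray(u, dtype=float)
    return np.log2(u + np.sqrt(u * u + 1.0))


_QUANTILE_GRID = np.linspace(0.10, 0.90, 17)


def _fit_affine(channel: np.ndarray, reference: np.ndarray):
    """Fit (a, b) so the channel's transformed quantiles match the reference.

    Minimises, over the 10th-90th percentile grid, the squared differences
    ``glog2((x_q - a) / b) - glog2(r_q)``.  Matching on the transformed
    (log-like) scale weights the quantiles evenly; a raw-scale fit would be
    dominated by the brightest quantiles and leave the intercept poorly
    identified.  ``b`` is parameterised as exp(log b), so the fitted scale
    is positive and the transform strictly increasing by construction.
    """
    from scipy.optimize import least_squares

    xq = np.nanquantile(channel, _QUANTILE_GRID)
    rq = np.nanquantile(reference, _QUANTILE_GRID)
    target = glog2(rq)
    b0 = np.nanmedian(xq / rq)
    if not np.isfinite(b0) or b0 <= 0:
        return None

    def resid(ab):
        a, logb = ab
        return glog2((xq - a) / np.exp(logb)) - target

    fit = least_squares(resid, x0=[0.0, np.log(b0)])
    if not fit.success:
        return None
    return float(fit.x[0]), float(np.exp(fit.x[1]))


def normalize_vs(table: IntensityTable
                 ) -> tuple[IntensityTable, pd.DataFrame]:
    """Variance-stabilising normalization of a raw intensity table.

    Returns the transformed table (log2-like glog scale) and the fitted
    per-channel coefficients ``(a, b)`` for reuse on a matched table
    (see :func:`transfer_normalization`).  The reference channel is the one
    whose median intensity is the median across channels.  If the affine
    fit fails (or would give a non-positive scale), the channel falls back
    to a scale-only fit with a warning.
    """
    if table.scale != "raw":
        raise ValueError("normalize_vs expects raw intensities")
    vals = table.values
    n_obs = vals.notna().sum(axis=0)
    if (n_obs == 0).any():
        bad = list(vals.columns[n_obs == 0])
        raise ValueError(f"all-missing channels: {bad}")
    medians = vals.median(axis=0)
    ref_channel = (medians - medians.median()).abs().idxmin()
    ref = vals[ref_channel].to_numpy()

    coeffs = {}
    out = {}
    for c in vals.columns:
        fitted = _fit_affine(vals[c].to_numpy(), ref)
        if fitted is None:
            logger.warning("channel %s: affine fit failed, falling back "
                           "to scale-only", c)
            b = float(np.nanmedian(vals[c]) / np.nanmedian(ref))
            if not np.isfinite(b) or b <= 0:
                raise ValueError(f"channel {c}: cannot fit a positive scale")
            fitted = (0.0, b)
        a, b = fitted
        coeffs[c] = (a, b)
        out[c] = glog2((vals[c].to_numpy() - a) / b)
    coeff_df = pd.DataFrame(coeffs, index=["a", "b"]).T
    transformed = pd.DataFrame(out, index=vals.index)
    return (replace(table, values=transformed, scale="log2"), coeff_df)


def transfer_normalization(table: IntensityTable,
                           coefficients: pd.DataFrame) -> IntensityTable:
    """Apply previously fitted (a, b) coefficients without re-estimation.

    Used for the heavy (newly synthesized) fraction, whose intensities
    legitimately change over the time course: the light-derived calibration
    is frozen so the accumulation signal survives normalization.
    """
    if table.scale != "raw":
        raise ValueError("transfer_normalization expects raw intensities")
    missing = set(table.values.columns) - set(coefficients.index)
    if missing:
        raise ValueError(f"no coefficients for channels: {sorted(missing)}")
    out = {}
    for c in table.values.columns:
        a, b = coefficients.loc[c, "a"], coefficients.loc[c, "b"]
        out[c] = glog2((table.values[c].to_numpy() - a) / b)
    return replace(table, values=pd.DataFrame(out, index=table.values.index),
                   scale="log2")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(table: IntensityTable, downshift: float = 1.8,
                   width: float = 0.3, *, seed: int) -> IntensityTable:
    """Left-censored imputation by a down-shifted Gaussian.

    Missing cells in channel ``c`` are drawn from
    ``Normal(mu_c - downshift * sigma_c, (width * sigma_c)^2)`` where
    ``mu_c`` and ``sigma_c`` are the channel's observed mean and SD.
    Channels with fewer than 3 observed values fall back to the table-wide
    mean and SD (logged).  Observed cells are untouched.
    """
    if table.scale == "raw":
        raise ValueError("impute on the log2 scale")
    rng = np.random.default_rng(seed)
    vals = table.values
    if not vals.isna().any().any():
        return table
    flat = vals.to_numpy().ravel()
    global_mu = np.nanmean(flat)
    global_sd = np.nanstd(flat, ddof=1)
    out = vals.copy()
    for c in vals.columns:
        col = out[c]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        observed = col.dropna()
        if len(observed) >= 3:
            mu, sd = observed.mean(), observed.std(ddof=1)
        else:
            logger.warning("channel %s: < 3 observed values, using "
                           "table-wide moments for imputation", c)
            mu, sd = global_mu, global_sd
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        out.loc[col.isna(), c] = draws
    return replace(table, values=out)


# ---------------------------------------------------------------------------
# ratio summaries
# ---------------------------------------------------------------------------

@dataclass
class SolubilityProfiles:
    """Per-protein log2(heat/mock) solubility over the recovery course.

    ``s`` has a (time_h, replicate) column MultiIndex of replicate-matched
    heat-minus-mock differences; ``mean_s`` averages across replicates.
    """

    s: pd.DataFrame
    mean_s: pd.DataFrame

    @property
    def timepoints(self) -> list[float]:
        return list(self.mean_s.columns)

    def at_time(self, t: float) -> pd.DataFrame:
        """Replicate-level solubility values at one time point."""
        return self.s.xs(t, axis=1, level="time_h")


def compute_solubility(table: IntensityTable, silac: str = "light",
                       lysis: str = "NP40") -> SolubilityProfiles:
    """Replicate-matched log2(heat/mock) per time point.

    Solubility at time t, replicate r is the difference of the matched
    heat and mock channel values; channels must pair one-to-one on
    (time_h, replicate) within the selected SILAC fraction and lysis.
    """
    if table.scale == "raw":
        raise ValueError("compute_solubility expects a log2-scale table")
    sub = table.select_channels(silac=silac, lysis=lysis,
                                condition=("heat", "mock"))
    meta = sub.channel_meta.loc[sub.values.columns]
    pairs: dict[tuple[float, int], dict[str, str]] = {}
    for cid, row in meta.iterrows():
        pairs.setdefault((row["time_h"], row["replicate"]), {})[
            row["condition"]] = cid
    bad = [key for key, d in pairs.items() if set(d) != {"heat", "mock"}]
    if bad:
        raise ValueError(f"unmatched heat/mock channels at (time, rep): {bad}")
    cols = {}
    for (t, r), d in sorted(pairs.items()):
        cols[(t, r)] = sub.values[d["heat"]] - sub.values[d["mock"]]
    s = pd.DataFrame(cols)
    s.columns = pd.MultiIndex.from_tuples(s.columns,
                                          names=["time_h", "replicate"])
    mean_s = s.T.groupby(level="time_h").mean().T
    return SolubilityProfiles(s=s, mean_s=mean_s)


def compute_total_solubility(np40: IntensityTable,
                             sds: IntensityTable) -> pd.DataFrame:
    """log2(NP-40 / SDS) per protein and condition.

    Matched on (condition, time_h, replicate, silac); replicate values are
    averaged per condition at the earliest available time point (the
    pre-shock control has no time coordinate).  Proteins absent from either
    table are omitted (count logged).
    """
    for t in (np40, sds):
        if t.scale == "raw":
            raise ValueError("compute_total_solubility expects log2 tables")
    shared = np40.proteins.intersection(sds.proteins)
    n_dropped = len(np40.proteins.union(sds.proteins)) - len(shared)
    if n_dropped:
        logger.info("total solubility: %d proteins present in only one "
                    "lysis table were omitted", n_dropped)
    meta_np = np40.channel_meta.loc[np40.values.columns]
    meta_sds = sds.channel_meta.loc[sds.values.columns]
    out = {}
    for cond in meta_np["condition"].dropna().unique():
        sel_np = meta_np[meta_np["condition"] == cond]
        sel_sds = meta_sds[meta_sds["condition"] == cond]
        if sel_sds.empty:
            continue
        # restrict to the earliest shared time point (NaN = pre-shock)
        times = sel_np["time_h"]
        t0 = np.nan if times.isna().any() else times.min()
        if np.isnan(t0):
            sel_np = sel_np[times.isna()]
            sel_sds = sel_sds[sel_sds["time_h"].isna()]
        else:
            sel_np = sel_np[times == t0]
            sel_sds = sel_sds[sel_sds["time_h"] == t0]
        diffs = []
        for cid, row in sel_np.iterrows():
            match = sel_sds[(sel_sds["replicate"] == row["replicate"])
                            & (sel_sds["silac"] == row["silac"])]
            if match.empty:
                continue
            diffs.append(np40.values.loc[shared, cid]
                         - sds.values.loc[shared, match.index[0]])
        if diffs:
            out[cond] = pd.concat(diffs, axis=1).mean(axis=1)
    return pd.DataFrame(out)


def compute_synthesis_ratios(heavy: IntensityTable,
                             lysis: str = "NP40") -> pd.DataFrame:
    """Heavy-fraction accumulation: log2(intensity_t / intensity_preshock).

    Returns a DataFrame with (condition, time_h) column MultiIndex of
    across-replicate mean ratios to the pre-shock control (replicate-
    matched differences on the log2 scale).
    """
    if heavy.scale == "raw":
        raise ValueError("compute_synthesis_ratios expects a log2 table")
    sub = heavy.select_channels(silac="heavy", lysis=lysis)
    meta = sub.channel_meta.loc[sub.values.columns]
    pre = meta[meta["condition"] == "preshock"]
    if pre.empty:
        raise ValueError("no pre-shock channel in the heavy table")
    pre_by_rep = {row["replicate"]: cid for cid, row in pre.iterrows()}
    cols = {}
    for cond in ("mock", "heat"):
        sel = meta[meta["condition"] == cond]
        for t in sorted(sel["time_h"].dropna().unique()):
            diffs = []
            for cid, row in sel[sel["time_h"] == t].iterrows():
                pre_cid = pre_by_rep.get(row["replicate"])
                if pre_cid is None:
                    continue
                diffs.append(sub.values[cid] - sub.values[pre_cid])
            if diffs:
                cols[(cond, t)] = pd.concat(diffs, axis=1).mean(axis=1)
    ratios = pd.DataFrame(cols)
    ratios.columns = pd.MultiIndex.from_tuples(
        ratios.columns, names=["condition", "time_h"])
    return ratios


def rank_upregulated(ratios: pd.DataFrame, t: float = 5.0,
                     condition: str = "heat") -> pd.Series:
    """Proteins ordered by descending heat-shock accumulation at time t.

    Stable sort, so ties keep the input protein order.
    """
    col = ratios[(condition, t)]
    return col.sort_values(ascending=False, kind="stable")
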