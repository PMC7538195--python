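"""Synthetic heat-shock solubility and thermal-profiling experiments.

This module emulates the statistical structure of a proteome-wide study of
heat-induced protein aggregation in human cells: a two-condition time course
(44 degC heat shock vs 37 degC mock shock, sampled at 0, 1, 2, 3 and 5 h of
recovery) with dynamic-SILAC light (pre-existing) and heavy (newly
synthesized) fractions quantified in TMT channels, NP-40 (soluble) vs SDS
(total) lysis contrasts, and a 12-temperature melting gradient with two mock
and three heat-shock replicates.  Every simulated experiment comes with a
ground-truth table so that downstream estimators (aggregator calls,
disaggregation slopes, thermal-stability scores) can be checked for
parameter recovery.

Generative model, in the order the pipeline consumes it:

* Aggregators (a configurable fraction of the proteome) receive a planted
  log2 solubility drop ``true_drop`` below the aggregation cut-off
  log2(2/3) and a linear recovery rate ``true_slope`` (log2 solubility
  relaxes back to 0 at a constant rate, truncated at 0).  A Gaussian copula
  plants the requested rank correlations between drop and slope and between
  disorder fraction and slope.
* Sequences are drawn per class from multinomial amino-acid frequencies
  (lengths log-normal); the aggregator class is shifted toward charged
  residues (K, R, E up; I, L, V, F down), which produces the downstream
  class differences in gravy, pI and molecular weight.
* The melting gradient uses a sigmoid soluble-fraction model with midpoint
  ``Tm``, scale ``melt_slope`` and a non-melting ``plateau``; heat-shocked
  aliquots use ``Tm + delta_Tm`` and, for aggregators, lose the
  pre-aggregated pool at the two sub-shock temperatures.
* Measurement noise is multiplicative log-normal, with per-channel scale
  effects, per-protein-per-batch offsets, and left-censoring (probit in log
  intensity) below a detection quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntensityTable, write_complexes, write_fasta
from .seqfeatures import AMINO_ACIDS, molecular_weight

FC_CUT = float(np.log2(2.0 / 3.0))

#: Baseline amino-acid frequencies (human-proteome-like, in percent).
_BASE_AA_PCT = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "Q": 4.8, "E": 7.1,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 9.9, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}
#: Composition shift applied to the aggregator class (multiplicative).
_AGGREGATOR_AA_SHIFT = {
    "K": 1.35, "R": 1.35, "E": 1.15,
    "I": 0.70, "L": 0.80, "V": 0.75, "F": 0.75,
}

_LOCALIZATIONS = ("cytosol", "nucleus", "mitochondrion", "ER",
                  "membrane", "secreted")
_LOC_P = (0.30, 0.25, 0.15, 0.10, 0.12, 0.08)
_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)

#: TMT labels in order of increasing reporter mass (11-plex).
_TMT11 = ("126", "127N", "127C", "128N", "128C", "129N", "129C",
          "130N", "130C", "131N", "131C")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the recovery time course and the melting gradient."""

    timepoints_h: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0)
    n_replicates: int = 3
    batches: tuple[str, ...] | None = None  # per replicate; default 1:1
    tpp_temperatures: tuple[float, ...] = (
        37.0, 37.8, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6,
        62.0, 65.4, 66.3)
    tpp_replicates: tuple[tuple[str, int], ...] = (("mock", 2), ("heat", 3))
    heat_shock_temp: float = 44.0

    def __post_init__(self) -> None:
        temps = np.asarray(self.tpp_temperatures)
        if not (np.diff(temps) > 0).all():
            raise ValueError("tpp_temperatures must be strictly increasing")
        if not (temps[:2] < self.heat_shock_temp).all():
            raise ValueError("first two gradient temperatures must lie "
                             "below the heat-shock temperature")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.batches is not None and len(self.batches) != self.n_replicates:
            raise ValueError("batches must list one label per replicate")

    @property
    def replicate_batches(self) -> tuple[str, ...]:
        if self.batches is not None:
            return self.batches
        return tuple(f"batch{r}" for r in range(1, self.n_replicates + 1))


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable settings of the synthetic proteome.

    Effect-size marginals are free parameters of the generator (the study
    they emulate does not report them); defaults are chosen so that the
    typical recovery time |true_drop| / true_slope of about 9 h exceeds the
    5 h sampling window, i.e. most aggregators are still recovering at the
    last time point, and the linear-relaxation regime holds for slope
    estimation.
    """

    n_proteins: int = 2000
    aggregator_fraction: float = 0.063
    # copula rank-correlation targets (Spearman)
    corr_drop_slope: float = -0.42       # true_drop vs true_slope
    corr_disorder_slope: float = 0.25    # disorder_fraction vs true_slope
    # effect-size marginals
    drop_gamma_shape: float = 2.0        # |drop| below the cut: Gamma
    drop_gamma_scale: float = 0.6
    slope_gamma_shape: float = 4.0       # recovery rate (sol-units/h)
    slope_gamma_scale: float = 0.05
    disorder_beta_aggregator: tuple[float, float] = (2.8, 5.2)
    disorder_beta_soluble: tuple[float, float] = (2.2, 7.8)
    # abundance / synthesis
    log2_abundance_mean: float = 20.0
    log2_abundance_sd: float = 2.5
    synthesis_gamma_shape: float = 3.0   # per-hour accumulation constant
    synthesis_gamma_scale: float = 0.08
    n_induced: int = 10                  # heat-induced (HSP-like) proteins
    induction_range: tuple[float, float] = (6.0, 12.0)
    # pre-stress insoluble sub-population
    insoluble_fraction: float = 0.10
    # melting behaviour
    tm_mean: float = 50.0
    tm_sd: float = 4.0
    tm_range: tuple[float, float] = (40.0, 63.0)
    melt_slope_range: tuple[float, float] = (0.8, 1.8)
    plateau_max: float = 0.15
    aggregator_delta_tm: float = 2.5     # heat-induced stabilisation, degC
    aggregator_delta_tm_sd: float = 0.5
    # sequences
    length_meanlog_aggregator: float = float(np.log(500.0))
    length_meanlog_soluble: float = float(np.log(380.0))
    length_sdlog: float = 0.40
    min_length: int = 50
    # complexes
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (5, 20)
    n_coherent_complexes: int = 2
    coherent_complex_size: int = 8
    # peptide support
    low_support_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_proteins < 50:
            raise ValueError("n_proteins must be >= 50")
        if not 0.0 < self.aggregator_fraction < 0.5:
            raise ValueError("aggregator_fraction must be in (0, 0.5)")
        for name in ("insoluble_fraction", "low_support_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.complex_size_range[0] < 5:
            raise ValueError("complexes must have >= 5 members")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model shared by both simulated assays."""

    channel_log2_sd: float = 0.15    # iid per-cell measurement noise
    channel_scale_sd: float = 0.30   # per-channel multiplicative offset
    batch_sd: float = 0.20           # per-protein, per-batch offset
    detect_quantile: float = 0.05    # left-censoring threshold quantile
    censor_width: float = 0.5        # probit width (log2 units)

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(channel_log2_sd=0.0, channel_scale_sd=0.0,
                   batch_sd=0.0, detect_quantile=0.0)


@dataclass
class Proteome:
    """Ground truth plus annotations for one synthetic proteome."""

    truth: pd.DataFrame              # indexed by protein_id
    sequences: dict[str, str]
    complexes: dict[str, set[str]]
    params: GeneratorParams

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out = self.truth.copy()
        out["complex_ids"] = [
            ";".join(sorted(c for c, mem in self.complexes.items()
                            if pid in mem))
            for pid in out.index]
        out.rename_axis("protein_id").to_csv(outdir / "truth.tsv", sep="\t")
        write_fasta(self.sequences, outdir / "sequences.fasta")
        write_complexes(self.complexes, outdir / "complexes.tsv")


def melting_fraction(T, Tm, melt_slope, plateau=0.0):
    """Soluble fraction remaining after brief exposure to temperature ``T``.

    A descending sigmoid with midpoint ``Tm``, temperature scale
    ``melt_slope`` (degC) and a non-melting ``plateau`` fraction:
    ``plateau + (1 - plateau) / (1 + exp((T - Tm) / melt_slope))``.
    Strictly decreasing in ``T``; tends to 1 as T -> -inf and to
    ``plateau`` as T -> +inf.
    """
    melt_slope = np.asarray(melt_slope, dtype=float)
    if np.any(melt_slope <= 0):
        raise ValueError("melt_slope must be positive")
    plateau = np.asarray(plateau, dtype=float)
    if np.any(plateau < 0) or np.any(plateau >= 1):
        raise ValueError("plateau must be in [0, 1)")
    z = (np.asarray(T, dtype=float) - np.asarray(Tm, dtype=float)) / melt_slope
    return plateau + (1.0 - plateau) * stats.logistic.sf(z)


def _spearman_to_pearson(rho_s: float) -> float:
    # Gaussian copula: rho_s = (6/pi) asin(r/2)
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _class_aa_probs() -> tuple[np.ndarray, np.ndarray]:
    base = np.array([_BASE_AA_PCT[aa] for aa in AMINO_ACIDS], dtype=float)
    base /= base.sum()
    shifted = base.copy()
    for aa, mult in _AGGREGATOR_AA_SHIFT.items():
        shifted[AMINO_ACIDS.index(aa)] *= mult
    shifted /= shifted.sum()
    return base, shifted


def _draw_sequences(rng: np.random.Generator, n: int, meanlog: float,
                    sdlog: float, min_length: int,
                    probs: np.ndarray) -> list[str]:
    lengths = np.maximum(
        np.rint(rng.lognormal(meanlog, sdlog, size=n)).astype(int),
        min_length)
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(aa, size=L, p=probs)) for L in lengths]


def generate_proteome(params: GeneratorParams | None = None, *,
                      seed: int) -> Proteome:
    """Draw a proteome-scale ground-truth table.

    Deterministic for fixed ``(params, seed)``.  The number of aggregators
    is exactly ``round(n_proteins * aggregator_fraction)``; the requested
    Spearman correlations are planted with a Gaussian copula among the
    aggregators (soluble proteins have drop = slope = 0).
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    n = params.n_proteins
    n_agg = int(round(n * params.aggregator_fraction))

    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    is_agg = np.zeros(n, dtype=bool)
    is_agg[rng.choice(n, size=n_agg, replace=False)] = True

    # --- copula for (|drop|, disorder, slope) among aggregators ----------
    r_ms = _spearman_to_pearson(-params.corr_drop_slope)  # |drop| vs slope
    r_ds = _spearman_to_pearson(params.corr_disorder_slope)
    cov = np.array([[1.0, 0.0, r_ms],
                    [0.0, 1.0, r_ds],
                    [r_ms, r_ds, 1.0]])
    z = rng.multivariate_normal(np.zeros(3), cov, size=n_agg,
                                method="cholesky")
    u = stats.norm.cdf(z)
    mag = stats.gamma.ppf(u[:, 0], a=params.drop_gamma_shape,
                          scale=params.drop_gamma_scale)
    mag = np.maximum(mag, 1e-6)
    a_dis, b_dis = params.disorder_beta_aggregator
    dis_agg = stats.beta.ppf(u[:, 1], a_dis, b_dis)
    slope_agg = stats.gamma.ppf(u[:, 2], a=params.slope_gamma_shape,
                                scale=params.slope_gamma_scale)

    true_drop = np.zeros(n)
    true_slope = np.zeros(n)
    disorder = np.empty(n)
    true_drop[is_agg] = FC_CUT - mag
    true_slope[is_agg] = slope_agg
    disorder[is_agg] = dis_agg
    a_s, b_s = params.disorder_beta_soluble
    disorder[~is_agg] = rng.beta(a_s, b_s, size=(~is_agg).sum())

    # --- abundance, synthesis, induction ----------------------------------
    abundance = 2.0 ** rng.normal(params.log2_abundance_mean,
                                  params.log2_abundance_sd, size=n)
    synthesis = rng.gamma(params.synthesis_gamma_shape,
                          params.synthesis_gamma_scale, size=n)
    induction = np.ones(n)
    soluble_idx = np.flatnonzero(~is_agg)
    n_ind = min(params.n_induced, soluble_idx.size)
    if n_ind:
        chosen = rng.choice(soluble_idx, size=n_ind, replace=False)
        induction[chosen] = rng.uniform(*params.induction_range, size=n_ind)

    # --- pre-stress insoluble sub-population -------------------------------
    insoluble = rng.random(n) < params.insoluble_fraction
    soluble_frac_pre = np.where(
        insoluble, rng.uniform(0.30, 0.60, size=n),
        rng.uniform(0.85, 1.00, size=n))

    # --- melting behaviour --------------------------------------------------
    tm = np.clip(rng.normal(params.tm_mean, params.tm_sd, size=n),
                 *params.tm_range)
    melt_slope = rng.uniform(*params.melt_slope_range, size=n)
    plateau = rng.uniform(0.0, params.plateau_max, size=n)
    delta_tm = np.zeros(n)
    delta_tm[is_agg] = rng.normal(params.aggregator_delta_tm,
                                  params.aggregator_delta_tm_sd,
                                  size=n_agg)

    # --- sequences ----------------------------------------------------------
    base_p, agg_p = _class_aa_probs()
    seq_sol = _draw_sequences(rng, int((~is_agg).sum()),
                              params.length_meanlog_soluble,
                              params.length_sdlog, params.min_length, base_p)
    seq_agg = _draw_sequences(rng, n_agg, params.length_meanlog_aggregator,
                              params.length_sdlog, params.min_length, agg_p)
    sequences: dict[str, str] = {}
    it_sol, it_agg = iter(seq_sol), iter(seq_agg)
    for pid, agg in zip(ids, is_agg):
        sequences[pid] = next(it_agg) if agg else next(it_sol)

    # --- annotations --------------------------------------------------------
    localization = rng.choice(_LOCALIZATIONS, size=n, p=_LOC_P)
    chromosome = rng.choice(_CHROMOSOMES, size=n)

    truth = pd.DataFrame({
        "class": np.where(is_agg, "aggregator", "soluble"),
        "true_drop": true_drop,
        "true_slope": true_slope,
        "insoluble_subpop": insoluble,
        "abundance": abundance,
        "synthesis_rate": synthesis,
        "heat_induction": induction,
        "soluble_frac_pre": soluble_frac_pre,
        "Tm": tm,
        "melt_slope": melt_slope,
        "plateau": plateau,
        "delta_Tm": delta_tm,
        "disorder_fraction": disorder,
        "mw": [molecular_weight(sequences[p]) for p in ids],
        "localization": localization,
        "chromosome": chromosome,
        "sequence": [sequences[p] for p in ids],
    }, index=pd.Index(ids, name="protein_id"))

    complexes = _draw_complexes(rng, truth, params)
    return Proteome(truth=truth, sequences=sequences,
                    complexes=complexes, params=params)


def _draw_complexes(rng: np.random.Generator, truth: pd.DataFrame,
                    params: GeneratorParams) -> dict[str, set[str]]:
    """Random complexes plus optional planted coherent ones.

    Coherent complexes group aggregators whose planted drop and slope are
    already similar (nearest neighbours in standardised kinetics space), so
    their solubility trajectories move together without disturbing the
    planted marginals or copula correlations.
    """
    ids = truth.index.to_numpy()
    complexes: dict[str, set[str]] = {}
    lo, hi = params.complex_size_range
    for i in range(params.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ids, size=size, replace=False)
        complexes[f"CPX{i + 1:04d}"] = set(members)

    agg_ids = truth.index[truth["class"] == "aggregator"].to_numpy()
    size = params.coherent_complex_size
    if params.n_coherent_complexes and agg_ids.size >= size:
        kin = truth.loc[agg_ids, ["true_drop", "true_slope"]].to_numpy()
        kin = (kin - kin.mean(axis=0)) / kin.std(axis=0)
        taken: set[int] = set()
        for j in range(params.n_coherent_complexes):
            free = np.array([i for i in range(len(agg_ids))
                             if i not in taken])
            if free.size < size:
                break
            anchor = int(rng.choice(free))
            dists = np.linalg.norm(kin[free] - kin[anchor], axis=1)
            members_idx = free[np.argsort(dists)[:size]]
            taken.update(members_idx.tolist())
            complexes[f"COH{j + 1:04d}"] = set(agg_ids[members_idx])
    return complexes


# ---------------------------------------------------------------------------
# Recovery time course (dynamic SILAC + TMT, NP-40 vs SDS)
# ---------------------------------------------------------------------------

#: Heavy-label incorporation starts 1.5 h before the shock (medium switch).
LABEL_LEAD_H = 1.5
#: Post-shock translational stall: depth and recovery time constant (h).
STALL_DEPTH = 0.5
STALL_TAU_H = 2.0


def _relaxed_drop(true_drop: np.ndarray, true_slope: np.ndarray,
                  t: float) -> np.ndarray:
    """Expected log2 solubility at recovery time t (linear return to 0)."""
    return np.minimum(true_drop + true_slope * t, 0.0)


def _tmt_label(condition: str, time_h: float | None) -> str:
    order = [("mock", 0.0), ("mock", 1.0), ("mock", 2.0), ("mock", 3.0),
             ("mock", 5.0), ("preshock", None), ("heat", 0.0),
             ("heat", 1.0), ("heat", 2.0), ("heat", 3.0), ("heat", 5.0)]
    try:
        return _TMT11[order.index((condition, time_h))]
    except ValueError:
        return ""


def _apply_noise(rng: np.random.Generator, log2_vals: pd.DataFrame,
                 noise: NoiseParams,
                 batch_of_channel: pd.Series | None) -> pd.DataFrame:
    """Channel scale offsets, per-protein batch offsets, iid noise, censoring."""
    out = log2_vals.copy()
    n_prot, n_chan = out.shape
    if noise.channel_scale_sd > 0:
        out += rng.normal(0.0, noise.channel_scale_sd, size=n_chan)
    if noise.batch_sd > 0 and batch_of_channel is not None:
        batches = sorted(batch_of_channel.dropna().unique())
        offsets = pd.DataFrame(
            rng.normal(0.0, noise.batch_sd, size=(n_prot, len(batches))),
            index=out.index, columns=batches)
        for ch in out.columns:
            b = batch_of_channel.get(ch)
            if pd.notna(b):
                out[ch] += offsets[b]
    if noise.channel_log2_sd > 0:
        out += rng.normal(0.0, noise.channel_log2_sd, size=out.shape)
    if noise.detect_quantile > 0:
        flat = out.to_numpy()
        thresh = np.nanquantile(flat, noise.detect_quantile)
        p_missing = stats.norm.cdf((thresh - flat) / noise.censor_width)
        drop = rng.random(size=out.shape) < p_missing
        out = out.mask(drop)
    return out


def simulate_solubility_course(proteome: Proteome,
                               design: ExperimentDesign | None = None,
                               noise: NoiseParams | None = None, *,
                               seed: int,
                               include_sds: bool = True,
                               include_heavy: bool = True) -> IntensityTable:
    """Simulate the dynamic-SILAC recovery experiment.

    Light NP-40 channels carry ``abundance * soluble_frac_pre *
    2**drop(t)`` under heat (drop relaxes linearly to 0 at ``true_slope``),
    SDS channels carry total abundance without the solubility factor, and
    heavy channels accumulate as ``1 - exp(-k (t + 1.5 h))`` with a
    post-shock translational stall that decays over recovery.  Newly
    synthesized proteins aggregate like pre-existing ones.
    """
    design = design or ExperimentDesign()
    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed)
    truth = proteome.truth
    n = len(truth)

    base = np.log2(truth["abundance"].to_numpy())
    log_frac_pre = np.log2(truth["soluble_frac_pre"].to_numpy())
    drop = truth["true_drop"].to_numpy()
    slope = truth["true_slope"].to_numpy()
    k = truth["synthesis_rate"].to_numpy()
    induction = truth["heat_induction"].to_numpy()

    silacs = ("light", "heavy") if include_heavy else ("light",)
    lyses = ("NP40", "SDS") if include_sds else ("NP40",)
    t_max = max(design.timepoints_h)

    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    def add_channel(cid, expected_log2, condition, time_h, silac, rep, lysis):
        cols[cid] = expected_log2
        meta_rows.append({
            "channel_id": cid, "condition": condition, "time_h": time_h,
            "silac": silac, "replicate": rep,
            "batch": design.replicate_batches[rep - 1], "lysis": lysis,
            "temperature_C": np.nan,
            "tmt_label": _tmt_label(condition, time_h)})

    for rep in range(1, design.n_replicates + 1):
        for silac in silacs:
            for lysis in lyses:
                # pre-shock control (collected just before partitioning)
                x = base.copy()
                if silac == "heavy":
                    x = x + np.log2(1.0 - np.exp(-k * LABEL_LEAD_H))
                if lysis == "NP40":
                    x = x + log_frac_pre
                add_channel(f"pre_r{rep}_{silac[0].upper()}_{lysis}",
                            x, "preshock", np.nan, silac, rep, lysis)
                for cond in ("mock", "heat"):
                    for t in design.timepoints_h:
                        x = base.copy()
                        d_t = (_relaxed_drop(drop, slope, t)
                               if cond == "heat" else np.zeros(n))
                        if silac == "heavy":
                            x = x + np.log2(
                                1.0 - np.exp(-k * (t + LABEL_LEAD_H)))
                            if cond == "heat":
                                stall = 1.0 - STALL_DEPTH * np.exp(
                                    -t / STALL_TAU_H)
                                x = x + np.log2(stall)
                                x = x + (t / t_max) * np.log2(induction)
                        if lysis == "NP40":
                            x = x + log_frac_pre + d_t
                        add_channel(
                            f"{cond}_t{t:g}_r{rep}_{silac[0].upper()}_{lysis}",
                            x, cond, t, silac, rep, lysis)

    values = pd.DataFrame(cols, index=truth.index)
    meta = pd.DataFrame(meta_rows).set_index("channel_id")
    values = _apply_noise(rng, values, noise, meta["batch"])

    # peptide support per protein x replicate (abundance-linked Poisson,
    # with a planted low-support fraction that the quality filter removes)
    lam = np.clip(5.0 + 0.8 * (base - 20.0), 0.3, 40.0)
    support = pd.DataFrame(
        rng.poisson(lam[:, None],
                    size=(n, design.n_replicates)),
        index=truth.index,
        columns=[f"rep{r}" for r in range(1, design.n_replicates + 1)])
    n_low = int(round(n * proteome.params.low_support_fraction))
    if n_low:
        low = rng.choice(n, size=n_low, replace=False)
        support.iloc[low, :] = 1

    return IntensityTable(values=2.0 ** values, channel_meta=meta,
                          peptide_support=support, scale="raw")


# ---------------------------------------------------------------------------
# 12-temperature melting gradient (2D thermal proteome profiling)
# ---------------------------------------------------------------------------

def simulate_tpp2d(proteome: Proteome,
                   design: ExperimentDesign | None = None,
                   noise: NoiseParams | None = None, *,
                   seed: int) -> IntensityTable:
    """Simulate the melting gradient after heat or mock shock.

    Heat-condition curves melt at ``Tm + delta_Tm``; aggregators'
    heat curves are additionally scaled by ``2**true_drop`` at the two
    sub-shock temperatures (their pre-aggregated pool is absent from the
    soluble fraction there, while at higher temperatures that pool would
    have melted in either condition).
    """
    design = design or ExperimentDesign()
    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed)
    truth = proteome.truth

    base = np.log2(truth["abundance"].to_numpy())
    tm = truth["Tm"].to_numpy()
    dtm = truth["delta_Tm"].to_numpy()
    ms = truth["melt_slope"].to_numpy()
    pl = truth["plateau"].to_numpy()
    drop = truth["true_drop"].to_numpy()
    low_temps = set(design.tpp_temperatures[:2])

    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for cond, n_rep in design.tpp_replicates:
        midpoint = tm + (dtm if cond == "heat" else 0.0)
        for rep in range(1, n_rep + 1):
            for T in design.tpp_temperatures:
                x = base + np.log2(melting_fraction(T, midpoint, ms, pl))
                if cond == "heat" and T in low_temps:
                    x = x + drop
                cid = f"{cond}_r{rep}_T{T:.1f}"
                cols[cid] = x
                meta_rows.append({
                    "channel_id": cid, "condition": cond, "time_h": np.nan,
                    "silac": "light", "replicate": rep,
                    "batch": f"{cond}_r{rep}", "lysis": "NP40",
                    "temperature_C": T, "tmt_label": ""})

    values = pd.DataFrame(cols, index=truth.index)
    meta = pd.DataFrame(meta_rows).set_index("channel_id")
    # batch offsets are not applied along the gradient: replicate-level
    # shifts are already covered by per-channel scale effects, which the
    # per-temperature normalisation removes
    tpp_noise = NoiseParams(channel_log2_sd=noise.channel_log2_sd,
                            channel_scale_sd=noise.channel_scale_sd,
                            batch_sd=0.0,
                            detect_quantile=noise.detect_quantile,
                            censor_width=noise.censor_width)
    values = _apply_noise(rng, values, tpp_noise, None)
    return IntensityTable(values=2.0 ** values, channel_meta=meta,
                          scale="raw")
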