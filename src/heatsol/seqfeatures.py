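"""Sequence-derived physicochemical features.

Computes, per protein sequence, the quantities compared between heat-shock
aggregators and soluble proteins: a summed Kyte-Doolittle hydropathy score
(gravy), the isoelectric point, the average molecular weight, per-residue
amino-acid composition, and counts of candidate Hsp70-binding motifs
(a short hydrophobic stretch flanked by positively charged residues).

Notes on conventions
--------------------
* ``gravy_score`` returns the SUM of per-residue hydropathy values; the
  conventional length-normalised mean is available with ``normalize=True``.
* The isoelectric point uses the EMBOSS pKa set, pinned here so results are
  stable across environments; the set is echoed in output headers by the CLI.
* Molecular weights use average (not monoisotopic) residue masses, the
  convention for proteome-scale reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "R": -4.5, "K": -3.9, "N": -3.5, "D": -3.5, "Q": -3.5, "E": -3.5,
    "H": -3.2, "P": -1.6, "Y": -1.3, "W": -0.9, "S": -0.8, "T": -0.7,
    "G": -0.4, "A": 1.8, "M": 1.9, "C": 2.5, "F": 2.8, "L": 3.8,
    "V": 4.2, "I": 4.5,
}

#: EMBOSS pKa set: termini plus ionisable side chains.
PKA_EMBOSS = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,           # positive groups
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # negative groups
}
_POSITIVE_SIDE = ("K", "R", "H")
_NEGATIVE_SIDE = ("D", "E", "C", "Y")

#: Average residue masses (Da); one water (18.02 Da) is added per chain.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Motif-scan alphabets: hydrophobic core residues and basic flanks.
HSP70_HYDROPHOBIC = frozenset("LIVFMWY")
HSP70_BASIC = frozenset("KR")
HSP70_CORE_LENGTHS = (4, 5)


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1}")


def gravy_score(sequence: str, normalize: bool = False) -> float:
    """Summed Kyte-Doolittle hydropathy (mean if ``normalize``)."""
    _check_sequence(sequence)
    total = sum(KYTE_DOOLITTLE[aa] for aa in sequence)
    return total / len(sequence) if normalize else total


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    _check_sequence(sequence)
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA_EMBOSS["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (PKA_EMBOSS["Cterm"] - ph))
    for aa in _POSITIVE_SIDE:
        n = sequence.count(aa)
        if n:
            pos += n / (1.0 + 10.0 ** (ph - PKA_EMBOSS[aa]))
    for aa in _NEGATIVE_SIDE:
        n = sequence.count(aa)
        if n:
            neg += n / (1.0 + 10.0 ** (PKA_EMBOSS[aa] - ph))
    return pos - neg


def isoelectric_point(sequence: str, xtol: float = 1e-6) -> float:
    """pH at which the net charge vanishes.

    ``net_charge`` is strictly decreasing in pH, so the root on [0, 14] is
    unique; it is bracketed and found by Brent bisection.
    """
    _check_sequence(sequence)
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo) <= 0 or net_charge(sequence, hi) >= 0:
        # cannot happen for canonical sequences (termini always ionise)
        raise RuntimeError("net charge does not bracket zero on [0, 14]")
    return float(optimize.brentq(
        lambda ph: net_charge(sequence, ph), lo, hi, xtol=xtol))


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    _check_sequence(sequence)
    return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS


def aa_fractions(sequence: str) -> dict[str, float]:
    _check_sequence(sequence)
    n = len(sequence)
    return {aa: sequence.count(aa) / n for aa in AMINO_ACIDS}


def scan_hsp70_motifs(sequence: str) -> tuple[int, list[tuple[int, int]]]:
    """Count candidate Hsp70-binding motifs and return their spans.

    A motif is a maximal run of exactly 4 or 5 consecutive hydrophobic
    residues (L, I, V, F, M, W, Y) immediately preceded AND followed by a
    basic residue (K or R).  Each basic-bounded run counts once; spans are
    1-based inclusive over the hydrophobic core.
    """
    _check_sequence(sequence)
    spans: list[tuple[int, int]] = []
    for m in re.finditer("([KR])([LIVFMWY]+)(?=[KR])", sequence):
        core = m.group(2)
        if len(core) in HSP70_CORE_LENGTHS:
            start = m.start(2) + 1
            spans.append((start, start + len(core) - 1))
    return len(spans), spans


@dataclass
class CompositionComparison:
    """Per-class median amino-acid composition and its link to hydropathy."""

    median_fractions: pd.DataFrame     # rows = amino acids, one col per class
    difference: pd.Series              # aggregator minus soluble, per residue
    gravy_values: pd.Series            # per-residue hydropathy, same order
    pearson_r: float                   # correlation of difference vs gravy
    pearson_p: float


def aa_composition(sequences_by_class: Mapping[str, Iterable[str]],
                   aggregator_class: str = "aggregator",
                   soluble_class: str = "soluble") -> CompositionComparison:
    """Compare median amino-acid composition between protein classes.

    For each amino acid the median sequence fraction is computed per class;
    the aggregator-minus-soluble difference is then correlated (Pearson)
    with the residue's hydropathy value.  With identical compositions the
    correlation is undefined and reported as NaN.
    """
    medians = {}
    for cls, seqs in sequences_by_class.items():
        seqs = list(seqs)
        if len(seqs) < 2:
            raise ValueError(f"need >= 2 sequences per class, class {cls!r}")
        frac = pd.DataFrame([aa_fractions(s) for s in seqs])
        medians[cls] = frac.median()
    med = pd.DataFrame(medians).reindex(list(AMINO_ACIDS))
    diff = med[aggregator_class] - med[soluble_class]
    gravy = pd.Series(KYTE_DOOLITTLE).reindex(list(AMINO_ACIDS))
    if np.allclose(diff.to_numpy(), 0.0) or diff.std() == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(diff.to_numpy(), gravy.to_numpy())
    return CompositionComparison(median_fractions=med, difference=diff,
                                 gravy_values=gravy,
                                 pearson_r=float(r), pearson_p=float(p))


def feature_table(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Per-protein feature TSV contents: gravy, pI, MW, motif count, AA fractions."""
    rows = []
    for pid, seq in sequences.items():
        count, _ = scan_hsp70_motifs(seq)
        row = {
            "protein_id": pid,
            "gravy": gravy_score(seq),
            "pI": isoelectric_point(seq),
            "mw": molecular_weight(seq),
            "hsp70_motif_count": count,
        }
        row.update({f"frac_{aa}": f for aa, f in aa_fractions(seq).items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id")
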