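"""Quantitative containers and the TSV/FASTA dialect shared by all stages.

The universal quantitative input is an :class:`IntensityTable`: a protein ×
channel matrix of TMT reporter intensities together with per-channel design
metadata (condition, recovery time, SILAC label, replicate, batch, lysis
detergent, gradient temperature).  Tables are written as two plain TSV files
-- a wide intensity matrix keyed by ``protein_id`` and a channel-metadata
table keyed by ``channel_id`` -- so that every intermediate of the pipeline
can be inspected with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Columns every channel-metadata table may carry.  Absent coordinates are
#: stored as NA (e.g. ``temperature_C`` is NA outside the melting gradient).
CHANNEL_META_COLUMNS = (
    "condition",
    "time_h",
    "silac",
    "replicate",
    "batch",
    "lysis",
    "temperature_C",
    "tmt_label",
)


@dataclass
class IntensityTable:
    """Protein × channel intensities plus the experimental design.

    Parameters
    ----------
    values
        DataFrame indexed by ``protein_id`` with one column per channel.
        Non-negative on the raw scale; real-valued after log transform.
        Missing (censored) measurements are NaN.
    channel_meta
        DataFrame indexed by ``channel_id`` (matching ``values.columns``)
        with design coordinates from :data:`CHANNEL_META_COLUMNS`.
    peptide_support
        Optional protein × replicate table of unique-peptide counts used by
        the quality filter.
    scale
        ``"raw"`` for reporter intensities, ``"log2"`` for transformed data
        (including the glog2 scale, which is log2-like by construction).
    """

    values: pd.DataFrame
    channel_meta: pd.DataFrame
    peptide_support: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.channel_meta.index)
        if missing:
            raise ValueError(f"channels without metadata: {sorted(missing)}")
        if not self.values.index.is_unique:
            raise ValueError("protein identifiers must be unique")
        if self.scale == "raw":
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("raw intensities must be non-negative")

    # -- selection ---------------------------------------------------------

    def select_channels(self, **coords) -> "IntensityTable":
        """Subset channels by design coordinates, e.g. ``silac="light"``."""
        meta = self.channel_meta.loc[list(self.values.columns)]
        mask = pd.Series(True, index=meta.index)
        for key, want in coords.items():
            if isinstance(want, (list, tuple, set, frozenset)):
                mask &= meta[key].isin(list(want))
            else:
                mask &= meta[key] == want
        cols = meta.index[mask]
        return replace(self, values=self.values[cols],
                       channel_meta=self.channel_meta.loc[cols])

    def channels_where(self, **coords) -> list[str]:
        return list(self.select_channels(**coords).values.columns)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def log2(self) -> "IntensityTable":
        """Plain log2 transform (zeros become missing)."""
        if self.scale != "raw":
            raise ValueError("table is already on a log scale")
        vals = self.values.where(self.values > 0)
        return replace(self, values=np.log2(vals), scale="log2")

    # -- persistence -------------------------------------------------------

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.values.rename_axis("protein_id").to_csv(
            prefix.parent / (prefix.name + ".intensities.tsv"), sep="\t")
        self.channel_meta.rename_axis("channel_id").to_csv(
            prefix.parent / (prefix.name + ".channels.tsv"), sep="\t")
        if self.peptide_support is not None:
            self.peptide_support.rename_axis("protein_id").to_csv(
                prefix.parent / (prefix.name + ".peptides.tsv"), sep="\t")

    @classmethod
    def read(cls, intensities: str | Path, channels: str | Path,
             peptides: str | Path | None = None,
             scale: str = "raw") -> "IntensityTable":
        values = pd.read_csv(intensities, sep="\t", index_col="protein_id")
        meta = pd.read_csv(channels, sep="\t", index_col="channel_id")
        support = None
        if peptides is not None:
            support = pd.read_csv(peptides, sep="\t", index_col="protein_id")
        return cls(values=values, channel_meta=meta,
                   peptide_support=support, scale=scale)


# -- sequences and complexes ------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_complexes(complexes: Mapping[str, Iterable[str]],
                    path: str | Path) -> None:
    rows = [(cid, pid) for cid, members in complexes.items()
            for pid in members]
    pd.DataFrame(rows, columns=["complex_id", "protein_id"]).to_csv(
        path, sep="\t", index=False)


def read_complexes(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {cid: set(grp["protein_id"])
            for cid, grp in df.groupby("complex_id")}
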