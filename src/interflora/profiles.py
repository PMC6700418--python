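"""Phylogenetic and co-occurrence profiles of KEGG orthologs.

A KO's *phylogenetic profile* records which genera of the community carry it
(binary presence over genera, thresholded from genus-level relative
abundance); its *co-occurrence profile* is its relative abundance across
metagenome samples.  Anti-correlated phylogenetic profiles of two
pathway-adjacent KOs suggest a complementary, interspecific distribution;
a positive co-occurrence correlation indicates the two functions meet in the
same individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ProfileSet:
    """Aligned binary genus-presence and sample-abundance matrices per KO."""

    kos: list[str]
    genera: list[str]
    samples: list[str]
    genus_presence: np.ndarray  # (n_kos, n_genera) int8 in {0,1}
    sample_abundance: np.ndarray  # (n_kos, n_samples) float, >= 0
    constant_presence: np.ndarray = field(default=None)  # type: ignore[assignment]
    _ko_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genus_presence = np.asarray(self.genus_presence, dtype=np.int8)
        self.sample_abundance = np.asarray(self.sample_abundance, dtype=float)
        if self.genus_presence.shape[0] != self.sample_abundance.shape[0]:
            raise ValueError("presence and abundance matrices disagree on KO count")
        if self.constant_presence is None:
            row_min = self.genus_presence.min(axis=1)
            row_max = self.genus_presence.max(axis=1)
            self.constant_presence = row_min == row_max
        self._ko_index = {ko: i for i, ko in enumerate(self.kos)}

    def __contains__(self, ko: str) -> bool:
        return ko in self._ko_index

    def presence(self, ko: str) -> np.ndarray:
        return self.genus_presence[self._ko_index[ko]]

    def abundance(self, ko: str) -> np.ndarray:
        return self.sample_abundance[self._ko_index[ko]]


def validate_abundance(table: pd.DataFrame, name: str = "abundance table") -> None:
    if (table.to_numpy() < 0).any():
        raise ValueError(f"{name} contains negative values")
    if table.index.duplicated().any():
        raise ValueError(f"{name} has duplicated row labels")
    if table.columns.duplicated().any():
        raise ValueError(f"{name} has duplicated column labels")


def genus_level_abundance(long_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a gene-level long table to a KO x genus abundance table.

    ``long_table`` columns: gene_id, ko_id, genus, abundance.  Each cell is
    the mean relative abundance over the genes annotated to that KO within
    that genus; absent (KO, genus) combinations are zero.
    """
    required = {"gene_id", "ko_id", "genus", "abundance"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    if (long_table["abundance"] < 0).any():
        raise ValueError("negative abundance in long table")
    wide = long_table.pivot_table(
        index="ko_id", columns="genus", values="abundance", aggfunc="mean", fill_value=0.0
    )
    wide.index.name = "ko"
    wide.columns.name = "genus"
    return wide.sort_index().sort_index(axis=1)


def build_profiles(
    ko_by_genus: pd.DataFrame,
    ko_by_sample: pd.DataFrame,
    presence_epsilon: float = 0.0,
    drop_empty_genera: bool = True,
) -> ProfileSet:
    """Assemble aligned profiles over the KOs shared by both tables.

    Presence is ``abundance > presence_epsilon`` (strict).  Genera with no
    presence at all are dropped by default.  KOs with constant presence are
    retained but flagged — their phylogenetic correlation is undefined
    downstream.
    """
    if presence_epsilon < 0:
        raise ValueError("presence_epsilon must be >= 0")
    validate_abundance(ko_by_genus, "KO x genus table")
    validate_abundance(ko_by_sample, "KO x sample table")
    kos = sorted(set(ko_by_genus.index) & set(ko_by_sample.index))
    if not kos:
        raise ValueError("no KO shared between the genus and sample tables")
    genus = ko_by_genus.loc[kos]
    presence = (genus.to_numpy() > presence_epsilon).astype(np.int8)
    genera = list(genus.columns)
    if drop_empty_genera:
        keep = presence.sum(axis=0) > 0
        presence = presence[:, keep]
        genera = [g for g, k in zip(genera, keep) if k]
    sample = ko_by_sample.loc[kos]
    return ProfileSet(
        kos=list(kos),
        genera=genera,
        samples=list(sample.columns),
        genus_presence=presence,
        sample_abundance=sample.to_numpy(dtype=float),
    )


def read_wide_tsv(path: str | Path, index_name: str = "ko") -> pd.DataFrame:
    """Read a wide TSV (first column = KO id, remaining = samples/genera).

    Transparent to gzip via pandas' compression inference.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    return df


def write_wide_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_long_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-level long TSV (gene_id, ko_id, genus, abundance)."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ko_id": str, "genus": str})
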