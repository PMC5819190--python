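"""Bundled reference datasets for the profile and structure comparisons.

Two small TSV fixtures ship with the package so the statistical stages can
run without any sequence or structure inputs:

* ``fungal_peptidase_counts.tsv`` — a published census of peptidase-coding
  genes in 23 fungal genomes (8 mesophilic, 2 thermotolerant, 13
  thermophilic species), broken down by catalytic type (Serine, Aspartic,
  Metallo, Threonine, Cysteine, Glutamic, Asparagine, Mixed, Unknown).
  Two rows of the printed source table carry totals that differ from the
  sum of their catalytic-type columns (241 vs 242 and 340 vs 331); the
  per-type columns are the quantities every analysis uses and are
  transcribed as printed, with the printed total kept in ``total``.
* ``aspartic_peptidase_structures.tsv`` — per-structure metrics of 12
  homology-modeled A1A aspartic peptidases (molecular mass, pI, secondary
  structure element counts, surface area, volume, number of internal
  cavities) from 4 non-thermophilic and 8 thermophilic species.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrix import CountMatrix

CATALYTIC_TYPES: tuple[str, ...] = (
    "Serine", "Aspartic", "Metallo", "Threonine", "Cysteine",
    "Glutamic", "Asparagine", "Mixed", "UNK",
)
#: The seven mechanistically defined catalytic types (no Mixed / Unknown).
SEVEN_TYPES: tuple[str, ...] = CATALYTIC_TYPES[:7]

MESOPHILIC = "mesophilic"
THERMOTOLERANT = "thermotolerant"
THERMOPHILIC = "thermophilic"


def _read(name: str) -> pd.DataFrame:
    with resources.files("thermopep.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_peptidase_counts(drop_total: bool = True) -> CountMatrix:
    """The 23-species catalytic-type count matrix with group labels."""
    df = _read("fungal_peptidase_counts.tsv").set_index("species")
    groups = df.pop("group")
    if drop_total:
        df = df.drop(columns=["total"])
    return CountMatrix(df, groups)


def load_structure_metrics() -> pd.DataFrame:
    """Per-structure metrics of the 12 modeled aspartic peptidases."""
    return _read("aspartic_peptidase_structures.tsv")


def cavity_counts_by_group() -> dict[str, list[int]]:
    """Cavity-count vectors of the structure table, keyed by group."""
    df = load_structure_metrics()
    return {g: df.loc[df["group"] == g, "n_cavities"].tolist()
            for g in df["group"].unique()}
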