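"""Species-by-category count matrices with per-species group labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_COLUMN = "group"


@dataclass
class CountMatrix:
    """Non-negative integer counts of peptidase categories per species.

    ``counts`` is indexed by species; every species carries exactly one
    group label (e.g. mesophilic / thermotolerant / thermophilic).
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        self.groups = self.groups.reindex(self.counts.index)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate species labels in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"species without a group label: {missing}")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def subset_groups(self, groups: list[str]) -> "CountMatrix":
        """Rows whose group label is in ``groups`` (e.g. to drop thermotolerant)."""
        mask = self.groups.isin(groups)
        return CountMatrix(self.counts.loc[mask].copy(), self.groups.loc[mask].copy())

    def subset_categories(self, categories: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, categories].copy(), self.groups.copy())

    def relativized(self) -> pd.DataFrame:
        """Rows rescaled to percentages (row sums 100)."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        if (totals == 0).any():
            raise ValueError("cannot relativize a row of all-zero counts")
        return self.counts.div(totals, axis=0) * 100.0

    def values(self, relativize: bool = False) -> np.ndarray:
        return (self.relativized() if relativize else self.counts).to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, GROUP_COLUMN, self.groups)
        out.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if GROUP_COLUMN not in df.columns:
            raise ValueError(f"count matrix TSV must carry a {GROUP_COLUMN!r} column")
        groups = df[GROUP_COLUMN].astype(str)
        counts = df.drop(columns=[c for c in df.columns if not
                                  pd.api.types.is_numeric_dtype(df[c])])
        return cls(counts, groups)

    @classmethod
    def from_frame(cls, counts: pd.DataFrame, groups: dict[str, str] | pd.Series) -> "CountMatrix":
        return cls(counts, pd.Series(groups))
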