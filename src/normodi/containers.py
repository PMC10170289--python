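"""Core in-memory containers shared across the pipeline.

An :class:`AbundanceTable` is a thin, stateful wrapper around a pandas
DataFrame with samples as rows and features (taxa, genes, metabolites) as
columns.  The ``state`` field tracks where the table sits in the
normalisation chain: raw counts, relative abundances (rows closed to 1) or
a transformed (e.g. CLR) matrix in which downstream multivariate statistics
operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "SampleMetadata", "STATES"]

STATES = ("raw", "relative", "transformed")


@dataclass
class AbundanceTable:
    """Sample x feature abundance matrix.

    Parameters
    ----------
    data
        DataFrame with unique sample identifiers as the index and unique
        feature identifiers as columns.  Values must be non-negative reals
        in states ``raw`` / ``relative``; NaN marks a missing measurement.
    state
        One of ``raw``, ``relative``, ``transformed``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        values = self.data.to_numpy(dtype=float)
        if self.state != "transformed":
            neg = np.argwhere(values < 0)  # NaN compares False, so missing passes
            if neg.size:
                r, c = neg[0]
                raise ValueError(
                    "negative abundance at sample "
                    f"{self.data.index[r]!r}, feature {self.data.columns[c]!r}"
                )
        if self.state == "relative":
            sums = np.nansum(values, axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            if bad.size:
                raise ValueError(
                    f"state='relative' but row {self.data.index[bad[0]]!r} "
                    f"sums to {sums[bad[0]]!r}, not 1"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "AbundanceTable":
        """Return a new table holding ``data``, defaulting to the same state."""
        return AbundanceTable(data=data, state=self.state if state is None else state)

    def subset_samples(self, sample_ids: Iterable) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return self.with_data(self.data.loc[ids])


@dataclass
class SampleMetadata:
    """Map from sample identifier to group label (HC, NIP, Placebo, ...)."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if "group" not in self.frame.columns:
            raise ValueError("metadata frame needs a 'group' column")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in metadata: {dups}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SampleMetadata":
        frame = pd.DataFrame({"group": pd.Series(dict(mapping))})
        frame.index.name = "sample_id"
        return cls(frame)

    @property
    def sample_ids(self) -> list:
        return self.frame.index.tolist()

    def groups_for(self, sample_ids: Iterable) -> pd.Series:
        """Group labels for ``sample_ids``; any sample without a row is an error."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing}")
        return self.frame.loc[ids, "group"]

    def group_labels(self) -> list:
        """Distinct group labels in first-appearance order."""
        seen: dict = {}
        for g in self.frame["group"]:
            seen.setdefault(g, None)
        return list(seen)
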