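"""Core in-memory containers exchanged between pipeline stages.

``SequenceRead`` carries one FASTQ record through QC and tag extraction;
``CountTable`` is the central samples x features integer matrix consumed by
every downstream statistic. Distance matrices and trees are represented by
:class:`skbio.DistanceMatrix` and :class:`skbio.TreeNode` rather than bespoke
types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAX_PHRED = 60


@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read: id, bases over {A,C,G,T,N}, Phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValidationError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if not set(self.bases) <= set("ACGTN"):
            bad = sorted(set(self.bases) - set("ACGTN"))
            raise ValidationError(f"read {self.read_id!r}: invalid bases {bad}")
        if self.quals and not all(0 <= q <= MAX_PHRED for q in self.quals):
            raise ValidationError(
                f"read {self.read_id!r}: Phred scores must lie in [0, {MAX_PHRED}]"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRead":
        return SequenceRead(
            self.read_id,
            revcomp(self.bases),
            tuple(reversed(self.quals)),
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CountTable:
    """Samples x features matrix of non-negative integer counts.

    Samples are rows, features are columns; both label sets are ordered and
    unique. This orientation is fixed package-wide.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("count table contains non-numeric cells")
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {df.index[r]!r}, "
                    f"feature {df.columns[c]!r}"
                )
            if not np.allclose(values, np.round(values)):
                r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValidationError(
                    f"non-integer count at sample {df.index[r]!r}, "
                    f"feature {df.columns[c]!r}"
                )
        self._df = df.astype(np.int64)

    @classmethod
    def from_arrays(
        cls,
        sample_ids: Iterable[str],
        feature_ids: Iterable[str],
        counts: np.ndarray,
    ) -> "CountTable":
        df = pd.DataFrame(
            np.asarray(counts), index=list(sample_ids), columns=list(feature_ids)
        )
        return cls(df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.sample_totals()
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValidationError(f"all-zero samples: {empty}")
        return self._df.div(totals, axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"CountTable({n} samples x {m} features)"


def as_group_series(groups: Mapping[str, str] | pd.Series) -> pd.Series:
    """Coerce a sample_id -> group mapping to a pandas Series."""
    s = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    return s.astype(str)
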