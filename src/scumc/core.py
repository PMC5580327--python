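"""Core genomic containers shared across the package.

All coordinates are 0-based, half-open (BED convention). A CpG is addressed
by the position of the cytosine of the CpG dinucleotide on the plus strand;
the dinucleotide itself occupies ``[pos, pos + 2)``.
"""
from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

METHYLOME_COLUMNS = ("chrom", "pos", "meth_ratio", "coverage")


@dataclass(frozen=True)
class CpGRecord:
    """One CpG observation in one sample.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        0-based position of the C of the CpG dinucleotide (plus strand).
    meth_ratio : float
        Methylated read fraction in ``[0, 1]``.
    coverage : int
        Number of aligned reads supporting the call (non-negative).
    """

    chrom: str
    pos: int
    meth_ratio: float
    coverage: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")
        if not 0.0 <= self.meth_ratio <= 1.0:
            raise ValueError(
                f"methylation ratio {self.meth_ratio} outside [0, 1] at "
                f"{self.chrom}:{self.pos}"
            )
        if self.coverage < 0:
            raise ValueError(
                f"negative coverage {self.coverage} at {self.chrom}:{self.pos}"
            )


class Methylome:
    """A sample-labelled, position-sorted table of CpG observations.

    Wraps a :class:`pandas.DataFrame` with columns
    ``chrom, pos, meth_ratio, coverage``. Construction sorts by
    ``(chrom, pos)``, validates value ranges and rejects duplicate
    positions within a chromosome.
    """

    def __init__(self, sample_id: str, records: pd.DataFrame):
        if not sample_id:
            raise ValueError("sample_id must be a non-empty string")
        df = records.loc[:, list(METHYLOME_COLUMNS)].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["meth_ratio"] = df["meth_ratio"].astype(np.float64)
        df["coverage"] = df["coverage"].astype(np.int64)
        if len(df):
            if (df["pos"] < 0).any():
                raise ValueError("negative CpG position")
            bad = df[(df["meth_ratio"] < 0) | (df["meth_ratio"] > 1)]
            if len(bad):
                row = bad.iloc[0]
                raise ValueError(
                    f"methylation ratio {row.meth_ratio} outside [0, 1] at "
                    f"{row.chrom}:{row.pos}"
                )
            if (df["coverage"] < 0).any():
                raise ValueError("negative coverage")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(f"duplicate CpG position {row.chrom}:{row.pos}")
        self.sample_id = sample_id
        self._df = df

    @classmethod
    def from_records(
        cls, sample_id: str, records: Iterable[CpGRecord | tuple]
    ) -> "Methylome":
        rows = []
        for r in records:
            if isinstance(r, CpGRecord):
                rows.append((r.chrom, r.pos, r.meth_ratio, r.coverage))
            else:
                rows.append(tuple(r))
        df = pd.DataFrame(rows, columns=list(METHYLOME_COLUMNS))
        if not len(rows):
            df = cls.empty_frame()
        return cls(sample_id, df)

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "meth_ratio": pd.Series(dtype=np.float64),
                "coverage": pd.Series(dtype=np.int64),
            }
        )

    @property
    def records(self) -> pd.DataFrame:
        """The underlying sorted frame (do not mutate)."""
        return self._df

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self._df[self._df["chrom"] == chrom]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        return self.sample_id == other.sample_id and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"Methylome({self.sample_id!r}, n={len(self)})"


@dataclass
class GenomicRegion:
    """Half-open genomic interval with a free-form attribute map."""

    chrom: str
    start: int
    end: int
    attrs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def merge_regions(
    regions: Iterable[GenomicRegion], book_ended: bool = True
) -> list[GenomicRegion]:
    """Merge overlapping (and optionally book-ended) intervals.

    Returns a sorted, non-overlapping list; attributes are dropped.
    """
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted((r.start, r.end) for r in by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            joins = s <= cur_e if book_ended else s < cur_e
            if joins:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicRegion(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicRegion(chrom, cur_s, cur_e))
    return out


class RegionIndex:
    """Membership / overlap queries against a merged interval set.

    Intervals are merged per chromosome into sorted, disjoint arrays;
    queries are numpy ``searchsorted`` lookups.
    """

    def __init__(self, regions: Iterable[GenomicRegion]):
        merged = merge_regions(regions)
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for r in merged:
            starts.setdefault(r.chrom, []).append(r.start)
            ends.setdefault(r.chrom, []).append(r.end)
        self._starts = {c: np.asarray(v, dtype=np.int64) for c, v in starts.items()}
        self._ends = {c: np.asarray(v, dtype=np.int64) for c, v in ends.items()}

    def contains_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean array: is each point inside some interval?"""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos.shape, dtype=bool)
        res[ok] = pos[ok] < self._ends[chrom][idx[ok]]
        return res

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.overlaps_many(chrom, np.array([start]), np.array([end]))[0])

    def overlaps_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean array: does each half-open query overlap some interval?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        # intervals with start < query_end, minus those with end <= query_start
        a = np.searchsorted(self._starts[chrom], ends, side="left")
        b = np.searchsorted(self._ends[chrom], starts, side="right")
        return a > b
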