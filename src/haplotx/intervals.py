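"""Genomic interval arithmetic and plain-text I/O shared by every pipeline stage.

Coordinates are 0-based, half-open throughout the package.  BED files are
read and written natively in that convention; GTF conversion (1-based,
closed) happens only at the file boundary.  Region-level set operations are
strand-agnostic: strand is consulted only where the biology demands it
(5' ends, promoters, bidirectionality), never for nucleotide counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length map defining the coordinate universe."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, size in self.chrom_sizes.items():
                fh.write(f"{name}\t{size}\n")

    @property
    def total_bases(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        """Raise if any interval escapes its chromosome (the interval is named)."""
        for iv in intervals:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"interval {iv} on unknown chromosome {iv.chrom!r}")
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv} extends beyond chromosome {iv.chrom!r} "
                    f"(length {self.chrom_sizes[iv.chrom]})"
                )

    def as_interval_set(self) -> "IntervalSet":
        return IntervalSet(
            [GenomicInterval(c, 0, n) for c, n in self.chrom_sizes.items()]
        )


def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Collapse an (n, 2) array of [start, end) rows into disjoint sorted rows.

    Bookended intervals ([10,20) and [20,30)) merge, per the half-open
    convention.
    """
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.array(out, dtype=np.int64)


class IntervalSet:
    """A collection of genomic intervals supporting merge/subtract/overlap.

    Set operations drop strand (regions, not features).  A normalized set is
    sorted by (chrom, start) and pairwise disjoint per chromosome.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), normalized: bool = False):
        self.intervals: tuple[GenomicInterval, ...] = tuple(intervals)
        self._normalized = normalized
        self._per_chrom: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.merge().intervals == other.merge().intervals

    @property
    def is_empty(self) -> bool:
        return len(self.intervals) == 0

    def per_chrom(self) -> dict[str, np.ndarray]:
        """Merged, sorted (n, 2) coordinate arrays keyed by chromosome."""
        if self._per_chrom is None:
            buckets: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._per_chrom = {
                c: _merge_array(np.array(rows, dtype=np.int64))
                for c, rows in buckets.items()
            }
        return self._per_chrom

    @classmethod
    def from_arrays(cls, per_chrom: Mapping[str, np.ndarray]) -> "IntervalSet":
        ivs = [
            GenomicInterval(c, int(s), int(e))
            for c in sorted(per_chrom)
            for s, e in per_chrom[c]
        ]
        out = cls(ivs, normalized=True)
        return out

    def merge(self, layout: GenomeLayout | None = None) -> "IntervalSet":
        """Union coverage as a disjoint sorted set (idempotent)."""
        if layout is not None:
            layout.validate(self.intervals)
        return IntervalSet.from_arrays(self.per_chrom())

    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.per_chrom().values()))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases covered by self and not by other, as a disjoint sorted set."""
        out: dict[str, np.ndarray] = {}
        other_pc = other.per_chrom()
        for chrom, a in self.per_chrom().items():
            b = other_pc.get(chrom)
            if b is None or len(b) == 0:
                out[chrom] = a
                continue
            rows = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        rows.append((cur, b[k, 0]))
                    cur = max(cur, b[k, 1])
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    rows.append((cur, e))
            out[chrom] = np.array(rows, dtype=np.int64).reshape(-1, 2)
        return IntervalSet.from_arrays(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Bases covered by both sets."""
        out: dict[str, np.ndarray] = {}
        other_pc = other.per_chrom()
        for chrom, a in self.per_chrom().items():
            b = other_pc.get(chrom)
            if b is None or len(b) == 0:
                continue
            rows = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    rows.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if rows:
                out[chrom] = np.array(rows, dtype=np.int64)
        return IntervalSet.from_arrays(out)

    def overlap_bases(self, other: "IntervalSet") -> int:
        """Total shared bases (symmetric)."""
        return self.intersect(other).total_bases()

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        arr = self.per_chrom().get(iv.chrom)
        if arr is None or len(arr) == 0:
            return False
        idx = np.searchsorted(arr[:, 0], iv.end)
        return bool(idx > 0 and arr[idx - 1, 1] > iv.start)

    def contains_points(self, chroms: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        """Boolean membership per (chrom, position) point."""
        pc = self.per_chrom()
        res = np.zeros(len(positions), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        for chrom in np.unique(chroms):
            arr = pc.get(str(chrom))
            mask = chroms == chrom
            if arr is None or len(arr) == 0:
                continue
            pos = positions[mask]
            idx = np.searchsorted(arr[:, 0], pos, side="right")
            hit = (idx > 0) & (pos < arr[np.maximum(idx - 1, 0), 1])
            res[mask] = hit
        return res


def merge(s: IntervalSet, layout: GenomeLayout | None = None) -> IntervalSet:
    return s.merge(layout)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


def overlap_bases(a: IntervalSet, b: IntervalSet) -> int:
    return a.overlap_bases(b)


# ---------------------------------------------------------------------------
# BED / chrom-sizes I/O (tab-separated, 0-based half-open, BED3/BED6)
# ---------------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_df(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = BED6_COLUMNS[:ncol]
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_bed(path: str | Path) -> IntervalSet:
    df = read_bed_df(path)
    strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return IntervalSet(
        GenomicInterval(c, s, e, st if st in VALID_STRANDS else ".")
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)
    )


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names are given)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0 if scores is None else scores[i]
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t{score}\t{iv.strand}\n"
                )
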