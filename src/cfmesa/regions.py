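"""Genomic intervals, annotation sets, and the CpG position index.

All coordinates are 0-based half-open throughout the package. Chromosome
names are normalized to the ``chr``-prefixed convention and ordered
chr1..chr22, chrX, chrY, then anything else lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree

REGION_KINDS = frozenset(
    {"CGI", "DHS", "promoter", "TSS", "PAS", "marker", "target"}
)

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)}
_CHROM_ORDER["chrX"] = 23
_CHROM_ORDER["chrY"] = 24


def normalize_chrom(chrom: str) -> str:
    """Return the ``chr``-prefixed form of a chromosome name."""
    chrom = str(chrom).strip()
    if not chrom.startswith("chr"):
        chrom = "chr" + chrom
    return chrom


def chrom_sort_key(chrom: str):
    """Sort key giving chr1..chr22, chrX, chrY natural order."""
    chrom = normalize_chrom(chrom)
    return (_CHROM_ORDER.get(chrom, 1000), chrom)


@dataclass(frozen=True)
class GenomicRegion:
    """A typed genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str
    gene: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.end:
            raise ValueError(
                f"region {self.name}: start {self.start} >= end {self.end}"
            )
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            self.chrom == normalize_chrom(chrom)
            and self.start < end
            and start < self.end
        )


@dataclass
class AnnotationSet:
    """A collection of regions of one kind, indexed for overlap queries."""

    kind: str
    regions: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            self._index(r)

    def _index(self, region: GenomicRegion) -> None:
        tree = self._trees.setdefault(region.chrom, IntervalTree())
        tree.addi(region.start, region.end, region)

    def add(self, region: GenomicRegion) -> None:
        if region.kind != self.kind:
            raise ValueError(
                f"cannot add kind {region.kind!r} to {self.kind!r} set"
            )
        self.regions.append(region)
        self._index(region)

    def query(self, chrom: str, start: int, end: int) -> list[GenomicRegion]:
        """Regions overlapping [start, end) on chrom, in coordinate order."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda r: (r.start, r.end, r.name))

    def query_point(self, chrom: str, pos: int) -> list[GenomicRegion]:
        return self.query(chrom, pos, pos + 1)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(
            sorted(
                self.regions,
                key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end),
            )
        )


class CpGIndex:
    """Sorted reference CpG positions per chromosome.

    Used to validate fragment methylation-state strings (one symbol per
    reference CpG the fragment overlaps) and to look up CpGs in regions.
    """

    def __init__(self, positions: dict[str, Iterable[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(set(int(p) for p in pos)), dtype=np.int64)
            self._pos[normalize_chrom(chrom)] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos, key=chrom_sort_key)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(normalize_chrom(chrom), np.empty(0, dtype=np.int64))

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """CpG positions within [start, end) on chrom."""
        pos = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return int(hi - lo)

    def total(self) -> int:
        return sum(len(v) for v in self._pos.values())

    @classmethod
    def from_bed(cls, path) -> "CpGIndex":
        """Build from a BED file of single-base CpG intervals."""
        positions: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                chrom, start = fields[0], int(fields[1])
                positions.setdefault(chrom, []).append(start)
        return cls(positions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for p in self.positions(chrom):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")
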