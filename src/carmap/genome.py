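"""Genome, bin-table and CAR-site data model.

Coordinates are 0-based, half-open throughout (BED-native). A genome is an
ordered list of chromosomes; binning tiles each chromosome with fixed-width
bins (the last bin may be short); cohesin-associated regions (CARs) are point
anchors obtained from BED intervals by midpoint reduction. These objects are
the shared coordinate frame for the contact-matrix statistics and for the
loop-extrusion simulator, where CAR bins act as boundary elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, MalformedRecordError, MissingReferenceError

__all__ = [
    "GenomeModel",
    "BinTable",
    "CARSet",
    "bin_genome",
    "load_car_sites",
    "anchor_to_bin",
]


@dataclass(frozen=True)
class GenomeModel:
    """Ordered list of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidParameterError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise InvalidParameterError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise MissingReferenceError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeModel":
        """Read a UCSC-style two-column chrom.sizes file (name, length)."""
        chroms: list[tuple[str, int]] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise MalformedRecordError(f"{path}:{lineno}: expected two columns")
            chroms.append((parts[0], int(parts[1])))
        return cls(tuple(chroms))

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self.chromosomes)
        )


@dataclass(frozen=True)
class BinTable:
    """Fixed-width tiling of every chromosome of a genome.

    Bins are half-open intervals [start, end); all bins except possibly the
    last per chromosome have width ``binsize``. Bin indices are dense, 0-based
    and per-chromosome.
    """

    genome: GenomeModel
    binsize: int

    def __post_init__(self) -> None:
        if self.binsize < 1:
            raise InvalidParameterError(f"binsize must be >= 1, got {self.binsize}")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.genome.length(chrom) / self.binsize)

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.binsize

    def ends(self, chrom: str) -> np.ndarray:
        ends = self.starts(chrom) + self.binsize
        ends[-1] = min(int(ends[-1]), self.genome.length(chrom))
        return ends


def bin_genome(genome: GenomeModel, binsize: int) -> BinTable:
    """Tile ``genome`` with ``binsize``-bp bins (last bin per chromosome may be short)."""
    return BinTable(genome=genome, binsize=binsize)


def anchor_to_bin(anchor: int, chrom: str, bins: BinTable) -> int:
    """Index of the bin whose half-open interval contains ``anchor``.

    Equals floor(anchor / binsize); an anchor at or beyond the chromosome
    length is out of range under the half-open convention.
    """
    length = bins.genome.length(chrom)
    if anchor < 0 or anchor >= length:
        raise MissingReferenceError(
            f"anchor {anchor} outside [0, {length}) on {chrom!r}"
        )
    return int(anchor) // bins.binsize


@dataclass
class CARSet:
    """Per-chromosome ordered anchor points (bp) for cohesin-associated regions.

    Anchors are sorted ascending and unique within each chromosome; optional
    source intervals are retained when the set was loaded from BED.
    """

    genome: GenomeModel
    anchors: dict[str, np.ndarray]
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, np.ndarray] = {}
        for chrom, pts in self.anchors.items():
            if chrom not in self.genome:
                raise MissingReferenceError(f"unknown chromosome {chrom!r}")
            arr = np.unique(np.asarray(pts, dtype=np.int64))
            length = self.genome.length(chrom)
            if arr.size and (arr[0] < 0 or arr[-1] >= length):
                raise MissingReferenceError(
                    f"anchor outside [0, {length}) on {chrom!r}"
                )
            cleaned[chrom] = arr
        self.anchors = cleaned

    def chrom_anchors(self, chrom: str) -> np.ndarray:
        if chrom not in self.genome:
            raise MissingReferenceError(f"unknown chromosome {chrom!r}")
        return self.anchors.get(chrom, np.empty(0, dtype=np.int64))

    def anchor_bins(self, chrom: str, bins: BinTable) -> np.ndarray:
        """Bin index of every anchor on ``chrom`` (sorted, possibly duplicated bins collapsed)."""
        pts = self.chrom_anchors(chrom)
        return np.unique(pts // bins.binsize).astype(np.int64)

    def n_anchors(self) -> int:
        return sum(arr.size for arr in self.anchors.values())

    def to_bed(self, path: str | Path) -> None:
        """Write anchors as 1-bp BED intervals [a, a+1); midpoint reduction is the identity."""
        with open(path, "w") as fh:
            for chrom, _ in self.genome.chromosomes:
                for a in self.anchors.get(chrom, ()):
                    fh.write(f"{chrom}\t{a}\t{a + 1}\n")


def load_car_sites(path: str | Path, genome: GenomeModel) -> CARSet:
    """Load CAR anchors from a BED file (3+ columns, 0-based half-open).

    Each interval is reduced to its integer midpoint floor((start+end)/2);
    duplicate midpoints collapse to a single anchor.
    """
    anchors: dict[str, list[int]] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise MalformedRecordError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if chrom not in genome:
            raise MissingReferenceError(
                f"{path}:{lineno}: chromosome {chrom!r} not in genome"
            )
        if end <= start:
            raise MalformedRecordError(
                f"{path}:{lineno}: end {end} <= start {start}"
            )
        anchors.setdefault(chrom, []).append((start + end) // 2)
        intervals.setdefault(chrom, []).append((start, end))
    return CARSet(genome=genome, anchors={c: np.array(v) for c, v in anchors.items()},
                  intervals=intervals)
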