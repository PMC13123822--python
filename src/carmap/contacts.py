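"""Binned cis contact-matrix container and plain-text I/O.

Only intra-chromosomal (cis) matrices are modeled: every downstream statistic
(decay curves, slopes, pile-ups, CAR offsets) operates at cis range. Counts
are stored raw and symmetric; no matrix balancing is applied — the
observed/expected transform in :mod:`carmap.loops` plays the normalizing role.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, MalformedRecordError, MissingReferenceError
from .genome import BinTable

__all__ = ["ContactMatrix", "read_coo", "write_coo", "total_contacts",
           "read_dense", "write_dense"]


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact counts for one chromosome.

    ``counts[i, j]`` is the number of contacts between bins i and j;
    the matrix is densely stored (yeast-scale cis matrices are small).
    """

    chrom: str
    binsize: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.float64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidParameterError(f"counts must be square, got shape {c.shape}")
        if (c < 0).any():
            raise MalformedRecordError("negative contact counts")
        if not np.array_equal(c, c.T):
            raise InvalidParameterError("counts must be symmetric")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def scaled(self, k: float) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.binsize, self.counts * k)


def total_contacts(matrix: ContactMatrix) -> float:
    """Sum of counts over the upper triangle including the diagonal.

    Each unordered bin pair is counted once, so for a simulated matrix this
    equals the number of contact events registered.
    """
    c = matrix.counts
    return float(np.triu(c).sum())


def write_coo(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (i <= j, zeros omitted) as triplet text.

    The header names the chromosome, bin size and matrix dimension so the file
    is self-describing; integer counts are written as integers so that
    ``read_coo(write_coo(m))`` is the identity.
    """
    c = matrix.counts
    ii, jj = np.nonzero(np.triu(c))
    with open(path, "w") as fh:
        fh.write(f"# chrom: {matrix.chrom}\n")
        fh.write(f"# binsize: {matrix.binsize}\n")
        fh.write(f"# n_bins: {matrix.n_bins}\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            v = c[i, j]
            fh.write(f"{i}\t{j}\t{int(v) if v == int(v) else repr(v)}\n")


def _parse_header(lines: list[str], path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        if not line.startswith("#"):
            break
        if ":" in line:
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    if "chrom" not in meta or "binsize" not in meta:
        raise MalformedRecordError(f"{path}: header must name chrom and binsize")
    return meta


def read_coo(path: str | Path, bins: BinTable | None = None,
             chrom: str | None = None, n_bins: int | None = None) -> ContactMatrix:
    """Read triplet text (bin_i, bin_j, count) into a symmetric matrix.

    Upper-triangle storage is accepted: entries are mirrored, and duplicate
    (i, j) rows are summed. The matrix dimension comes from ``bins`` when a
    bin table is given, else from the file header.
    """
    lines = Path(path).read_text().splitlines()
    meta = _parse_header(lines, path)
    chrom = chrom or meta["chrom"]
    binsize = int(meta["binsize"])
    if bins is not None:
        if bins.binsize != binsize:
            raise MalformedRecordError(
                f"{path}: binsize {binsize} != bin table binsize {bins.binsize}"
            )
        n = bins.n_bins(chrom)
    elif n_bins is not None:
        n = n_bins
    elif "n_bins" in meta:
        n = int(meta["n_bins"])
    else:
        raise MalformedRecordError(f"{path}: matrix dimension unknown")

    counts = np.zeros((n, n), dtype=np.float64)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise MalformedRecordError(f"{path}:{lineno}: expected 3 columns")
        i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
        if not (0 <= i < n and 0 <= j < n):
            raise MissingReferenceError(
                f"{path}:{lineno}: bin index ({i},{j}) out of range for {n} bins"
            )
        if v < 0:
            raise MalformedRecordError(f"{path}:{lineno}: negative count {v}")
        counts[i, j] += v
        if i != j:
            counts[j, i] += v
    return ContactMatrix(chrom=chrom, binsize=binsize, counts=counts)


def write_dense(matrix: ContactMatrix, path: str | Path) -> None:
    """Dense whitespace-separated export for small fixtures."""
    header = f"chrom: {matrix.chrom}\nbinsize: {matrix.binsize}"
    np.savetxt(path, matrix.counts, fmt="%.17g", header=header)


def read_dense(path: str | Path) -> ContactMatrix:
    lines = Path(path).read_text().splitlines()
    meta = _parse_header(lines, path)
    counts = np.loadtxt(path)
    return ContactMatrix(chrom=meta["chrom"], binsize=int(meta["binsize"]),
                         counts=np.atleast_2d(counts))
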