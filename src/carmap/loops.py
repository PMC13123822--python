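"""Observed/expected normalization, CAR-pair pile-ups and offset profiles.

The expected profile E(d) is the mean count over all pixel pairs at
separation d; dividing by it removes the distance decay so loop signal
stands out. Pile-ups stack O/E windows centered on CAR-CAR anchor pairs
(off-diagonal "spots"); the corner-enrichment score — center-pixel O/E over
the mean of the four corner blocks — is the fold-change statistic for
positioned-loop strength. The CAR offset profile tracks mean O/E at pixels
pairing each CAR with its +1..+K neighbor.

Undefined O/E pixels (zero expected) propagate as NaN, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import ContactMatrix
from .errors import (
    DegenerateInputError,
    EmptyInputError,
    InvalidParameterError,
)
from .genome import BinTable, CARSet

__all__ = [
    "ExpectedProfile",
    "OEMatrix",
    "PileupResult",
    "CAROffsetProfile",
    "expected_by_distance",
    "observed_over_expected",
    "car_pair_windows",
    "pileup",
    "corner_enrichment",
    "car_offset_profile",
]


@dataclass
class ExpectedProfile:
    """E(d): mean count over all pixel pairs at separation d = 0..n-1."""

    chrom: str
    expected: np.ndarray


@dataclass
class OEMatrix:
    """Observed/expected ratio matrix; NaN where the expected is zero."""

    chrom: str
    binsize: int
    values: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class PileupResult:
    """Pixel-wise mean of log2(O/E) over stacked anchor-pair windows.

    The map is odd-by-odd so a unique center pixel exists; ``enrichment``
    holds the corner score computed with the default corner size.
    """

    map: np.ndarray
    n_windows: int
    n_skipped: int
    window_bp: int
    binsize: int
    enrichment: float = float("nan")

    def write(self, path: str | Path) -> None:
        """Dense text matrix plus a key-value sidecar (<path>.info)."""
        np.savetxt(path, self.map, fmt="%.8g")
        Path(str(path) + ".info").write_text(
            f"n_windows\t{self.n_windows}\n"
            f"n_skipped\t{self.n_skipped}\n"
            f"window_bp\t{self.window_bp}\n"
            f"binsize\t{self.binsize}\n"
            f"enrichment\t{self.enrichment:.8g}\n"
        )


@dataclass
class CAROffsetProfile:
    """Mean O/E at (CAR_m, CAR_{m+k}) pixels for offsets k = 1..K."""

    offsets: np.ndarray
    mean_oe: np.ndarray
    n_pairs: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tmean_oe\tn_pairs\n")
            for k, v, n in zip(self.offsets, self.mean_oe, self.n_pairs):
                fh.write(f"{int(k)}\t{v:.8g}\t{int(n)}\n")


def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    """Per-diagonal mean count: E(d) = sum of counts at separation d / (n - d)."""
    c = matrix.counts
    n = c.shape[0]
    expected = np.array(
        [np.trace(c, offset=d) / (n - d) for d in range(n)], dtype=np.float64
    )
    return ExpectedProfile(chrom=matrix.chrom, expected=expected)


def observed_over_expected(matrix: ContactMatrix,
                           expected: ExpectedProfile | None = None) -> OEMatrix:
    """Divide counts by the distance expected; NaN where E(d) == 0.

    With the per-matrix expected (the default), the mean of defined O/E
    values along every diagonal is exactly 1. A pooled profile may be passed
    instead for cross-sample comparison at matched depth.
    """
    if expected is None:
        expected = expected_by_distance(matrix)
    n = matrix.n_bins
    if expected.expected.size < n:
        raise InvalidParameterError(
            f"expected profile has {expected.expected.size} diagonals, matrix has {n}"
        )
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = expected.expected[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(e > 0, matrix.counts / e, np.nan)
    return OEMatrix(chrom=matrix.chrom, binsize=matrix.binsize, values=oe)


def car_pair_windows(cars: CARSet, bins: BinTable, chrom: str,
                     min_sep: int = 15_000, max_sep: int = 100_000,
                     w: int = 5_000) -> tuple[list[tuple[int, int]], int]:
    """Anchor-pair pixel centers with full ±w windows inside the matrix.

    Returns all ordered CAR pairs (m < n) whose separation lies in
    [min_sep, max_sep] and whose window fits in bounds, plus the count of
    pairs skipped for running off a matrix edge. Windows must not cross the
    diagonal, hence min_sep > 2w.
    """
    if min_sep <= 2 * w:
        raise InvalidParameterError(
            f"min_sep ({min_sep}) must exceed twice the window half-width ({2 * w})"
        )
    if max_sep <= min_sep:
        raise InvalidParameterError("max_sep must exceed min_sep")
    anchors = cars.chrom_anchors(chrom)
    abins = anchors // bins.binsize
    n = bins.n_bins(chrom)
    wb = w // bins.binsize
    pairs: list[tuple[int, int]] = []
    skipped = 0
    for m in range(anchors.size):
        for k in range(m + 1, anchors.size):
            sep = int(anchors[k] - anchors[m])
            if sep < min_sep:
                continue
            if sep > max_sep:
                break
            ci, cj = int(abins[m]), int(abins[k])
            if ci - wb < 0 or cj + wb >= n:
                skipped += 1
                continue
            pairs.append((ci, cj))
    return pairs, skipped


def pileup(oe: OEMatrix, windows: list[tuple[int, int]], w: int = 5_000) -> PileupResult:
    """Stack ±w windows around anchor-pair pixels; mean log2(O/E) per pixel.

    NaN O/E pixels are excluded from their pixel's mean with per-pixel
    denominators; a pixel undefined in every window stays NaN.
    """
    if not windows:
        raise EmptyInputError("no anchor-pair windows to stack")
    wb = w // oe.binsize
    size = 2 * wb + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n = oe.n_bins
    for ci, cj in windows:
        if ci - wb < 0 or ci + wb >= n or cj - wb < 0 or cj + wb >= n:
            raise InvalidParameterError(f"window at ({ci},{cj}) out of bounds")
        block = oe.values[ci - wb: ci + wb + 1, cj - wb: cj + wb + 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            logb = np.log2(block)
        ok = np.isfinite(logb)
        acc[ok] += logb[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        mean_map = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    result = PileupResult(map=mean_map, n_windows=len(windows), n_skipped=0,
                          window_bp=w, binsize=oe.binsize)
    try:
        result.enrichment = corner_enrichment(result)
    except (DegenerateInputError, InvalidParameterError):
        result.enrichment = float("nan")
    return result


def corner_enrichment(p: PileupResult, corner_size: int = 3) -> float:
    """Center-pixel O/E over the mean of the four corner blocks, in linear space.

    The pile-up map stores mean log2(O/E); values are exponentiated before
    averaging so the score is a fold-change of linear O/E, matching how
    corner numbers annotate pile-up heatmaps.
    """
    size = p.map.shape[0]
    if corner_size < 1 or corner_size >= (size + 1) // 2:
        raise InvalidParameterError(
            f"corner_size must be in [1, {(size + 1) // 2 - 1}] for a {size}-wide map"
        )
    linear = np.power(2.0, p.map)
    c = size // 2
    center = linear[c, c]
    k = corner_size
    corners = np.concatenate([
        linear[:k, :k].ravel(), linear[:k, -k:].ravel(),
        linear[-k:, :k].ravel(), linear[-k:, -k:].ravel(),
    ])
    corners = corners[np.isfinite(corners)]
    if corners.size == 0 or corners.mean() == 0:
        raise DegenerateInputError("corner blocks contain no defined O/E signal")
    if not np.isfinite(center):
        raise DegenerateInputError("center pixel has no defined O/E signal")
    return float(center / corners.mean())


def car_offset_profile(oe: OEMatrix, cars: CARSet, bins: BinTable, chrom: str,
                       K: int = 5, window: int = 0) -> CAROffsetProfile:
    """Mean O/E at (CAR_m, CAR_{m+k}) pixels for k = 1..K.

    ``window`` > 0 averages a (2*window+1)^2 pixel block around each pair
    pixel instead of the single pixel. NaN pixels are skipped; requires at
    least K+1 anchors on the chromosome.
    """
    anchors = cars.chrom_anchors(chrom)
    if anchors.size < K + 1:
        raise EmptyInputError(
            f"need >= {K + 1} CARs for offsets up to +{K}, have {anchors.size}"
        )
    abins = (anchors // bins.binsize).astype(int)
    n = oe.n_bins
    mean_oe = np.full(K, np.nan)
    n_pairs = np.zeros(K, dtype=np.int64)
    for k in range(1, K + 1):
        vals = []
        for m in range(anchors.size - k):
            i, j = abins[m], abins[m + k]
            lo_i, hi_i = max(i - window, 0), min(i + window + 1, n)
            lo_j, hi_j = max(j - window, 0), min(j + window + 1, n)
            block = oe.values[lo_i:hi_i, lo_j:hi_j]
            v = np.nanmean(block) if np.isfinite(block).any() else np.nan
            if np.isfinite(v):
                vals.append(v)
        if vals:
            mean_oe[k - 1] = float(np.mean(vals))
            n_pairs[k - 1] = len(vals)
    return CAROffsetProfile(offsets=np.arange(1, K + 1), mean_oe=mean_oe,
                            n_pairs=n_pairs)
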