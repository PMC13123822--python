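"""Contact-probability decay curves P(s) and their log-log derivative slopes.

P(s) is the mean contact frequency per valid pixel pair, aggregated on
log-spaced distance bins; the derivative slope d log10 P / d log10 s is the
local decay exponent, whose bumps report characteristic loop sizes. Multiple
chromosomes are pooled by concatenating per-diagonal sums and valid-pair
counts before normalization, giving genome-wide curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import ContactMatrix
from .errors import InvalidParameterError

__all__ = [
    "DecayCurve",
    "SlopeCurve",
    "contact_decay",
    "derivative_slope",
    "band_summary",
    "slope_shift",
    "DISTANCE_BANDS",
]

# Diagnostic distance bands used throughout the mutant-panel comparisons:
# small random loops, the cohesin-dependent ~10 kb regime, the CAR-spacing
# regime, and the loop-expansion regime.
DISTANCE_BANDS: dict[str, tuple[int, int]] = {
    "2-10kb": (2_000, 10_000),
    "10-20kb": (10_000, 20_000),
    "20-50kb": (20_000, 50_000),
    "50-200kb": (50_000, 200_000),
}


@dataclass
class DecayCurve:
    """P(s) on log-spaced distance bins.

    ``edges`` are bin edges in bp (log-spaced by a constant factor); ``p`` is
    the mean contact frequency per valid pixel pair in each bin; ``n_pairs``
    the number of valid pixel pairs aggregated. Bins with zero valid pairs
    are flagged by ``valid`` rather than silently zeroed.
    """

    edges: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray

    @property
    def mids(self) -> np.ndarray:
        """Geometric-mean bin midpoints (bp); log-equally spaced."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def valid(self) -> np.ndarray:
        return self.n_pairs > 0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("distance_bp\tp\tn_pairs\n")
            for m, p, n in zip(self.mids, self.p, self.n_pairs):
                fh.write(f"{m:.6g}\t{p:.10g}\t{int(n)}\n")


@dataclass
class SlopeCurve:
    """d log10 P / d log10 s on the decay curve's usable grid."""

    mids: np.ndarray
    slope: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("distance_bp\tslope\n")
            for m, s in zip(self.mids, self.slope):
                fh.write(f"{m:.6g}\t{s:.10g}\n")


def _diagonal_sums(matrix: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(sum of counts, number of pixel pairs) for each separation diagonal d >= 1."""
    c = matrix.counts
    n = c.shape[0]
    sums = np.array([np.trace(c, offset=d) for d in range(1, n)], dtype=np.float64)
    pairs = np.arange(n - 1, 0, -1, dtype=np.float64)
    return sums, pairs


def contact_decay(matrices: ContactMatrix | list[ContactMatrix],
                  min_sep: int | None = None, max_sep: int | None = None,
                  log_factor: float = 1.25) -> DecayCurve:
    """Mean contact frequency per pixel pair, on log-spaced distance bins.

    Each separation diagonal d contributes its summed counts over all pixel
    pairs (i, i+d), normalized by the number of such pairs, aggregated within
    log bins of constant factor ``log_factor``. The diagonal itself (d = 0)
    is excluded; the default minimum separation is two bins, the conventional
    guard against self-ligation artifacts.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if not matrices:
        raise InvalidParameterError("need at least one matrix")
    binsize = matrices[0].binsize
    if any(m.binsize != binsize for m in matrices):
        raise InvalidParameterError("all matrices must share a binsize")
    if log_factor <= 1.0:
        raise InvalidParameterError(f"log_factor must be > 1, got {log_factor}")

    span = max(m.n_bins for m in matrices) * binsize
    if min_sep is None:
        min_sep = 2 * binsize
    if max_sep is None:
        max_sep = span
    if min_sep < binsize:
        raise InvalidParameterError("min_sep must be >= binsize")
    if max_sep <= min_sep:
        raise InvalidParameterError("empty separation range")

    n_log_bins = int(np.ceil(np.log(max_sep / min_sep) / np.log(log_factor)))
    n_log_bins = max(n_log_bins, 1)
    edges = min_sep * log_factor ** np.arange(n_log_bins + 1)

    sums = np.zeros(n_log_bins)
    pairs = np.zeros(n_log_bins)
    for m in matrices:
        dsums, dpairs = _diagonal_sums(m)
        sep_bp = np.arange(1, m.n_bins) * binsize
        keep = (sep_bp >= min_sep) & (sep_bp < edges[-1])
        idx = np.floor(np.log(sep_bp[keep] / min_sep) / np.log(log_factor)).astype(int)
        idx = np.clip(idx, 0, n_log_bins - 1)
        np.add.at(sums, idx, dsums[keep])
        np.add.at(pairs, idx, dpairs[keep])

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(pairs > 0, sums / np.maximum(pairs, 1), np.nan)
    return DecayCurve(edges=edges, p=p, n_pairs=pairs)


def derivative_slope(curve: DecayCurve, smooth_window: int = 3) -> SlopeCurve:
    """Slope of log10 P vs log10 s on the smoothed decay curve.

    log10 P is smoothed by a centered moving average over ``smooth_window``
    usable bins (endpoints left unsmoothed, where no full window exists);
    the slope uses centered finite differences with one-sided differences at
    the endpoints. Defined only where P > 0 in the smoothing window.
    """
    usable = curve.valid & np.isfinite(curve.p) & (curve.p > 0)
    if usable.sum() < 3:
        raise InvalidParameterError("need >= 3 usable bins with P > 0")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise InvalidParameterError("smooth_window must be a positive odd integer")

    x = np.log10(curve.mids[usable])
    y = np.log10(curve.p[usable])

    ys = y.copy()
    half = smooth_window // 2
    if half and y.size >= smooth_window:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        ys[half:-half] = np.convolve(y, kernel, mode="valid")

    slope = np.gradient(ys, x)
    return SlopeCurve(mids=curve.mids[usable], slope=slope)


def band_summary(curve: DecayCurve,
                 bands: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
    """Valid-pair-weighted mean of P(s) over bins intersecting each named band."""
    if bands is None:
        bands = DISTANCE_BANDS
    lo_edges, hi_edges = curve.edges[:-1], curve.edges[1:]
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        if hi <= curve.edges[0] or lo >= curve.edges[-1]:
            raise InvalidParameterError(
                f"band {name!r} ({lo}-{hi} bp) outside curve range "
                f"({curve.edges[0]:.0f}-{curve.edges[-1]:.0f} bp)"
            )
        mask = (hi_edges > lo) & (lo_edges < hi) & curve.valid & np.isfinite(curve.p)
        w = curve.n_pairs[mask]
        out[name] = float((curve.p[mask] * w).sum() / w.sum()) if w.sum() else float("nan")
    return out


def slope_shift(mutant: SlopeCurve, reference: SlopeCurve,
                band: tuple[float, float]) -> float:
    """Mean slope difference (mutant - reference) over a distance band.

    Positive values in the 50-200 kb band are the loop-expansion signature:
    the mutant's contact frequency decays more slowly (or rises) at long
    range relative to the reference.
    """
    if mutant.mids.shape != reference.mids.shape or not np.allclose(
        mutant.mids, reference.mids
    ):
        raise InvalidParameterError("slope curves must share a distance grid")
    lo, hi = band
    mask = (mutant.mids >= lo) & (mutant.mids < hi)
    if not mask.any():
        raise InvalidParameterError(f"band {band} contains no grid points")
    return float(np.mean(mutant.slope[mask] - reference.slope[mask]))
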