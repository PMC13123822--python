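"""Phenotype comparison report: the mutant-panel workflow end to end.

For each sample (a simulator preset or a matrix file) the report computes
band summaries, derivative-slope shifts against a wild-type reference and a
cohesin-null reference, corner enrichment of the CAR pile-up, and the CAR
offset profile, then classifies each sample for two qualitative phenotypes:

* positioned loops present — corner enrichment at or above a threshold
  (default 1.5), i.e. a center "spot" above the background of random distal
  interactions;
* loop expansion — mean derivative-slope increase over the wild-type
  reference in the 50-200 kb band at or above a threshold (default 0.05).

Both thresholds are explicit calibration constants, tunable from the CLI and
recorded in the report header; classifications are pure functions of the
stored statistics and are invariant to global scaling of the input counts
(both statistics are O/E- or slope-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contacts import ContactMatrix, read_coo, write_coo
from .decay import (
    DISTANCE_BANDS,
    DecayCurve,
    SlopeCurve,
    band_summary,
    contact_decay,
    derivative_slope,
    slope_shift,
)
from .errors import InvalidParameterError
from .genome import CARSet, load_car_sites
from .loops import (
    CAROffsetProfile,
    PileupResult,
    car_offset_profile,
    car_pair_windows,
    corner_enrichment,
    observed_over_expected,
    pileup,
)
from .simulate import (
    SimulationConfig,
    TrajectorySummary,
    config_from_toml,
    preset,
    preset_names,
    simulate,
)

__all__ = [
    "SampleStats",
    "PhenotypeReport",
    "classify_positioned_loops",
    "classify_loop_expansion",
    "analyze_sample",
    "run_panel",
    "run_pipeline",
    "POSITIONED_THRESHOLD",
    "EXPANSION_THRESHOLD",
    "EXPANSION_BAND",
]

POSITIONED_THRESHOLD = 1.5
EXPANSION_THRESHOLD = 0.05
EXPANSION_BAND = (50_000, 200_000)


def classify_positioned_loops(enrichment: float,
                              threshold: float = POSITIONED_THRESHOLD) -> bool:
    """Positioned loops are called present iff corner enrichment >= threshold."""
    if not enrichment > 0 or not math.isfinite(enrichment):
        raise InvalidParameterError(
            f"enrichment must be a positive finite score, got {enrichment}"
        )
    return enrichment >= threshold


def classify_loop_expansion(shift: float,
                            threshold: float = EXPANSION_THRESHOLD) -> bool:
    """Loop expansion is called iff the 50-200 kb slope shift vs WT >= threshold."""
    if shift is None or not math.isfinite(shift):
        raise InvalidParameterError("shift vs the wild-type reference is required")
    return shift >= threshold


@dataclass
class SampleStats:
    """All per-sample statistics the report stores."""

    name: str
    bands: dict[str, float]
    decay: DecayCurve
    slopes: SlopeCurve
    enrichment: float
    offset_profile: CAROffsetProfile | None
    pileup: PileupResult
    mean_loop_size_bp: float = float("nan")
    shift_vs_wt: float = float("nan")
    shift_vs_null: float = float("nan")
    positioned_loops: bool | None = None
    loop_expansion: bool | None = None


@dataclass
class PhenotypeReport:
    samples: list[SampleStats]
    reference: str
    null_reference: str | None
    positioned_threshold: float
    expansion_threshold: float
    parameters: dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row: dict[str, object] = {"sample": s.name}
            row.update({f"p_{k}": v for k, v in s.bands.items()})
            row["corner_enrichment"] = s.enrichment
            row["slope_shift_vs_wt_50-200kb"] = s.shift_vs_wt
            row["slope_shift_vs_null_50-200kb"] = s.shift_vs_null
            row["mean_loop_size_bp"] = s.mean_loop_size_bp
            if s.offset_profile is not None:
                for k, v in zip(s.offset_profile.offsets, s.offset_profile.mean_oe):
                    row[f"car_offset_+{int(k)}"] = v
            row["positioned_loops"] = s.positioned_loops
            row["loop_expansion"] = s.loop_expansion
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        header = (
            f"# carmap {__version__} phenotype report\n"
            f"# reference: {self.reference}  null_reference: {self.null_reference}\n"
            f"# positioned_threshold: {self.positioned_threshold}  "
            f"expansion_threshold: {self.expansion_threshold}\n"
            + "".join(f"# {k}: {v}\n" for k, v in self.parameters.items())
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def analyze_sample(name: str, matrix: ContactMatrix, cars: CARSet,
                   config: SimulationConfig,
                   summary: TrajectorySummary | None = None,
                   pileup_min_sep: int = 15_000, pileup_max_sep: int = 100_000,
                   window: int = 5_000, corner_size: int = 3,
                   log_factor: float = 1.25, smooth_window: int = 3,
                   offset_K: int = 5) -> SampleStats:
    """Compute every per-sample statistic for one contact matrix."""
    bins = config.bins
    curve = contact_decay(matrix, log_factor=log_factor)
    slopes = derivative_slope(curve, smooth_window=smooth_window)
    bands = band_summary(curve, DISTANCE_BANDS)

    oe = observed_over_expected(matrix)
    windows, skipped = car_pair_windows(cars, bins, matrix.chrom,
                                        min_sep=pileup_min_sep,
                                        max_sep=pileup_max_sep, w=window)
    pile = pileup(oe, windows, w=window)
    pile.n_skipped = skipped
    enr = corner_enrichment(pile, corner_size=corner_size)

    n_anchors = cars.chrom_anchors(matrix.chrom).size
    profile = None
    if n_anchors >= offset_K + 1:
        profile = car_offset_profile(oe, cars, bins, matrix.chrom, K=offset_K)

    stats = SampleStats(name=name, bands=bands, decay=curve, slopes=slopes,
                        enrichment=enr, offset_profile=profile, pileup=pile)
    if summary is not None:
        stats.mean_loop_size_bp = summary.mean_loop_size_bp
    return stats


def run_panel(config: SimulationConfig,
              sample_names: list[str] | None = None,
              reference: str = "WT", null_reference: str = "MCD1-AID",
              positioned_threshold: float = POSITIONED_THRESHOLD,
              expansion_threshold: float = EXPANSION_THRESHOLD,
              **analyze_kwargs) -> PhenotypeReport:
    """Simulate the preset panel under one configuration and classify it.

    Every sample uses the same genome, CARs and contact budget so curves and
    pile-ups are directly comparable; only the extruder kinetics differ.
    """
    names = sample_names or preset_names()
    if reference not in names:
        names = [reference] + names
    samples: dict[str, SampleStats] = {}
    chrom = config.genome.names[0]
    for name in names:
        mats, summary = simulate(config, preset(name).params)
        samples[name] = analyze_sample(name, mats[chrom], config.cars, config,
                                       summary=summary, **analyze_kwargs)
    return _classify(list(samples.values()), reference, null_reference,
                     positioned_threshold, expansion_threshold,
                     parameters={"seed": config.seed, "n_cells": config.n_cells,
                                 "binsize": config.binsize})


def _classify(samples: list[SampleStats], reference: str,
              null_reference: str | None, positioned_threshold: float,
              expansion_threshold: float,
              parameters: dict[str, object] | None = None) -> PhenotypeReport:
    by_name = {s.name: s for s in samples}
    if reference not in by_name:
        raise InvalidParameterError(f"missing reference sample {reference!r}")
    ref = by_name[reference]
    null = by_name.get(null_reference) if null_reference else None
    for s in samples:
        s.shift_vs_wt = slope_shift(s.slopes, ref.slopes, EXPANSION_BAND)
        if null is not None:
            s.shift_vs_null = slope_shift(s.slopes, null.slopes, EXPANSION_BAND)
        s.positioned_loops = classify_positioned_loops(s.enrichment,
                                                       positioned_threshold)
        s.loop_expansion = classify_loop_expansion(s.shift_vs_wt,
                                                   expansion_threshold)
    return PhenotypeReport(samples=samples, reference=reference,
                           null_reference=null_reference,
                           positioned_threshold=positioned_threshold,
                           expansion_threshold=expansion_threshold,
                           parameters=parameters or {})


def run_pipeline(config_path: str | Path, outdir: str | Path,
                 log=lambda msg: None) -> PhenotypeReport:
    """Config-driven pipeline: simulate/load samples, compute, classify, write.

    The TOML config names samples as presets or COO matrix files, the CAR
    source, references and thresholds; all outputs are deterministic given
    the seeds in the config. Per sample it writes decay, slope, band,
    pile-up (+sidecar) and offset-profile files, plus report.tsv.
    """
    import tomllib

    config_path = Path(config_path)
    if not config_path.exists():
        raise IOError(f"config file not found: {config_path}")
    doc = tomllib.loads(config_path.read_text())
    base = config_path.parent
    sim_config, _ = config_from_toml(config_path)

    cars = sim_config.cars
    if "car_bed" in doc:
        bed = base / doc["car_bed"]
        if not bed.exists():
            raise IOError(f"CAR BED file not found: {bed}")
        cars = load_car_sites(bed, sim_config.genome)

    sample_table = doc.get("samples", {p: {"preset": p} for p in preset_names()})
    reference = doc.get("reference", "WT")
    null_reference = doc.get("null_reference",
                             "MCD1-AID" if "MCD1-AID" in sample_table else None)
    positioned_threshold = float(doc.get("positioned_threshold",
                                         POSITIONED_THRESHOLD))
    expansion_threshold = float(doc.get("expansion_threshold",
                                        EXPANSION_THRESHOLD))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = sim_config.genome.names[0]
    samples: list[SampleStats] = []
    for name, entry in sample_table.items():
        summary = None
        if "preset" in entry:
            log(f"simulating {name} (preset {entry['preset']})")
            mats, summary = simulate(sim_config, preset(entry["preset"]).params)
            matrix = mats[chrom]
            write_coo(matrix, outdir / f"{name}.coo.tsv")
            summary.write_tsv(outdir / f"{name}.loops.tsv")
        elif "matrix" in entry:
            mpath = base / entry["matrix"]
            if not mpath.exists():
                raise IOError(f"matrix file not found: {mpath}")
            log(f"loading {name} from {mpath}")
            matrix = read_coo(mpath, bins=sim_config.bins)
        else:
            raise InvalidParameterError(
                f"sample {name!r} must name a preset or a matrix file"
            )
        stats = analyze_sample(name, matrix, cars, sim_config, summary=summary)
        stats.decay.write_tsv(outdir / f"{name}.decay.tsv")
        stats.slopes.write_tsv(outdir / f"{name}.slope.tsv")
        with open(outdir / f"{name}.bands.tsv", "w") as fh:
            fh.write("band\tmean_p\n")
            for band, v in stats.bands.items():
                fh.write(f"{band}\t{v:.10g}\n")
        stats.pileup.write(outdir / f"{name}.pileup.txt")
        if stats.offset_profile is not None:
            stats.offset_profile.write_tsv(outdir / f"{name}.offsets.tsv")
        log(f"{name}: enrichment={stats.enrichment:.3g} "
            f"skipped_windows={stats.pileup.n_skipped}")
        samples.append(stats)

    report = _classify(samples, reference, null_reference,
                       positioned_threshold, expansion_threshold,
                       parameters={"seed": sim_config.seed,
                                   "n_cells": sim_config.n_cells,
                                   "binsize": sim_config.binsize,
                                   "config": str(config_path)})
    report.write_tsv(outdir / "report.tsv")
    return report
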