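"""Shared fixtures: small genomes, random matrices, and the simulated panel."""

from __future__ import annotations

import numpy as np
import pytest

import carmap as cm

# Study seed for the simulated mutant panel; every panel statistic in the
# suite derives from this single deterministic run.
PANEL_SEED = 7


def random_contact_matrix(rng: np.random.Generator, n_bins: int,
                          binsize: int = 400, density: float = 0.3,
                          chrom: str = "chrT") -> cm.ContactMatrix:
    """Random symmetric integer count matrix for oracle tests."""
    upper = rng.integers(0, 20, size=(n_bins, n_bins))
    upper[rng.random((n_bins, n_bins)) > density] = 0
    counts = np.triu(upper)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return cm.ContactMatrix(chrom=chrom, binsize=binsize,
                            counts=counts.astype(float))


@pytest.fixture
def small_genome() -> cm.GenomeModel:
    return cm.GenomeModel((("chrV", 100_000), ("chrII", 50_000)))


@pytest.fixture(scope="session")
def panel_config():
    return cm.default_config(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def panel(panel_config):
    """Simulated mutant panel under identical study conditions.

    Maps preset name -> (ContactMatrix, TrajectorySummary). 2,000 cells on a
    500-kb chromosome at 400-bp bins with the shipped CAR ladder.
    """
    out = {}
    for name in cm.preset_names():
        mats, summary = cm.simulate(panel_config, cm.preset(name).params)
        out[name] = (mats["chrSim"], summary)
    return out


@pytest.fixture(scope="session")
def panel_stats(panel, panel_config):
    """Per-preset derived statistics shared by the ordering/classification tests."""
    bins = panel_config.bins
    cars = panel_config.cars
    stats = {}
    for name, (matrix, summary) in panel.items():
        curve = cm.contact_decay(matrix)
        slopes = cm.derivative_slope(curve)
        oe = cm.observed_over_expected(matrix)
        windows, _ = cm.car_pair_windows(cars, bins, "chrSim")
        pile = cm.pileup(oe, windows)
        profile = cm.car_offset_profile(oe, cars, bins, "chrSim")
        stats[name] = {
            "matrix": matrix,
            "summary": summary,
            "slopes": slopes,
            "enrichment": cm.corner_enrichment(pile),
            "offsets": profile.mean_oe,
        }
    return stats
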