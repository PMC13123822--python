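"""O/E normalization, CAR-pair pile-ups, corner scores and offset profiles."""

import numpy as np
import pytest

import carmap as cm
from carmap.errors import EmptyInputError, InvalidParameterError
from carmap.loops import OEMatrix, PileupResult
from conftest import random_contact_matrix


def brute_force_expected(matrix):
    n = matrix.n_bins
    e = np.zeros(n)
    for d in range(n):
        vals = [matrix.counts[i, i + d] for i in range(n - d)]
        e[d] = np.mean(vals)
    return e


def brute_force_pileup(oe, windows, wb):
    size = 2 * wb + 1
    acc, cnt = np.zeros((size, size)), np.zeros((size, size))
    for ci, cj in windows:
        for a in range(size):
            for b in range(size):
                v = oe.values[ci - wb + a, cj - wb + b]
                if np.isfinite(v) and v > 0:
                    acc[a, b] += np.log2(v)
                    cnt[a, b] += 1
    return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def brute_force_corner(map_, corner_size):
    lin = 2.0 ** map_
    c = map_.shape[0] // 2
    k = corner_size
    corners = []
    for block in (lin[:k, :k], lin[:k, -k:], lin[-k:, :k], lin[-k:, -k:]):
        corners.extend(block.ravel().tolist())
    corners = [v for v in corners if np.isfinite(v)]
    return lin[c, c] / np.mean(corners)


class TestExpectedByDistance:
    def test_uniform(self):
        m = cm.ContactMatrix("c", 400, np.full((12, 12), 2.5))
        assert np.allclose(cm.expected_by_distance(m).expected, 2.5)

    def test_single_pixel_counting(self):
        counts = np.zeros((10, 10))
        counts[2, 5] = counts[5, 2] = 14.0
        e = cm.expected_by_distance(cm.ContactMatrix("c", 400, counts)).expected
        assert e[3] == pytest.approx(14.0 / 7)
        assert np.all(e[np.arange(10) != 3] == 0)

    @pytest.mark.parametrize("seed", [0, 7, 13])
    def test_brute_force_oracle(self, seed):
        m = random_contact_matrix(np.random.default_rng(seed), 25)
        assert np.allclose(cm.expected_by_distance(m).expected,
                           brute_force_expected(m), rtol=0, atol=1e-12)


class TestObservedOverExpected:
    def test_diagonal_means_are_one(self):
        m = random_contact_matrix(np.random.default_rng(4), 30)
        oe = cm.observed_over_expected(m)
        n = m.n_bins
        for d in range(n):
            vals = np.array([oe.values[i, i + d] for i in range(n - d)])
            defined = vals[np.isfinite(vals)]
            if defined.size:
                assert abs(defined.mean() - 1.0) < 1e-9

    def test_uniform_matrix_gives_ones(self):
        m = cm.ContactMatrix("c", 400, np.full((10, 10), 3.0))
        oe = cm.observed_over_expected(m)
        assert np.allclose(oe.values, 1.0)

    def test_zero_diagonal_is_undefined_not_zero(self):
        counts = np.full((10, 10), 2.0)
        for i in range(7):
            counts[i, i + 3] = counts[i + 3, i] = 0.0
        oe = cm.observed_over_expected(cm.ContactMatrix("c", 400, counts))
        assert np.all(np.isnan([oe.values[i, i + 3] for i in range(7)]))


class TestCarPairWindows:
    def make_cars(self, genome, anchors_bp):
        return cm.CARSet(genome=genome,
                         anchors={"chrT": np.array(anchors_bp, dtype=int)})

    def test_hand_enumeration(self):
        # CARs at bins 10, 40, 70 (binsize 100); separations 20-40 bins,
        # window 5 bins: pairs (10,40) and (40,70) only
        genome = cm.GenomeModel((("chrT", 10_000),))
        bins = cm.bin_genome(genome, 100)
        cars = self.make_cars(genome, [1_050, 4_050, 7_050])
        pairs, skipped = cm.car_pair_windows(cars, bins, "chrT",
                                             min_sep=2_000, max_sep=4_000,
                                             w=500)
        assert pairs == [(10, 40), (40, 70)]
        assert skipped == 0

    def test_close_anchors_filtered(self):
        genome = cm.GenomeModel((("chrT", 10_000),))
        bins = cm.bin_genome(genome, 100)
        cars = self.make_cars(genome, [4_000, 4_500, 5_000])
        pairs, _ = cm.car_pair_windows(cars, bins, "chrT",
                                       min_sep=2_000, max_sep=4_000, w=500)
        assert pairs == []

    def test_edge_windows_skipped_and_counted(self):
        genome = cm.GenomeModel((("chrT", 10_000),))
        bins = cm.bin_genome(genome, 100)
        cars = self.make_cars(genome, [200, 3_050, 9_900])
        pairs, skipped = cm.car_pair_windows(cars, bins, "chrT",
                                             min_sep=2_000, max_sep=8_000,
                                             w=500)
        assert skipped == 2  # both pairs involving an edge anchor
        assert pairs == []

    def test_window_crossing_diagonal_rejected(self):
        genome = cm.GenomeModel((("chrT", 10_000),))
        bins = cm.bin_genome(genome, 100)
        cars = self.make_cars(genome, [1_050, 4_050])
        with pytest.raises(InvalidParameterError):
            cm.car_pair_windows(cars, bins, "chrT", min_sep=1_000,
                                max_sep=4_000, w=500)


class TestPileup:
    def test_flat_oe_gives_zero_map(self):
        oe = OEMatrix("c", 400, np.ones((40, 40)))
        result = cm.pileup(oe, [(10, 30)], w=2_000)
        assert np.allclose(result.map, 0.0)
        assert result.n_windows == 1

    def test_center_mean_in_log2(self):
        vals = np.ones((40, 40))
        vals[10, 30] = vals[30, 10] = 2.0
        vals[12, 32] = vals[32, 12] = 8.0
        oe = OEMatrix("c", 400, vals)
        result = cm.pileup(oe, [(10, 30), (12, 32)], w=2_000)
        c = result.map.shape[0] // 2
        assert result.map[c, c] == pytest.approx(2.0)  # (1 + 3) / 2

    def test_zero_windows_rejected(self):
        oe = OEMatrix("c", 400, np.ones((20, 20)))
        with pytest.raises(EmptyInputError):
            cm.pileup(oe, [], w=2_000)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_contact_matrix(rng, 60)
        oe = cm.observed_over_expected(m)
        windows = [(int(rng.integers(6, 25)), int(rng.integers(35, 54)))
                   for _ in range(6)]
        result = cm.pileup(oe, windows, w=2_000)
        expected = brute_force_pileup(oe, windows, 5)
        assert np.allclose(result.map, expected, equal_nan=True)


class TestCornerEnrichment:
    def flat(self, size=25):
        return PileupResult(map=np.zeros((size, size)), n_windows=1,
                            n_skipped=0, window_bp=4_800, binsize=400)

    def test_flat_map_scores_one(self):
        assert cm.corner_enrichment(self.flat()) == pytest.approx(1.0)

    def test_center_over_corners(self):
        p = self.flat()
        p.map[:] = 1.0  # oe 2 everywhere
        p.map[12, 12] = 2.0  # oe 4 at center
        assert cm.corner_enrichment(p) == pytest.approx(2.0)

    def test_corner_size_bounds(self):
        with pytest.raises(InvalidParameterError):
            cm.corner_enrichment(self.flat(), corner_size=13)
        with pytest.raises(InvalidParameterError):
            cm.corner_enrichment(self.flat(), corner_size=0)

    @pytest.mark.parametrize("seed", [1, 9])
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = self.flat()
        p.map = rng.normal(0, 1, size=(25, 25))
        for corner_size in (1, 3, 5):
            assert cm.corner_enrichment(p, corner_size) == pytest.approx(
                brute_force_corner(p.map, corner_size)
            )


class TestCarOffsetProfile:
    def setup_oe(self, anchors_bins, values, n=100, binsize=400):
        genome = cm.GenomeModel((("chrT", n * binsize),))
        bins = cm.bin_genome(genome, binsize)
        cars = cm.CARSet(genome=genome, anchors={
            "chrT": np.array(anchors_bins) * binsize + binsize // 2})
        oe = OEMatrix("chrT", binsize, values)
        return oe, cars, bins

    def test_uniform_oe(self):
        anchors = [10, 25, 40, 55, 70, 85]
        oe, cars, bins = self.setup_oe(anchors, np.ones((100, 100)))
        profile = cm.car_offset_profile(oe, cars, bins, "chrT", K=5)
        assert np.allclose(profile.mean_oe, 1.0)
        assert np.all(np.diff(profile.n_pairs) < 0)

    def test_constructed_pair_signal(self):
        anchors = [10, 25, 40, 55, 70, 85]
        vals = np.ones((100, 100))
        for m in range(len(anchors) - 1):
            i, j = anchors[m], anchors[m + 1]
            vals[i, j] = vals[j, i] = 3.0
        for m in range(len(anchors) - 2):
            i, j = anchors[m], anchors[m + 2]
            vals[i, j] = vals[j, i] = 1.5
        oe, cars, bins = self.setup_oe(anchors, vals)
        profile = cm.car_offset_profile(oe, cars, bins, "chrT", K=3)
        assert profile.mean_oe[0] == pytest.approx(3.0)
        assert profile.mean_oe[1] == pytest.approx(1.5)
        assert profile.mean_oe[2] == pytest.approx(1.0)

    def test_too_few_cars_rejected(self):
        oe, cars, bins = self.setup_oe([10, 25, 40], np.ones((100, 100)))
        with pytest.raises(EmptyInputError):
            cm.car_offset_profile(oe, cars, bins, "chrT", K=5)

    def test_simulated_wild_type_profile_decays(self, panel_stats):
        offsets = panel_stats["WT"]["offsets"]
        assert np.all(np.diff(offsets) <= 0)
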