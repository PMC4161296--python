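"""Landscape families and the rugged-landscape approximation operators."""

import numpy as np
import pytest

from peakwalk import (
    BroadPeakLandscape,
    EmptyTargetError,
    MultiPeakLandscape,
    MultiplicativeLandscape,
    SequenceSpace,
    TabulatedLandscape,
    find_local_maxima,
    generate_rugged,
    greedy_basin,
    plateau_approximate,
    threshold_binarize,
)


class TestBroadPeak:
    def test_membership_and_fitness(self):
        space = SequenceSpace(4)
        land = BroadPeakLandscape(space, "AAAA", 1, target_advantage=2.0)
        assert land.in_target("AAAA") and land.in_target("AAAC")
        assert not land.in_target("AACC")
        assert land.fitness("AAAC") == 2.0 and land.fitness("AACC") == 1.0
        assert land.target_size() == 13

    def test_from_fraction(self):
        space = SequenceSpace(10)
        land = BroadPeakLandscape.from_fraction(space, "A" * 10, 0.55)
        assert land.w == 5

    def test_width_bounds(self):
        with pytest.raises(ValueError):
            BroadPeakLandscape(SequenceSpace(4), "AAAA", 5)


class TestMultiPeak:
    def test_min_distance_membership_brute_force(self, rng):
        space = SequenceSpace(6)
        land = MultiPeakLandscape.random(space, 3, 1, rng)
        for _ in range(200):
            s = space.random_sequence(rng)
            d = min(sum(a != b for a, b in zip(s, c)) for c in land.centers)
            assert land.in_target(s) == (d <= 1)
            assert land.distance(s) == d

    def test_needs_center(self):
        with pytest.raises(ValueError):
            MultiPeakLandscape(SequenceSpace(4), (), 1)


class TestMultiplicative:
    def test_gradient(self):
        space = SequenceSpace(5)
        land = MultiplicativeLandscape(space, "AAAAA", 0.1, 1)
        assert land.fitness("AAAAA") == pytest.approx(1.1**5)
        assert land.fitness("CCCCC") == pytest.approx(1.0)

    def test_sigma_zero_is_flat(self):
        space = SequenceSpace(5)
        land = MultiplicativeLandscape(space, "AAAAA", 0.0, 1)
        for s in ("AAAAA", "ACGTA", "TTTTT"):
            assert land.fitness(s) == 1.0


class TestGenerateRugged:
    def test_noise_free_cone_peaks_at_anchor(self, rng):
        space = SequenceSpace(3)
        land = generate_rugged(space, "ACG", slope=1.0, noise_sd=0.0, rng=rng)
        assert find_local_maxima(land) == ["ACG"]

    def test_seeded_reproducibility(self):
        space = SequenceSpace(3)
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        l1 = generate_rugged(space, "AAA", 1.0, 2.0, r1)
        l2 = generate_rugged(space, "AAA", 1.0, 2.0, r2)
        assert all(l1.fitness(s) == l2.fitness(s) for s in space.iter_sequences())

    def test_pure_noise_local_maxima_fraction(self):
        """For an i.i.d. random field the chance a sequence beats all its
        3L neighbors is 1/(3L+1); check the empirical count over seeds."""
        space = SequenceSpace(4)
        n_seeds = 20
        counts = [
            len(
                find_local_maxima(
                    generate_rugged(space, "A" * 4, 0.0, 10.0, np.random.default_rng(s))
                )
            )
            for s in range(n_seeds)
        ]
        expected = space.size / (3 * space.L + 1)  # 256/13 ~ 19.7
        assert abs(np.mean(counts) - expected) < 3.0

    def test_capacity_guard(self, rng):
        space = SequenceSpace(11)  # 4**11 > 1e6
        with pytest.raises(ValueError):
            generate_rugged(space, "A" * 11, 1.0, 1.0, rng)


class TestLocalMaximaAndBasins:
    def test_constant_landscape_no_strict_maxima(self):
        space = SequenceSpace(2, "01")
        land = TabulatedLandscape(space, {s: 1.0 for s in space.iter_sequences()})
        assert find_local_maxima(land) == []

    def test_worked_example_maxima(self, tiny_table):
        assert set(find_local_maxima(tiny_table)) == {"00", "11"}

    def test_greedy_fixed_point(self, tiny_table):
        assert greedy_basin(tiny_table, "00") == "00"
        assert greedy_basin(tiny_table, "11") == "11"

    def test_greedy_best_improving_neighbor(self, tiny_table):
        # neighbors of 01 are 00 (5) and 11 (3); steepest ascent goes to 00
        assert greedy_basin(tiny_table, "01") == "00"
        assert greedy_basin(tiny_table, "10") == "00"

    def test_basins_partition_space(self, rng):
        space = SequenceSpace(4)
        land = generate_rugged(space, "AAAA", 0.5, 2.0, rng)
        maxima = set(find_local_maxima(land))
        peaks = {s: greedy_basin(land, s) for s in space.iter_sequences()}
        assert set(peaks.values()) <= maxima
        assert len(peaks) == space.size  # every sequence in exactly one basin


class TestThresholdBinarize:
    def test_worked_example(self, tiny_table):
        approx = threshold_binarize(tiny_table, 3.0)
        assert approx.target == {"00", "11"}
        assert approx.fitness("01") == 1.0 and approx.fitness("00") == 2.0

    def test_low_threshold_whole_space(self, tiny_table):
        assert threshold_binarize(tiny_table, 0.5).target == {"00", "01", "10", "11"}

    def test_empty_target_flagged(self, tiny_table):
        with pytest.raises(EmptyTargetError):
            threshold_binarize(tiny_table, 6.0)


class TestPlateauApproximate:
    def test_worked_example(self, tiny_table):
        approx = plateau_approximate(tiny_table, 5.0)
        # 00, 01, 10 all greedy-ascend to 00 (fitness 5); 11 is its own
        # sub-threshold peak (fitness 3 = f_max)
        assert approx.target == {"00", "01", "10"}
        assert approx.fitness("11") == 3.0
        assert approx.fitness("00") == 5.0  # target fitness untouched

    def test_single_basin_cone(self, rng):
        space = SequenceSpace(3)
        land = generate_rugged(space, "AAA", 1.0, 0.0, rng)
        approx = plateau_approximate(land, land.max_fitness())
        assert approx.target == set(space.iter_sequences())

    def test_more_lenient_than_threshold(self, rng):
        space = SequenceSpace(4)
        for seed in range(5):
            land = generate_rugged(
                space, "AAAA", 0.5, 2.0, np.random.default_rng(seed)
            )
            f_star = np.percentile([f for _, f in land.items()], 90)
            thr = threshold_binarize(land, f_star)
            plat = plateau_approximate(land, f_star)
            assert thr.target <= plat.target

    def test_complement_exactly_flat(self, rng):
        space = SequenceSpace(3)
        land = generate_rugged(space, "AAA", 0.5, 2.0, rng)
        f_star = land.max_fitness()  # only the global peak's basin qualifies
        plat = plateau_approximate(land, f_star)
        outside = {plat.fitness(s) for s in space.iter_sequences() if s not in plat.target}
        assert len(outside) <= 1


def test_tabulated_file_round_trip(tmp_path, tiny_table):
    approx = threshold_binarize(tiny_table, 3.0)
    path = tmp_path / "land.txt"
    approx.to_file(path)
    back = TabulatedLandscape.from_file(path)
    assert back.target == approx.target
    assert all(back.fitness(s) == approx.fitness(s) for s in back.space.iter_sequences())
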