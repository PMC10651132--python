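"""Two-color matching, the flipped-channel chance control, and densities."""

import itertools

import numpy as np
import pytest

from stapull import (
    MatchParams,
    Spot,
    SpotSet,
    chance_coincidence,
    flip_spotset,
    fov_result,
    match_spots,
    summarize_sample,
)


def make_set(coords, shape=(100, 100), pixel_size_um=0.1, fov=""):
    spots = [Spot(x, y, 10.0, 10.0, 5) for x, y in coords]
    return SpotSet(spots, shape, pixel_size_um, fov=fov)


def brute_force_min_total_distance(coords_a, coords_b, radius):
    """Best one-to-one matching by exhaustive enumeration (small sets only)."""
    best = []
    best_cost = None
    na, nb = len(coords_a), len(coords_b)
    for k in range(min(na, nb), -1, -1):
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.permutations(range(nb), k):
                pairs = list(zip(ia, ib))
                ds = [
                    np.hypot(
                        coords_a[i][0] - coords_b[j][0], coords_a[i][1] - coords_b[j][1]
                    )
                    for i, j in pairs
                ]
                if any(d > radius for d in ds):
                    continue
                cost = sum(ds)
                if best_cost is None or (len(pairs), -cost) > (len(best), -best_cost):
                    best, best_cost = pairs, cost
        if best:
            break
    return best


class TestMatchSpots:
    def test_within_two_pixels_matches(self):
        m = match_spots(make_set([(10, 10)]), make_set([(11, 11)]))
        assert len(m) == 1
        assert m[0].distance_px == pytest.approx(np.sqrt(2))

    def test_beyond_radius_no_match(self):
        assert match_spots(make_set([(10, 10)]), make_set([(12.5, 10)])) == []

    def test_greedy_picks_nearest_of_two_candidates(self):
        m = match_spots(make_set([(0, 0)]), make_set([(1, 0), (1.5, 0)]))
        assert len(m) == 1
        assert m[0].spot_b.x == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_maximal_matching_oracle(self, seed):
        """Greedy one-to-one agrees in cardinality with brute-force optimum."""
        rng = np.random.default_rng(seed)
        ca = [tuple(p) for p in rng.uniform(0, 20, (5, 2))]
        cb = [tuple(p) for p in rng.uniform(0, 20, (5, 2))]
        got = match_spots(make_set(ca), make_set(cb), MatchParams(2.0))
        oracle = brute_force_min_total_distance(ca, cb, 2.0)
        assert len(got) == len(oracle)

    def test_symmetry_of_match_count(self):
        rng = np.random.default_rng(3)
        ca = [tuple(p) for p in rng.uniform(0, 50, (20, 2))]
        cb = [tuple(p) for p in rng.uniform(0, 50, (25, 2))]
        assert len(match_spots(make_set(ca), make_set(cb))) == len(
            match_spots(make_set(cb), make_set(ca))
        )

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(4)
        ca = [tuple(p) for p in rng.uniform(0, 50, (30, 2))]
        cb = [tuple(p) for p in rng.uniform(0, 50, (30, 2))]
        counts = [
            len(match_spots(make_set(ca), make_set(cb), MatchParams(r)))
            for r in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            match_spots(make_set([(1, 1)]), make_set([(1, 1)], shape=(50, 50)))


class TestChanceCoincidence:
    def test_empty_channel_gives_zero(self):
        assert chance_coincidence(make_set([(10, 10)]), make_set([])) == 0

    def test_center_spot_is_fixed_point_of_flip(self):
        center = ((100 - 1) / 2, (100 - 1) / 2)
        assert chance_coincidence(make_set([center]), make_set([center])) == 1

    def test_flip_maps_corners(self):
        flipped = flip_spotset(make_set([(0, 0), (99, 99)]))
        coords = flipped.coordinates()
        np.testing.assert_allclose(coords, [[99, 99], [0, 0]])

    def test_sparse_poisson_chance_rate(self):
        """Cross-channel pairs within r match n1*n2*pi*r^2/A on average.

        The analytic rate counts candidate pairs; the one-to-one match count
        sits slightly below it at 0.01 spots/px^2 because a spot can have
        several in-radius partners but claims only one.
        """
        from scipy.spatial import cKDTree

        rng = np.random.default_rng(11)
        shape = (100, 100)
        pairs, matches, pred = [], [], []
        for _ in range(300):
            n1, n2 = 100, 100  # 0.01 spots/px^2
            ca = rng.uniform(0, 99, (n1, 2))
            cb = rng.uniform(0, 99, (n2, 2))
            a = make_set([tuple(p) for p in ca], shape)
            b = make_set([tuple(p) for p in cb], shape)
            flipped = 99.0 - cb
            pairs.append(
                cKDTree(ca).count_neighbors(cKDTree(flipped), 2.0)
            )
            matches.append(chance_coincidence(a, b, MatchParams(2.0)))
            pred.append(n1 * n2 * np.pi * 4 / (100 * 100))
        diff = np.array(pairs, dtype=float) - np.array(pred)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se
        # one-to-one saturation deficit stays below 20% at this density
        assert np.mean(matches) == pytest.approx(np.mean(pred), rel=0.2)


class TestFovResult:
    def test_arithmetic_of_densities(self):
        # constructed counts: the density formulas are plain arithmetic
        rng = np.random.default_rng(0)
        shape = (100, 100)
        px = np.sqrt(1000.0) / 100  # area exactly 1000 um^2
        a = make_set([(i * 3.0, 50.0) for i in range(10)], shape, px)
        b = make_set([(i * 3.0, 50.0) for i in range(7)], shape, px)
        r = fov_result(a, b, MatchParams(1.0))
        assert r.n_coincident == 7
        assert r.area_um2 == pytest.approx(1000.0)
        assert r.corrected_density == pytest.approx((7 - r.n_chance) / 1000.0)
        assert r.total_density == pytest.approx((10 + 7 - 7) / 1000.0)

    def test_blank_fov_all_zero(self):
        r = fov_result(make_set([]), make_set([]))
        assert r.n_coincident == r.n_chance == 0
        assert r.corrected_density == 0.0 and r.total_density == 0.0

    def test_negative_corrected_density_preserved_signed(self):
        # channel-B spots land on channel-A positions only after the flip,
        # so chance matches exceed direct ones
        a = make_set([(10, 10), (20, 80)])
        b = make_set([(89, 89), (79, 19)])
        r = fov_result(a, b)
        assert r.n_coincident == 0 and r.n_chance == 2
        assert r.corrected_density < 0

    def test_coincident_multiplicity_switch(self):
        a = make_set([(10, 10), (30, 30)])
        b = make_set([(10.5, 10)])
        r2 = fov_result(a, b, coincident_multiplicity=2)
        assert r2.total_density == pytest.approx((2 + 1 - 2 * 1) / a.area_um2)


class TestSampleSummary:
    def test_identical_fovs_mean_equals_single(self):
        a = make_set([(10, 10), (40, 70)], fov="0")
        b = make_set([(10.4, 10.2)], fov="0")
        single = fov_result(a, b)
        summary = summarize_sample([single] * 64)
        assert summary.mean_corrected_density == pytest.approx(single.corrected_density)
        assert summary.sd_corrected_density == pytest.approx(0.0, abs=1e-12)

    def test_fraction_oligomeric_ratio_definition(self):
        # 445 coincident of 1000 total detections -> 0.445
        shape = (1000, 1000)
        coincident = [(float(5 + 2 * i), 11.0) for i in range(445)]
        extra_a = [(float(5 + 2 * i), 600.0) for i in range(300)]
        extra_b = [(float(5 + 2 * i), 300.0) for i in range(255)]
        a = make_set(coincident + extra_a, shape)
        b = make_set([(x, y + 0.5) for x, y in coincident] + extra_b, shape)
        r = fov_result(a, b)
        assert r.n_coincident == 445
        s = summarize_sample([r])
        assert s.fraction_oligomeric_raw == pytest.approx(445 / 1000)
        assert s.fraction_oligomeric == pytest.approx((445 - r.n_chance) / 1000)

    def test_negative_pooled_coincidence_clamps_to_zero(self):
        a = make_set([(10, 10), (20, 80)])
        b = make_set([(89, 89), (79, 19)])
        r = fov_result(a, b)
        assert r.n_coincident - r.n_chance < 0
        s = summarize_sample([r])
        assert s.fraction_oligomeric == 0.0 and s.clamped

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample([])

    def test_monomer_only_sample_fraction_near_zero(self):
        from stapull import DetectionParams, SceneSpec, simulate_scene, stapull_fov

        results = []
        for seed in range(15):
            spec = SceneSpec(
                fov_shape_px=(128, 128),
                monomer_density_per_um2=0.05,
                oligomer_density_per_um2=0.0,
                n_frames=2,
                seed=200 + seed,
            )
            _, s1, s2 = simulate_scene(spec)
            results.append(stapull_fov(s1, s2, DetectionParams()))
        s = summarize_sample(results)
        assert s.fraction_oligomeric < 0.05
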