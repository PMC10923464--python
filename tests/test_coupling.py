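"""Ring-wise Ripley statistics: oracles, edge correction, probabilities."""

import numpy as np
import pytest

from sodamap import (
    CellMask,
    EdgeWeights,
    RingSpec,
    SpotSet,
    coupling_probabilities,
    edge_weight,
    null_moments,
    pair_distances,
    ripley_profile,
    run_soda,
)
from sodamap.coupling import RipleyProfile


def brute_force_pairs(s1, s2, rings):
    """O(N1*N2) reference: explicit double loop with half-open ring binning."""
    out = []
    radii = rings.radii
    for i, p in enumerate(s1.positions):
        for j, q in enumerate(s2.positions):
            d = float(np.sqrt(((p - q) ** 2).sum()))
            if d >= radii[-1]:
                continue
            for k in range(rings.n_rings):
                if radii[k] <= d < radii[k + 1]:
                    out.append((i, j, round(d, 9), k))
                    break
    return sorted(out)


def brute_force_khat(s1, s2, rings, mask, weights):
    """Reference K_hat: double loop, per-pair scalar weight calls."""
    k_hat = np.zeros(rings.n_rings)
    radii = rings.radii
    for p in s1.positions:
        for q in s2.positions:
            d = float(np.sqrt(((p - q) ** 2).sum()))
            if not 0 <= d < radii[-1]:
                continue
            k = int(np.searchsorted(radii, d, side="right")) - 1
            w = weights.weights(p[None], np.array([d]))[0] if d > 0 else 1.0
            k_hat[k] += w
    return mask.measure / (s1.n * s2.n) * k_hat


class TestPairDistances:
    def test_single_pair_in_first_ring(self):
        s1 = SpotSet(np.array([[0.0, 0.0]]))
        s2 = SpotSet(np.array([[0.0, 5.0]]))
        i, j, d, ring = pair_distances(s1, s2, RingSpec(np.array([0.0, 10.0])))
        assert len(i) == 1 and d[0] == 5.0 and ring[0] == 0

    def test_boundary_distance_goes_to_outer_ring(self):
        s1 = SpotSet(np.array([[0.0, 0.0]]))
        s2 = SpotSet(np.array([[0.0, 10.0]]))
        rings = RingSpec(np.array([0.0, 10.0, 20.0]))
        _, _, d, ring = pair_distances(s1, s2, rings)
        assert d[0] == 10.0 and ring[0] == 1

    def test_beyond_last_ring_excluded(self):
        s1 = SpotSet(np.array([[0.0, 0.0]]))
        s2 = SpotSet(np.array([[0.0, 20.0]]))
        i, *_ = pair_distances(s1, s2, RingSpec(np.array([0.0, 20.0])))
        assert len(i) == 0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(42)
        box = 10_000.0  # 10 um
        s1 = SpotSet(rng.uniform(0, box, (200, 2)))
        s2 = SpotSet(rng.uniform(0, box, (200, 2)))
        rings = RingSpec.uniform(100.0, 5)  # r_max 500 nm
        i, j, d, ring = pair_distances(s1, s2, rings)
        got = sorted(zip(i.tolist(), j.tolist(), np.round(d, 9).tolist(), ring.tolist()))
        assert got == brute_force_pairs(s1, s2, rings)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pair_distances(
                SpotSet(np.zeros((1, 2))), SpotSet(np.zeros((1, 3))),
                RingSpec(np.array([0.0, 10.0])),
            )


class TestEdgeWeights:
    def test_interior_point_weight_one(self):
        mask = CellMask(np.ones((100, 100), bool), 100.0)
        assert edge_weight(np.array([5000.0, 5000.0]), 800.0, mask) == 1.0

    def test_half_plane_edge(self):
        grid = np.zeros((100, 100), bool)
        grid[:, 50:] = True
        mask = CellMask(grid, 100.0)
        w = edge_weight(np.array([5000.0, 5000.0]), 800.0, mask)
        assert w == pytest.approx(2.0, abs=0.02)

    def test_quarter_plane_corner(self):
        grid = np.zeros((100, 100), bool)
        grid[50:, 50:] = True
        mask = CellMask(grid, 100.0)
        w = edge_weight(np.array([5000.0, 5000.0]), 800.0, mask)
        assert w == pytest.approx(4.0, abs=0.05)

    def test_3d_half_space(self):
        grid = np.zeros((40, 40, 40), bool)
        grid[20:, :, :] = True
        mask = CellMask(grid, 100.0)
        w = edge_weight(np.array([2000.0, 2000.0, 2000.0]), 500.0, mask)
        assert w == pytest.approx(2.0, abs=0.05)

    def test_weight_capped_at_20(self):
        grid = np.zeros((100, 100), bool)
        grid[50, 50] = True
        mask = CellMask(grid, 100.0)
        w = edge_weight(np.array([5050.0, 5050.0]), 4000.0, mask)
        assert w == 20.0

    def test_point_outside_mask_raises(self):
        grid = np.zeros((10, 10), bool)
        grid[0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            edge_weight(np.array([500.0, 500.0]), 10.0, CellMask(grid, 100.0))


class TestRipleyProfile:
    def test_single_pair_arithmetic(self):
        # |Omega| = 10^6 nm^2 (100x100 px at 10 nm), one pair at d = 5 nm
        mask = CellMask(np.ones((100, 100), bool), 10.0)
        s1 = SpotSet(np.array([[500.0, 500.0]]))
        s2 = SpotSet(np.array([[500.0, 505.0]]))
        prof = ripley_profile(s1, s2, RingSpec(np.array([0.0, 10.0])), mask)
        assert prof.k_hat[0] == pytest.approx(1e6)
        assert prof.ring_measure[0] == pytest.approx(np.pi * 100.0)

    def test_no_pairs_gives_zero(self, rectangle_mask, default_rings):
        s1 = SpotSet(np.array([[5000.0, 2000.0]]))
        s2 = SpotSet(np.array([[5000.0, 8000.0]]))
        prof = ripley_profile(s1, s2, default_rings, rectangle_mask)
        assert (prof.k_hat == 0).all()

    def test_matches_bruteforce_khat(self, rectangle_mask):
        rng = np.random.default_rng(11)
        rings = RingSpec.uniform(100.0, 6)
        weights = EdgeWeights(rectangle_mask)
        pts1 = rectangle_mask.sample_uniform(50, rng)
        pts2 = rectangle_mask.sample_uniform(50, rng)
        s1, s2 = SpotSet(pts1), SpotSet(pts2)
        prof = ripley_profile(s1, s2, rings, rectangle_mask, weights=weights)
        oracle = brute_force_khat(s1, s2, rings, rectangle_mask, weights)
        np.testing.assert_allclose(prof.k_hat, oracle, rtol=1e-9)

    def test_empty_spot_set_raises(self, rectangle_mask, default_rings):
        with pytest.raises(ValueError):
            ripley_profile(
                SpotSet(np.empty((0, 2))), SpotSet(np.array([[5000.0, 5000.0]])),
                default_rings, rectangle_mask,
            )


class TestNullMoments:
    def test_mc_mean_matches_ring_measure(self, rectangle_mask):
        rng = np.random.default_rng(5)
        # interior reference spots: circles never leave the mask
        pts = rng.uniform(2000.0, 8000.0, (40, 2))
        rings = RingSpec.uniform(150.0, 4)
        mean, sd = null_moments(SpotSet(pts), 60, rings, rectangle_mask,
                                n_resamples=400, seed=9)
        a = rings.ring_measures(2)
        se = sd / np.sqrt(400)
        assert (np.abs(mean - a) <= 3 * se).all()

    def test_mc_sd_stable_in_resample_count(self, rectangle_mask):
        rng = np.random.default_rng(6)
        pts = rng.uniform(2000.0, 8000.0, (40, 2))
        rings = RingSpec.uniform(150.0, 2)
        _, sd_small = null_moments(SpotSet(pts), 60, rings, rectangle_mask,
                                   n_resamples=100, seed=1)
        _, sd_big = null_moments(SpotSet(pts), 60, rings, rectangle_mask,
                                 n_resamples=1000, seed=1)
        assert (np.abs(sd_small - sd_big) / sd_big <= 0.25).all()

    def test_tiny_counts_and_huge_ring_stay_finite(self):
        mask = CellMask(np.ones((20, 20), bool), 100.0)
        s1 = SpotSet(np.array([[1000.0, 1000.0]]))
        rings = RingSpec(np.array([0.0, 10_000.0]))
        mean, sd = null_moments(s1, 1, rings, mask, n_resamples=100, seed=4)
        assert np.isfinite(mean).all() and np.isfinite(sd).all()

    def test_deterministic_given_seed(self, rectangle_mask, default_rings):
        s1 = SpotSet(np.array([[5000.0, 5000.0], [4000.0, 6000.0]]))
        a = null_moments(s1, 10, default_rings, rectangle_mask, n_resamples=50, seed=3)
        b = null_moments(s1, 10, default_rings, rectangle_mask, n_resamples=50, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


def _profile_from(k_hat, a, pairs):
    """Hand-built profile: pairs is a list of (i, j, d, ring)."""
    k_hat, a = np.asarray(k_hat, float), np.asarray(a, float)
    rings = RingSpec(100.0 * np.arange(len(k_hat) + 1, dtype=float))
    i, j, d, ring = (
        np.array([p[0] for p in pairs], dtype=np.int64),
        np.array([p[1] for p in pairs], dtype=np.int64),
        np.array([p[2] for p in pairs], dtype=float),
        np.array([p[3] for p in pairs], dtype=np.int64),
    )
    return RipleyProfile(
        rings=rings, k_hat=k_hat, ring_measure=a, n1=int(i.max(initial=-1)) + 1 or 1,
        n2=int(j.max(initial=-1)) + 1 or 1, mask_measure=1e8,
        pair_i=i, pair_j=j, pair_d=d, pair_ring=ring, pair_w=np.ones(len(i)),
    )


class TestCouplingProbabilities:
    def test_doubled_khat_gives_half_probability(self):
        prof = _profile_from([200.0], [100.0], [(0, 0, 50.0, 0)])
        res = coupling_probabilities(prof, (np.array([100.0]), np.array([1.0])), 0.05)
        assert res.p_ring[0] == pytest.approx(0.5)
        assert res.pair_prob[0] == pytest.approx(0.5)

    def test_deficit_gives_zero_probability(self):
        prof = _profile_from([80.0], [100.0], [(0, 0, 50.0, 0)])
        res = coupling_probabilities(prof, (np.array([100.0]), np.array([1e-6])), 0.05)
        assert res.p_ring[0] == 0.0 and res.n_coupled == 0.0
        assert np.isnan(res.mean_distance)

    def test_insignificant_excess_gives_zero(self):
        prof = _profile_from([110.0], [100.0], [(0, 0, 50.0, 0)])
        res = coupling_probabilities(prof, (np.array([100.0]), np.array([100.0])), 0.05)
        assert res.p_ring[0] == 0.0

    def test_weighted_distance_moments(self):
        prof = _profile_from(
            [400.0], [100.0], [(0, 0, 40.0, 0), (0, 1, 60.0, 0)]
        )
        res = coupling_probabilities(prof, (np.array([100.0]), np.array([1.0])), 0.05)
        assert res.mean_distance == pytest.approx(50.0)
        assert res.sd_distance == pytest.approx(10.0)

    def test_spot_probability_capped_at_one(self):
        prof = _profile_from(
            [1000.0], [100.0],
            [(0, 0, 10.0, 0), (0, 1, 20.0, 0), (0, 2, 30.0, 0)],
        )
        res = coupling_probabilities(prof, (np.array([100.0]), np.array([1.0])), 0.05)
        assert res.spot_prob_ch1[0] == 1.0
        assert (res.pair_prob <= 1.0).all()

    def test_n_coupled_clamped_to_min_count(self):
        prof = _profile_from(
            [1000.0], [100.0],
            [(0, 0, 10.0, 0), (0, 1, 20.0, 0)],
        )
        res = coupling_probabilities(prof, (np.array([100.0]), np.array([1.0])), 0.05)
        assert res.n_coupled <= min(prof.n1, prof.n2)


class TestRunSoda:
    def test_coupled_scenario_recovers_truth(self, coupled_scenario):
        sc, mask, s1, s2, _ = coupled_scenario
        _, res = run_soda(s1, s2, mask, n_resamples=200, seed=1)
        assert res.p_value < 1e-4
        assert 0.40 <= res.coupling_fraction_ch2 <= 0.60
        assert 40.0 <= res.mean_distance <= 65.0

    def test_self_colocalization_is_maximal(self, rectangle_mask, default_rings):
        rng = np.random.default_rng(8)
        pts = rectangle_mask.sample_uniform(80, rng)
        s = SpotSet(pts)
        _, res = run_soda(s, SpotSet(pts.copy()), rectangle_mask,
                          rings=default_rings, n_resamples=200, seed=2)
        assert res.p_value < 1e-6
        assert res.mean_distance < default_rings.radii[1]

    def test_deterministic_given_seed(self, coupled_scenario):
        _, mask, s1, s2, _ = coupled_scenario
        _, r1 = run_soda(s1, s2, mask, n_resamples=60, seed=5)
        _, r2 = run_soda(s1, s2, mask, n_resamples=60, seed=5)
        assert r1.p_value == r2.p_value and r1.n_coupled == r2.n_coupled

    def test_association_flags_follow_spot_probability(self, coupled_scenario):
        _, mask, s1, s2, _ = coupled_scenario
        _, res = run_soda(s1, s2, mask, n_resamples=100, seed=3)
        np.testing.assert_array_equal(res.associated_ch2, res.spot_prob_ch2 > 0.5)


class TestRingSpec:
    def test_from_string(self):
        rings = RingSpec.from_string("0:300:30")
        assert rings.n_rings == 10 and rings.r_max == 300.0

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            RingSpec(np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            RingSpec(np.array([0.0, 20.0, 20.0]))

    def test_ring_measures_3d_shell_volume(self):
        rings = RingSpec(np.array([0.0, 10.0, 20.0]))
        vols = rings.ring_measures(3)
        assert vols[0] == pytest.approx(4 / 3 * np.pi * 1000.0)
        assert vols[1] == pytest.approx(4 / 3 * np.pi * 7000.0)
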