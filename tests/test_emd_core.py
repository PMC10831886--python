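"""Transport distances: 1D closed form, LP oracle, sliced estimator, point case."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import wasserstein_distance, wasserstein_distance_nd

from remapot import RateMap, TransportConfig, emd_1d, exact_emd_2d, single_point_wasserstein, sliced_emd
from remapot.emd_core import (
    MassMismatchError,
    exact_2d_op_count,
    hungarian_op_count,
    sliced_op_count,
    sliced_percent_complexity,
)
from remapot.synthetic_fields import GaussianFieldSpec, make_place_field, make_translated_pair


def random_field(n, rng):
    c = rng.uniform(1, n - 2, 2)
    s = rng.uniform(0.7, 1.6)
    return make_place_field(GaussianFieldSpec(n, tuple(c), s, s))


class TestEmd1D:
    def test_identical_is_zero(self):
        assert emd_1d([0.2, 0.5, 0.3], [0.2, 0.5, 0.3]) == 0.0

    @pytest.mark.parametrize(
        "wa, wb, pos, expected",
        [
            ([1, 0, 0], [0, 0, 1], [0, 1, 2], 2.0),  # unit mass moved two bins
            ([1, 0], [0.5, 0.5], [0, 1], 0.5),  # half the mass moves one bin
            ([1, 0, 0], [0, 0, 1], [0.0, 1.0, 5.0], 5.0),  # non-unit spacing
        ],
    )
    def test_hand_cases(self, wa, wb, pos, expected):
        assert emd_1d(wa, wb, pos) == pytest.approx(expected, abs=1e-12)

    def test_unequal_mass_strict_policy_raises(self):
        with pytest.raises(MassMismatchError):
            emd_1d([1.0, 0.0], [0.5, 0.0])

    @given(st.integers(0, 10_000))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 32))
        wa = rng.uniform(0, 1, n)
        wb = rng.uniform(0, 1, n)
        wa[rng.integers(0, n)] += 0.5  # guarantee positive mass
        wb[rng.integers(0, n)] += 0.5
        pos = np.cumsum(rng.uniform(0.1, 2.0, n))
        ours = emd_1d(wa, wb, pos, mass_policy="normalize")
        ref = wasserstein_distance(pos, pos, wa, wb)
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_matches_exact_2d_on_single_row(self):
        # the 1D closed form and the transportation LP agree on 1 x n maps
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(2, 33))
            wa = rng.uniform(0, 1, n) + 1e-6
            wb = rng.uniform(0, 1, n) + 1e-6
            closed = emd_1d(wa, wb, mass_policy="normalize")
            lp = exact_emd_2d(RateMap(wa), RateMap(wb)).value
            assert closed == pytest.approx(lp, abs=1e-9)


class TestExact2D:
    def test_unit_deltas_euclidean(self, delta_map):
        a = delta_map((5, 5), (0, 0))
        b = delta_map((5, 5), (3, 4))
        assert exact_emd_2d(a, b).value == pytest.approx(5.0, abs=1e-9)

    def test_two_by_two_diagonal(self, delta_map):
        a = delta_map((2, 2), (0, 0))
        b = delta_map((2, 2), (1, 1))
        assert exact_emd_2d(a, b).value == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_row_shift_half_masses(self):
        a = RateMap(np.array([[0.5, 0.5], [0.0, 0.0]]))
        b = RateMap(np.array([[0.0, 0.0], [0.5, 0.5]]))
        assert exact_emd_2d(a, b).value == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_nd_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            a = RateMap(rng.uniform(0, 1, (6, 6)))
            b = RateMap(rng.uniform(0, 1, (6, 6)))
            ours = exact_emd_2d(a, b).value
            pts = a.bin_centers()
            ref = wasserstein_distance_nd(
                pts, pts, a.values.ravel(), b.values.ravel()
            )
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            maps = [RateMap(rng.uniform(0, 1, (6, 6))) for _ in range(3)]
            d01 = exact_emd_2d(maps[0], maps[1]).value
            d10 = exact_emd_2d(maps[1], maps[0]).value
            d02 = exact_emd_2d(maps[0], maps[2]).value
            d12 = exact_emd_2d(maps[1], maps[2]).value
            assert d01 == pytest.approx(d10, abs=1e-8)  # symmetry
            assert d02 <= d01 + d12 + 1e-8  # triangle inequality
        m = RateMap(rng.uniform(0, 1, (6, 6)))
        assert exact_emd_2d(m, m).value == pytest.approx(0.0, abs=1e-9)

    def test_oversize_map_rejected(self):
        big = RateMap(np.ones((40, 40)))
        with pytest.raises(ValueError, match="capped"):
            exact_emd_2d(big, big)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            exact_emd_2d(RateMap(np.zeros((3, 3))), RateMap(np.ones((3, 3))))


class TestSliced:
    def test_identical_maps_zero_any_seed(self):
        m = make_place_field(GaussianFieldSpec(9, (4.0, 4.0), 1, 1))
        for seed in (0, 1, 2):
            cfg = TransportConfig(seed=seed, n_projections=50)
            assert sliced_emd(m, m, cfg).value == pytest.approx(0.0, abs=1e-12)

    def test_corrected_deltas_recover_euclidean_gap(self, delta_map, cfg):
        a = delta_map((9, 9), (4, 2))
        b = delta_map((9, 9), (4, 6))
        assert sliced_emd(a, b, cfg).value == pytest.approx(4.0, rel=0.02)

    def test_uncorrected_deltas_give_two_over_pi(self, delta_map):
        cfg = TransportConfig(seed=0, n_projections=10_000, slice_correction="none")
        a = delta_map((9, 9), (4, 2))
        b = delta_map((9, 9), (4, 6))
        assert sliced_emd(a, b, cfg).value == pytest.approx(4 * 2 / np.pi, rel=0.02)

    def test_deterministic_given_seed(self, delta_map):
        a = delta_map((9, 9), (4, 2))
        b = delta_map((9, 9), (4, 6))
        cfg = TransportConfig(seed=5, n_projections=200)
        assert sliced_emd(a, b, cfg).value == sliced_emd(a, b, cfg).value

    def test_within_five_percent_of_exact_on_field_pairs(self):
        rng = np.random.default_rng(42)
        for i in range(20):
            a = random_field(8, rng)
            b = random_field(8, rng)
            exact = exact_emd_2d(a, b).value
            est = sliced_emd(a, b, TransportConfig(seed=100 + i, n_projections=10_000)).value
            assert abs(est - exact) / exact < 0.05

    def test_translation_identity_interior_gaussians(self):
        fixed, moved = make_translated_pair(33, 1.0, (16.0, 21.0))
        cfg = TransportConfig(seed=7, n_projections=10_000)
        assert sliced_emd(fixed, moved, cfg).value == pytest.approx(5.0, rel=0.02)

    def test_rate_invariance_normalized(self):
        a = make_place_field(GaussianFieldSpec(17, (8.0, 6.0), 1, 1))
        b = make_place_field(GaussianFieldSpec(17, (8.0, 10.0), 1, 1))
        cfg = TransportConfig(seed=3, n_projections=500)
        base = sliced_emd(a, b, cfg).value
        for c in (0.1, 3.0, 250.0):
            scaled = RateMap(b.values * c)
            assert sliced_emd(a, scaled, cfg).value == pytest.approx(base, abs=1e-9)

    def test_mass_policy_error_raises_on_mismatch(self):
        a = RateMap(np.ones((3, 3)))
        b = RateMap(np.ones((3, 3)) * 2)
        cfg = TransportConfig(seed=0, n_projections=10, mass_policy="error")
        with pytest.raises(MassMismatchError):
            sliced_emd(a, b, cfg)

    def test_different_shapes_supported(self, delta_map):
        # unlike bin-to-bin correlation, transport handles unequal map sizes
        a = delta_map((5, 5), (2, 2))
        b = delta_map((9, 7), (2, 2))
        cfg = TransportConfig(seed=0, n_projections=2000)
        assert sliced_emd(a, b, cfg).value == pytest.approx(0.0, abs=1e-9)


class TestSinglePoint:
    def test_all_mass_at_point_is_zero(self, delta_map):
        from remapot import normalize

        p = normalize(delta_map((5, 5), (2, 3)))
        assert single_point_wasserstein(p, (2.0, 3.0)) == 0.0

    def test_two_point_average(self):
        arr = np.zeros((1, 3))
        arr[0, 0] = 0.5
        arr[0, 2] = 0.5
        p = RateMap(arr, normalized=True)
        assert single_point_wasserstein(p, (0.0, 0.0)) == pytest.approx(1.0)

    def test_uniform_block_hand_value(self):
        p = RateMap(np.full((3, 3), 1 / 9), normalized=True)
        expected = (4 * 1 + 4 * np.sqrt(2)) / 9
        assert single_point_wasserstein(p, (1.0, 1.0)) == pytest.approx(expected, abs=1e-12)

    def test_requires_normalized_unless_flagged(self):
        p = RateMap(np.ones((3, 3)))
        with pytest.raises(ValueError, match="normalized"):
            single_point_wasserstein(p, (1.0, 1.0))
        assert single_point_wasserstein(p, (1.0, 1.0), normalize=True) > 0

    def test_equals_exact_emd_against_delta(self):
        # all mass must travel to the point, so the LP plan is forced
        rng = np.random.default_rng(17)
        for _ in range(20):
            vals = rng.uniform(0, 1, (8, 8))
            p = RateMap(vals / vals.sum(), normalized=True)
            q = (int(rng.integers(0, 8)), int(rng.integers(0, 8)))
            delta = np.zeros((8, 8))
            delta[q] = 1.0
            lp = exact_emd_2d(p, RateMap(delta, normalized=True)).value
            assert single_point_wasserstein(p, q) == pytest.approx(lp, abs=1e-9)


class TestOpCounts:
    def test_published_complexity_arithmetic(self):
        assert exact_2d_op_count(16, 16) == 16_777_216
        assert exact_2d_op_count(32, 32) == 1_073_741_824
        assert sliced_op_count(16 * 16, 1000) == pytest.approx(2_048_000)
        assert sliced_op_count(32 * 32, 1000) == pytest.approx(10_240_000)
        assert sliced_percent_complexity(32, 32, 1000) == pytest.approx(0.9537, abs=1e-3)
        assert hungarian_op_count(256) == 256**3
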