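import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as ndshift

from stereonir import (
    SGMParams,
    aggregate_costs_sgm,
    census_transform,
    compute_disparity,
    lr_consistency,
    matching_cost_volume,
    subpixel_refine,
    winner_take_all,
)
from stereonir.geometry import DisparityMap
from stereonir.sgm import CostVolume


def scanline_dp(costs, P1, P2, reverse=False):
    """Independent 1D scanline-optimisation oracle (classic DP recurrence).

    costs: (N, D) array for one row.  Returns the accumulated path costs.
    """
    N, D = costs.shape
    order = range(N - 1, -1, -1) if reverse else range(N)
    L = np.zeros_like(costs, dtype=float)
    prev = None
    for i in order:
        if prev is None:
            L[i] = costs[i]
        else:
            m = prev.min()
            for d in range(D):
                cands = [prev[d], m + P2]
                if d > 0:
                    cands.append(prev[d - 1] + P1)
                if d < D - 1:
                    cands.append(prev[d + 1] + P1)
                L[i] = L[i]  # keep shape
                L[i, d] = costs[i, d] + min(cands) - m
        prev = L[i]
    return L


class TestCensus:
    def test_constant_image_all_zero_descriptors(self):
        assert np.all(census_transform(np.full((10, 10), 5.0), 5) == 0)

    def test_monotonic_remap_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        a = census_transform(img, 7)
        b = census_transform(np.exp(3 * img) + 7, 7)
        assert np.array_equal(a, b)

    def test_single_bright_pixel_seen_by_neighbours(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        desc = census_transform(img, 3)
        # each 8-neighbour of the bright pixel sees it as its sole set bit
        assert desc[3, 3] == 0  # everything dimmer than the centre
        for dy, dx in itertools.product((-1, 0, 1), repeat=2):
            if (dy, dx) == (0, 0):
                continue
            d = int(desc[3 + dy, 3 + dx])
            assert d != 0 and (d & (d - 1)) == 0  # exactly one bit set

    def test_window_validation(self):
        with pytest.raises(ValueError):
            census_transform(np.zeros((4, 4)), 4)
        with pytest.raises(ValueError):
            census_transform(np.zeros((4, 4)), 9)


class TestCostVolume:
    def test_identical_views_zero_cost_at_zero_disparity(self):
        rng = np.random.default_rng(1)
        img = rng.random((12, 16))
        vol = matching_cost_volume(img, img, SGMParams(d_min=0, d_max=4, cost="census"))
        assert np.all(vol.costs[:, :, 0] == 0)

    def test_integer_shift_zero_cost_plane(self):
        rng = np.random.default_rng(2)
        left = rng.random((12, 32))
        right = np.roll(left, -3, axis=1)  # right view content shifted left
        vol = matching_cost_volume(left, right, SGMParams(d_min=0, d_max=6, cost="census"))
        interior = vol.costs[4:-4, 8:-8, 3]
        assert np.all(interior == 0)

    def test_wta_matches_brute_force_search(self):
        rng = np.random.default_rng(3)
        left = rng.random((16, 16))
        right = rng.random((16, 16))
        params = SGMParams(d_min=0, d_max=5, cost="census", census_window=3)
        vol = matching_cost_volume(left, right, params)
        cl = census_transform(left, 3)
        cr = census_transform(right, 3)
        # brute force per-pixel argmin over the search range
        for r in range(16):
            for c in range(6, 16):
                best = min(
                    range(6),
                    key=lambda d: bin(int(cl[r, c]) ^ int(cr[r, c - d])).count("1"),
                )
                assert vol.costs[r, c, best] == np.min(vol.costs[r, c])

    def test_hybrid_cost_requires_explicit_volume_choice(self):
        with pytest.raises(ValueError):
            matching_cost_volume(np.zeros((8, 8)), np.zeros((8, 8)), SGMParams(d_max=3))


class TestAggregation:
    def test_single_row_equals_scanline_dp_oracle(self):
        """Exhaustive: 8-path aggregation of a 1-row image decomposes into
        forward + backward scanline DP plus pass-through terms."""
        P1, P2 = 1.0, 3.0
        rng = np.random.default_rng(4)
        for N in range(2, 11):
            for D in (2, 3, 5):
                costs = rng.integers(0, 10, size=(1, N, D)).astype(float)
                vol = CostVolume(costs=costs.copy(), disparities=np.arange(D), sentinel=1e9)
                agg = aggregate_costs_sgm(vol, SGMParams(d_min=0, d_max=D - 1, P1=P1, P2=P2))
                fwd = scanline_dp(costs[0], P1, P2)
                bwd = scanline_dp(costs[0], P1, P2, reverse=True)
                expected = fwd + bwd + 6 * costs[0]
                assert np.allclose(agg.costs[0], expected)

    def test_zero_penalties_collapse_to_scaled_raw(self):
        rng = np.random.default_rng(5)
        costs = rng.random((6, 7, 4))
        vol = CostVolume(costs=costs.copy(), disparities=np.arange(4), sentinel=1e9)
        agg = aggregate_costs_sgm(vol, SGMParams(d_min=0, d_max=3, P1=0.0, P2=1e-12))
        assert np.allclose(agg.costs, 8 * costs, atol=1e-9)

    def test_aggregation_beats_raw_wta_on_noisy_pair(self):
        rng = np.random.default_rng(6)
        left = gaussian_filter(rng.random((48, 64)), 1.5)
        right = np.roll(left, -4, axis=1)
        left = left + rng.normal(0, 0.08, left.shape)
        right = right + rng.normal(0, 0.08, right.shape)
        params = SGMParams(d_min=0, d_max=8, cost="census")
        vol = matching_cost_volume(left, right, params)
        raw_err = np.mean(winner_take_all(vol).values[8:-8, 12:-12] != 4)
        agg_err = np.mean(winner_take_all(aggregate_costs_sgm(vol, params)).values[8:-8, 12:-12] != 4)
        assert agg_err <= raw_err


class TestWinnerTakeAll:
    def test_equals_exhaustive_argmin_on_random_volumes(self):
        rng = np.random.default_rng(7)
        costs = rng.random((8, 8, 8))
        vol = CostVolume(costs=costs, disparities=np.arange(2, 10), sentinel=1e9)
        wta = winner_take_all(vol)
        assert np.array_equal(wta.values, 2 + np.argmin(costs, axis=2))

    def test_all_equal_costs_tie_to_d_min(self):
        vol = CostVolume(costs=np.ones((4, 4, 5)), disparities=np.arange(3, 8), sentinel=1e9)
        assert np.all(winner_take_all(vol).values == 3)


class TestSubpixel:
    @staticmethod
    def _volume_from_curve(curve):
        c = np.asarray(curve, float)[None, None, :]
        return CostVolume(costs=np.repeat(c, 2, axis=0), disparities=np.arange(c.shape[2]), sentinel=1e9)

    @staticmethod
    def _integer(vol, d):
        v = np.full((2, 1), float(d))
        return DisparityMap(values=v, valid=np.ones_like(v, bool), search_range=(0, 10))

    def test_symmetric_costs_give_zero_offset(self):
        vol = self._volume_from_curve([5, 1, 5])
        r = subpixel_refine(vol, self._integer(vol, 1), "parabola")
        assert np.all(r.values == 1.0)

    def test_parabola_recovers_exact_vertex(self):
        d0 = 0.3
        curve = [(d - 1 - d0) ** 2 for d in range(3)]
        vol = self._volume_from_curve(curve)
        r = subpixel_refine(vol, self._integer(vol, 1), "parabola")
        assert r.values[0, 0] == pytest.approx(1.3, abs=1e-12)

    def test_vee_exact_on_v_shaped_costs(self):
        for d0 in (0.15, 0.35, -0.4):
            curve = [abs(d - 1 - d0) for d in range(3)]
            vol = self._volume_from_curve(curve)
            r = subpixel_refine(vol, self._integer(vol, 1), "vee")
            assert r.values[0, 0] == pytest.approx(1 + d0, abs=1e-9)

    def test_boundary_and_degenerate_unrefined(self):
        vol = self._volume_from_curve([1, 2, 3])
        r = subpixel_refine(vol, self._integer(vol, 0), "parabola")  # boundary
        assert np.all(r.values == 0.0)
        flat = self._volume_from_curve([2, 2, 2])  # non-convex triple
        r2 = subpixel_refine(flat, self._integer(flat, 1), "parabola")
        assert np.all(r2.values == 1.0)


class TestLRConsistency:
    def _dmap(self, vals):
        v = np.asarray(vals, float)
        return DisparityMap(values=v, valid=np.ones_like(v, bool), search_range=(0, 10))

    def test_consistent_maps_all_valid(self):
        dl = self._dmap(np.full((4, 12), 3.0))
        dr = self._dmap(np.full((4, 12), 3.0))
        ok = lr_consistency(dl, dr, 1.0)
        assert ok[:, 3:].all()

    def test_infinite_tolerance_keeps_everything_in_bounds(self):
        rng = np.random.default_rng(8)
        dl = self._dmap(rng.uniform(0, 3, (4, 12)))
        dr = self._dmap(rng.uniform(0, 3, (4, 12)))
        ok = lr_consistency(dl, dr, np.inf)
        assert ok[:, 4:].all()

    def test_disagreement_invalidated(self):
        dl = self._dmap(np.full((4, 12), 3.0))
        vals = np.full((4, 12), 3.0)
        vals[:, 5] = 7.0
        dr = self._dmap(vals)
        ok = lr_consistency(dl, dr, 1.0)
        assert not ok[:, 8].any()  # 8 - round(3) = 5 disagrees


class TestComputeDisparity:
    def test_identical_views_zero_disparity(self):
        rng = np.random.default_rng(9)
        img = gaussian_filter(rng.random((32, 48)), 1.0)
        d = compute_disparity(img, img, SGMParams(d_min=0, d_max=5))
        sel = d.valid & (np.arange(48)[None, :] > 8)
        assert np.all(np.abs(d.values[sel]) < 0.01)

    def test_integer_shift_recovered_exactly_at_wta(self):
        rng = np.random.default_rng(10)
        left = gaussian_filter(rng.random((32, 64)), 1.2)
        right = np.roll(left, -5, axis=1)
        d = compute_disparity(left, right, SGMParams(d_min=0, d_max=9, subpixel=False))
        interior = np.zeros_like(d.valid)
        interior[6:-6, 10:-10] = True
        assert np.all(d.values[d.valid & interior] == 5.0)

    @pytest.mark.parametrize("frac", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_fractional_shift_recovered_subpixel(self, frac):
        rng = np.random.default_rng(11)
        base = gaussian_filter(rng.random((48, 72)), 2.0)
        shift = 4 + frac
        right = ndshift(base, (0, -shift), order=3, mode="nearest")
        d = compute_disparity(base, right, SGMParams(d_min=0, d_max=9))
        interior = np.zeros_like(d.valid)
        interior[8:-8, 12:-12] = True
        sel = d.valid & interior
        assert np.abs(d.values[sel] - shift).mean() <= 0.25
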