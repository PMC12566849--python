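"""Size grid construction, PSD <-> number-density conversion, percentiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanomill as nm
from nanomill.exceptions import GridError, PSDError
from nanomill.grid_psd import diameter_to_volume, rebin_volume, volume_to_diameter


def make_psd(d_edges_um, vol_pct, time=0.0):
    return nm.PSDRecord(time=time, d_edges=np.asarray(d_edges_um, float),
                        vol_pct=np.asarray(vol_pct, float))


class TestBuildGrid:
    def test_one_diameter_doubling_gives_three_volume_doublings(self):
        grid = nm.build_grid(100, 200, 1, 100)
        assert grid.n_bins == 3
        assert grid.ratio == pytest.approx(2.0, abs=0)

    def test_bin_count_matches_logarithm_arithmetic(self):
        # oracle: ceil(q * log2((d_max/d_min)**3))
        grid = nm.build_grid(10, 100_000, 3, 100)
        expected = math.ceil(3 * math.log2((100_000 / 10) ** 3) - 1e-9)
        assert grid.n_bins == expected == 120

    def test_rejects_bad_inputs(self):
        with pytest.raises(GridError):
            nm.build_grid(-1, 100, 1, 50)
        with pytest.raises(GridError):
            nm.build_grid(200, 100, 1, 50)
        with pytest.raises(GridError):
            nm.build_grid(100, 200, 0, 50)
        with pytest.raises(GridError):
            nm.build_grid(1, 1e9, 200, 50)  # > 10,000 bins

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        d_min=st.floats(1.0, 1e4),
        span=st.floats(1.5, 1e3),
        q=st.integers(1, 6),
    )
    def test_ratio_constant_and_span_covered(self, d_min, span, q):
        d_max = d_min * span
        grid = nm.build_grid(d_min, d_max, q, d_min)
        ratios = grid.edges[1:] / grid.edges[:-1]
        assert np.all(np.abs(ratios / grid.ratio - 1) < 1e-12)
        assert grid.edges[0] <= diameter_to_volume(d_min, d_min) * (1 + 1e-12)
        assert grid.edges[-1] >= diameter_to_volume(d_max, d_min) * (1 - 1e-12)
        assert np.all(grid.pivots >= grid.edges[:-1])
        assert np.all(grid.pivots <= grid.edges[1:])

    def test_diameter_volume_round_trip(self):
        d = np.logspace(0, 5, 37)
        back = volume_to_diameter(diameter_to_volume(d, 123.4), 123.4)
        assert np.allclose(back, d, rtol=1e-12)


class TestPsdToState:
    def test_single_bin_number_is_volume_over_pivot(self):
        grid = nm.build_grid(100, 800, 1, 100)
        # psd bin aligned with grid bin 2
        edges_um = grid.d_edges_nm[2:4] / 1e3
        psd = make_psd(edges_um, [100.0])
        state = nm.psd_to_state(psd, grid, total_volume_fraction=1.0)
        expect = np.zeros(grid.n_bins)
        expect[2] = 1.0 / grid.pivots[2]
        assert np.allclose(state.N, expect, rtol=1e-12)

    def test_empty_distribution_rejected(self):
        with pytest.raises(PSDError):
            make_psd([0.1, 0.2], [0.0])

    def test_mass_outside_grid_is_an_error(self):
        grid = nm.build_grid(1000, 8000, 1, 1000)
        psd = make_psd([0.1, 10.0], [100.0])
        with pytest.raises(GridError, match="lost"):
            nm.psd_to_state(psd, grid)

    def test_rebinning_matches_quadrature_oracle(self):
        # random 5-bin curve vs brute-force overlap integration of the
        # piecewise-constant density in log diameter
        rng = np.random.default_rng(42)
        src = np.sort(rng.uniform(0.2, 50.0, 6))
        vol = rng.uniform(0.1, 1.0, 5)
        vol = vol * 100 / vol.sum()
        grid = nm.build_grid(100, 100_000, 2, 1000)
        dst, lost = rebin_volume(vol, src * 1e3, grid.d_edges_nm)
        # oracle: integrate each source bin's constant log-density over
        # destination intervals with dense trapezoid sampling
        dst_log = np.log(grid.d_edges_nm)
        src_log = np.log(src * 1e3)
        oracle = np.zeros(grid.n_bins)
        for b in range(5):
            dens = vol[b] / (src_log[b + 1] - src_log[b])
            for i in range(grid.n_bins):
                lo = max(src_log[b], dst_log[i])
                hi = min(src_log[b + 1], dst_log[i + 1])
                if hi > lo:
                    oracle[i] += dens * (hi - lo)
        assert np.allclose(dst, oracle, rtol=1e-9, atol=1e-12)
        assert abs(lost) < 1e-9

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_conserves_volume(self, seed):
        rng = np.random.default_rng(seed)
        grid = nm.build_grid(100, 100_000, 2, 1000)
        vol = rng.uniform(0.0, 1.0, 10)
        vol[rng.integers(0, 10)] += 1.0  # ensure nonzero
        vol = vol * 100 / vol.sum()
        edges_um = np.logspace(np.log10(0.2), np.log10(80.0), 11)
        psd = make_psd(edges_um, vol)
        state = nm.psd_to_state(psd, grid, total_volume_fraction=2.5)
        assert state.total_volume(grid) == pytest.approx(2.5, rel=1e-9)


class TestStateToPsd:
    def test_single_bin_state(self):
        grid = nm.build_grid(100, 800, 1, 100)
        N = np.zeros(grid.n_bins)
        N[1] = 3.0
        psd = nm.state_to_psd(nm.ParticleState(0.0, N), grid)
        assert psd.vol_pct[1] == pytest.approx(100.0)
        assert psd.vol_pct.sum() == pytest.approx(100.0)

    def test_equal_volume_bins_split_evenly(self):
        grid = nm.build_grid(100, 800, 1, 100)
        N = np.zeros(grid.n_bins)
        N[0] = 1.0 / grid.pivots[0]
        N[2] = 1.0 / grid.pivots[2]
        psd = nm.state_to_psd(nm.ParticleState(0.0, N), grid)
        assert psd.vol_pct[0] == pytest.approx(50.0, rel=1e-12)
        assert psd.vol_pct[2] == pytest.approx(50.0, rel=1e-12)

    def test_all_zero_state_rejected(self):
        grid = nm.build_grid(100, 800, 1, 100)
        with pytest.raises(PSDError):
            nm.state_to_psd(nm.ParticleState(0.0, np.zeros(grid.n_bins)), grid)

    def test_round_trip_on_bimodal_curve(self, scenario, production_grid):
        psd0 = nm.gen_initial_psd(scenario, production_grid)
        state = nm.psd_to_state(psd0, production_grid)
        back = nm.state_to_psd(state, production_grid)
        assert np.max(np.abs(back.vol_pct - psd0.vol_pct)) < 1e-6


class TestPercentiles:
    def test_single_bin_median_is_log_midpoint(self):
        psd = make_psd([0.1, 0.2], [100.0])
        assert nm.percentiles(psd, [0.5])[0] == pytest.approx(
            math.sqrt(100 * 200), rel=1e-9
        )

    def test_symmetric_distribution_median_at_center(self):
        psd = make_psd([0.1, 0.2, 0.4, 0.8], [25.0, 50.0, 25.0])
        assert nm.percentiles(psd, [0.5])[0] == pytest.approx(
            math.sqrt(200 * 400), rel=1e-9
        )

    def test_matches_cumulative_interpolation_oracle(self):
        rng = np.random.default_rng(7)
        edges = np.sort(rng.uniform(0.05, 20.0, 7))
        vol = rng.uniform(0.5, 2.0, 6)
        vol = vol * 100 / vol.sum()
        psd = make_psd(edges, vol)
        probs = [0.1, 0.5, 0.9]
        got = nm.percentiles(psd, probs)
        # oracle: manual piecewise-linear inversion of cumulative volume
        cum = np.concatenate([[0.0], np.cumsum(vol)])
        for prob, d in zip(probs, got):
            target = prob * 100
            k = int(np.searchsorted(cum, target)) - 1
            f = (target - cum[k]) / (cum[k + 1] - cum[k])
            logd = np.log10(edges[k] * 1e3) + f * (
                np.log10(edges[k + 1] * 1e3) - np.log10(edges[k] * 1e3)
            )
            assert d == pytest.approx(10**logd, rel=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_probability(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.sort(rng.uniform(0.05, 50.0, 9))
        vol = rng.uniform(0.0, 1.0, 8) + 1e-6
        vol = vol * 100 / vol.sum()
        psd = make_psd(edges, vol)
        probs = np.sort(rng.uniform(0.01, 0.99, 5))
        d = nm.percentiles(psd, probs)
        assert np.all(np.diff(d) >= -1e-12)

    def test_rejects_probs_outside_unit_interval(self):
        psd = make_psd([0.1, 0.2], [100.0])
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(PSDError):
                nm.percentiles(psd, [bad])


class TestPSDRecordInvariants:
    def test_sum_must_be_100(self):
        with pytest.raises(PSDError):
            make_psd([0.1, 0.2, 0.4], [50.0, 49.0])

    def test_negative_volume_rejected(self):
        with pytest.raises(PSDError):
            make_psd([0.1, 0.2, 0.4], [101.0, -1.0])

    def test_edges_must_ascend(self):
        with pytest.raises(PSDError):
            make_psd([0.2, 0.1], [100.0])
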