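import numpy as np
import pytest
from scipy import special

import hdspace as h
from hdspace.circular import kappa_from_resultant
from hdspace.tuning import HD_BIN_COUNT, HDTuningCurve, hd_bin_centers


def make_curve(rate, occupancy=None):
    rate = np.asarray(rate, dtype=float)
    occ = np.ones(HD_BIN_COUNT) if occupancy is None else np.asarray(occupancy)
    edges = np.linspace(0, 2 * np.pi, HD_BIN_COUNT + 1)
    mean = float(np.sum(rate * occ) / occ.sum())
    return HDTuningCurve(edges, rate, occ, mean)


class TestComputeHDTuning:
    def test_sixty_six_degree_bins(self, wake_traj, wake_mask):
        st = h.SpikeTrain("c", np.array([1.0, 2.0]))
        curve = h.compute_hd_tuning(st, wake_traj, wake_mask)
        assert curve.rate.shape == (60,)
        np.testing.assert_allclose(np.diff(curve.bin_edges), np.deg2rad(6.0))

    def test_occupancy_sums_to_masked_duration(self, wake_traj, wake_mask):
        st = h.SpikeTrain("c", np.array([1.0]))
        curve = h.compute_hd_tuning(st, wake_traj, wake_mask)
        expected = wake_traj.frame_dt()[wake_mask].sum()
        assert curve.occupancy_s.sum() == pytest.approx(expected)

    def test_homogeneous_cell_flat_within_poisson_ci(self, arena, wake_traj,
                                                     wake_mask):
        m = h.CellModel(kind="homogeneous", baseline_rate=5.0)
        st = h.generate_spikes(m, wake_traj, arena, seed=8)
        curve = h.compute_hd_tuning(st, wake_traj, wake_mask)
        ok = curve.visited & (curve.occupancy_s > 1.0)
        sd = np.sqrt(5.0 / curve.occupancy_s[ok])
        assert np.all(np.abs(curve.rate[ok] - 5.0) < 4.5 * sd)

    def test_no_spikes_all_zero(self, short_traj, short_mask):
        curve = h.compute_hd_tuning(h.SpikeTrain("c", np.empty(0)),
                                    short_traj, short_mask)
        assert np.nansum(curve.rate) == 0.0


class TestResultantVector:
    def test_point_mass(self):
        rate = np.zeros(60)
        rate[10] = 3.0
        length, direction = h.resultant_vector(make_curve(rate))
        assert length == pytest.approx(1.0)
        assert direction == pytest.approx(hd_bin_centers()[10])

    def test_uniform_curve_zero_length(self):
        length, direction = h.resultant_vector(make_curve(np.full(60, 2.0)))
        assert length == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses_quarter_turn_apart(self):
        # bins 0 and 15 are 90 deg apart: |e^{i0} + e^{i pi/2}| / 2 = sqrt(2)/2
        rate = np.zeros(60)
        rate[0] = rate[15] = 1.0
        length, direction = h.resultant_vector(make_curve(rate))
        assert length == pytest.approx(np.sqrt(2) / 2)
        mid = (hd_bin_centers()[0] + hd_bin_centers()[15]) / 2
        assert direction == pytest.approx(mid)


class TestConcentration:
    def test_uniform_curve_near_zero(self):
        assert h.concentration(make_curve(np.full(60, 1.0))) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_inversion_consistent_with_bessel_ratio(self):
        # independent oracle: A(kappa) = I1/I0 from scipy, then invert
        for kappa in (0.5, 1.0, 2.0, 4.0, 8.0):
            r = special.i1(kappa) / special.i0(kappa)
            assert kappa_from_resultant(r) == pytest.approx(kappa, rel=0.02)

    def test_von_mises_spike_sample_recovery(self):
        # ~6000 spikes from a kappa=2 von Mises tuning on near-uniform
        # occupancy recover kappa within [1.6, 2.4]
        rng = np.random.default_rng(12)
        n = 20000
        traj = h.Trajectory(np.arange(n) / 39.0, np.full(n, 26.0),
                            np.full(n, 23.0), rng.uniform(0, 2 * np.pi, n))
        m = h.CellModel(kind="pure_hd", preferred_direction=2.0, kappa=2.0,
                        peak_rate=85.0, baseline_rate=0.0)
        st = h.generate_spikes(m, traj, h.ArenaSpec(), seed=13)
        assert st.n > 4000
        curve = h.compute_hd_tuning(st, traj, np.ones(n, dtype=bool))
        assert 1.6 <= h.concentration(curve) <= 2.4


class TestShuffleTest:
    def test_strong_hd_cell_attains_minimum_p(self, arena, wake_traj, wake_mask):
        m = h.CellModel(kind="pure_hd", preferred_direction=1.0, kappa=2.0)
        for seed in range(3):
            st = h.generate_spikes(m, wake_traj, arena, seed=20 + seed)
            p = h.shuffle_test(st, wake_traj, wake_mask, n_shuffles=500, seed=seed)
            assert p == pytest.approx(1 / 501)

    def test_too_short_session_errors(self, arena):
        traj = h.simulate_trajectory(arena, h.TrajectoryParams(duration=30.0, seed=3))
        st = h.SpikeTrain("c", np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            h.shuffle_test(st, traj, n_shuffles=100)

    def test_null_p_values_super_uniform(self, arena, short_traj, short_mask):
        # homogeneous cells: P(p <= alpha) must not exceed alpha
        m = h.CellModel(kind="homogeneous", baseline_rate=5.0)
        ps = []
        for seed in range(100):
            st = h.generate_spikes(m, short_traj, arena, seed=300 + seed)
            ps.append(h.shuffle_test(st, short_traj, short_mask,
                                     n_shuffles=100, seed=seed))
        ps = np.asarray(ps)
        for alpha in (0.05, 0.2, 0.5):
            slack = 3 * np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + slack


class TestSplitHalf:
    def test_identical_halves_r_equals_one(self):
        # second half replays the first: tuning curves match exactly
        n = 4000
        t = np.arange(n) / 39.0
        hd = np.tile(np.linspace(0, 2 * np.pi, n // 2, endpoint=False), 2)
        traj = h.Trajectory(t, np.full(n, 26.0), np.full(n, 23.0), hd)
        half = t[n // 2]
        spike_t = np.concatenate([t[100:300:2] + 1e-4, t[100:300:2] + half + 1e-4])
        r = h.split_half_stability(h.SpikeTrain("c", spike_t), traj,
                                   np.ones(n, dtype=bool))
        assert r == pytest.approx(1.0)

    def test_stable_cell_exceeds_criterion(self, arena, wake_traj, wake_mask):
        m = h.CellModel(kind="pure_hd", preferred_direction=0.7)
        hits = 0
        for seed in range(10):
            st = h.generate_spikes(m, wake_traj, arena, seed=40 + seed)
            hits += h.split_half_stability(st, wake_traj, wake_mask) > 0.75
        assert hits >= 9


class TestClassify:
    def test_homogeneous_not_hd(self, arena, wake_traj, wake_mask):
        st = h.generate_spikes(h.CellModel(kind="homogeneous", baseline_rate=8.0),
                               wake_traj, arena, seed=50)
        cls = h.classify_hd_cell(st, wake_traj, wake_mask, n_shuffles=200,
                                 p_threshold=0.01)
        assert not cls.is_hd

    def test_pure_hd_cell_is_hd(self, arena, wake_traj, wake_mask):
        st = h.generate_spikes(h.CellModel(kind="pure_hd", kappa=4.0,
                                           preferred_direction=2.5),
                               wake_traj, arena, seed=51)
        cls = h.classify_hd_cell(st, wake_traj, wake_mask, seed=1)
        assert cls.is_hd
        assert cls.shuffle_p <= 0.001 and cls.split_half_r > 0.75 \
            and cls.concentration > 1.0


class TestRateMap:
    def test_default_half_cm_bins(self, arena, short_traj, short_mask):
        st = h.SpikeTrain("c", np.array([1.0, 2.0]))
        rm = h.compute_rate_map(st, short_traj, arena, short_mask)
        assert rm.bin_size == 0.5
        assert rm.rate.shape == (106, 92)

    def test_occupancy_p_sums_to_one(self, arena, short_traj, short_mask):
        st = h.SpikeTrain("c", np.array([1.0, 2.0]))
        for sigma in (0.0, 2.5):
            rm = h.compute_rate_map(st, short_traj, arena, short_mask,
                                    sigma=sigma)
            assert np.nansum(rm.occupancy_p) == pytest.approx(1.0)

    def test_homogeneous_map_flat(self, arena, wake_traj, wake_mask):
        st = h.generate_spikes(h.CellModel(kind="homogeneous", baseline_rate=10.0),
                               wake_traj, arena, seed=60)
        rm = h.compute_rate_map(st, wake_traj, arena, wake_mask, bin_size=2.0,
                                sigma=4.0)
        good = rm.visited & np.isfinite(rm.rate)
        assert np.nanmedian(rm.rate[good]) == pytest.approx(10.0, rel=0.1)

    def test_sigma_zero_equals_raw_ratio(self, arena, short_traj, short_mask):
        st = h.SpikeTrain("c", short_traj.t[short_mask][::7] + 1e-4)
        rm = h.compute_rate_map(st, short_traj, arena, short_mask, bin_size=2.0,
                                sigma=0.0)
        # independent oracle: plain histogram division
        dtf = short_traj.frame_dt()
        occ, _, _ = np.histogram2d(short_traj.x[short_mask], short_traj.y[short_mask],
                                   bins=[rm.x_edges, rm.y_edges],
                                   weights=dtf[short_mask])
        idx = short_traj.frame_index(st.times)
        keep = short_mask[idx]
        cnt, _, _ = np.histogram2d(short_traj.x[idx[keep]], short_traj.y[idx[keep]],
                                   bins=[rm.x_edges, rm.y_edges])
        expect = np.where(occ > 0, cnt / np.where(occ > 0, occ, 1), np.nan)
        np.testing.assert_allclose(rm.rate, expect, atol=1e-9, equal_nan=True)
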