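import numpy as np
import pytest
from scipy.optimize import minimize

import hdspace as h
from hdspace.glm import (
    WALL_COLUMNS,
    build_border_regressors,
    build_egocentric_regressors,
    frames_to_bins,
    time_bins,
    zscore_columns,
)


def make_point_traj(points, hd=None):
    """Trajectory visiting the given (x, y) points at 39 Hz."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    hd = np.zeros(n) if hd is None else np.asarray(hd, dtype=float)
    return h.Trajectory(np.arange(n) / 39.0, points[:, 0], points[:, 1], hd)


class TestSmoothing:
    def test_single_spike_sums_to_one(self):
        out = h.bin_and_smooth_spikes(np.array([5.0]), 0.0, 10.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_conservation_on_random_trains(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            times = np.sort(rng.uniform(0, 60.0, rng.integers(10, 500)))
            out = h.bin_and_smooth_spikes(times, 0.0, 60.0)
            assert out.sum() == pytest.approx(len(times), abs=1e-9)

    def test_default_bin_and_kernel_widths(self):
        import inspect

        sig = inspect.signature(h.bin_and_smooth_spikes)
        assert sig.parameters["bin_ms"].default == 5.0
        assert sig.parameters["smooth_sd_ms"].default == 25.6

    def test_empty_span_errors(self):
        with pytest.raises(ValueError):
            time_bins(1.0, 1.0)


class TestBorderRegressors:
    def test_center_is_all_zero(self, arena):
        traj = make_point_traj([(26.5, 23.0)])
        flags = build_border_regressors(traj, arena)
        np.testing.assert_array_equal(flags[:, 0], [0, 0, 0, 0])

    @pytest.mark.parametrize(
        "point,expected",
        [
            ((5.0, 23.0), (0, 0, 1, 0)),  # near west only
            ((50.0, 23.0), (1, 0, 0, 0)),  # near east only
            ((26.5, 40.0), (0, 1, 0, 0)),  # near north only
            ((26.5, 5.0), (0, 0, 0, 1)),  # near south only
            ((5.0, 5.0), (0, 0, 0, 0)),  # SW corner excluded
            ((40.0, 40.0), (0, 0, 0, 0)),  # NE corner excluded
        ],
    )
    def test_hand_computed_geometry(self, arena, point, expected):
        flags = build_border_regressors(make_point_traj([point]), arena)
        np.testing.assert_array_equal(flags[:, 0], expected)

    def test_matches_brute_force_distance_oracle(self, arena, short_traj):
        flags = build_border_regressors(short_traj, arena)
        for i in range(0, short_traj.n, 97):
            x, y = short_traj.x[i], short_traj.y[i]
            d = [arena.width - x, arena.height - y, x, y]
            expect = [
                1.0 if d[w] < 15 and all(d[o] >= 15 for o in range(4) if o != w)
                else 0.0
                for w in range(4)
            ]
            np.testing.assert_array_equal(flags[:, i], expect)

    def test_oversized_wall_distance_rejected(self, arena):
        with pytest.raises(ValueError):
            build_border_regressors(make_point_traj([(5.0, 5.0)]), arena,
                                    wall_distance_cm=25.0)


class TestEgocentricRegressors:
    # at (50, 23) the nearest wall is East, bearing 0
    @pytest.mark.parametrize(
        "hd_deg,expected",
        [
            (0.0, (0, 0)),  # wall dead ahead
            (270.0, (1, 0)),  # phi = +90: wall on the left
            (90.0, (0, 1)),  # phi = -90: wall on the right
            (315.0, (1, 0)),  # phi = +45, inside the left window
            (180.0, (0, 0)),  # wall dead behind
        ],
    )
    def test_side_windows_near_east_wall(self, arena, hd_deg, expected):
        traj = make_point_traj([(50.0, 23.0)], hd=[np.deg2rad(hd_deg)])
        flags = build_egocentric_regressors(traj, arena)
        np.testing.assert_array_equal(flags[:, 0], expected)

    def test_far_from_walls_both_zero(self, arena):
        traj = make_point_traj([(26.5, 23.0)], hd=[1.0])
        np.testing.assert_array_equal(
            build_egocentric_regressors(traj, arena)[:, 0], (0, 0)
        )

    def test_invalid_window_rejected(self, arena):
        with pytest.raises(ValueError):
            build_egocentric_regressors(make_point_traj([(5.0, 23.0)]), arena,
                                        half_window_deg=120.0)


class TestHDRateRegressor:
    def test_flat_curve_gives_constant(self, wake_traj, wake_mask):
        st = h.SpikeTrain("c", np.array([1.0]))
        curve = h.compute_hd_tuning(st, wake_traj, wake_mask)
        flat = curve
        flat.rate = np.full(60, 3.0)
        series = h.hd_expected_rate_regressor(flat, wake_traj)
        assert np.all(series == 3.0)

    def test_series_bounded_by_curve(self, arena, wake_traj, wake_mask):
        st = h.generate_spikes(h.CellModel(kind="pure_hd"), wake_traj, arena,
                               seed=4)
        curve = h.compute_hd_tuning(st, wake_traj, wake_mask)
        series = h.hd_expected_rate_regressor(curve, wake_traj)
        assert series.min() >= np.nanmin(curve.rate) - 1e-12
        assert series.max() <= np.nanmax(curve.rate) + 1e-12

    def test_positively_correlates_with_hd_cell_counts(self, arena, wake_traj,
                                                       wake_mask):
        st = h.generate_spikes(h.CellModel(kind="pure_hd", kappa=4.0),
                               wake_traj, arena, seed=5)
        curve = h.compute_hd_tuning(st, wake_traj, wake_mask)
        edges, centers = time_bins(wake_traj.t[0],
                                   wake_traj.t[-1] + 1 / 39.0)
        y = h.bin_and_smooth_spikes(st.times, wake_traj.t[0], edges[-1])
        x = frames_to_bins(h.hd_expected_rate_regressor(curve, wake_traj),
                           wake_traj, centers)
        assert np.corrcoef(x, y)[0, 1] > 0.1


class TestFit:
    def test_intercept_only_is_log_mean(self):
        y = np.array([0.0, 1.0, 2.0, 5.0])
        fit = h.fit_poisson_glm(y, np.empty((4, 0)))
        assert fit.beta0 == pytest.approx(np.log(y.mean()))

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(0)
        n = 5000
        X = zscore_columns(rng.normal(size=(n, 3)))[0]
        beta_true = np.array([-1.0, 0.3, -0.2, 0.1])
        y = rng.poisson(np.exp(beta_true[0] + X @ beta_true[1:]))
        fit = h.fit_poisson_glm(y, X)

        def negll(b):
            eta = b[0] + X @ b[1:]
            return -(y @ eta - np.exp(eta).sum())

        oracle = minimize(negll, np.zeros(4), method="BFGS",
                          options={"gtol": 1e-10}).x
        est = np.array([fit.beta0] + list(fit.beta.values()))
        np.testing.assert_allclose(est, oracle, atol=1e-5)
        assert fit.converged

    def test_matches_statsmodels_on_smoothed_counts(self):
        # continuous-response cross-check on non-integer y
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 3000
        X = zscore_columns(rng.normal(size=(n, 2)))[0]
        y = h.bin_and_smooth_spikes(np.sort(rng.uniform(0, 15.0, 400)), 0.0,
                                    15.0)
        y = y[:n] if y.size >= n else np.pad(y, (0, n - y.size))
        fit = h.fit_poisson_glm(y, X)
        res = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Poisson()).fit(tol=1e-10)
        est = np.array([fit.beta0] + list(fit.beta.values()))
        np.testing.assert_allclose(est, res.params, atol=1e-6)

    def test_known_beta_recovery(self):
        rng = np.random.default_rng(2)
        n = 200_000
        X = zscore_columns(rng.normal(size=(n, 4)))[0]
        beta_true = np.array([-2.0, 0.25, -0.15, 0.1, 0.05])
        y = rng.poisson(np.exp(beta_true[0] + X @ beta_true[1:]))
        fit = h.fit_poisson_glm(y, X)
        est = np.array([fit.beta0] + list(fit.beta.values()))
        np.testing.assert_allclose(est, beta_true, atol=0.03)

    def test_zscore_flags_constant_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Z, degenerate = zscore_columns(X)
        assert list(degenerate) == [0]
        assert np.all(Z[:, 0] == 0)
        assert Z[:, 1].std() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def glm_session(arena):
    models = [
        h.CellModel(kind="pure_hd", preferred_direction=1.0),
        h.CellModel(kind="hd_border", preferred_direction=2.0,
                    gain_per_wall=(3.0, 1.0, 1.0, 1.0)),
        h.CellModel(kind="hd_egocentric", preferred_direction=4.0,
                    side_gain=(1.5, 0.5)),
        h.CellModel(kind="hd_egocentric", preferred_direction=4.0,
                    side_gain=(0.5, 1.5)),
        h.CellModel(kind="hd_egocentric", preferred_direction=0.5,
                    side_gain=(1.5, 1.5)),
    ]
    return h.simulate_session(models, arena, h.TrajectoryParams(duration=600.0),
                              seed=7)


class TestModulationScores:
    def test_pure_hd_not_border_modulated(self, glm_session):
        bm = h.border_modulation(glm_session, "cell000")
        assert not bm.is_border_modulated
        assert abs(bm.border_modulation) < 0.1

    def test_border_cell_recovers_gained_wall(self, glm_session):
        bm = h.border_modulation(glm_session, "cell001")
        assert bm.best_wall == "east"
        assert bm.is_border_modulated
        assert set(bm.fit.beta) == set(WALL_COLUMNS) | {"hd_expected_rate"}

    def test_egocentric_cell_scores_high(self, glm_session):
        em = h.egocentric_modulation(glm_session, "cell002")
        assert em.egocentric_modulation > 0.2

    def test_swapping_side_gains_preserves_score(self, glm_session):
        a = h.egocentric_modulation(glm_session, "cell002").egocentric_modulation
        b = h.egocentric_modulation(glm_session, "cell003").egocentric_modulation
        assert a == pytest.approx(b, abs=0.15)

    def test_symmetric_gains_score_near_zero(self, glm_session):
        em = h.egocentric_modulation(glm_session, "cell004")
        assert em.egocentric_modulation < 0.1

    def test_too_few_spikes_rejected(self, glm_session, arena):
        sparse = h.SpikeTrain("sparse", np.linspace(1.0, 500.0, 40))
        glm_session.spikes.append(sparse)
        try:
            with pytest.raises(ValueError, match="100 spikes"):
                h.border_modulation(glm_session, "sparse")
        finally:
            glm_session.spikes.pop()

    def test_random_wall_labels_rarely_exceed_threshold(self, glm_session,
                                                        arena):
        # control: circularly shifted wall flags should not produce border
        # modulation for a pure HD cell
        from hdspace.glm import _fit_modulation
        from hdspace.io_core import speed_filter

        traj = glm_session.trajectory
        mask = speed_filter(traj)
        curve = h.compute_hd_tuning(glm_session.spike_train("cell000"), traj,
                                    mask)
        cols = build_border_regressors(traj, glm_session.arena)
        hits = 0
        rng = np.random.default_rng(9)
        n_controls = 12
        for _ in range(n_controls):
            shift = rng.integers(2000, traj.n - 2000)
            shifted = np.roll(cols, shift, axis=1)
            fit, _ = _fit_modulation(glm_session, "cell000", shifted,
                                     WALL_COLUMNS, curve, mask, 5.0, 25.6)
            hits += max(fit.beta[w] for w in WALL_COLUMNS) > 0.1
        assert hits <= 2
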