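"""Staircase, psychometric-fit and discrimination-ellipse tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromadiet.psychophysics import (
    DEFAULT_PRIORS,
    HueAxisSet,
    Observer,
    StaircaseError,
    StaircaseParams,
    cvd_threshold_ratio,
    discrimination_log_axis_ratio,
    ellipse_radius,
    fit_discrimination_ellipse,
    fit_psychometric,
    observer_p_correct,
    replay_staircase,
    run_session,
    run_staircase,
    tukey_outliers,
)
from chromadiet.synthetic import ellipse_form


AXES = HueAxisSet()


class TestObserverModel:
    def test_guess_floor_at_zero_saturation(self):
        obs = Observer(thresholds=(0.1,) * 8)
        assert observer_p_correct(obs, 0, 0.0) == pytest.approx(0.25)
        assert observer_p_correct(obs, 0, 1e-9) == pytest.approx(0.25, abs=1e-3)

    def test_ceiling_without_lapse(self):
        obs = Observer(thresholds=(0.1,) * 8, lapse_rate=0.0)
        assert observer_p_correct(obs, 0, 1e6) == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_identity(self):
        obs = Observer(thresholds=(0.2,) * 8, lapse_rate=0.04)
        p = observer_p_correct(obs, 3, 0.2)
        assert p == pytest.approx(0.25 + (1 - 0.25 - 0.04) / 2)

    def test_monotone_in_saturation(self):
        obs = Observer(thresholds=(0.1,) * 8)
        sats = np.linspace(0, 2, 200)
        p = observer_p_correct(obs, 0, sats)
        assert (np.diff(p) >= -1e-12).all()


class TestStaircase:
    def test_hand_traced_sequence(self):
        """C,C,W,C from start 1.0 -> 1.0, 0.5, 0.25, 0.375; reversals at 3, 4."""
        sats, revs = replay_staircase(
            [True, True, False, True], StaircaseParams(s_max=1.0)
        )
        assert sats == [1.0, 0.5, 0.25, 0.375]
        assert revs == [3, 4]

    def test_always_wrong_stays_clamped(self):
        sats, revs = replay_staircase([False] * 30, StaircaseParams(s_max=1.0))
        assert set(sats) == {1.0} and revs == []

    def test_always_correct_halves_without_reversals(self):
        sats, revs = replay_staircase([True] * 10, StaircaseParams(s_max=1.0))
        assert sats == [1.0 * 0.5**i for i in range(10)] and revs == []

    def test_guard_raises_with_log(self):
        obs = Observer(thresholds=(1e-6,) * 8)  # essentially always correct
        with pytest.raises(StaircaseError) as ei:
            run_staircase(
                obs, 0, StaircaseParams(max_trials=20), np.random.default_rng(0)
            )
        assert len(ei.value.log) == 20

    def test_terminates_after_18_reversals(self, rng):
        obs = Observer(thresholds=(0.1,) * 8)
        log = run_staircase(obs, 0, StaircaseParams(), rng)
        assert sum(t.reversal for t in log) == 18

    @given(st.integers(0, 200))
    @settings(deadline=None, max_examples=30)
    def test_multiplicative_update_invariant(self, seed):
        """Replay check: every saturation follows from the previous response
        by the 0.5x/1.5x rule with clamping at s_max."""
        r = np.random.default_rng(seed)
        obs = Observer(thresholds=(0.1,) * 8)
        p = StaircaseParams()
        log = run_staircase(obs, 0, p, r)
        for prev, cur in zip(log, log[1:]):
            factor = p.down_factor if prev.correct else p.up_factor
            assert cur.saturation == pytest.approx(
                min(prev.saturation * factor, p.s_max), rel=1e-12
            )


class TestSession:
    def test_fixed_seed_replays_identically(self):
        obs = Observer(thresholds=(0.1,) * 8)
        a = run_session(obs, AXES, StaircaseParams(), np.random.default_rng(5))
        b = run_session(obs, AXES, StaircaseParams(), np.random.default_rng(5))
        assert a == b

    def test_every_axis_runs_two_staircases(self, rng):
        obs = Observer(thresholds=(0.1,) * 8)
        log = run_session(obs, AXES, StaircaseParams(), rng)
        for a in range(8):
            per_axis = [t for t in log if t.axis == a]
            assert {t.phase for t in per_axis} == {1, 2}
            assert sum(t.reversal for t in per_axis) == 36
        counts = [sum(1 for t in log if t.axis == a) for a in range(8)]
        assert sum(counts) == len(log)  # bookkeeping conservation

    def test_second_staircase_continues_from_first(self, rng):
        obs = Observer(thresholds=(0.1,) * 8)
        log = run_session(obs, AXES, StaircaseParams(second_start="continue"), rng)
        for a in range(8):
            per_axis = [t for t in log if t.axis == a]
            last1 = [t for t in per_axis if t.phase == 1][-1]
            first2 = [t for t in per_axis if t.phase == 2][0]
            p = StaircaseParams()
            factor = p.down_factor if last1.correct else p.up_factor
            assert first2.saturation == pytest.approx(
                min(last1.saturation * factor, p.s_max)
            )


class TestPsychometricFit:
    def _designed_trials(self, obs, rng, n_per_level=500):
        levels = obs.thresholds[0] * np.exp(np.linspace(-2, 2, 9))
        sats = np.repeat(levels, n_per_level)
        p = observer_p_correct(obs, 0, sats)
        return sats, rng.random(sats.size) < p

    @pytest.mark.parametrize("method", ["bayes", "map"])
    def test_recovers_known_threshold(self, rng, method):
        """Known observer (slope 2, lapse 0), 500 trials/level: the fitted
        45% threshold lands within 10% of the generative 45% saturation."""
        obs = Observer(thresholds=(0.1,) * 8, slope=2.0, lapse_rate=0.0)
        sats, corr = self._designed_trials(obs, rng)
        fit = fit_psychometric(sats, corr, method=method)
        q0 = 0.2 / 0.75
        true45 = 0.1 * math.exp(math.log(q0 / (1 - q0)) / 2.0)
        assert fit.fittable
        assert fit.threshold == pytest.approx(true45, rel=0.10)

    def test_all_correct_unfittable(self):
        fit = fit_psychometric(np.array([0.1, 0.2, 0.4]), np.array([True, True, True]))
        assert not fit.fittable and np.isnan(fit.threshold)

    def test_single_level_unfittable(self):
        fit = fit_psychometric(
            np.full(20, 0.1), np.array([True, False] * 10, dtype=bool)
        )
        assert not fit.fittable

    def test_log_axis_equivariance(self, rng):
        """Scaling every saturation by 10 scales the threshold by 10."""
        obs = Observer(thresholds=(0.1,) * 8, slope=3.0)
        sats, corr = self._designed_trials(obs, rng, n_per_level=200)
        f1 = fit_psychometric(sats, corr)
        f2 = fit_psychometric(sats * 10, corr)
        assert f2.threshold == pytest.approx(10 * f1.threshold, rel=1e-6)


class TestDiscriminationEllipse:
    def test_equal_thresholds_give_circle(self):
        pts = 0.3 * AXES.unit_vectors
        ell = fit_discrimination_ellipse(pts)
        assert ell.valid
        assert ell.radii[0] == pytest.approx(0.3, abs=1e-9)
        assert ell.radii[1] == pytest.approx(0.3, abs=1e-9)

    def test_exact_recovery_of_rotated_ellipse(self):
        """8 noiseless points on a known rotated ellipse: radii and
        orientation recovered to 1e-6 (exact-interpolation oracle)."""
        A_true = ellipse_form(2.0, 1.0, 45.0)
        pts = np.array(
            [ellipse_radius(A_true, a) for a in AXES.angles_deg]
        )[:, None] * AXES.unit_vectors
        ell = fit_discrimination_ellipse(pts)
        assert ell.valid
        assert ell.radii[0] == pytest.approx(2.0, abs=1e-6)
        assert ell.radii[1] == pytest.approx(1.0, abs=1e-6)
        assert ell.orientation_deg == pytest.approx(45.0, abs=1e-6)
        np.testing.assert_allclose(ell.A, A_true, atol=1e-6)

    def test_seven_point_fit(self):
        pts = 0.3 * AXES.unit_vectors
        pts[2] = np.nan
        ell = fit_discrimination_ellipse(pts)
        assert ell.valid and ell.radii[0] == pytest.approx(0.3, abs=1e-9)

    def test_too_few_points_raise(self):
        pts = 0.3 * AXES.unit_vectors
        pts[:4] = np.nan
        with pytest.raises(ValueError, match=">= 5"):
            fit_discrimination_ellipse(pts)

    @given(st.integers(0, 100))
    @settings(deadline=None, max_examples=20)
    def test_matches_gradient_oracle_on_noiseless_inputs(self, seed):
        """The linear least-squares conic equals an independent gradient-based
        minimiser of the same objective on noiseless 8-point inputs."""
        from scipy.optimize import minimize as sp_minimize

        r = np.random.default_rng(seed)
        A_true = ellipse_form(
            1.0 + r.uniform(0.2, 2.0), 1.0, r.uniform(0, 180)
        )
        pts = np.array(
            [ellipse_radius(A_true, a) for a in AXES.angles_deg]
        )[:, None] * AXES.unit_vectors

        def obj(p):
            a, b, c = p
            q = a * pts[:, 0] ** 2 + 2 * b * pts[:, 0] * pts[:, 1] + c * pts[:, 1] ** 2
            return ((q - 1.0) ** 2).sum()

        res = sp_minimize(obj, x0=[1.0, 0.0, 1.0], method="BFGS", tol=1e-14)
        ell = fit_discrimination_ellipse(pts)
        np.testing.assert_allclose(
            [ell.A[0, 0], ell.A[0, 1], ell.A[1, 1]], res.x, atol=1e-6
        )


class TestDiscriminationLogAxisRatio:
    def test_isotropic_is_zero(self):
        assert discrimination_log_axis_ratio(np.full(8, 0.2)).log_axis_ratio == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_diagonal_ellipse_gives_ln2(self):
        """Thresholds consistent with an ellipse of diagonal radii 2:1 give a
        log axis ratio of exactly ln 2 (the fit interpolates)."""
        A_true = ellipse_form(2.0, 1.0, -45.0)  # major along the negative diagonal
        thr = np.array([ellipse_radius(A_true, a) for a in AXES.angles_deg])
        for method in ("log-radius", "conic"):
            res = discrimination_log_axis_ratio(thr, method=method)
            assert res.log_axis_ratio == pytest.approx(math.log(2.0), abs=1e-9)

    def test_swapping_diagonals_flips_sign(self):
        A_true = ellipse_form(1.5, 1.0, -45.0)
        thr = np.array([ellipse_radius(A_true, a) for a in AXES.angles_deg])
        swapped = thr.copy()
        for i, j in zip(AXES.blue_yellow, AXES.reflected):
            swapped[i], swapped[j] = thr[j], thr[i]
        a = discrimination_log_axis_ratio(thr).log_axis_ratio
        b = discrimination_log_axis_ratio(swapped).log_axis_ratio
        assert a == pytest.approx(-b, abs=1e-9)

    @given(st.floats(0.1, 10.0), st.integers(0, 50))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_uniform_scaling(self, scale, seed):
        r = np.random.default_rng(seed)
        thr = np.exp(r.normal(-2, 0.3, 8))
        a = discrimination_log_axis_ratio(thr).log_axis_ratio
        b = discrimination_log_axis_ratio(thr * scale).log_axis_ratio
        assert a == pytest.approx(b, abs=1e-7)


class TestCvdScreen:
    def test_equal_thresholds_ratio_one(self):
        assert cvd_threshold_ratio(np.full(8, 0.1)) == pytest.approx(1.0)

    def test_ratio_two(self):
        thr = np.full(8, 1.0)
        for i in AXES.cardinal_l:
            thr[i] = 2.0
        assert cvd_threshold_ratio(thr) == pytest.approx(2.0)

    def test_tukey_fences_flag_outlier(self, rng):
        ratios = np.concatenate([1.0 + 0.01 * rng.standard_normal(29), [10.0]])
        flags = tukey_outliers(ratios)
        assert flags[-1] and flags[:29].sum() == 0
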