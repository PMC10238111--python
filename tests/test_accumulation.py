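"""PAM and SPAM accumulation indices and their AGB calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ricepam.accumulation import (
    AGBRegressor,
    PAMConfig,
    SPAMInputs,
    Trajectory,
    fit_agb_model,
    heading_observation,
    pam_index,
    pam_index_series,
    predict_agb,
    spam_index,
    spam_index_series,
)
from ricepam.errors import (
    DegenerateDesignError,
    NonMonotoneTrajectoryError,
    RicePamError,
)


def traj(t, integrand=None, vi1=None, vi2=None, h=None, t0=0.0):
    n = len(t)
    if integrand is not None:
        vi1 = vi2 = [1.0] * n
        h = list(integrand)
    return Trajectory.from_arrays("P", t, vi1, vi2, h, t0)


class TestPamIndex:
    def test_single_rectangle(self):
        assert pam_index(traj([10], [1.0])) == pytest.approx(10.0)

    def test_two_rectangles(self):
        # integrand 1 over (0,10], 2 over (10,20]
        assert pam_index(traj([10, 20], [1.0, 2.0])) == pytest.approx(30.0)

    def test_empty_sum(self):
        assert pam_index(traj([], [])) == 0.0
        assert pam_index_series(traj([], [])).size == 0

    def test_trapezoid_variant(self):
        # panels: (0+1)/2*10 = 5 and (1+2)/2*10 = 15
        cfg = PAMConfig(quadrature="trapezoid")
        assert pam_index(traj([10, 20], [1.0, 2.0]), cfg) == pytest.approx(20.0)

    def test_daily_sampling_tracks_fine_quadrature(self):
        """Daily rectangle accumulation of a smooth seasonal integrand stays
        within 2% of its 0.1-day-step quadrature."""
        def integrand(t):
            vi = 0.85 / (1 + np.exp(-0.15 * (t - 30)))
            h = 1.1 / (1 + np.exp(-0.13 * (t - 45)))
            return vi**2 * h

        days = np.arange(1, 91)
        coarse = pam_index(traj(days, integrand(days)))
        fine_t = np.arange(0.1, 90.0 + 1e-9, 0.1)
        fine = np.sum(integrand(fine_t) * 0.1)
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_quadrature_variants_converge(self):
        def integrand(t):
            return (0.8 / (1 + np.exp(-0.2 * (t - 30)))) ** 2

        t = np.arange(0.1, 90, 0.1)
        rect = pam_index(traj(t, integrand(t)))
        trap = pam_index(traj(t, integrand(t)), PAMConfig(quadrature="trapezoid"))
        assert rect == pytest.approx(trap, rel=1e-3)

    @given(st.integers(0, 8))
    def test_additivity_over_prefixes(self, k):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(1, 80, 8))
        g = rng.uniform(0, 2, 8)
        full = pam_index(traj(t, g))
        k = min(k, 7)
        head = pam_index(traj(t[: k + 1], g[: k + 1]))
        tail = pam_index(traj(t[k + 1:], g[k + 1:], t0=t[k])) if k < 7 else 0.0
        assert head + tail == pytest.approx(full, rel=1e-12)

    def test_series_monotone_for_nonnegative_integrand(self, rng):
        t = np.sort(rng.uniform(1, 80, 12))
        series = pam_index_series(traj(t, rng.uniform(0, 3, 12)))
        assert (np.diff(series) >= 0).all()

    def test_trajectory_validation(self):
        with pytest.raises(NonMonotoneTrajectoryError):
            traj([10, 10], [1.0, 1.0])          # duplicate time
        with pytest.raises(NonMonotoneTrajectoryError):
            traj([20, 10], [1.0, 1.0])          # unsorted
        with pytest.raises(NonMonotoneTrajectoryError):
            traj([5], [1.0], t0=5.0)            # first obs not after t0
        with pytest.raises(RicePamError):
            traj([10], vi1=[1.0], vi2=[1.0], h=[-0.1])
        with pytest.raises(RicePamError):
            PAMConfig(quadrature="simpson")


class TestSpamIndex:
    def test_pre_heading_triangle(self):
        inp = SPAMInputs(t=40, vi_t=0.8, h_t=1.0, T1=60, vi_T1=0.9, h_T1=1.0)
        assert spam_index(inp) == pytest.approx(12.8)  # 0.64*40/2

    def test_post_heading_triangle_plus_trapezoid(self):
        inp = SPAMInputs(t=80, vi_t=0.7, h_t=1.1, T1=60, vi_T1=0.9, h_T1=1.0)
        # 0.81*30 + (0.539 + 0.81)*10
        assert spam_index(inp) == pytest.approx(37.79)

    @given(
        t1=st.floats(20, 70),
        vi=st.floats(0.05, 0.95),
        h=st.floats(0.01, 1.5),
    )
    def test_continuity_at_heading(self, t1, vi, h):
        """Both branches agree exactly when the target day is heading day."""
        at = SPAMInputs(t=t1, vi_t=vi, h_t=h, T1=t1, vi_T1=vi, h_T1=h)
        just_after = SPAMInputs(t=t1, vi_t=vi, h_t=h, T1=t1 - 1e-12, vi_T1=vi, h_T1=h)
        assert spam_index(at) == pytest.approx(spam_index(just_after), rel=1e-9)
        # branch formulas coincide algebraically at t == T1
        pre = vi**2 * h * t1 / 2
        post = vi**2 * h * t1 / 2 + (vi**2 * h + vi**2 * h) * 0.0 / 2
        assert pre == post

    def test_target_before_transplanting(self):
        with pytest.raises(RicePamError, match="precedes"):
            SPAMInputs(t=0, vi_t=0.5, h_t=1.0, T1=60, vi_T1=0.9, h_T1=1.0)
        with pytest.raises(RicePamError):
            SPAMInputs(t=40, vi_t=0.5, h_t=1.0, T1=0, vi_T1=0.9, h_T1=1.0)

    def test_whitelist_enforced(self):
        trajectory = traj([30, 60, 80], [0.5, 0.8, 0.7])
        with pytest.raises(RicePamError, match="CIgreen"):
            spam_index_series(trajectory, 60, vi_name="CIgreen")
        # whitelisted index passes
        out = spam_index_series(trajectory, 60, vi_name="NDVI")
        assert out.shape == (3,)

    def test_heading_observation_window(self):
        trajectory = traj([30, 58, 80], [0.5, 0.8, 0.7])
        t_h, vi_h, h_h = heading_observation(trajectory, 60, window=5)
        assert t_h == 58
        with pytest.raises(RicePamError, match="within 5"):
            heading_observation(traj([30, 80], [0.5, 0.7]), 60, window=5)

    def test_series_matches_scalar(self):
        trajectory = traj([30, 58, 80], [0.5, 0.8, 0.7])
        series = spam_index_series(trajectory, 60)
        expected = [
            spam_index(SPAMInputs(t=t, vi_t=1.0, h_t=g, T1=58, vi_T1=1.0, h_T1=0.8))
            for t, g in [(30, 0.5), (58, 0.8), (80, 0.7)]
        ]
        assert np.allclose(series, expected)


class TestAgbModel:
    def test_exact_line(self):
        pairs = [(i, 5.0 * i + 10.0) for i in range(6)]
        model = fit_agb_model(pairs)
        assert model.slope_ == pytest.approx(5.0, abs=1e-10)
        assert model.intercept_ == pytest.approx(10.0, abs=1e-10)
        assert model.rmse_ == pytest.approx(0.0, abs=1e-9)
        assert model.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_noisy_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 40, 30)
        y = 4.2 * x + 30 + rng.normal(0, 15, 30)
        model = fit_agb_model(np.column_stack([x, y]))
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert model.slope_ == pytest.approx(slope, abs=1e-10)
        assert model.intercept_ == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDesignError):
            fit_agb_model([(1.0, 5.0), (2.0, 9.0)])

    def test_constant_index(self):
        with pytest.raises(DegenerateDesignError):
            fit_agb_model([(1.0, 5.0), (1.0, 9.0), (1.0, 2.0)])

    def test_predict_and_floor(self):
        model = AGBRegressor()
        model.slope_, model.intercept_ = 5.0, 10.0
        assert predict_agb(model, 2.0) == pytest.approx(20.0)
        assert predict_agb(model, 0.0) == pytest.approx(10.0)

        model.intercept_ = -100.0
        assert predict_agb(model, 1.0) == 0.0  # floored
        assert model.n_floored_ == 1
        out = predict_agb(model, np.array([1.0, 50.0]))
        assert out[0] == 0.0 and out[1] == pytest.approx(150.0)
        assert model.n_floored_ == 1
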