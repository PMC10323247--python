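"""Diffusion-estimator tests: projection geometry, CVE closed forms,
MSD cross-validation, motility classification calibration."""

import numpy as np
import pytest

from tirftrack import (
    MicrotubulePath,
    Projected1DTrack,
    Spot,
    Track,
    classify_motility,
    cve_diffusion,
    msd_diffusion,
    project_onto_path,
)

DT = 0.113
PX = 0.13


def track_from_xy(xy, track_id=0):
    spots = [
        Spot(frame=f, x=float(x), y=float(y), sigma=1.1,
             integrated_intensity=100.0, local_background=0.0)
        for f, (x, y) in enumerate(xy)
    ]
    return Track(track_id=track_id, spots=spots)


def brownian_1d(n_steps, D, dt=DT, sigma_loc=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    s = np.cumsum(np.concatenate([[0.0], rng.normal(0, np.sqrt(2 * D * dt), n_steps)]))
    if sigma_loc > 0:
        s = s + rng.normal(0, sigma_loc, n_steps + 1)
    return Projected1DTrack(0, s, np.arange(n_steps + 1), np.zeros(n_steps + 1), dt)


class TestProjection:
    def test_straight_path_arclength_equals_x(self):
        path = MicrotubulePath([[0, 10], [50, 10]], pixel_size=PX)
        xs = np.array([3.0, 7.5, 20.0, 41.2])
        tr = track_from_xy([(x, 10.0) for x in xs])
        p1d = project_onto_path(tr, path, pixel_size=PX, dt=DT)
        assert np.allclose(p1d.s, xs * PX, atol=1e-9)
        assert np.allclose(p1d.residuals, 0.0, atol=1e-9)

    def test_perpendicular_offset_preserves_arclength(self):
        path = MicrotubulePath([[0, 10], [50, 10]], pixel_size=PX)
        xs = np.array([3.0, 7.5, 20.0, 41.2])
        tr = track_from_xy([(x, 12.0) for x in xs])  # +2 px offset
        p1d = project_onto_path(tr, path, pixel_size=PX, dt=DT)
        assert np.allclose(p1d.s, xs * PX, atol=1e-9)
        assert np.allclose(np.abs(p1d.residuals), 2.0 * PX, atol=1e-9)

    def test_semicircle_arclengths(self):
        """Points at angles theta on a radius-r semicircle map to arclength
        r*theta within 1% for 1 px path sampling."""
        r = 40.0
        theta_path = np.linspace(0, np.pi, int(np.pi * r) + 1)  # ~1 px steps
        pts = np.stack([50 + r * np.cos(theta_path), 50 + r * np.sin(theta_path)], 1)
        path = MicrotubulePath(pts, pixel_size=PX)
        thetas = np.array([0.3, 0.9, 1.7, 2.6])
        xy = [(50 + r * np.cos(t), 50 + r * np.sin(t)) for t in thetas]
        p1d = project_onto_path(track_from_xy(xy), path, pixel_size=PX, dt=DT)
        assert np.allclose(p1d.s, r * thetas * PX, rtol=0.01)

    def test_principal_axis_projection_is_isometry_for_straight_tracks(self):
        """Pairwise arclength differences equal along-axis distances."""
        rng = np.random.default_rng(3)
        t = np.linspace(0, 10, 40)
        xy = np.stack([5 + 3 * t, 7 + 4 * t], 1)  # line of slope 4/3
        p1d = project_onto_path(track_from_xy(xy), None, pixel_size=PX, dt=DT)
        d_axis = np.abs(np.subtract.outer(t, t)) * 5.0 * PX  # |dxy| = 5 dt
        d_s = np.abs(np.subtract.outer(p1d.s, p1d.s))
        assert np.allclose(d_s, d_axis, atol=1e-9)
        _ = rng

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError):
            MicrotubulePath([[5, 5], [5, 5]], pixel_size=PX)


class TestCVE:
    def test_constant_positions_zero_estimates(self):
        s = np.full(50, 1.23)
        p1d = Projected1DTrack(0, s, np.arange(50), np.zeros(50), DT)
        est = cve_diffusion(p1d)
        assert est.D_hat == 0.0
        assert est.sigma2_loc_hat == 0.0

    def test_long_noiseless_brownian_recovery(self):
        """Mean CVE over ten 1e5-step noiseless tracks within 1% of truth
        (single-track sampling SD is ~0.8%, so the check uses an ensemble)."""
        rng = np.random.default_rng(1)
        est = [cve_diffusion(brownian_1d(100_000, 0.05, rng=rng)).D_hat
               for _ in range(10)]
        assert np.mean(est) == pytest.approx(0.05, rel=0.01)

    def test_static_noise_closed_form(self):
        """Static + iid noise: <d^2> -> 2 sigma^2, lag-1 cov -> -sigma^2,
        hence mean D_hat -> 0 (2 s.e.) and sigma2_loc -> sigma^2 (5%)."""
        rng = np.random.default_rng(2)
        sigma = 0.02
        Ds, S2s = [], []
        for _ in range(1000):
            s = rng.normal(0, sigma, 101)
            p1d = Projected1DTrack(0, s, np.arange(101), np.zeros(101), DT)
            est = cve_diffusion(p1d)
            Ds.append(est.D_hat)
            S2s.append(est.sigma2_loc_hat)
        Ds, S2s = np.array(Ds), np.array(S2s)
        se = Ds.std(ddof=1) / np.sqrt(len(Ds))
        assert abs(Ds.mean()) < 2 * se
        assert S2s.mean() == pytest.approx(sigma**2, rel=0.05)

    def test_gap_spanning_steps_excluded(self):
        # positions with one large jump across a gap: excluded from moments
        s = np.concatenate([np.zeros(20), np.full(20, 10.0)])
        frames = np.concatenate([np.arange(20), np.arange(25, 45)])
        p1d = Projected1DTrack(0, s, frames, np.zeros(40), DT)
        est = cve_diffusion(p1d)
        assert est.D_hat == 0.0  # the jump never enters

    def test_too_short_flagged_invalid(self):
        p1d = Projected1DTrack(0, np.arange(5.0), np.arange(5), np.zeros(5), DT)
        est = cve_diffusion(p1d, min_steps=10)
        assert not est.valid
        assert np.isnan(est.D_hat)

    def test_bad_blur_coefficient_rejected(self):
        p1d = brownian_1d(100, 0.05)
        with pytest.raises(ValueError):
            cve_diffusion(p1d, R=0.3)

    def test_blur_R_one_sixth_with_subframe_averaged_noise_free(self):
        """With R=1/6 and no noise, sigma2_loc estimates the blur-induced
        pseudo-variance; D_hat stays unbiased on long sampled tracks."""
        p1d = brownian_1d(50_000, 0.04, rng=np.random.default_rng(4))
        est = cve_diffusion(p1d, R=1 / 6)
        assert est.D_hat == pytest.approx(0.04, rel=0.02)


class TestMSD:
    def test_cross_validates_cve_on_long_tracks(self):
        p1d = brownian_1d(10_000, 0.05, rng=np.random.default_rng(5))
        d_cve = cve_diffusion(p1d).D_hat
        d_msd = msd_diffusion(p1d, max_lag=10)
        assert abs(d_cve - d_msd) / 0.05 < 0.03

    def test_static_noiseless_zero(self):
        s = np.full(200, 2.0)
        p1d = Projected1DTrack(0, s, np.arange(200), np.zeros(200), DT)
        assert msd_diffusion(p1d) == 0.0

    def test_ballistic_track_slope_grows_with_lag(self):
        """Directed motion: MSD ~ v^2 tau^2, so the fitted slope increases
        with max_lag — a model-violation detector."""
        v = 0.1
        s = v * np.arange(500) * DT
        p1d = Projected1DTrack(0, s, np.arange(500), np.zeros(500), DT)
        d_small = msd_diffusion(p1d, max_lag=5)
        d_large = msd_diffusion(p1d, max_lag=20)
        assert d_large > d_small * 2


class TestClassification:
    def test_exact_zero_is_static(self):
        s = np.full(60, 1.0)
        p1d = Projected1DTrack(0, s, np.arange(60), np.zeros(60), DT)
        est = cve_diffusion(p1d)
        assert classify_motility(est, dt=DT) == "static"

    def test_static_false_positive_rate_calibrated(self):
        """<= alpha of simulated static tracks classified diffusive."""
        rng = np.random.default_rng(6)
        n_fp = 0
        n = 400
        for _ in range(n):
            s = rng.normal(0, 0.02, 101)
            p1d = Projected1DTrack(0, s, np.arange(101), np.zeros(101), DT)
            est = cve_diffusion(p1d)
            n_fp += classify_motility(est, alpha=0.05, dt=DT) == "diffusive"
        assert n_fp / n <= 0.08  # 0.05 nominal + simulation margin

    def test_power_on_diffusive_tracks(self):
        """>95% of D=0.06 tracks with 100 steps classified diffusive."""
        rng = np.random.default_rng(7)
        n_hit = 0
        n = 300
        for _ in range(n):
            p1d = brownian_1d(100, 0.06, sigma_loc=0.02, rng=rng)
            est = cve_diffusion(p1d)
            n_hit += classify_motility(est, alpha=0.05, dt=DT) == "diffusive"
        assert n_hit / n > 0.95


def test_parameter_recovery_at_study_scale():
    """Ensemble median D_hat within 15% of truth for D in the measured
    regime (0.011-0.06 µm²/s), 200 tracks x 100 steps, sigma_loc 0.02 µm."""
    rng = np.random.default_rng(8)
    for D in (0.011, 0.04, 0.06):
        est = [
            cve_diffusion(brownian_1d(100, D, sigma_loc=0.02, rng=rng)).D_hat
            for _ in range(200)
        ]
        assert np.median(est) == pytest.approx(D, rel=0.15)


def test_sigma2_recovery_long_tracks():
    """Injected localization variance recovered within 10% at 500 steps."""
    rng = np.random.default_rng(9)
    s2 = [
        cve_diffusion(brownian_1d(500, 0.03, sigma_loc=0.02, rng=rng)).sigma2_loc_hat
        for _ in range(300)
    ]
    assert np.mean(s2) == pytest.approx(4e-4, rel=0.10)
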