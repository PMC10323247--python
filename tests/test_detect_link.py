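"""Detection, linking, segmentation and kymograph tests on rendered scenes."""

import numpy as np
import pytest

from tirftrack import (
    ImageStack,
    MicrotubulePath,
    SceneConfig,
    Spot,
    default_max_disp,
    detect_spots,
    detect_stack,
    link_tracks,
    make_kymograph,
    render_microtubule_channel,
    render_stack,
    segment_microtubules,
    simulate_tracks,
    straight_path,
    unit_intensity_for_snr,
)


def render_single_spot(x0, y0, cfg, rng=None, noise=True):
    """One stationary monomer at (x0, y0); returns the rendered first frame."""
    path = MicrotubulePath([[x0 - 1e-3, y0], [x0 + 1e-3, y0]], pixel_size=cfg.pixel_size)
    truth = simulate_tracks(cfg, path, n_particles=1, rng=rng or cfg.rng())
    truth.s[:] = path.length / 2
    truth.surviving[:] = 1
    stack = render_stack(truth, cfg, rng=rng, noise=noise)
    return stack.frames[0]


class TestRender:
    def test_zero_signal_zero_noise_gives_zero_stack(self, horizontal_path):
        cfg = SceneConfig(
            n_frames=3, image_size=(48, 96), unit_intensity=0.0,
            background_rate=0.0, read_noise_sd=0.0, seed=1,
        )
        truth = simulate_tracks(cfg, horizontal_path, n_particles=4)
        stack = render_stack(truth, cfg)
        assert np.all(stack.frames == 0)

    def test_noiseless_psf_volume_matches_unit_intensity(self):
        """Pixel sum of one noiseless monomer equals gain x unit photons
        (PSF normalization, Gaussian truncation < 0.5%)."""
        cfg = SceneConfig(
            n_frames=1, image_size=(48, 48), background_rate=0.0,
            read_noise_sd=0.0, unit_intensity=500.0, bleach_rate=0.0,
        )
        frame = render_single_spot(24.0, 24.0, cfg, noise=False)
        expected = cfg.camera_gain * cfg.unit_intensity
        assert frame.sum() == pytest.approx(expected, rel=0.005)

    def test_poisson_mean_fitted_intensity(self):
        """Mean fitted integrated intensity over noisy frames matches
        gain x unit_intensity within 3 s.e. (Poisson mean)."""
        cfg = SceneConfig(n_frames=1, image_size=(48, 48), seed=9)
        cfg.unit_intensity = unit_intensity_for_snr(cfg, 12)
        rng = cfg.rng()
        vals = []
        for _ in range(120):
            frame = render_single_spot(24.2, 23.7, cfg, rng=rng)
            spots = detect_spots(frame, cfg.psf_sigma, snr_min=4)
            assert spots
            vals.append(spots[0].integrated_intensity)
        vals = np.array(vals)
        expected = cfg.camera_gain * cfg.unit_intensity
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se + 0.03 * expected

    def test_uint16_output_clipped_and_typed(self, small_config, horizontal_path):
        truth = simulate_tracks(small_config, horizontal_path, n_particles=2)
        stack = render_stack(truth, small_config, dtype="uint16")
        assert stack.frames.dtype == np.uint16


class TestDetect:
    def test_blank_noise_frames_produce_no_spots(self):
        """False-positive calibration: snr_min=5 on pure noise frames."""
        n_fp = 0
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            frame = rng.poisson(20, (64, 64)) * 20.0 + rng.normal(0, 10, (64, 64))
            n_fp += bool(detect_spots(frame, 1.1, snr_min=5))
        assert n_fp <= 1  # >= 99% of frames clean

    def test_subpixel_localization_at_snr10(self):
        """Sub-pixel localization RMSE < 0.15 px at SNR 10 (ensemble of 30
        noise realizations of a spot at (20.30, 21.70))."""
        cfg = SceneConfig(n_frames=1, image_size=(48, 48), seed=2)
        cfg.unit_intensity = unit_intensity_for_snr(cfg, 10)
        rng = cfg.rng()
        errs = []
        for _ in range(30):
            frame = render_single_spot(20.30, 21.70, cfg, rng=rng)
            spots = detect_spots(frame, cfg.psf_sigma, snr_min=4)
            assert len(spots) == 1
            errs.append([spots[0].x - 20.30, spots[0].y - 21.70])
        assert np.sqrt(np.mean(np.square(errs))) < 0.15

    def test_two_spots_five_sigma_apart_resolved(self):
        cfg = SceneConfig(n_frames=1, image_size=(48, 48), seed=4)
        cfg.unit_intensity = unit_intensity_for_snr(cfg, 12)
        sep = 5 * cfg.psf_sigma
        rng = cfg.rng()
        f1 = render_single_spot(24 - sep / 2, 24.0, cfg, rng=rng, noise=False)
        f2 = render_single_spot(24 + sep / 2, 24.0, cfg, rng=rng, noise=False)
        lam = (f1 + f2 - cfg.background_rate * cfg.camera_gain) / cfg.camera_gain
        frame = rng.poisson(np.clip(lam, 0, None)) * cfg.camera_gain
        spots = detect_spots(frame, cfg.psf_sigma, snr_min=4)
        assert len(spots) == 2

    def test_nonfinite_frame_rejected(self):
        frame = np.zeros((32, 32))
        frame[5, 5] = np.nan
        with pytest.raises(ValueError):
            detect_spots(frame, 1.1)


def _static_spot(frame, x, y):
    return Spot(frame=frame, x=x, y=y, sigma=1.1, integrated_intensity=100.0,
                local_background=0.0)


class TestLink:
    def test_single_particle_single_track(self):
        spots = [[_static_spot(f, 10.0 + 0.01 * f, 12.0)] for f in range(30)]
        tracks = link_tracks(spots, max_disp=3)
        assert len(tracks) == 1
        assert len(tracks[0]) == 30

    def test_two_distant_static_particles_no_swaps(self):
        spots = [
            [_static_spot(f, 10.0, 10.0), _static_spot(f, 30.0, 10.0)]
            for f in range(20)
        ]
        tracks = link_tracks(spots, max_disp=5)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.xy[:, 0]) == 0.0

    def test_gap_closing_within_max_gap(self):
        spots = [[_static_spot(f, 10.0, 10.0)] if f not in (5, 6) else []
                 for f in range(15)]
        tracks = link_tracks(spots, max_disp=3, max_gap=2)
        assert len(tracks) == 1
        assert len(tracks[0]) == 13

    def test_gap_beyond_max_gap_splits(self):
        spots = [[_static_spot(f, 10.0, 10.0)] if not 5 <= f < 12 else []
                 for f in range(20)]
        tracks = link_tracks(spots, max_disp=3, max_gap=2)
        assert len(tracks) == 2

    def test_no_step_exceeds_gate(self):
        """Hard invariant: no linked single-frame displacement > max_disp."""
        rng = np.random.default_rng(0)
        spots = []
        for f in range(50):
            spots.append(
                [_static_spot(f, float(x), float(y))
                 for x, y in rng.uniform(0, 60, size=(8, 2))]
            )
        md = 4.0
        for tr in link_tracks(spots, max_disp=md, max_gap=3):
            xy = tr.xy
            fr = tr.frames
            steps = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
            elapsed = np.diff(fr)
            assert np.all(steps <= md * np.sqrt(elapsed) + 1e-9)


class TestSegmentAndKymograph:
    def test_straight_microtubule_recovered_on_row(self):
        cfg = SceneConfig(n_frames=5, image_size=(64, 96), seed=6)
        path = straight_path(32.0, 8, 87, pixel_size=cfg.pixel_size)
        mt = render_microtubule_channel(path, cfg, rng=cfg.rng())
        found = segment_microtubules(mt)
        assert len(found) == 1
        assert np.all(np.abs(found[0].points[:, 1] - 32.0) < 0.5)

    def test_blank_channel_returns_empty(self):
        cfg = SceneConfig(n_frames=5, image_size=(48, 48), mt_intensity=0.0, seed=1)
        mt = render_microtubule_channel([], cfg, rng=cfg.rng())
        with pytest.warns(UserWarning):
            assert segment_microtubules(mt) == []

    def test_two_parallel_microtubules_disjoint(self):
        cfg = SceneConfig(n_frames=5, image_size=(80, 96), seed=3)
        p1 = straight_path(20.0, 8, 87, pixel_size=cfg.pixel_size)
        p2 = straight_path(50.0, 8, 87, pixel_size=cfg.pixel_size)
        mt = render_microtubule_channel([p1, p2], cfg, rng=cfg.rng())
        found = segment_microtubules(mt)
        assert len(found) == 2
        ys = sorted(np.median(p.points[:, 1]) for p in found)
        assert ys[0] == pytest.approx(20, abs=1)
        assert ys[1] == pytest.approx(50, abs=1)

    def test_static_particle_vertical_kymograph_line(self):
        cfg = SceneConfig(
            n_frames=30, image_size=(48, 96), static_fraction=1.0,
            bleach_rate=0.0, oligomer_size_distribution=[1.0], seed=2,
        )
        cfg.unit_intensity = unit_intensity_for_snr(cfg, 20)
        path = straight_path(24.0, 8, 87, pixel_size=cfg.pixel_size)
        truth = simulate_tracks(cfg, path, n_particles=1, rng=cfg.rng())
        stack = render_stack(truth, cfg, rng=cfg.rng())
        kymo = make_kymograph(stack, path, width=5)
        cols = kymo.argmax(axis=1)
        assert np.ptp(cols) <= 2  # constant arclength column +/- 1 px

    def test_microtubule_channel_kymograph_time_invariant(self):
        cfg = SceneConfig(n_frames=10, image_size=(48, 96), read_noise_sd=0.0,
                          background_rate=0.0, seed=5)
        path = straight_path(24.0, 8, 87, pixel_size=cfg.pixel_size)
        mt = render_microtubule_channel(path, cfg, noise=False)
        kymo = make_kymograph(mt, path, width=3, reducer="mean")
        assert np.allclose(kymo, kymo[0], rtol=1e-6)

    def test_kymograph_width_validated(self, small_config, horizontal_path):
        stack = ImageStack(np.zeros((2, 48, 96), dtype=np.float32))
        with pytest.raises(ValueError):
            make_kymograph(stack, horizontal_path, width=0)


def test_diffusive_scene_trajectory_recovery():
    """Most trajectories in a sparse diffusive scene are recovered as single
    tracks (majority coverage at 1 px tolerance)."""
    cfg = SceneConfig(
        n_frames=60, image_size=(96, 96), D=0.06, static_fraction=0.0,
        oligomer_size_distribution=[1.0], bleach_rate=0.0, seed=13,
    )
    cfg.unit_intensity = unit_intensity_for_snr(cfg, 10)
    rng = cfg.rng()
    paths = [straight_path(y, 9, 86, pixel_size=cfg.pixel_size) for y in (20, 48, 76)]
    truths = [simulate_tracks(cfg, p, n_particles=2, rng=rng) for p in paths]
    frames = None
    for tr in truths:
        st = render_stack(tr, cfg, noise=False)
        frames = st.frames if frames is None else frames + st.frames
    frames -= (len(truths) - 1) * cfg.background_rate * cfg.camera_gain
    lam = np.clip(frames / cfg.camera_gain, 0, None)
    noisy = rng.poisson(lam) * cfg.camera_gain + rng.normal(0, cfg.read_noise_sd, frames.shape)
    stack = ImageStack(noisy, pixel_size=cfg.pixel_size, dt=cfg.dt)
    spots = detect_stack(stack, psf_sigma_guess=cfg.psf_sigma, snr_min=4)
    md = default_max_disp(0.15, cfg.dt, cfg.pixel_size)
    tracks = link_tracks(spots, max_disp=md, max_gap=5, min_length=5)
    rec = 0
    for truth in truths:
        for p in range(truth.n_particles):
            txy = truth.path.point_at(truth.s[p])
            best = 0.0
            for tr in tracks:
                fr, xy = tr.frames, tr.xy
                d = np.hypot(xy[:, 0] - txy[fr, 0], xy[:, 1] - txy[fr, 1])
                best = max(best, np.sum(d < 1.0) / truth.n_frames)
            rec += best >= 0.5
    assert rec >= 5  # 6 particles total
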