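"""Simulate a single-molecule movie, then re-measure it blind.

Renders diffusing GFP-tagged particles on a microtubule with realistic EMCCD
noise, detects sub-pixel spots, links them into tracks, projects each track
onto its averaged path, and estimates per-track diffusion coefficients with
the covariance-based estimator (CVE).
"""

import numpy as np

from tirftrack import (
    SceneConfig,
    classify_motility,
    cve_diffusion,
    default_max_disp,
    detect_stack,
    link_tracks,
    project_onto_path,
    render_stack,
    simulate_tracks,
    straight_path,
    unit_intensity_for_snr,
)

cfg = SceneConfig(
    n_frames=150, image_size=(48, 256), D=0.05, static_fraction=0.2,
    oligomer_size_distribution=[1.0], bleach_rate=0.0, seed=42,
)
cfg.unit_intensity = unit_intensity_for_snr(cfg, 12)  # peak SNR 12
rng = cfg.rng()

path = straight_path(24.0, 10, 245, pixel_size=cfg.pixel_size)
truth = simulate_tracks(cfg, path, n_particles=6, rng=rng)
stack = render_stack(truth, cfg, rng=rng)

spots = detect_stack(stack, psf_sigma_guess=cfg.psf_sigma, snr_min=4)
max_disp = default_max_disp(0.15, cfg.dt, cfg.pixel_size)
tracks = link_tracks(spots, max_disp=max_disp, max_gap=5, min_length=20)

print(f"simulated {truth.n_particles} particles "
      f"({np.sum(truth.D > 0)} diffusive at D = {cfg.D} um^2/s, "
      f"{np.sum(truth.D == 0)} static); recovered {len(tracks)} tracks\n")
print("track  n_steps   D_hat (um^2/s)   class")
for tr in tracks:
    p1d = project_onto_path(tr, None, pixel_size=cfg.pixel_size, dt=cfg.dt)
    est = cve_diffusion(p1d)
    if est.valid:
        classify_motility(est, dt=cfg.dt)
    print(f"{tr.track_id:5d}  {est.n_steps:7d}   {est.D_hat:14.4f}   "
          f"{est.motility_class}")
print("\nD_hat is the noise-corrected 1D diffusion coefficient along the "
      "filament; 'static' tracks are indistinguishable from pure "
      "localization jitter.")
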