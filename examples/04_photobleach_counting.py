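"""Photobleaching calibration and molecule counting.

Calibrates the single-fluorophore unit intensity from simulated bleaching
traces (accepting only single-step traces found by change-point detection),
then counts molecules in oligomer tracks by dividing their first-20-frame
mean intensity by the unit.
"""

import numpy as np

from tirftrack import (
    SceneConfig,
    calibrate_unit_intensity,
    count_molecules,
    simulate_photobleach_trace,
)

# separate photobleaching experiment: higher illumination -> fast bleaching
calib_cfg = SceneConfig(bleach_rate=0.2, n_frames=150, seed=21)
unit_true = calib_cfg.camera_gain * calib_cfg.unit_intensity
rng = calib_cfg.rng()
traces = [
    simulate_photobleach_trace(1, calib_cfg, rng=rng, noise_sd=0.1 * unit_true,
                               n_frames=150)
    for _ in range(300)
]
cal = calibrate_unit_intensity(traces)
print(f"true unit intensity : {unit_true:8.1f} ADU")
print(f"calibrated unit     : {cal.unit_intensity:8.1f} ADU "
      f"({cal.n_accepted}/{cal.n_traces} traces accepted)")

# binding-movie conditions: low bleaching during the counting window
movie = SceneConfig(bleach_rate=0.01, n_frames=25, seed=22)
mrng = movie.rng()
print("\ntrue size   median counted (200 tracks each)")
for k in (1, 2, 4, 7, 10):
    counts = []
    for _ in range(200):
        tr = simulate_photobleach_trace(k, movie, rng=mrng,
                                        noise_sd=0.2 * unit_true, n_frames=25)
        counts.append(count_molecules(0, float(tr[:20].mean()),
                                      cal.unit_intensity).n_rounded)
    print(f"{k:9d}   {np.median(counts):8.0f}")
print("\nCounting divides the mean track intensity by the calibrated "
      "single-molecule unit; sizes up to ~10 are recovered faithfully.")
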