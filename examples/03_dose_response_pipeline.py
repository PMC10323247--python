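"""End-to-end importin dose-response with Ran-GTP rescue.

Builds a synthetic titration from the competition model (the free-complex
fraction sets the lattice-bound density), renders fields of view, and runs
the full quantification pipeline: microtubule segmentation, per-microtubule
background-corrected intensity, condition medians with 95% CIs, and
Mann-Whitney tests against the no-importin control.
"""

from tirftrack import PipelineParams, SceneConfig, run_pipeline, simulate_dose_response

cfg = SceneConfig(n_frames=6, image_size=(96, 192), seed=7)
conditions = [{"augmin": 1.0, "importin_b": d} for d in (0, 25, 50, 100, 200, 400)]
conditions.append({"augmin": 1.0, "importin_b": 400, "ran": 3500})

fovs = simulate_dose_response(conditions, cfg, n_fov_per_condition=4,
                              density0=1.0, n_mts=4, seed=7)
res = run_pipeline(fovs, PipelineParams(track_movies=False),
                   control_condition=conditions[0])

print(res.condition_summary.to_string(index=False))
print()
print(res.pairwise_tests.to_string(index=False))
print("\nMedians are background-corrected intensities per microtubule area "
      "(ADU/px); the titration falls monotonically with importin and the "
      "Ran-GTP condition returns to the control level.")
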