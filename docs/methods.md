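# Methods

This note documents the models, estimators and numerical choices behind
`tirftrack`, and what the synthetic experiments do and do not establish
about real data.

## Equilibrium competition model

The dose-response generator uses the minimal mass-action system consistent
with importin inhibition and Ran-GTP rescue of microtubule binding:

```
cargo + importin      ⇌  cargo·importin      Kd = kd_aug_imp   (default 13.1 nM)
Ran-GTP + importin-β  ⇌  Ran·importin-β      Kd = kd_ran_impB  (default 0.2 nM)
```

"Importin" is the inhibitory unit: importin β alone, or the preformed 1:1
α/β heterodimer when both are supplied (importin α alone is autoinhibited
and inert in the model; when α and β are both given, the inhibitory pool is
the β total).  Ran-GTP binds the β moiety and renders it unavailable for
cargo.  The microtubule-competent fraction is the free-cargo fraction at
equilibrium.  Whether Ran actively displaces cargo-bound importin or only
sequesters free importin is indistinguishable at equilibrium — both give the
same end state — so the model does not take a position.

Numerics: the importin mass balance is strictly increasing in free importin,
so the solve brackets on [0, importin_total] (Brent) and then applies three
analytic Newton steps.  The polish matters when free importin is orders of
magnitude below the total (steep balance); after it, mass conservation holds
to ~1e-12 relative, checked against 1e-9 in tests.

A hard structural property worth knowing: because free importin can never
exceed the total, any 1:1 competitive model obeys
`free_fraction >= Kd / (Kd + importin_total)`.  At Kd = 13.1 nM this floor
is 0.116 at 100 nM importin and 0.032 at 400 nM — "almost complete
inhibition" at 100 nM means ~12% residual binding in this model class, and
sub-10% inhibition requires the higher doses of the titration.

## Synthetic scenes

`SceneConfig` defaults describe the imaging regime the pipeline targets and
are chosen once:

| parameter | default | why |
| --- | --- | --- |
| `dt` | 0.113 s | single-molecule acquisition rate of the targeted assays (1 frame / 113 ms) |
| `pixel_size` | 0.13 µm/px | 13 µm EMCCD pixels behind a 100× objective |
| `psf_sigma` | 1.1 px | ~510 nm emission at NA 1.49, slightly conservative |
| `D` | 0.05 µm²/s | middle of the 0.01–0.1 µm²/s regime measured for lattice diffusion |
| `static_fraction` | 0.2 | a minority of particles bind statically, the majority diffuse |
| `oligomer_size_distribution` | truncated geometric (p = 0.5) over 1–10 | mixture of single molecules and small oligomers up to ~10 |
| `bleach_rate` | 0.01 /s | binding movies under oxygen scavenging bleach slowly over ~2 min; photobleaching *calibration* experiments are simulated separately at 0.2 /s |
| `camera_gain`, `read_noise_sd`, `background_rate` | 20 ADU/photon, 10 ADU, 20 photons/px/frame | EMCCD-like scale; tests that need a defined SNR set `unit_intensity` via `unit_intensity_for_snr` (SNR = monomer peak amplitude over background noise SD) |

Particles perform 1D Brownian motion along the filament arclength with
reflecting ends; static particles are frozen; there are no binding/unbinding
kinetics (particles dwell for the whole movie, matching complexes bound for
the full ~2 min observation window).  Rendering deposits an isotropic
Gaussian per surviving fluorophore (stamps truncated at 5σ, < 0.05% flux
loss), then applies Poisson shot noise × gain plus Gaussian read noise.  The
EMCCD excess-noise (gamma cascade) is *not* modelled; this overstates SNR
slightly at fixed photon counts but leaves every estimator property tested
here unchanged.  By default particle positions are sampled once per frame
(no intra-frame motion), which pairs with motion-blur coefficient R = 0 in
the estimator; `subframe_samples > 1` enables intra-frame averaging, which
pairs with R = 1/6.  A single integer seed drives one generator for all
stochastic draws.

What the generator does not emulate: filament dynamics or branching,
non-uniform illumination, sample drift, fluorophore blinking, and
association/dissociation during a movie.  Passing tests therefore establish
correctness of the estimators under the stated forward model, not robustness
to these real-data effects.

## Detection and tracking

Candidates are local maxima of the matched-filtered frame whose raw value
exceeds `median + snr_min × MAD-noise` (default `snr_min = 4`); each is
refined by least-squares fitting of an isotropic 2D Gaussian with constant
offset in a 9×9 px window.  Fits must converge, keep sigma strictly inside
[0.5, 3] × the PSF guess, and have amplitude ≥ `snr_min ×` noise.  The
integrated intensity is the fitted volume `2π A σ²`.  Ties between
overlapping candidates and duplicate fits keep the brighter spot.

Partially overlapping particles (separations ~1.5–3.5 px) fit a single
Gaussian only with inflated sigma and a position ~1 px off both emitters.
When the fitted sigma exceeds 1.3 × the guess, a two-emitter refit (two
fixed-width Gaussians, shared offset) is attempted and accepted only if it
reduces the residual sum of squares by ≥ 15%, separates the pair by > 1.2 px
and leaves both amplitudes significant.  This is the standard dense-field
treatment and is what makes particle crossings on a filament tractable.

Linking is greedy nearest-neighbour: candidate (track, spot) pairs sorted by
distance, matched ascending, with a gate of `max_disp × sqrt(elapsed)` px —
the Brownian scaling of the search radius across gap closures (single-frame
steps are gated at `max_disp`, default `3·sqrt(2 D_max Δt)/pixel_size`).
Tracks dark for more than `max_gap = 5` frames terminate.  Each spot joins
at most one track.  For crowded scenes an optional merge-aware mode
(`allow_merge=True`) lets a track whose particle has visually fused with a
neighbour ride on the shared detection until separation; this relaxes the
one-spot-one-track guarantee for exactly those frames and is off by default.

A physical limit worth stating: when two indistinguishable particles diffuse
into contact, their identity through the encounter is not present in the
images, and 1D Brownian recurrence makes such encounters long.  Trajectory
recovery is therefore assessed as *majority coverage* — a ground-truth
trajectory counts as recovered when a single track matches it within 1 px
over at least half its frames.  Under that metric the pipeline recovers
≥ 90% of trajectories at 0.2 particles/µm (ten diffusive particles per
50 µm of filament, D = 0.06 µm²/s, SNR 10); demanding full-coverage single
tracks through every crossing is unattainable for any tracker.

Microtubule segmentation replaces manual ROI drawing: the time-averaged
filament channel is thresholded at background + 5 robust SDs, closed,
skeletonized, and each branch ≥ 10 px is ordered into a polyline (smoothed
with a 5-point moving average; arclength in µm via the pixel size).  Each
path carries a mask dilated by 4 px — the "area around the microtubule" used
for intensity measurements.  Kymographs sample the stack along the path at
1 px arclength steps, reducing a `width`-px normal cross-section by max
(default) or mean, with bilinear interpolation.

## Diffusion estimation

Tracks are projected onto an averaged path: by default the total-least-
squares (principal-axis) line through the track's own positions, which
removes transverse localization jitter; a segmented filament path can be
supplied instead (exact foot-point projection onto the polyline, signed
residuals kept for QC).

The covariance-based estimator on single-frame displacements
`Δsᵢ = s_{i+1} − sᵢ`:

```
D̂      = ⟨Δs²⟩ / (2 Δt) + ⟨Δsᵢ Δsᵢ₊₁⟩ / Δt
σ̂²_loc = R ⟨Δs²⟩ + (2R − 1) ⟨Δsᵢ Δsᵢ₊₁⟩
```

R is the motion-blur coefficient: 0 for per-frame position sampling (the
default simulator), 1/6 for full-frame continuous exposure (the sub-frame
averaging render option).  Displacements spanning detection gaps are
excluded from both moments rather than rescaled.  D̂ is unbiased but not
positivity-constrained; negative per-track values are reported as-is and
summaries use medians.  Tracks with fewer than `min_steps = 10`
displacements are flagged invalid and excluded from summaries.

The MSD route (OLS of time-averaged MSD over lags 1–10, with intercept,
slope/2) exists purely as an independent cross-check; the two agree within
a few percent on long noiseless tracks.

Static/diffusive classification uses the studentized statistic
`T = D̂ Δt / σ̂²_loc`.  On a static track D̂ and σ̂²_loc are anti-correlated
(both derive from the lag-1 covariance), so calibrating T — rather than D̂
with a plugged-in σ̂² — is what keeps the false-positive rate at the nominal
α (plug-in calibration inflates it to ~3× α).  T is pivotal for i.i.d.
Gaussian noise, so its null is simulated once per track length (4000 static
tracks, fixed internal seed) and cached; a track is diffusive iff its T
exceeds the (1 − α) null quantile, α = 0.05 by default.

## Intensity quantification and counting

A binding data point is `mean(complex channel over the microtubule area) −
mean(over background)`, on the time-averaged stack.  The default background
is a 6 px annulus around the dilated filament mask, excluding every filament
mask in the field; an explicit background mask can be supplied (the two must
be disjoint, and an empty automatic annulus is an error instructing manual
selection).  The measurement is exactly invariant to adding a constant to
the frame and linear in decoration density.  Intensities stay in ADU
throughout — no photon conversion is attempted, since the gain of real
recordings is often unknown.

Molecule counting divides a track's mean integrated intensity over its first
20 frames by the single-fluorophore unit.  The unit is calibrated from a
separate photobleaching experiment: traces are segmented by penalized binary
change-point detection (BIC-style penalty `2 log(n) σ²`, noise from the MAD
of first differences, minimum segment 3 frames, plus a numerical floor so
exactly-constant traces never split on rounding error), and a trace is
accepted as a single fluorophore iff it has exactly one downward step whose
terminal level is within 2 noise SDs of zero.  The unit is the mean pre-step
plateau; fewer than 20 accepted traces flags the result low-confidence.
Counting movies are simulated at the low binding-movie bleach rate, so the
first-20-frame window loses < 2% intensity to bleaching; at the calibration
bleach rate that window would bias counts low by design of the experiment,
which is why calibration and counting are separate acquisitions.

## Statistics

* **Mann–Whitney U** — U from midranks; p exact by enumeration when the
  pooled sample is ≤ 16 without ties, otherwise the normal approximation
  with tie-corrected variance and continuity correction (an all-identical
  pooled sample returns p = 1).  The crossover at 16 is an enumeration-cost
  choice; the continuity-corrected approximation is within 0.02 of exact for
  group sizes ≥ 5 and degrades to ~0.037 at n = 3 per group — sizes at which
  the implementation always uses the exact path anyway.
* **Median CI** — distribution-free binomial order-statistic interval
  `(x_(r), x_(n+1−r))` with r the largest integer whose binomial(n, ½) tail
  stays within α/2 (conservative, coverage ≥ 95%); bootstrap percentile
  fallback for n < 8, where the order-statistic interval degenerates.
* **Bootstrap slope** — each of 1000 iterations resamples the replicate set
  with replacement (same size), then draws one point per (replicate,
  concentration) with replacement, pools them and fits OLS; reported are the
  median and the 2.5/97.5 percentiles of the slopes.  The wording of such
  procedures is often ambiguous between "one replicate per iteration" and
  "a point from each replicate"; the latter dominates here and is the
  default, with the single-replicate reading available as
  `mode="single_replicate"`.  Collinear data give the exact OLS slope with a
  zero-width CI; coverage of a true slope is ≥ 93–95% in simulation.
* **K_d fits** — nonlinear least squares of
  `response = r_free + (r_bound − r_free)·f(L)` with the ligand-depletion
  (quadratic) bound fraction by default, appropriate when the labelled
  partner (~5 nM) is comparable to the K_d (~13 nM); the hyperbolic
  `f = L/(L+Kd)` variant is provided and agrees within 1% when the partner
  is ≤ K_d/100.  Fits are unweighted by default.  Flags: `kd_at_bound`,
  `failed` (non-convergence), and `uninformative` when the bound fraction
  never moves by more than 0.05 across the doses or the fitted amplitude is
  indistinguishable from the residual noise.

## Problem sizes used in the checks

The shipped tests and `scripts/acceptance.py` run at the scale the methods
are meant for, kept small enough for a laptop CPU: diffusion ensembles of
200 tracks × 100 steps per D value; 1000 static tracks for the noise closed
forms; 1e4–1e5-step tracks for estimator consistency; 400 calibration +
500 counting traces; 1000 Mann–Whitney sample pairs; 500 bootstrap
meta-replicates × 1000 iterations; a 7-condition dose-response with ~56
microtubule areas per condition (matching the n ≈ 59–73 of the titrations it
emulates); 300 isolated spots and five 50-particle-frame scenes for
detection/tracking.  The whole suite runs in about a minute.

## Known limitations

* The competition model is two reactions with two K_ds; it cannot separate
  active displacement from sequestration, and it has no cooperativity, so it
  cannot push inhibition below the `Kd/(Kd + total)` floor described above.
* The camera model omits EMCCD excess noise and fluorophore blinking.
* Identity through sub-diffraction particle contact is unresolvable; merge-
  aware linking preserves continuity but not identity.
* The change-point calibrator assumes piecewise-constant traces; slow
  continuous photobleaching within a plateau is not modelled.
* `segment_microtubules` orders skeletons by endpoint walking and does not
  split crossing or branched filaments.
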