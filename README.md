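# tirftrack

Single-molecule TIRF quantification on microtubules, with a fully synthetic
ground-truth generator so every stage of the analysis is verifiable.

## The problem

In vitro reconstitutions of regulated microtubule binding image a GFP-tagged
protein complex (here: the hetero-octameric augmin/HAUS complex) on
surface-immobilized, stabilized microtubules by TIRF microscopy, and ask
quantitative questions of the movies:

* How much complex is bound to the lattice under each condition (e.g. an
  importin titration, with or without Ran-GTP)?
* How do individual complexes move — statically bound, or diffusing along the
  lattice, and with what diffusion coefficient?
* How many molecules are in each bound particle (monomers vs small
  oligomers)?
* Is a dose-response slope different from zero, and what is the dissociation
  constant of the underlying interaction?

Raw microscopy data for such studies are rarely deposited, so this package
pairs the analysis chain with a forward model: rendered TIRF image stacks
with known ground truth, and an equilibrium competition model that emulates
importin inhibition and Ran-GTP rescue of lattice binding.

## What is inside

| module | contents |
| --- | --- |
| `tirftrack.equilibrium` | 1:1 mass-action competition: cargo + importin ⇌ cargo·importin (K_d), Ran-GTP sequesters importin-β; solved by bracketing + Newton polish |
| `tirftrack.simulate` / `render` | 1D Brownian tracks on filaments (reflecting ends, static subpopulation, oligomer sizes 1–10, exponential photobleaching) rendered as Gaussian-PSF images with Poisson shot noise × gain + read noise |
| `tirftrack.detect` / `link` | MAD-thresholded candidates, sub-pixel 2D Gaussian fits (with a two-emitter refit for partially overlapping particles), greedy nearest-neighbour linking with Brownian (√t) gap gates |
| `tirftrack.mtpaths` | automated microtubule segmentation (threshold → skeleton → ordered path + dilated mask) and kymographs |
| `tirftrack.diffusion` | projection onto an averaged path, covariance-based estimator (CVE) `D̂ = ⟨Δs²⟩/2Δt + ⟨ΔsᵢΔsᵢ₊₁⟩/Δt` with localization-variance estimate `σ̂² = R⟨Δs²⟩ + (2R−1)⟨ΔsᵢΔsᵢ₊₁⟩`, MSD cross-check, static/diffusive classification against a simulated null |
| `tirftrack.quantify` | per-microtubule background-corrected intensity, first-20-frame track intensity, change-point photobleaching calibration, molecule counting |
| `tirftrack.stats` | Mann–Whitney U (exact ≤ 16 pooled, tie-corrected normal beyond), distribution-free median 95% CIs, replicate-aware bootstrap regression slopes, quadratic (ligand-depletion) and hyperbolic 1:1 K_d fits |
| `tirftrack.pipeline` / `io` / `cli` | dose-response orchestration, TIFF/CSV/YAML formats, `tirftrack` command line |

## Worked example

The competition model that drives the synthetic dose-response
(`examples/01_competition_model.py`):

```
importin (nM)   free-complex fraction
           0      1.000
          25      0.350
          50      0.210
         100      0.117
         200      0.062
         400      0.032

400 nM importin + 3500 nM Ran-GTP -> free fraction 0.998
```

With K_d = 13.1 nM, importin titrates the microtubule-competent fraction of
a 1 nM complex down ~30-fold; saturating Ran-GTP sequesters the importin and
restores it.  Feeding these fractions into rendered image stacks and running
the blind pipeline (`examples/03_dose_response_pipeline.py`) returns the same
shape from the images alone:

```
                       condition  n     median     ci_low    ci_high
           augmin=1;importin_b=0 16 171.900243 153.479184 203.969045
          augmin=1;importin_b=25 16  50.478465  39.702589  59.152032
          augmin=1;importin_b=50 16  36.929850  26.227828  47.356505
         augmin=1;importin_b=100 16  16.922468   6.096550  28.429698
         augmin=1;importin_b=200 16   6.393887   0.261921  18.978360
         augmin=1;importin_b=400 16   3.796392  -0.399196   9.092922
augmin=1;importin_b=400;ran=3500 16 155.498758 133.250535 192.925294
```

Medians are background-corrected intensities per microtubule area (ADU/px)
with distribution-free 95% CIs; the Ran-GTP condition is statistically
indistinguishable from the control (Mann–Whitney p = 0.16) while every
importin dose differs from it (p < 1e-5).  The other examples cover
single-molecule tracking and diffusion estimation (`02`), photobleaching
calibration and molecule counting (`04`), and the bootstrap-slope / K_d
statistics (`05`).

A thin CLI mirrors the stages for shell use:

```bash
tirftrack simulate --out scene/ --seed 1 --n-particles 8
tirftrack detect scene/complex.tif --out spots.csv
tirftrack track spots.csv --out tracks.csv
tirftrack diffuse tracks.csv --out diffusion.csv
tirftrack quantify scene/complex.tif scene/microtubule.tif --out binding.csv
tirftrack run --out results/ --seed 1     # end-to-end dose-response demo
```

## Limitations

Microtubules are static line segments (no dynamics, branching or nucleation
chemistry); the camera model approximates the EMCCD excess-noise cascade by
Poisson × gain + Gaussian read noise; binding/unbinding kinetics during a
movie are not simulated (particles dwell for the full observation window).
See `docs/methods.md` for the full model description and numerical choices.
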