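# lamsurf

Depth-resolved (laminar) fMRI analysis of illusory surface-motion
perception, as a tested, reusable Python pipeline.

## The problem

When a luminance-defined surface is *perceived* to move without any local
motion signal in half of the visual field, any activity difference in that
half's cortical representation must arrive by top-down feedback.  Because
feedback projections terminate preferentially in superficial and deep
cortical layers, ultra-high-field fMRI sampled across cortical depth can
test for a feedback signature — if the analysis solves several coupled
problems first: building stimulus predictors for sustained and transient
responses, mapping population receptive fields (pRFs), placing equi-volume
depth levels, removing the draining-vein bias that drags gradient-echo BOLD
toward the pial surface, projecting cortical statistics back into visual
space, and running depth-resolved group inference.

`lamsurf` implements that chain for a block-design experiment with three
conditions that are pixel-identical in the left hemifield: a rotating
'Pac-Man' disk (motion induction), the same figure static, and a
wedge-pair dynamic control.  It targets researchers who want the analysis
machinery — and a ground-truthed synthetic cortical phantom to validate it —
without the original scanner data.

## The core models

- **GLM** — per condition, a sustained boxcar and a transient onset/offset
  predictor, convolved with a canonical double-gamma HRF, high-pass
  filtered (DCT projection, 35 s cutoff), fitted by OLS, and expressed as
  percent signal change against the initial 20.8 s pre-stimulus baseline.
- **pRF** — isotropic Gaussian pRF `g(x₀, y₀, σ)`; exhaustive grid search
  with per-candidate least-squares amplitude over 32 bar configurations.
- **Equi-volume depth levels** — boundaries at
  `r_j = √(r_wm² + (j/n)(r_pial² − r_wm²))` on curved geometry (equidistant
  in the flat limit), 10 compartments → 11 levels, 0 % = pial.
- **Draining-vein deconvolution** — forward model `observed = W·local`, W
  lower-triangular with unit diagonal (deep→superficial); inversion by
  sequential substitution, equal to a triangular solve.
- **Visual-field projection** —
  `V_ij = Σ_k M_ijk p_k / Σ_k M_ijk`, a pRF-density-normalised weighted
  mean, pooled across subjects by concatenation before normalisation.
- **Group statistics** — depth-profile condition contrasts,
  Bonferroni-corrected onset detection, superficial-peak classification
  (upper third of grey matter) with chi-squared area comparison, and
  likelihood-ratio tests between nested linear mixed models (random
  intercept + depth slope per subject, ML).

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic validation does and does not establish.

## Worked example

Simulate ten subjects with the phantom's programmed feedback signature
(a 0.3 % sustained increment for the motion condition, peaking at 25 %
depth in V1, 50 % in V2, 40 % in V3) and run the full chain:

```python
from lamsurf import PipelineConfig, run_pipeline

config = PipelineConfig(seed=42, n_subjects=10)
result = run_pipeline(config)

for area, con in result.contrasts.items():
    peak = con.loc[con["mean"].idxmax()]
    print(f"{area}: motion-dynamic peaks at {100*peak['depth_fraction']:.0f}% depth, "
          f"amplitude {peak['mean']:.2f} +/- {peak['sem']:.2f}%")
stat, df, p = result.chisq
print(f"superficial-peak ratio chi-squared({df}) = {stat:.2f}, p = {p:.3g}")
```

Output:

```
V1: motion-dynamic peaks at 30% depth, amplitude 0.29 +/- 0.01%
V2: motion-dynamic peaks at 50% depth, amplitude 0.31 +/- 0.01%
V3: motion-dynamic peaks at 40% depth, amplitude 0.32 +/- 0.01%
superficial-peak ratio chi-squared(2) = 30.00, p = 3.06e-07
```

The motion−dynamic contrast, after GLM, ROI averaging and draining-vein
deconvolution, recovers each area's programmed peak depth to within one
depth level and the 0.3 % amplitude to within the group SEM; V1's peaks are
superficial (upper third) while V2/V3's are not, which the chi-squared test
detects.

A command-line interface mirrors the library
(`lamsurf design|simulate|deconvolve|run`), e.g.:

```sh
lamsurf design schedule --seed 1 --out events.tsv
lamsurf run --seed 42 --out results/
```

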