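# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical software methods appendix.  It states
nothing the tests or `scripts/acceptance.py` do not themselves compute.

## Reflectance calibration

Raw hyperspectral intensity is converted to relative reflectance with the
standard black/white correction, `I = (I0 − D)/(W − D) × 100`, where the dark
image `D` defines 0 % and the white reference `W` defines 100 %.  The
correction is exact and affine-invariant: rescaling `I0`, `W`, `D` by the
same affine map leaves `I` unchanged.  A pixel with `W − D` below 10⁻⁹ makes
the division undefined; this raises an error naming the offending pixel
count rather than clamping, because silent clamping would corrupt every
downstream model.

## Smoothing and ROI spectra

Savitzky–Golay smoothing is applied along the spectral axis only.  Defaults
are window 11 and polynomial order 2, common Vis–NIR practice; both are
exposed in the config since the appropriate window depends on band spacing
and detector noise.  ROI averaging is a plain arithmetic mean over a
rectangular pixel window (half-open intervals, row-major, 0-based).  Both
operations are linear and act on different axes, so smooth-then-average and
average-then-smooth agree to float precision; the pipeline calibrates first
and smooths before averaging.

## The wavelength grid

Spectra live on 600 evenly spaced bands covering [400, 1000) nm.  The
acquisition this emulates reports 2.5 nm optical resolution yet treats the
range as 600 variables; whether those come from ~1 nm sampling or
interpolation is not documented, so the grid size is a config parameter with
600 as the default.

## Synthetic data generator

The generator is the package's test bed and defines its study conditions.

* **Region baselines.**  Monotone piecewise-cubic (PCHIP) curves through
  fixed control points give each region its documented shape: a global
  reflectance minimum at 430 nm, a rise to an exactly flat plateau over
  600–780 nm, a decline to 970 nm and a final rise, for the gluteal,
  pectoral and abdominal regions; a non-decreasing curve from 430 nm onward
  for the dorsal region; and mean reflectance ordered
  gluteal > pectoral > abdominal > dorsal.
* **Latent basis.**  Four components by default: one broad linear slope plus
  Gaussian absorption bumps near 500, 780 and 980 nm (the spectral features
  discussed for this tissue: dietary pigments and O–H stretching overtones).
  Amplitudes are a few percent reflectance per unit score, small against the
  baseline separation between regions.
* **Scores and mixing.**  Latent scores are i.i.d. standard normal per
  (sample, region); an optional two-cluster mode shifts the first component
  by ±1.8 to reproduce the two-cluster structure such texture tables can
  show in PCA.  Indicators are sparse linear combinations of the scores
  (unit-norm rows), so each indicator has a well-defined set of informative
  bands; springiness/resilience share a component and cohesiveness/chewiness
  share one, giving the Spearman structure real tables show.  Values are
  mapped to instrument-like units with per-region offsets (e.g. gluteal
  hardness highest, gluteal adhesiveness lowest, pectoral hardness lowest).
* **Nonlinearity.**  A `nonlinearity` coefficient `c ∈ [0, 1]` routes a
  variance-preserving fraction of the springiness and resilience signal
  through `(s₁² − 1)/√2`, a quadratic in one latent score.  This is what
  lets the kernel and network models beat linear PLSR on some draws,
  emulating mixed model rankings; those two indicators are also the ones
  such studies predict worst, which the default `c = 0.25` reproduces.
* **Noise.**  I.i.d. Gaussian per band (default sd 0.2 % reflectance) and
  per indicator (default sd 0.1 standardized units).  No spatial noise
  correlation exists except through the latent field in generated cubes
  (Gaussian-filtered white noise).  Real skin images have structured noise,
  specular artefacts and segmentation error that this generator does not
  attempt; passing tests therefore demonstrate correctness of the
  *computations*, not field performance on real fish.

Defaults (387 samples, 600 bands, four regions, noise as above) are the
generated stand-in for the study cohort; analysis scripts and acceptance
checks that train all six models use 300 samples per region, a size at which
every fit is well-conditioned and the complete workflow runs in minutes on
one CPU.

## PLSR

Single-response NIPALS on z-scored `X` and `y` (population sd; constant
columns are centred and left unscaled).  The per-component regression
vectors `β_a = W_a (P_aᵀ W_a)⁻¹ q_a` are computed for every component count
in one pass, which makes cross-validation cheap: the CV component count
minimises deterministic contiguous k-fold RMSE over 1..15 (default), capped
by the rank bound `min(n−1, p)`.  At full rank PLSR reproduces ordinary
least squares, which the tests verify against a normal-equations oracle, and
the implementation is cross-checked against an independent PLS
implementation.  Per-indicator models are fit one response at a time.

## Interval PLS family

`make_intervals` partitions the band axis into contiguous intervals whose
sizes differ by at most one (longer intervals first).  Candidate band sets
are scored by **cross-validated** calibration residuals plugged into the
`N−1−R` RMSEC form, with `R` the CV-selected component count for that band
set (capped by its width).  Scoring candidates by refit training error
cannot discard uninformative intervals — training error never favours fewer
bands — whereas out-of-fold error does; the PLSR protocol here is CV-based
throughout, so the interval criterion uses the same residuals.  Ties break
to the lowest interval index (iPLS), the lexicographically first combination
(SiPLS), and the lowest dropped index (BiPLS).  SiPLS enumerates
combinations exhaustively under a configurable budget; BiPLS stops at the
first non-improving elimination and keeps at least one interval.

## LS-SVM

RBF kernel `k(x, x') = exp(−‖x−x'‖²/σ²)` on z-scored inputs.  The dual is
the bias-constrained linear system `[[0, 1ᵀ], [1, K + I/γ]] [b; α] = [0; y]`,
solved densely with a residual check and one jitter-and-retry (10⁻¹⁰ on the
diagonal) before failing.  Grid mode searches log-spaced values of γ and σ²
in (10⁻³, 10³] (20 points each by default) by deterministic k-fold CV; the
upper end reflects the documented 0–1000 search range.  Whether the original
search was CV-based is not documented; CV is used here because train-set
search degenerates to γ → ∞ interpolation by construction.  As γ → ∞ the
solution interpolates the training targets, which the tests use as a limit
check against a from-scratch KKT solve.

## BP-ANN

One sigmoid hidden layer (default 10 units), linear output, full-batch
gradient descent with momentum on z-scored data.  Protocol: at most 1000
epochs, stop when training MSE ≤ 10⁻⁵, learning rate 0.01, momentum factor
0.01.  Initial weights are uniform(−1, 1)/√fan-in from a seeded generator,
so training is bit-reproducible per seed; a NaN loss aborts with the epoch
number.  The transfer/learning/training functions of the original protocol
are not fully documented; sigmoid/linear with plain momentum is the
conventional reading, and the epoch cap, goal and rates follow the stated
values.  The training-step cap means the network often underfits large-band
problems within 1000 epochs; it is one of six models competing per cell, so
retention only selects it where it genuinely wins.

## Evaluation conventions

* Targets are z-scored on calibration-set statistics; the same scaler is
  applied unchanged to the prediction set, and error metrics are reported in
  standardized-target units.  Raw TPA scales differ by four orders of
  magnitude across indicators (hardness ~2000 instrument units, resilience
  ~0.3), so standardized errors are the only ones comparable across
  indicators.
* `RMSEC = sqrt(Σ(ŷᵢ−yᵢ)²/(N−1−R))`.  `R` is the latent-variable count for
  the PLS family; for LS-SVM it is set to 2 (γ, σ²) and for the network to 1,
  a convention the source protocol leaves open.
* `r_c`/`r_p` default to the squared Pearson correlation between predicted
  and measured values, bounded in [0, 1] and equal to 1 for any affine
  relation.  A residual-ratio form (`Σ(ŷ−y)²/Σ(ŷ−ȳ)²`) circulates in print
  for these quantities; as typeset it approaches 0, not 1, for a perfect
  model, so it is implemented only as `mode="printed"` for transparency and
  is not the default.
* The calibration/prediction split is random 75/25 under a stage seed
  (undocumented in the original protocol); Kennard–Stone max-min selection
  is available when a deterministic, design-spanning split is wanted.
* Best-model retention is argmax `r_p` per (region, indicator); ties break
  to lower RMSEP, then model-name order.
* The Spearman matrix reports raw two-sided p-values at α = 0.05 with no
  multiplicity correction, matching how significant-pair counts are usually
  reported for these tables; with 28 pairs, ~1.4 false positives are
  expected under independence.

## RC wavelength selection

The β-profile comes from the full-spectrum PLSR fit on standardized
variables (magnitudes are only comparable across bands after
standardization), with the CV-selected component count.  Default selection
keeps local extrema of β — peaks *and* valleys, i.e. positive and negative
associations — whose magnitude exceeds 0.1·max|β|; `top_k` (largest |β|,
ties to the lowest band index) is provided for deterministic tests.  No
retention threshold is documented for the original analysis, only resulting
subset sizes of 60–114 of 600 bands; the 0.1 default produces subsets of
that order on generated data but the threshold is a free parameter.  One
subset is selected per (region, indicator), the reading consistent with
per-indicator wavelength counts.  In the pipeline's reduced-wavelength arm
the RC subset constrains PLSR, LS-SVM and the network; the interval methods
are their own band selectors and always search the full grid.

## Pixel-wise maps

`predict_pixelwise` applies a fitted model to each pixel spectrum
independently — literally one prediction call per pixel, because the
contract is pointwise and batched linear algebra can differ in the last
float bit.  Maps are rendered through Pillow as PNG with a linear two-anchor
colour ramp (blue `(0.13, 0.25, 0.80)` at vmin to orange `(1.0, 0.55, 0.10)`
at vmax — the anchor RGBs are an artifact choice), a ramp strip, and a
sidecar JSON with the scale endpoints; rendering identical inputs is
byte-identical.  The scale spans each map's own min/max by default (a shared
range is available for cross-map comparison); constant maps render mid-ramp.
Values are in raw indicator units via the model's inverse target scaling.
Foreground masks are supplied explicitly or derived from a mean-reflectance
threshold; there is no automatic fish segmentation.

## Pipeline and reproducibility

`run_pipeline` derives every stage seed (generation, per-region splits,
per-cell network initialisation) from the global seed through SHA-256, so an
identical config + seed reproduces the report CSV byte for byte, network
cells included.  Every output file is hashed into `manifest.json`.  Model
archives are single-file `.npz` with a format-version tag and are refused if
the version is newer than the reader.

## Known limitations

* The generator's noise model is unstructured; no claim is made about
  performance on real skin images.
* ROI placement is explicit coordinates; region detection is out of scope.
* The network's fixed protocol (1000 epochs, lr 0.01) underfits
  high-dimensional inputs; this is faithful to the stated protocol rather
  than a tuned learner.
* No scatter corrections (SNV/MSC) or derivative preprocessing; the
  pipeline implements exactly the preprocessing named above.
* The printed-form r mode and the `R` convention for non-PLS models are
  documented interpretations of under-specified conventions.
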