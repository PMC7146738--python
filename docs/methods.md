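# Methods

This note records the models, assumptions and design choices behind
`odormix`, in the spirit of a statistical software methods appendix.  It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Psychophysical layer

Single-odorant intensity is modelled as affine in the natural log of the
odor activity value, OI = slope · lnOAV + intercept, with family-specific
coefficients: esters (1.40, −2.70), aldehydes (1.76, −1.82), aromatic
hydrocarbons (1.07, 0.00).  The aromatic intercept is stored explicitly as
zero so all three families share a single affine law type.  The laws are
deliberately unclamped: below the root of a law the predicted OI is
negative, which is a meaningful "sub-threshold" signal for downstream
filtering, not an error.  Clipping to the physical OIRS span [0, 8] is
applied only where a *panel reading* is simulated, and at the fitted
predictor's output (see below).

Thresholds for the nine registry odorants are stored in mg/m³ exactly as
tabulated (aldehyde values such as "40.6 E-3" parsed as 0.0406).  CAS
strings are opaque identifiers and are not checksum-validated; the registry
keeps 117-71-7 for n-heptaldehyde as tabulated even though reference
databases list 111-71-7 for heptanal — preserving the source rather than
silently correcting it.  The OIRS 1-butanol reference series itself
(12 ppm … 1550 ppm) is documentation, not computation, in this package.

## Synthetic panel generator

The generator emulates the statistical structure of small olfactometry
panels so that the full analysis is testable without proprietary data.

Design: a sample is a point (x_a, T) with mixing ratio x_a drawn from the
discrete levels {0.1, …, 0.9} and total stimulus T = lnOAV_a + lnOAV_b
uniform on [3, 10]; then lnOAV_a = x_a·T, lnOAV_b = (1−x_a)·T.  The band
[3, 10] is calibrated so that mixture intensities land in the ≈ 2–7 OIRS
range typical of panel studies.  Points whose additive intensity OI_sum
falls below 2.0 OIRS are rejected and redrawn (rejection keeps the design
distribution interpretable; truncation would not), since weak stimuli are
excluded from panel practice.

Ground truth: the default interaction is multiplicative suppression
OI_mix = OI_sum · (1 − ρ(x_a)) with the symmetric kernel
ρ(x_a) = ρ_max · (4·x_a·(1−x_a))^p.  This is the simplest form with the
two properties the analysis is designed to detect: antagonism peaks at
equal log-activity mixing and vanishes toward pure components, and the
reduction *ratio* is independent of the intensity level at fixed
composition.  Defaults: ρ_max = 0.35 for esters and aldehydes, 0.15 for
aromatics (weak interaction family), p = 1.  ρ_max < 0 yields synergism;
`additive` and `strongest_component` strategies ship for contrast.  The
kernel is a replaceable modelling convenience, not a mechanistic claim.

Measurement: panel readings are the ground-truth OI plus N(0, σ) noise with
σ = 0.3 OIRS (slightly inside the ≈ 0.4 OIRS error level accepted for human
panels), clipped to the OIRS span [0, 8] after noise — the scale saturates,
and sub-threshold readings floor at 0.  Defaults use 30 samples per pair,
matching reported panel sizes (21–34).

What the generator does **not** emulate: individual assessors and
inter-assessor variance, integer quantization of OIRS scores, drift or
session effects, and any composition-dependent noise.  Passing tests
therefore demonstrate that the pipeline recovers a known interaction
structure at realistic sample size and noise — not that real panels obey
the kernel.

## Intensity model

Inputs are the two component concentrations (mg/m³); the target is the
panel OI.  The regressor is an RBF-kernel ε-SVR (ε = 0.1 OIRS, fixed; only
C and γ are searched, on the canonical log₂ lattice C ∈ {2⁻⁵…2¹⁵},
γ ∈ {2⁻¹⁵…2³}).

**Feature scaling.**  The default is z-scored *log* concentration.  Plain
z-scoring of raw concentrations was implemented first and measured: over
seeded default ester datasets it yields a median held-out MAE of ≈ 0.9 OIRS
with frequently negative test R², because the design spans roughly four
concentration decades and, after raw-scale standardization, most samples
collapse into a cluster whose internal structure a single global RBF length
scale cannot resolve.  Log concentration is the scale on which the
psychophysical laws are linear, and restores held-out MAE to ≈ 0.2–0.35
OIRS.  `feature_scaling="standard"` retains the raw-scale behaviour for
comparison.

**Model selection.**  Mean CV MAE over seeded k folds (default 10), chosen
over R² for consistency with the error unit used to judge panels.  Fold
assignment is a seeded shuffle followed by contiguous blocks (fold sizes
differ by at most one).  Ties break toward smaller C, then smaller γ —
preferring flatter models.  The winning cell is refit on the whole training
split.  The scaler is fit once on the full training split (also used within
CV); with 20–25 training samples, per-fold re-scaling adds variance without
changing selections in practice, and the single-scaler contract keeps the
naive selection oracle exact.

**Prediction codomain.**  Raw SVR outputs are clipped to the OIRS span
[0, 8] (`oi_range`, disableable).  The panel target is defined on that
bounded scale — readings saturate at level 8 — so predictions beyond it are
not valid OIRS values; unclipped extrapolation beyond the sampled range
otherwise continues the log-linear trend to 10–12 "OIRS" and inflates
held-out error whenever a random split isolates the saturated corner.

**Split.**  Train size is round(0.7·n) with ties-to-even; the partition is
a seeded permutation without replacement.

## Interaction analysis

OI_sum, OI reduction and the reduction ratio follow their definitions
exactly, with no clamping; the ratio is undefined at OI_sum = 0 and such
rows are dropped and counted rather than imputed.

**Surface.**  The grid spans the rectangular bounding box of observed
per-component lnOAV values (not the convex hull), at `resolution` evenly
spaced points per axis; each cell is converted to concentrations and scored
by the model.  The only mask encoded in the surface is the weak-stimulus
rule OI_sum < 2.0 OIRS: this reproduces the familiar contour-map
presentation with a blank lower-left corner, while extrapolation risk
elsewhere in the rectangle is left to the reader (the measured sample
overlay shows where data support exists).  The mask uses OI_sum because it
is computable at every cell from the laws alone.

**Scatter.**  One row per measured sample and per usable unmasked cell,
with three principled exclusions beyond undefined ratios:

- rows with x_a outside (0, 1) (a component below its threshold has
  negative lnOAV, making the composition coordinate meaningless);
- rows whose odor intensity OI_mix is below the same 2.0 OIRS cut-off —
  the weak-stimulus exclusion applied to the quantity it is actually about:
  at faint stimuli the ratio's denominator amplifies panel or model error,
  and only mixtures with distinct olfactory stimulation are informative;
- predicted cells whose total stimulus T lies outside the measured T-range.
  The rectangle's far corner reaches T ≈ 2 × the largest sampled total,
  where an RBF model collapses to its bias term and the "reduction ratio"
  saturates toward 1 as a pure extrapolation artefact.

All drops are counted so that rows = n_measured + n_unmasked − n_dropped.

**Summary.**  `peak_ratio`/`peak_x_a` are the maximum reduction ratio and
its location over the *model-predicted* rows: the dense grid is the
analysis product, and a maximum over individual noisy panel readings would
be biased upward by measurement error (this also makes the additive-null
property — zero peak under an exact additive predictor — hold for any
dataset).  `intensity_ratio_correlation` is the Spearman rank correlation
between reduction ratio and predicted OI_mix over the same rows; rank
rather than linear correlation because the ratio is bounded and skewed.  A
constant input yields 0.0 by convention.

A caveat the test suite quantifies: even under the generator's ground
truth, the *marginal* ratio–intensity rank correlation is mildly negative
(down to ≈ −0.30 in some seeded runs), because the suppression factor
(1 − ρ(x_a)) enters both variables; the generator's independence is
conditional on composition.  Fitted models add smooth estimation error on
top, so individual runs can exceed |ρ| = 0.3 even though the underlying
construction is intensity-independent.  A partial rank correlation
controlling the composition kernel was evaluated and rejected: after
removing the composition effect, the residual ratio variation on a dense
grid is essentially the model-error field, and the statistic becomes
hypersensitive to it.

## Determinism and numerics

All randomness flows from three named seeds (generator, split, CV); no
global RNG state is used.  Identical configuration reproduces every numeric
artifact bit-for-bit (libsvm fits are deterministic given data).  Datasets,
surfaces and scatters are exported as plain CSV at full float precision;
models persist via joblib and reload to bit-identical predictions.
Degenerate inputs (zero-variance features, empty splits, undefined ratios,
empty design regions) raise typed errors naming the offending quantity
rather than propagating NaNs.

## Problem sizes

Default analyses use 30-sample panels, an 11 × 10 hyperparameter lattice
under 10-fold CV (≈ 1100 small SVR fits per model, about a second), and
50 × 50 surfaces; the multi-seed recovery study in the test suite repeats
the full pipeline 20 times.  These sizes match the scale of the panel
datasets the method targets.

## Known limitations

- Binary mixtures only; no ternary or higher-order designs.
- One SVR per pair; no transfer across pairs or families.
- The interaction kernel is phenomenological; recovering ρ_max says the
  pipeline works, not that nature uses that kernel.
- Surface cells outside the sampled band are displayed but unreliable;
  the scatter's T-band guard is a blunt (if effective) interpolation
  criterion.
- The weak-stimulus cut-off (2.0 OIRS) and the panel error benchmark
  (0.4 OIRS) are adopted constants of the field, not estimated quantities.
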