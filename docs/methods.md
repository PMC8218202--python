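# Methods

## Dose-response model

Single-agent responses are modelled with the four-parameter log-logistic
curve

    y(x) = d_min + (d_max − d_min) / (1 + (m/x)^λ),

the de-facto standard for percent-inhibition screens: `d_min` is the
zero-dose asymptote, `d_max` the saturating effect, `m` the inflection
dose (relative IC50) and `λ > 0` the Hill slope. Fitting is bounded
nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) on the parameterization `(d_min, d_max, log₁₀ m, λ)`.
Initialization: asymptotes at the observed response extremes, `m` at the
dose whose response is nearest the half-effect level, `λ = 1`. Bounds:
`λ ∈ (0.05, 10]`, `m` within a factor 100 of the tested range, asymptotes
in `[−200, 300]` (consistent with the ±200% quality window, with headroom
for stimulation). Zero-dose wells enter the fit anchored at `d_min`.

Degenerate inputs: a response spread below 1 pp yields a flat fit
(`flat=True`, constant prediction) rather than an ill-conditioned slope.
Growth-stimulating compounds fit with `d_min > d_max` and are flagged
`decreasing`; all downstream integrals use the fitted curve unchanged.

**RI** is the normalized area under the fitted curve on the log₁₀-dose
axis over the tested range. On that axis the model is a logistic in
`t = log₁₀ x`, so the integral has the closed form
`∫ 1/(1+e^{−k(t−t_m)}) dt = log(1+e^{k(t−t_m)})/k` with `k = λ ln 10`,
evaluated via `logaddexp`; tests confirm agreement with a dense trapezoid
quadrature to well below 1e-3. RI defaults to integrating the fitted
curve; integrating raw observations instead is a caller choice (fit the
observed slice yourself) — the fitted convention was chosen because per-dose
noise otherwise propagates directly into the score.

The **absolute IC50** is reported only when the fitted curve crosses 50%
inside the tested range; extrapolated crossings are suppressed and
flagged, because an IC50 outside the tested doses is an artifact of the
parametric tail.

## Synergy models

Expected effects are computed from the *fitted* monotherapy curves
evaluated at the matrix doses (configurable to raw row/column wells).
Monotherapy fractions are clamped to [0, 1] before the Bliss product; the
observed response is never clamped, so deltas keep their raw scale.

* Bliss: `E = 100·(f₁ + f₂ − f₁f₂)`.
* HSA: `E = max(y₁, y₂)`.
* Loewe: `E = y` solving `x₁/X₁(y) + x₂/X₂(y) = 1`, with
  `Xᵢ(y) = mᵢ((y − d_minᵢ)/(d_maxᵢ − y))^{1/λᵢ}`. The left side is
  strictly decreasing in `y` for increasing curves, so bisection over the
  shared attainable effect interval (tolerance 1e-10 in `y`) finds the
  unique root; when the doses push outside that interval the nearer
  boundary is returned with a per-cell `capped` flag rather than an error.
* ZIP: for each interior cell, a log-logistic is refit along the row with
  the zero-dose asymptote pinned to the fitted monotherapy effect of the
  row drug at that row's dose, and symmetrically along the column; the
  cell's smoothed effect is the mean of the two directional fits, and the
  delta is that mean minus the Bliss product of the monotherapy
  fractions. Pinning fixes only the lower asymptote; upper asymptote, `m`
  and `λ` are refit per slice with the same bounds as the monotherapy
  fit. Slices with fewer than two finite interior cells are skipped and
  the cell falls back to the other direction alone (cells with neither
  stay missing) — a pragmatic choice for sparse matrices.

Per-dose deltas are `observed − expected` in percentage points; the block
summary is the arithmetic mean over interior (both doses positive) finite
cells — monotherapy wells carry no interaction information. Missing wells
propagate as missing and a completeness fraction is reported. Statistical
significance of per-dose scores is deliberately not computed: typical
screens lack replicates, so no well-level error model is identifiable.

The landscape is bilinear interpolation of the delta grid on the
log₁₀-dose plane, subdividing each dose interval 10× (so original nodes
are reproduced exactly), plus the argmax/argmin cells of the raw grid.

## CSS and S

One CSS component fixes a drug at the tested dose nearest its relative
IC50 on the log axis (ties toward the lower dose), fits a log-logistic to
the combination responses along the other axis, and takes that curve's RI
over the axis's positive tested range — the same normalization as
single-agent RI, which is what makes CSS and RI directly comparable. CSS
is the mean of the two components; flat or unfittable slices fall back to
the slice mean with a degenerate flag. The slice curve is refit rather
than integrating raw slice wells, matching the RI convention above.

`S = CSS − max(RI_row, RI_col)` by default: the clinically meaningful
comparison is against the best single agent. `mean` and `sum` variants
are available behind a flag.

## QC and harmonization

Wells with inhibition strictly outside ±200% are flagged (the bounds
themselves pass — "less than −200% or larger than 200%" reads as strict)
and excluded from scoring but retained in exports. The study gate
computes Pearson correlation (Spearman behind a flag) between recomputed
and reported synergy scores and includes the study when `r > 0.6`
strictly; fewer than 3 pairs or zero variance makes the gate undecidable
and the study is not included. The gate defaults to the ZIP mean because
source publications report heterogeneous metrics and ZIP is the most
smoothing of the four. Replicates collapse by arithmetic mean (no
variance model: replicates are rare in practice). Blocks missing the
untreated control are scored with `d_min` free rather than anchored, plus
a warning flag.

## Simulation

The generator emulates checkerboard screens: log-spaced dose grids
(defaults: 5 doses per axis spanning two orders of magnitude around each
drug's inflection, within the plausible 1e-4–1e4 µM window), monotherapy
wells from the true curves, interior wells from the named interaction
model (Bliss product, HSA max, Loewe sham `y(x₁+x₂)` on one curve, or
Bliss + constant offset), additive i.i.d. Gaussian noise per well
(default sd 5 pp for screens, matching typical screen variability), and a
control fixed at 0. The Bliss product of log-logistic monotherapies is
itself the ZIP null — each slice is again log-logistic with a shifted
baseline — so one surface serves both nulls. Noise applies to treated
wells; monotherapy noise is a separate knob (`mono_noise_sd`,
`simulate_monotherapy`) so parameter-recovery experiments control it
explicitly. All randomness flows through `numpy.random.default_rng`
(PCG64) seeded from the spec.

Whole-screen simulation draws drugs from a synthetic panel (random
166-bit fingerprints, per-drug potency and efficacy) and cells from a
synthetic panel (random expression matrix, per-cell potency shift
multiplying every drug's `m`). The deterministic drug × cell → curve
structure is what the predictor is expected to learn. Not emulated: plate
spatial artifacts, heteroscedastic noise, dose-dependent error, batch
effects — so passing tests demonstrate correctness of the scoring
machinery, not robustness to real-plate pathologies.

## Predictor

LightGBM regressors, one per target, over: drug/cell identities and the
two concentrations as categorical features, concentrations again as
numeric, two 166-bit MACCS blocks (slots ordered lexicographically by
drug identifier so (A,B) and (B,A) share one canonical row), and
expression of the top-variance genes (top 5% by variance across the cell
panel, ties broken by gene identifier). Synergy targets are per-dose
deltas (the portal-style landscape display is per dose); block-summary
training is possible by aggregating upstream. Exposed hyperparameters:
trees = 500, max depth = 6, learning rate = 0.1, L2 leaf regularization
= 3 — the four knobs that matter most for boosted trees; the rest stay at
backend defaults. `deterministic=True, n_jobs=1` makes seeded retraining
bit-reproducible. The 10×10 prediction grid is linearly spaced from
max/10 to max ("equally distanced" read literally; log spacing behind a
flag). Expression enters raw (no log transform) — variance ranking on the
raw scale; callers can pre-transform.

Biomarker ranking is plain Pearson correlation of each gene's expression
with a per-cell sensitivity vector over overlapping cells (≥3 required),
ranked by |r|; zero-variance genes are excluded with a flag.

## Problem sizes in tests

The test suite uses 5×5-interior blocks throughout; parameter-recovery
experiments use 200 seeds at 8 doses and sd 5 pp; the predictor check
trains on a 500-block screen (12 drugs × 8 cells) with an 80/20 split;
biomarker recovery uses 100 seeds of 20 cells × 500 genes. The acceptance
script runs the same computations with a 300-block screen. These sizes
give stable Monte-Carlo estimates (gate correlations > 0.99, held-out R²
≈ 0.97) while keeping the whole suite fast.

## Known limitations

* Loewe requires both curves non-flat and invertible; inert drugs make
  the dose-equivalence equation meaningless and such cells are capped or
  unscored.
* ZIP deltas absorb part of a constant synergy offset into the slice fits
  (tests bound the absorption at ~1 pp for a 15 pp offset).
* CSS uses the relative IC50 (`m`), clipped into the tested range for
  slice selection; blocks whose monotherapies never reach 50% inhibition
  thus anchor the slice at a weakly identified dose.
* The predictor interpolates within the screened drug/cell/dose space; it
  has no mechanism for generalizing to unseen drugs or cell lines beyond
  fingerprint/expression similarity.
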