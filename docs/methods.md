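# Methods

## Design generation and factor coding

The three-factor Box–Behnken design places four runs on each of the three
factor-pair faces — the (±1, ±1) combinations with the third factor at its
center — plus `c` replicated center runs, giving 12 + c runs (17 with the
default c = 5). Coded levels are stored as exact integers, so column sums
(0) and sums of squares (8 per column) hold without float drift. Factor
coding is the affine map x = (actual − center)/half-range with centers
60 %, 30 min, 50 °C and half-ranges 20, 15, 10 for the bundled study
factors; decode∘code is the identity to machine precision. Canonical run
order is pair-block (the (x1,x2), (x1,x3), (x2,x3) blocks, centers last);
`paper_order=True` emits the published 17-run sequence so the bundled
fixture diffs cleanly.

## Quadratic response surface and ANOVA conventions

The model is the full 10-term second-order polynomial on coded factors, fit
by OLS (`numpy.linalg.lstsq` on the explicit model matrix). The ANOVA panel
follows the Design-Expert conventions that dominate the applied
response-surface literature, because those are the conventions the study's
printed diagnostics use:

* **Per-term SS** are partial (Type III): the SSE increase when a term is
  dropped and the reduced model refit. For terms orthogonal to everything
  else this reduces to the closed forms βᵢ²·8 (linear) and βᵢⱼ²·4
  (interaction), which the tests verify; the pure quadratic terms are
  non-orthogonal to the intercept, which is exactly why drop-term refits
  (rather than sequential SS) reproduce the published quadratic-term SS.
* **Lack of fit / pure error**: residual SS is split using replicate groups
  (duplicate coded rows; the BBD centers give pure-error DF = c − 1 = 4 and
  lack-of-fit DF = 3 on the 17-run design). If replicates agree exactly
  (noise-free synthetic data) the lack-of-fit F ratio is undefined and is
  reported as NaN rather than raising, so noise-free round-trip analyses
  still run. A design with no replicates at all raises an error, since the
  decomposition does not exist.
* **Predicted R²** comes from PRESS via the hat-matrix leave-one-out
  identity PRESS = Σ (eᵢ/(1 − hᵢᵢ))²; the tests check it against explicit
  leave-one-out refits.
* **CV%** = 100·√MSE / ȳ with ȳ the mean experimental response over all
  runs; **adequate precision** = (max ŷ − min ŷ)/√(p·MSE/n) over the design
  points with p = 10 parameters, the convention that reproduces the study's
  printed 25.0494 for TPC.
* p-value verdicts: significant < 0.05, highly < 0.01, exceptionally
  < 0.001.

On the bundled table the TPC panel reproduces every printed diagnostic at
printed precision. The TFC panel agrees to ~0.3 % relative (printed model F
46.54 vs recomputed 46.70, predicted R² 0.8503 vs 0.8510, and the printed
equation intercept 57.42 vs refit 57.412): the published TFC fit was
evidently computed from responses carrying more decimals than the table
prints. The tests assert the TPC panel tightly and the TFC panel at 0.5 %
relative for this reason. The published TPC *predicted-value* column is
additionally inconsistent with its own printed design (drift up to 0.6
units); the TFC predicted column is consistent to 0.006.

## Desirability optimization

Per-response desirability uses Derringer ramps (maximize, minimize or
target, with weight w and shape exponent s, defaults 1 and 1); the overall
objective is the weighted geometric mean, which is zero whenever any
component is zero. Because the study does not state its ramp anchors, the
default anchors each maximize-goal at the observed minimum and maximum of
that response in the design table — the conventional choice, and the one
that reproduces the published optimum location (61.4 % ethanol, 29.6 min,
50.2 °C) to well within rounding. The absolute value of D, by contrast, is
anchor-dependent: observed-range anchors give D = 0.933 against the
published 0.953, so D is only loosely comparable while the optimum location
is robust. The search is a dense grid scan (step 0.01 coded) over the
[−1, 1]³ cube, Nelder–Mead refinement from the best cell, then a bounded
L-BFGS-B polish (the surface can be almost flat along a weak factor, where
a simplex alone stalls); the reported optimum never has lower D than the
grid maximum, and grid ties break toward the smallest coded norm. No
extrapolation outside the cube is attempted, matching the validated factor
ranges.

## MLP surrogate

One network per response: min-max input/output scaling to [−1, 1], a single
tanh hidden layer (default 5 units — with 17 observations, wider layers
memorize), linear output, optional input-to-output skip connections
(cascade variant, off by default). Data are split 70/15/15 into
train/validation/test by a seeded shuffle (17 → 12/2/3; train rounded,
validation floored, remainder to test). Training minimizes training-set MSE
with either Levenberg–Marquardt (default) or BFGS (SciPy), checking
validation MSE once per epoch and returning the weights of the best
validation epoch after a patience of 6 failed checks. The LM implementation
uses Marquardt's diagonal scaling (J^T J + λ·diag(J^T J)) with λ ×10 on a
rejected step and ÷10 on acceptance, starting at 10⁻²; weights initialize
uniformly in ±0.2 so the tanh units start in their linear regime and early
epochs fit the smooth large-scale structure first. Analytic Jacobians and
gradients are tested against central finite differences.

Limitation: with 17 points the validation set has 2 members, so
best-validation weight selection is noisy and the achieved overall R² of a
10-seed sweep fluctuates with the sweep (typical best-of-10 values
0.85–0.99 across seed ranges; the canonical sweep over seeds 0–9 reaches
0.991 for TPC and 0.972 for TFC). This is inherent to validation-based
early stopping at this sample size, not to the optimizer.

## Comparison and validation metrics

`compare` reports R² = 1 − SSE/SStot, RMSE = √(SSE/n), AAD% with deviations
divided by the *predicted* value (the convention the study's formula
prints, even though part of the literature divides by the observed), and
SEP% = 100·RMSE/mean(observed). The published RSM RMSE/SEP cells of the
comparison table (6.7139 / 0.0649 for TPC) are not consistent with any
standard formula applied to the printed data (direct recomputation gives
RMSE ≈ 0.6) and are therefore not reproduced or asserted. `validate_optimum`
reports RSE% = 100·(actual − predicted)/predicted (signed) and RSD% using
the sample (n−1) SD of the two values, |a − b|/√2 — the convention that
reproduces the published 1.80/2.59 pairing — with pass thresholds 10 % and
5 %.

## Mass annotation

Monoisotopic masses use C 12 (exact), H 1.00782503, N 14.00307401,
O 15.99491462, S 31.97207117, P 30.97376200. The default [M−H]⁻ convention
subtracts the hydrogen-*atom* mass, neglecting the electron, because that
is how published calculated-mass columns are printed (apigenin 269.045);
the physically stricter proton-subtraction convention (+0.00055) is a flag.
Default match tolerance is 5 ppm, consistent with an Orbitrap-class
instrument at 140 000 resolution; matching returns all library entries in
the window sorted by |ppm|, and is invariant to library order and to
out-of-tolerance decoys. Neutral-loss flagging compares all ordered
precursor/fragment mass differences against a small table (hexosyl
162.0528, deoxyhexosyl 146.0579, galloyl 152.0110, sulfate 79.9568, CO₂
43.9898, H₂O 18.0106 Da) within ±0.05 Da — fragments in annotation tables
are printed at 2 dp and often at lower accuracy than the precursor, so a
sulfate loss can print as 80.00 against the exact 79.9568. No spectral
scoring, isotope patterns or retention modeling are attempted; confidence
levels are user-supplied metadata.

The bundled 104-row library is transcribed as printed, including its
internal anomalies: four rows (17, 79, 84, 94) have calculated masses
inconsistent with their printed formulas beyond printing precision, and
twelve printed observed masses deviate from their formula-derived masses by
more than 10 ppm (most egregiously tartaric acid at −571 ppm). These are
preserved, not corrected, and the tests pin the resulting self-match counts
(100/104 calculated-mass agreement at 0.0015 Th; 92/104 observed-mass
self-annotation at 10 ppm).

## Assay arithmetic

Percent inhibition is 100·(A − B)/A against the control (or untreated-cell)
absorbance; calibration inversion is x = (y − b)/m with the study's
published curves bundled as constants. IC50 interpolates inhibition against
log10(concentration) between the first adjacent bracketing pair — chosen
over 4PL fitting because the procedure is deterministic, exact on the
synthetic fixtures, and the study states only that IC50 values "were
determined". Noise-free 4PL curves are recovered within 5 % across Hill
slopes 0.5–3; curves that never cross 50 % raise a not-estimable error
carrying the "> max" / "< min" bound. Inhibition values outside [0, 100]
are flagged but never clamped.

## Synthetic-data generators

`simulate_bbd_responses` draws y = (model matrix)·β + N(0, σ²) at the BBD
points, with defaults σ = 0.6 (the replicate SDs of the real table are
roughly constant at ~0.3–1.2, so homoscedastic Gaussian noise is the
appropriate idealization) and c = 5 centers. Under it, pure-error MS is an
unbiased σ² estimator and the lack-of-fit test is null-true, which the
tests confirm at 500 replicates (type-I rate within a 99.9 % binomial band
of 5 %). `simulate_peaklist` perturbs library masses multiplicatively with
ppm-scale normal error plus optional uniform decoys; recovery at 5 ppm
tolerance with 2 ppm error matches the normal-tail expectation
2Φ(2.5) − 1 ≈ 0.988. `simulate_dose_response` produces 4PL inhibition with
additive noise. All generators accept either a seed or a shared
`numpy.random.Generator`, so multi-stage simulations are reproducible end
to end. What the generators do *not* emulate: run-order drift or
heteroscedasticity in the design responses, correlated mass errors or
isotope peaks in spectra, and plate-position effects in assays — passing
tests therefore demonstrate correctness of the estimators under their
stated assumptions, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

Everything runs at desk scale: the 17-run fit and full ANOVA take
milliseconds; the desirability grid scan evaluates 201³ ≈ 8.1 M points
vectorized (<2 s); Monte-Carlo calibrations use 500 replicates; annotation
of the 104-peak library is instantaneous. Ill-posed inputs fail loudly:
rank-deficient model matrices, leverage-1 PRESS, empty libraries,
non-positive controls and unparseable formulas all raise typed errors with
stage-tagged messages at the CLI (exit codes: 2 usage, 3 data, 4
numerical).
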