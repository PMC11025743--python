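# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `silcal`, and what the passing test suite does and
does not establish about real instrument data.

## Data model

Spectra are stored as a samples × channels absorbance matrix (log 1/R,
arbitrary units) with a strictly increasing wavelength axis in nm; the
default synthetic axis spans 902–1680 nm over 256 channels. No step size is
ever assumed: readers take the wavelength axis from the column headers
as-is, because instrument channel counts need not match the nominal
sampling interval. Reference values (the responses) are % DM for
composition and % or h⁻¹ for kinetic parameters; kd is stored as a
fraction per hour throughout, with any percentage display left to the
reporting layer. The canonical on-disk form is UTF-8 CSV (first column
sample id, wavelength-headed spectral columns, name-headed property
columns); XLSX with the same layout is accepted read-only, and both
point- and comma-decimal dialects are parsed (`auto` sniffs the separator).
Derived composition follows OM = 100 − ash and NFC = OM − CP − apNDF − EE;
a negative computed NFC is retained with a warning because it indicates
inconsistent wet-chemistry inputs rather than a software fault.

## Pre-treatments

Definitions: mean centering and autoscaling are column-wise with statistics
learned from calibration rows only and reused on prediction rows; SNV is
per-spectrum (x − mean)/SD (sample SD); MSC regresses each spectrum on the
calibration mean spectrum and inverts the affine fit; normalize divides by
the Euclidean norm (1-norm and max-norm selectable); baseline subtracts the
per-spectrum minimum (polynomial baseline selectable); detrend removes the
per-spectrum least-squares line over the wavelength axis; smoothing and
derivatives are Savitzky–Golay. Defaults for Savitzky–Golay are window 11,
polynomial order 2 — a common chemometric choice for 256-channel NIR
spectra — and both are exposed per step. Edge channels are handled by
scipy's `mode="interp"`: the polynomial fitted to the last full window is
evaluated at the edge, so no padded or fabricated boundary values enter the
derivative. All definitional choices that the field leaves ambiguous
(normalize norm, baseline form, smoothing parameters) are configuration,
not hard-coded claims.

The pipeline search enumerates ordered combinations of one to four steps
under a grammar that keeps candidates chemically sensible: no repeated
step, at most one of {MSC, SNV}, scatter correction before derivatives,
column-wise steps only terminal, and detrend leading or directly after SNV
or a derivative (this last rule admits the combinations that win in
practice, e.g. SNV + Detrend, 2Der + Detrend, Detrend + MC). Every
candidate — including the raw-spectra identity — is scored on one fixed
seeded cross-validation partition by the RMSE_CV at its RMSECV-optimal
latent count; ties (RMSECV equal to 1e-12) break toward fewer steps, then
token order, so the search is deterministic and the winner can never be
worse than applying no pre-treatment.

## PLS and cross-validation

The regression core is single-response NIPALS with per-component deflation.
X is always column-centered inside the model (the NIPALS convention) even
when the pipeline applied no mean centering, and y is always mean-centered;
reported pipeline labels therefore describe only what was done to the
spectra. When the response is orthogonal to the remaining predictor space
the component loop stops early and returns the null model (regression
vector 0, predictions at the response mean); exhausting the rank of X, by
contrast, is an error. At full rank the model reproduces ordinary least
squares, which the tests verify against a normal-equations oracle and
scikit-learn's PLS implementation.

Cross-validation partitions the n rows into ⌈n/⌈0.1·n⌉⌉ seeded random
segments (≈10% each, every row held out exactly once). Pre-treatment fit
state and centering constants are re-estimated inside each training fold.
The latent count is the global RMSECV minimizer capped at 10 (ties to the
smaller count), matching the complexity range sensible for datasets of
this size.

## Ordered predictor selection

Variables are ranked by an informative vector from a PLS model with hOPS
components: |regression vector|, |column–response correlation|, or their
elementwise product (the default, since it balances model-based and
marginal evidence; the literature leaves the exact construction open, so
all three are selectable and recorded). Numerical ties in informativity
(to 12 significant digits) keep wavelength order. hOPS defaults to the
RMSECV-optimal count on the current variable pool.

autoOPS evaluates nested prefixes of the ranking with sizes window (10),
window + increment (5), … up to 100% of the variables, each at its own
RMSECV-optimal latent count, on one CV partition held fixed across all
subset evaluations (removing partition noise from the comparison). The
full spectrum is always evaluated, so the winner never cross-validates
worse than no selection; ties go to the smaller subset. feedOPS reruns
autoOPS on its own selection until the relative RMSECV change drops below
2% or 10 loops have run. iOPS cuts the axis into contiguous intervals of
max(50, ⌈10%·p⌉) variables (the last interval absorbing the remainder —
256 channels give 50/50/50/50/56), computes a per-interval hOPS, searches
each interval, pools the selections and re-scores the union, falling back
to the full spectrum if the union scores worse.

A property whose best cross-validated correlation stays below 0.5 is
reported "unsuitable" rather than emitting a model; the threshold is
configuration, chosen because usable forage calibrations in this domain
report R_CV of roughly 0.53 and above.

## Sampling

Kennard–Stone picks the maximum-distance pair first, then repeatedly the
sample maximizing its minimum Euclidean distance to the selected set; exact
ties resolve to the lowest row index, making the split deterministic.
Distances are computed on whatever matrix is supplied, so the workflow
passes pre-treated spectra (the split should see the modeling geometry).
The default calibration fraction is 0.7. The outlier screen — the
literature typically reports *that* outliers were removed but not *how* —
is a standard chemometric leverage/studentized-residual screen on a
preliminary full-spectrum PLS (leverage > 3(nlv+1)/n or |studentized
residual| > 2.5, at most two passes, never more than 10% of samples by
default, worst offenders first); every threshold is exposed.

## Degradation kinetics

The first-order asymptotic model is implemented in its standard increasing
form Y(t) = a + b(1 − e^(−kd·t)) for the degraded fraction — the form
consistent with a being the readily soluble fraction; the decreasing
variant a + b·e^(−kd·t) is available via `form="exponential"` for
residue-style data. The Γ(2) survivor model R(t) = b(1 + λt)e^(−λt) + I
is fitted on the residue scale, and kd is derived as 0.59635·λ (a Γ(2)
distribution property applied verbatim as the field's conversion constant)
— never fitted, so the ratio is machine-exact. Degradation and residue
interconvert as 100 − values.

Fits use scipy's trust-region-reflective bounded least squares (the damped
Gauss–Newton family; bounds a, b, I ∈ [0, 100], rates ∈ (0, 1]) from five
deterministic starts spanning the rate bounds, keeping the lowest residual
sum of squares; tolerances are 1e-12 on the relative cost change with at
most 500 function evaluations. A curve with sample SD below 0.5% is
rejected as rate-unidentifiable before fitting. Noiseless curves over
realistic in situ parameter ranges (soluble fraction ~37–58%, degradable
fraction ~34–75%, kd 0.01–0.05 h⁻¹) are recovered to better than 1e-5
relative in all seeded draws, and with 1% Gaussian noise the median
relative error of kd stays under 15% across 200 replicates.

## Evaluation statistics

RMSE and Pearson r per phase; Lin's concordance correlation coefficient
CCC = 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²); MSEP = mean((pred − obs)²)
decomposed into squared bias SB = (x̄ − ȳ)², dispersion mismatch
MaF = (s_x − s_y)², and model random fluctuation MoF = 2s_x·s_y(1 − r).
All variances and SDs use the population (n) denominator, which makes the
decomposition exactly additive. The equivalence test regresses observed on
predicted and applies the joint F-test of (β₀, β₁) = (0, 1) with (2, n−2)
degrees of freedom at α = 0.05 (statsmodels OLS underneath); per-coefficient
standard errors are reported alongside because published tables print them
separately, but the single decision maps to the joint test. Degenerate
perfect fits follow explicit contracts: zero residual variance on exactly
the identity line is "equivalent, degenerate" (p = 1); on any other line it
rejects with p = 0. Under the null the empirical type-I error across 2000
seeded replicates sits within ±0.015 of the nominal 5%.

## Synthetic study conditions

The generator emulates dried-and-ground forage NIR data: each chemical
component is a sum of 3–6 Gaussian bands (centers inside the axis, widths
25–120 nm, heights 0.2–1.0 a.u.), giving smooth, strongly collinear
profiles — the regime variable selection must cope with. Per-sample
multiplicative scatter is a gain U(0.8, 1.2) and offset U(−0.05, 0.05)
(so MSC/SNV have a recoverable target), baseline drift a per-sample linear
slope U(−2e-4, 2e-4) a.u./channel, and instrument noise i.i.d. Gaussian
with SD 0.002 a.u. The default library has four components: component 0 is
a constant-concentration matrix background carrying each property's floor,
components 1–3 vary uniformly on [0, 1]. Non-negative loadings map
concentrations to five properties whose attainable ranges match the spans
seen in corn-silage surveys (CP 5.00–9.06, NDF 34.15–57.81, starch
11.00–40.53, DM 20.43–41.61, EE 1.26–3.76 % DM); because loadings are
non-negative and ranges are attained at corners, generated values can
never leave the configured ranges. With noise, scatter and drift switched
off, every property is an exact linear function of the spectra and a
3-latent-variable PLS reproduces it to machine precision — the linearity
oracle the PLS and pipeline tests lean on. Degradation-curve noise is
homoscedastic Gaussian in % units, matching the least-squares assumption
of the fitting stage. A single integer seed drives all randomness;
identical recipe + seed gives bit-identical output.

What passing tests show — and do not. The generator's spectra are linear
in composition with well-behaved noise; real reflectance spectra carry
moisture and particle-size effects, band shifts, detector nonlinearity and
reference-method error, none of which are simulated. Green tests therefore
establish that the algorithms are implemented correctly and behave as
designed under their own assumptions, not that any particular real-world
calibration will reach a given accuracy.

## Problem sizes

The test suite and examples run on deliberately modest sizes — 40–94
samples × 256 channels for spectra workflows, 60 × 100 for the
variable-selection efficacy studies (20 seeded replicates), 100 seeded
draws per kinetic model, 2000 Monte-Carlo replicates for the type-I error —
sizes this package's own validation needs, comparable to the datasets the
methods target. The full suite completes in well under a minute on one CPU.

## Known limitations

- Single-response PLS only (no PLS2/kernel PLS); no wavelet or
  orthogonal-signal-correction pre-treatments; no Duplex/SPXY splitting;
  no GA/UVE/CARS/sparse-PLS selection — all deliberate non-goals.
- The exact informative-vector construction and per-interval hOPS rule in
  the OPS literature admit variants; the defaults here are explicit,
  recorded decisions.
- Kinetics fits assume homoscedastic errors and apply no
  microbial-contamination correction to in situ residues.
- No vendor binary spectral formats (JCAMP-DX etc.); CSV/XLSX only.
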