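# Methods

## Screen data model and normalization

The interchange unit is the per-well median reporter fluorescence — one
row per (compound, medium condition, biological replicate) — in
delimited text with a mandatory header (comma default, tab accepted).
Raw per-event cytometry files are never parsed: the screen statistic
operates on well medians, so medians are the natural exported readout.
Vehicle wells carry the sentinel compound id `DMSO` (configurable).
Blinding maps are two-column tables (blinded_code, compound_id) and must
be bijections; `blind`/`unblind` compose to the identity, and vehicle
wells are never recoded.

Percent of control for a well is `100 × median / mean(vehicle medians)`
within the same condition. The vehicle aggregate is the **mean** of the
vehicle well medians (not a median-of-medians): the mean is the
conventional plate-control normalizer, and with positive medians it is
strictly positive, so the ratio is always defined. Every raw
fluorescence must be > 0; a global rescaling of all medians by any c > 0
leaves percents, effect summaries and SSMDs unchanged (tested).

## Effect summaries and the SSMD estimator

Per compound and condition, the replicate percentages give the mean
difference d̄ = mean(percent) − 100 and the sample SD s (n−1
denominator, consistent with the estimator below). At least two
replicates are required for s; at least three for the SSMD.

The SSMD β = δ/σ of the difference from control is estimated two ways:

* method of moments: β̂_MM = d̄/s;
* UMVUE: β̂ = k(n) · d̄/s with k(n) = Γ((n−1)/2)/Γ((n−2)/2) · √(2/(n−1)).

k(3) = 1/√π ≈ 0.5642 exactly; k(n) rises monotonically to 1. The
gamma ratio is evaluated via `scipy.special.gammaln` for numerical
stability at large n. Under normal sampling E[d̄/s] = β·√π at n = 3
(d̄ and s are independent; E[1/s] = √π/σ for two degrees of freedom),
which is what the UMVUE factor cancels — verified by simulation in the
test suite. For n = 3 the estimator's sampling variance is infinite
(1/s² is not integrable at two degrees of freedom); the mean is still
well-defined and the Monte-Carlo unbiasedness check uses the empirical
SE, which is adequate at 10⁵ derandomized draws.

s = 0 (noiseless synthetic input, or a degenerate plate) is flagged
`degenerate` and reported as signed infinity rather than dropped or
raised: downstream classification still sees the row, and the flag
propagates into the hit call. One-sample SSMD on percent-of-control
values is the only variant implemented; screens that normalize every
compound to a shared vehicle and report a single d̄ ± s per compound
are exactly this design, and the two-sample formulation is out of
scope, as are robust (median/MAD) variants and spatial plate
corrections.

When only published summaries (d̄, s, n) are available — the usual
situation for printed hit tables — `EffectSummary.from_moments` and
`ssmd_from_moments` consume them directly; replicate-level percentages
are then simply absent from the record. Recomputed UMVUE scores match
printed scores only up to input rounding: a row whose SD is printed as
"2.4" cannot pin its SSMD to 2 decimals, so table comparisons use 2 dp
where the printed SD has ≥ 3 significant figures and an outer ±0.15
envelope everywhere (observed worst deviation across the 72 shipped
rows: 0.125).

## Dual-flashlight classification

All comparisons are inclusive (≥). Qualification is per condition:
inducer-qualifying (full medium, d̄ ≤ −15 and β̂ ≤ −1),
basal-inhibitor-qualifying (full, both ≥ +15/+1), flux-inhibitor-
qualifying (starvation, both ≥ +15/+1). The single category per
compound is resolved with dual-modulator precedence: dual modulator if
inducer- and flux-inhibitor-qualifying, else inducer, else basal
inhibitor, else flux inhibitor, else no effect. Because screens quote
overlapping totals, `CategoryCounts` reports both the exclusive
partition and the overlapping headline numbers (`inducers_total`
includes dual modulators; `starvation_inhibitors_total` counts basal
inhibitors, flux inhibitors and dual modulators together).

Default thresholds are 15 percentage points and |β̂| = 1 ("fairly
moderate effect and above" in standard SSMD effect-size vocabulary).
Raising either threshold can only shrink the hit set (tested
monotonicity). Starvation-condition *decreases* beyond −15% have no
category — the assay's design gives would-be "flux enhancers" no
interpretation here — but they remain visible in the export.

The autofluorescence flag is advisory only: compounds whose |d̄|
reaches a configurable cut-off (default 1000%) are marked
`autofluorescence_suspect` without changing category. The default
separates the one shipped row at +2590% from everything else; a
stricter screener can lower it (at 200% it also catches the +234% row).
Compounds screened in a single condition are classified on the
available data and flagged `missing_condition`.

## 4PL dose-response fitting

Model, in x = log10(dose):
`y = Bottom + (Top − Bottom)/(1 + 10^((LogIC50 − x)·Hill))`; at
x = LogIC50 the value is exactly (Top + Bottom)/2, and IC50 =
10^LogIC50. Absorbance preprocessing subtracts the reference-wavelength
reading per well (when present) before averaging untreated controls to
the 100% anchor; the untreated mean must be positive.

Fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) with a
deterministic starting point: Top/Bottom from the extreme per-dose mean
responses, LogIC50 from the dose nearest the half-way crossing, Hill
±1 by response direction. Zero-dose controls are retained by mapping
them two decades below the smallest positive dose (configurable) so
they anchor the Top plateau. At least 5 distinct doses are required;
non-convergence returns `converged=False` with best-effort parameters
instead of raising. Bottom is unconstrained by default (matching the
common "variable slope" fit), with an optional non-negativity flag. A
profiled grid-search oracle (the model is linear in Bottom/Top at fixed
LogIC50/Hill) bounds the attainable RSS in the tests.

IC50 shift is the fold change IC50(mono)/IC50(combo) of two converged
fits; values > 1 mean the combination partner sensitizes. Synergy
indices (Bliss, Loewe, Chou–Talalay) are out of scope — the
screening-campaign design varies one drug at a fixed partner dose.

The canonical synthetic recovery study uses Bottom 0, Top 100,
IC50 10 µM, Hill −1.5, 8 half-log doses from 0.1 to 316 µM, triplicates,
5% additive noise. Hill −1.5 is typical of cytotoxicity curves; it also
matters statistically: at Hill −1 with all four parameters free, the
asymptotic SE of log10 IC50 under this design is ≈ 0.056, so a ±20%
(±0.079 log10) recovery criterion captures only ~85–88% of fits no
matter how good the optimizer — intrinsic sampling spread, not fit
error. At Hill −1.5 the SE is ≈ 0.036 and observed recovery is ~98%.
Experimentally reported IC50s from the original campaign (9.6–22.6 µM
monotherapy; 22.5→7.1 and 20.7→6.3 µM combination shifts) are not
reproducible from summaries alone since raw absorbances are not
published; the synthetic recovery study is the testable surrogate.

## OCR stress-test metrics

A trace is (time, OCR) with an ordered injection schedule: optional
treatment, then oligomycin, FCCP, rotenone/antimycin A. "After
injection X" means the half-open window (t_X, t_next] (the boundary
convention is a package choice; measurement timestamps rarely coincide
with injection times, so the choice is inert in practice). Metrics:

* non-mitochondrial = min after rotenone/antimycin A;
* basal = last measurement before the *first* injection − non-mito
  (when a treatment injection exists, "first" is the treatment
  injection — the wording "before first injection" is read literally;
  the alternative, anchoring basal to oligomycin, would fold the
  treatment response into basal);
* maximal = max after FCCP − non-mito;
* proton leak = min after oligomycin − non-mito;
* post-treatment = last measurement in the treatment segment −
  non-mito (omitted when no treatment injection).

Normalized metrics divide by basal. Only the min/max/last of each
segment matter, so metrics are invariant to timepoint density, and a
constant offset moves only the non-mitochondrial term (both tested).
Replicate wells (octuplicate or more in a typical run) are computed
per well and then averaged. ATP-linked respiration, spare capacity and
ECAR are not computed.

## Synthetic-data generator

The screen generator emulates the real readout chain: per-event
fluorescence lognormal with log-mean ln(1000) and log-SD 0.8 (a broad
right-skewed distribution typical of a cytometry reporter channel),
10,000 events per well summarized by the sample median, biological
triplicates with multiplicative between-replicate noise (lognormal,
CV 0.07 by default so a null screen shows percent-of-control SDs of
roughly 5–10%, matching the smallest SDs a real screen of this type
prints), two conditions with a 0.6× starvation vehicle level (the
reporter is partially degraded under starvation; the factor cancels in
normalization), 300 compounds, and planted per-condition fold-changes
on the median with full ground truth (true percents and the expected
dual-flashlight category). Two modes: `events` draws every event;
`wells` draws the well median directly from the asymptotic sampling
law of a lognormal median (log-median ~ Normal(·, σ√(π/2N))), which is
statistically indistinguishable here and orders of magnitude faster —
the modes are cross-checked in the tests. What the generator does *not*
model: compound autofluorescence spectra, cell-cycle or viability
confounds, plate-position bias, or heavy-tailed outlier wells; passing
tests therefore demonstrate estimator and pipeline correctness under
the declared noise model, not robustness to those artifacts.

For the null-screen calibration study, the configured conditions are
2000 compounds, replicate CV 0.12 (so the dual-threshold false-positive
probability is non-trivially exercised at ~0.7% rather than ~0), and
288 vehicle wells — about one control column per 384-well plate per
replicate across a campaign of that size. The vehicle count matters:
all compounds in a screen share one vehicle estimate, so hit indicators
are positively correlated, and with only a handful of control wells the
hit-count variance visibly exceeds binomial; at 288 control wells the
residual correlation is small relative to the 3-SE comparison band
against the independent brute-force Monte-Carlo oracle (which mirrors
the full generative model, vehicle noise included).

Dose-response and OCR generators add Gaussian noise to the exact model
curve / piecewise-constant segment means; all generators are
bit-reproducible from their seed (numpy `default_rng`).

## Numerical and formatting choices

Screen-table writers emit floats as their shortest round-trippable
decimal (`repr`) and readers parse with round-trip float precision, so
write→read is lossless bit-for-bit; generic results tables guarantee
≥ 6 significant digits. Condition names parse case-insensitively with
the aliases full/full_medium/fed/basal and
starvation/starved/starvation_medium. Pipeline runs are deterministic
given config and seed; reruns produce byte-identical effect, hit-call
and counts artifacts.

## Problem sizes in the shipped studies

The test suite and acceptance script use: 10⁵ triplicates for the
estimator-bias simulations, a single 2000-compound null screen vs a
4×10⁵-trial Monte-Carlo oracle, 500 noisy curves for the IC50 recovery
rate, 25–30 random traces/screens for the oracle and recovery
property checks. These sizes give Monte-Carlo SEs comfortably inside
every stated tolerance while keeping a full run in the tens of seconds.
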