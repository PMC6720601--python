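# Methods

## Scope and data model

The package models the statistics of an intra-laboratory validation of a
multiclass SRM/MRM residue method, not the chromatography or mass
spectrometry themselves. Its atoms are peak areas in a tidy table
(`analyte, matrix, sample_kind, level, day, replicate, transition_rank,
area`), with four sample kinds: `spiked` (blank matrix fortified before
extraction), `matrix_matched_std` (analyte added to blank extract just
before injection), `solvent_std` (standards in buffer), and `blank`.
The acquisition design lives in a separate method table: one row per
monitored transition with retention time, adduct, precursor/product m/z,
collision energy, quantifier/qualifier rank and the matrices in which the
analyte is acquired. Two quinolones are milk-only; eight isotope-labelled
or surrogate internal standards are used for quality control, never for
quantification.

## The synthetic experiment

The generator emulates the validation design: spiked replicates at
muscle levels {10, 33, 100, 150, 333, 1000, 1500} µg·kg⁻¹ or milk levels
{10, 33, 100, 150, 333} (optionally plus a 2 µg·kg⁻¹ half-MRL point for
the beta-lactams), 4 replicates/day × 3 days, each day with its own
matrix-matched curve at {2, 10, 33, 100, 150} plus blank, triplicate
injections, and one solvent curve.

One analyte's quantifier area at concentration c, day i, replicate j:

    A_ij = Rec · (a + b_MM·c) · (1 + d_i + e_ij),   b_MM = b_S·(1 + ME/100)

with d_i ~ N(0, σ_L) shared by the whole day and e_ij ~ N(0, σ_r), where
σ_r = CV_r/100 and σ_L = √((CV_wR/100)² − σ_r²). Noise is multiplicative
(constant CV): precision in this field is reported as CV across a 150-fold
concentration range, which an additive-error model could not reproduce.
That choice is an assumption of the generator, not a measured property of
any instrument. Calibration standards skip the extraction, so they carry
neither recovery loss nor the day effect — only injection noise (default
CV 2%); if the day effect also multiplied the standards, back-calculation
against the same-day curve would cancel it and no between-day component
could ever be observed. Blanks are N(0, blank_noise_sd) truncated at zero.
Qualifier areas are the quantifier times the reference ion ratio times a
small noise (default CV 3%). Everything derives from one integer seed
(numpy `default_rng`); a run is bit-reproducible.

What the generator does **not** emulate: peak shapes and integration
errors, heteroscedastic detector saturation at the top of the range,
carry-over, analyte instability (the known degradation of penicillins in
stored materials), and genuine cross-talk bleed-through between analytes
(the audit *screens* for the geometry that permits it; it does not inject
it into areas). Passing tests therefore demonstrate that the estimators
recover the truths of this generative model, not that any real instrument
meets the figures.

## Estimators

**Calibration.** Unweighted OLS (closed-form simple regression) of mean
area per level vs level, free intercept, blank included as a true level-0
point — forcing the line through zero would hide blank contamination.
Linearity is judged per point by the back-calculated deviation
(C_meas − C_true)/C_true·100; level 0 is exempt (division by zero).
Pruning removes the lowest non-zero level and refits while any point
exceeds the band (default ±20%), stopping at three non-zero levels; a
still-failing curve is flagged nonlinear rather than silently accepted.
Lowest-first removal mirrors practice: the failure mode is scarce response
at the bottom of the range.

**Matrix effect.** The printed convention ME = b_MM/b_S·100 cannot be
negative, yet suppression is routinely reported with negative signs; the
package therefore reports the signed deviation (b_MM/b_S − 1)·100 as
`me_percent` and exposes the raw ratio as `ratio_percent`. Significance
threshold defaults to |20|%.

**Recovery.** Per level, mean spiked area over mean matrix-matched area
×100; the overall figure is the unweighted mean over levels (every level
is one experiment; weighting by replicate count would let high levels
dominate). Spiked levels above the calibration ladder have no matching
standards, so by default the shared levels {10, 33, 100, 150} are used; a
caller requesting an absent level gets an error naming it.

**Precision.** Concentrations are back-calculated against the *same day's*
pruned curve and divided by the overall recovery fraction, then a one-way
random-effects ANOVA per level: s²_r = MS_within;
s²_L = max(0, (MS_between − MS_within)/n₀) with the standard unbalanced
coefficient n₀ = (N − Σnᵢ²/N)/(a − 1); s²_wR = s²_r + s²_L. Negative
component estimates truncate at zero (the usual method-of-moments
convention). CVs divide by the grand mean; pooling across levels is the
df-weighted RMS. With only 3 days the between-day component has ~2 df, so
single-run pooled CV_wR estimates scatter ±30% relative and carry a small
downward Jensen bias; the parameter-recovery driver quantifies this
(mean over 100 seeds within ~5% of truth).

**Decision limits.** CCα = MRL(1 + 1.64·cv), CCβ = CCα(1 + 1.64·cv), cv
the pooled within-lab CV as a fraction and 1.64 the one-sided 95% normal
quantile; the geometric identity CCβ·MRL = CCα² is enforced by a property
test. Pooling lets limits be computed at any MRL without re-validating.

**Operative LOD/LOQ.** No instrument S/N is available to a data pipeline,
so detection uses a blank-based surrogate: area > blank mean + 3·blank SD,
required of every replicate on both transitions. LOD is the lowest
detectable level; LOQ the lowest detectable level with CV_r and CV_wR both
≤ the precision threshold (default 20%, between the "acceptable" and
"insufficient" figures seen in practice; configurable). No qualifying
level, or pooled CV_wR above the threshold, classes the method
screening-only for that analyte.

**Identification.** Ion ratio = qualifier/quantifier (quantifier is the
stronger transition, keeping ratios ≤ 1) with the regulatory band ladder
(>50% → ±20; >20–50% → ±25; >10–20% → ±30; ≤10% → ±50, relative); RRT
deviation < 2.5% against a same-batch reference; IS gate requires all
eight internal standards above the detection threshold and names any
absentee. Reference ion ratios and RRTs are runtime inputs (same-batch
standards), not fixtures.

**Cross-talk screening.** All target pairs with |ΔRT| ≤ rt_window
(default 0.3 min) and precursor m/z within mz_tol (default 0.5, the
unit-resolution regime) are flagged, regardless of charge state — a
quadrupole transmits m/z, not charge. No co-elution tolerance is
standard, so the window is configurable. The bias helper quantifies the
worst case as (A_a + A_b)/A_a, full bleed-through of the interferer.

**Proficiency tests.** The organizers' σ is not published, so z-scores
are advisory, reconstructed as σ = range/4 (acceptability ≈ consensus ±
2σ); the authoritative verdict is the range check. "Not detected" with an
assigned consensus counts as out-of-range without a numeric z; unassigned
consensus values are not evaluable and excluded from pass/fail counts.

## Pipeline and determinism

`run_pipeline` executes the stages in fixed order from one YAML config in
which every threshold appears explicitly. Per-analyte generator seeds are
spawned from the master seed via `numpy.random.SeedSequence`, so reports
are byte-reproducible and re-running from a report's embedded config
regenerates it exactly. Analytes not acquired in the configured matrix
are excluded with a logged reason; concentrations above the retained
calibration range would require extract dilution, which is recorded as a
flag rather than extrapolated.

## Problem sizes

The default simulated experiment is the real design's size (3 × 4
replicates per level, 5–7 levels); Monte-Carlo drivers use 100 seeds,
and large-design bias checks use 50 days × 20 replicates — sizes chosen
so that Monte-Carlo standard errors are a few percent, comfortably inside
the assertions' tolerances.

## Known limitations

- The generator's normal multiplicative noise admits (rare) negative
  areas at high CVs, truncated to zero; at CV ≤ 35% this truncation is
  negligible but it slightly biases blanks.
- Recovery and matrix-effect truths enter the generator as constants; real
  recoveries drift with level and day.
- The MRL fixture is a small subset for exercising the limit machinery,
  not a regulatory database.
- The interference audit reasons on the monitored transitions only; shared
  *unmonitored* fragments (the actual hidden-transition chemistry) are
  inputs to the bias estimator, not predicted.
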