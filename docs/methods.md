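# Methods

This note documents the statistical procedures implemented in
`drugprofiler`, the defaults they ship with, the numerical choices behind
them, and what the synthetic-data generators do and do not emulate.

## Units and conventions

All concentrations are handled internally in μmol/L. Potencies are reported
on the molar scale: `pec50 = 6 − log10(EC50 [μmol/L]) = −log10(EC50 [M])`,
so an IC50 of 3.2 nmol/L corresponds to pIC50 ≈ 8.5. Dilution series are
descending geometric sequences defined by a start concentration, a dilution
factor > 1 and a point count.

The 4PL model is parameterized with `top` always the zero-dose asymptote
and `bottom` the high-dose plateau, with Hill slope h > 0; a decreasing
curve (competition, viability) has top > bottom and an increasing curve
(thermal stabilization) top < bottom. Curve direction is an explicit
argument to the fitter and never inferred from the data.

## 4PL fitting

Bounded nonlinear least squares (scipy `least_squares`, trust-region
reflective) with the Hill slope constrained to [0.2, 5] and the pEC50 to
two decades beyond the measured series. The optimizer is restarted from
three initial pEC50 guesses — series maximum, geometric midpoint, series
minimum — and the lowest-cost solution kept; this removes the need for
stochastic global search on these monotone single-site curves. `top` and
`bottom` accept three constraint forms: free, fixed to a value, or bounded
to an interval. Data whose response range is below `flat_epsilon`
(default 0.1 response units) raise a no-dose-dependence error rather than
returning an unstable fit; fits also require at least four positive dose
levels spanning more than one order of magnitude. On noiseless synthetic
curves the fitter recovers the generative pEC50 to < 1e-6 log units across
pEC50 5–9 and Hill 0.7–1.5, and agrees with an exhaustive grid search of
the objective to the grid resolution (tested at 0.001).

## Competition binding and depletion correction

Relative abundances are assumed vehicle-normalized, so the competition fit
constrains top = 1 by default and bounds the bottom plateau in [0, 0.5]
(complete competition may still leave background binding). The depletion
ratio r = second capture / first capture (clamped to [0, 1]) estimates the
fraction of target a single bead incubation leaves in the lysate; the
correction `Kd_app = IC50 · r` is the established convention for
bead-based competition experiments — the correction function is pluggable
should a different bead model be required. Replicate pKd_app values are
averaged on the log scale. Proteins whose curves are flat in all replicates
are flagged `not_competed` and carry no estimate; fitted IC50s at or beyond
the measured series are reported but flagged as censored
(`pKd_app > / <` the series boundary), since their exact value is not
identifiable within the measured range.

## 2D-TPP stabilization calling

The table is a long format of (protein, temperature, concentration,
fold change vs vehicle at the same temperature). A protein is called
stabilized iff at some concentration a temperature reaches fold ≥ 2.0 and a
*ladder-adjacent* temperature reaches ≥ 1.8 at that same concentration.
Adjacency is positional on the sorted ladder of temperatures observed for
that protein, not a °C distance — this mirrors the paired-temperature
multiplexing design of 2D-TPP. Both thresholds are parameters. The
same-concentration requirement can be relaxed with a flag (the criteria
sentence the defaults implement does not spell it out; the per-concentration
heatmap-column reading is the default). Dose-dependence of the
stabilization is *not* additionally required. Proteins observed at a single
temperature are reported as not callable rather than silently negative.

## ITDR combined fits

Each dataset is min-max normalized to [0, 1], datasets are pooled, and one
increasing 4PL is fitted. Because a finite dilution series never quite
reaches either plateau, the min-max normalized curve slightly overshoots the
true asymptotes; fixing the fitted asymptotes exactly at 0/1 therefore
biases the pEC50 when the EC50 sits near a series edge (about +0.06 log
units at pEC50 5.8 on a 30 μmol/L, factor-8, 7-point design). The pooled
fit instead anchors the asymptotes in narrow bands ([−0.2, 0.2] and
[0.8, 1.2]), which removes the truncation bias while preserving the
normalization contract; noiseless recovery is then exact. Flat datasets
(relative range < 10%) are excluded with a warning; if all are flat the fit
errors.

## DSF melting points

Tm is the temperature of the maximum of the first derivative of the
330/350 nm fluorescence ratio. The derivative is computed with a
Savitzky-Golay filter (local quadratic, default window 5 points), because a
derivative-maximum estimator on raw finite differences is noise-dominated.
The maximum must be interior and stand above both ramp ends beyond
floating-point ties; otherwise no transition was captured and an error is
raised. For a logistic transition the derivative maximum is the inflection
point, so the estimator is exact up to the grid step; with 1% amplitude
noise on a 0.2 °C grid the median error across seeds stays below 0.5 °C.

## Steroid calibration engine

Responses are analyte/internal-standard ratios. Four candidate models are
fitted per metabolite — {straight, quadratic} × {unweighted, 1/x-weighted}
— by weighted polynomial least squares; R² is computed with the same
weights as the fit so score and objective agree. Validation back-calculates
every retained point through the inverse model; the model is valid iff all
relative errors are ≤ 15% (default, configurable). Quadratic inversion uses
the root on the branch over which the fitted parabola is monotone across
the retained calibration range (the other root mirrors across the vertex),
bounded to [0, 2 × max nominal]; a non-monotone fit or an unreachable
response is non-invertible (infinite error in validation, NaN plus a flag
in sample quantification).

Outlier removal drops at most ⌊25% · n⌋ points. The removal order is
one-step-lookahead greedy: each retained point is tentatively removed, the
model refitted and revalidated, and the candidate whose removal minimizes
the refitted maximum back-calculation error is removed. A plain
worst-residual rule was rejected because a gross outlier at high
concentration drags the intercept and inflates the *relative* errors of the
low-concentration points, so the worst residual is often not the outlier.
The lookahead costs O(n) extra fits per removal — negligible for
calibration-sized n — and is deterministic. The first valid model found
retains the most points by construction; among the four combinations the
highest R² wins, with residual ties broken in the fixed order straight
before quadratic, unweighted before weighted. If no combination yields a
valid model the metabolite is not quantifiable.

Sample responses outside the retained calibration response range are still
quantified but flagged `out_of_range`. Treatment effects are
mean(treated)/mean(vehicle) with a two-sided Welch t-test
(Welch-Satterthwaite degrees of freedom); the degenerate zero-variance case
is defined as t = 0, p = 1 for equal means. No multiple-testing correction
is applied across metabolites (effects are reported per steroid).

## Bliss synergy

Inhibition fractions are 1 − viability/100 clamped to [0, 1] (viability can
exceed 100% by noise, and the Bliss expectation needs fractions). The
expectation for a combination well uses the monotherapy inhibitions at its
two doses; the well score is 100 × (observed replicate mean − expected),
and the whole-matrix score is the mean over all combination wells. The
default uses raw monotherapy means; an optional smoothing mode replaces the
monotherapy rows with fitted 4PL values before the expectation (an
approximation of whole-matrix preprocessing in matrix-correction tools).

Significance: replicates are resampled with replacement independently per
well; the whole-matrix score is recomputed per resample; the CI is the
2.5/97.5 percentile band and the two-sided p-value the (+1-corrected)
fraction of resampled scores on the opposite side of zero from the observed
score (observed |score| < 1e-9 is the degenerate noiseless case, p = 1).
Each well's resampling stream is seeded from the unordered pair of its two
doses, which makes p and CI exactly invariant under swapping the two agents.
In smoothing mode the fitted monotherapy reference is held fixed during
resampling; refitting per draw is ~2000× more expensive and the reference's
residual uncertainty is precisely what smoothing is meant to remove. The
classification is the four-way conjunction: score > 3, p < 0.05, CI low
bound > 0, and a window of ≥ 2 adjacent doses of each agent in which every
well score is positive (window semantics use positive scores, not per-well
significance; an alternative could be slotted in at the region detector).

## Synthetic-data generators

Noise models: multiplicative lognormal with unit median for MS abundances
and LC-MS responses (positive, CV-scaled signals); additive Gaussian in
percentage points for viability. One root seed per spec spawns independent
child streams per replicate/dataset, so identical specs are bit-identical
and replicates are independent.

Defaults mirror the profiled experimental designs: six-point competition
series starting at 30 μmol/L with factor 7 in triplicate; the
12-temperature ladder (42.1–63.9 °C) with four compound concentrations
(0.12–30 μmol/L); seven-point ITDR series starting at 30 μmol/L with
factor 8; 0.2 °C DSF ramps; 8-point calibration series spanning 0.5–64
concentration units with 3 vehicle vs 3 treated samples and a default true
fold of 6.5; and 6 + vehicle dose combination grids with factor-3 series
starting at 30 and 5 μmol/L. 2D-TPP fold changes derive from a shifted
logistic melting curve (vehicle midpoint 50 °C, slope 1.5 °C, shift
ΔTm_max · occupancy at a Hill-type midpoint), which yields
temperature-localized fold-change peaks like real stabilization heatmaps;
an explicit-pattern helper builds fixture tables directly from fold
dictionaries. Combination-matrix monotherapy curves place each agent's EC50
near the middle of its dilution series (2.0 and 0.33 μmol/L) with partial
maximal inhibition 0.7, so the grid spans ~4–65% inhibition and a
programmed +15 pp Bliss excess is exactly representable without clamping at
either end; a programmed excess block plus noise then has the programmed
whole-matrix mean (3.75 for +15 pp over 9 of 36 wells, exactly, in the
noiseless case).

What the generators do *not* emulate: TMT reporter-ion and isotope-impurity
structure, peptide-to-protein roll-up, plate/batch effects and positional
drift, chromatographic peak shape, heteroscedasticity beyond the single CV,
or correlated noise between wells. Passing recovery tests therefore
demonstrates correctness of the estimators under their assumed error
models, not robustness to every artifact of real instruments.

## Problem sizes

The validation studies use triplicate curve sets, 100-seed recovery studies
for binding and steroid folds, 50-seed studies for calibration
validity/budget and DSF noise, 200-seed power studies for synergy
classification, and 200–2000 bootstrap draws; these sizes give stable
pass/fail margins for the stochastic checks while keeping the whole suite
fast on a single CPU.

## Known limitations

- The depletion correction assumes a single bead incubation with
  first-order target capture; multi-step depletion schemes need a plugged-in
  correction.
- Censored affinities (IC50 beyond the series) are flagged, not modeled;
  no censored-regression estimate is attempted.
- ITDR pooling assumes a shared Hill slope and midpoint across datasets.
- The calibration engine considers exactly the four quoted model
  combinations; no log-log or power-law families.
- The bootstrap treats replicate plates as exchangeable per well; plate
  effects would require a hierarchical resampling scheme.
- 5PL/biphasic dose-response models, Loewe/ZIP/HSA synergy references and
  proteome-wide melting-curve ΔTm statistics are out of scope.
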