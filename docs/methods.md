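# Methods

## Scope and model structure

The package treats a ciliate population as a collection of cells whose
ribotype content (per-cell 18S rDNA and rRNA copies) is a power-law
function of cell size, modulated by life cycle stage. Three derived
procedures build on that core: a resting-cyst fraction estimator, a family
of growth-rate prediction models, and a single-cell sequence-variant
divergence analysis. Everything operates downstream of wet-lab work and
read denoising: inputs are per-cell trait tables, qPCR dilution series,
population copy-number totals, and denoised variant pools with abundances.

## Geometry

Fixed cells and macronuclei are prolate spheroids, `V = (π/6)·L·W²`, with
the length the single major axis and the width both minor axes. The
equivalent spherical diameter is `ESD = (6V/π)^(1/3)`; all sizes are μm/μm³.
The nucleocytoplasmic ratio is MV/CV. An MV ≥ CV input is flagged with a
warning rather than rejected, since such rows usually indicate a data-entry
problem the user should see, not a crash.

Maximum growth rate is the steepest least-squares slope of ln(abundance)
versus time (d⁻¹) over a sliding window of consecutive positive-abundance
points. The window defaults to 3 points and shrinks to the available data
(two points give the exact two-point rate). The windowing rule is a design
choice of this package; published rate values were obtained with an
earlier protocol whose windowing is not restated here.

## Allometric fits and their algebra

Fits are ordinary least squares of log10(response) on log10(predictor) —
no errors-in-variables correction, matching how such scaling relations are
conventionally reported. The slope t-test p-value is reported without
multiplicity adjustment. Exact transformations connect parameterizations:

- CV → ESD: slope ×3, intercept + slope·log10(π/6). Note
  log10(π/6) = −0.28100 at full precision; the reference table's ESD
  intercepts (0.396, 3.43) are the rounded forms of the exact transforms
  (0.39644, 3.42553).
- per-cell → population: coefficients unchanged, a `+log10 N` term added
  and the response relabeled from CNPC to total. `N` is the abundance of an
  idealized population of identical cell size.
- ratio of two fits on the same predictor: coefficient differences; the
  population terms cancel.

`table1_registry()` stores the published coefficients exactly as printed
(not re-derived), so derived quantities reproduce printed constants — e.g.
the ratio of the total-rRNA and total-rDNA relations has intercept
3.43 − 0.396 = 3.034 and 10^3.034 rounds to 1081. A zero-variance response
is reported with slope 0, R² = 0 and p = 1 rather than NaN.

## Cyst-fraction estimator

For an all-vegetative population the bulk ratio rRNA_total/rDNA_total is
`10^3.034 · ESD^0.33` (default baseline; injectable for species-specific
recalibration). Resting cysts retain rDNA but carry only ~0.02–0.5% of a
vegetative cell's rRNA, so the measured ratio deficit estimates their share
of the rDNA pool:

    cyst% = 1 − ((rRNA_total − rRNA_rc)/rDNA_total) / (10^b · ESD^a)

with `rRNA_rc` an optional correction for cyst rRNA carryover (default 0;
at ≤0.5% carryover it moves the estimate by <0.5 percentage points). The
printed intermediate form of this derivation (the log-scale "equation 11")
carries a sign typo in its last term that makes it inconsistent with the
final estimator; the implementation follows the final form above. Raw
estimates outside [0,1] — expected under measurement noise — are clamped
and flagged rather than rejected. ESD is the vegetative-cell ESD; for mixed
populations this is the natural choice because the baseline describes
vegetative cells, and it is configurable.

Uncertainty comes from a percentile bootstrap over replicate pools
(seeded, default 1000 resamples). With ~12 replicates, percentile
intervals sit slightly below nominal coverage, as is typical for the
method at small replicate counts.

## Growth-rate models

`log10(r) = c_t·t + c_x·log10(x) + b`, fitted by OLS (statsmodels), no
interaction term. Predictors: per-cell rDNA, per-cell rRNA/rDNA ratio
(log10-transformed like the others), per-cell rRNA, or CV. A constant
predictor or temperature is rejected as rank-deficient. The published
coefficient registry records n = 12 for the rDNA model, the value its
source table prints, although the accompanying text says n = 11; the
discrepancy is noted where the registry is defined. Model comparison ranks
by R² with ΔR² annotations and requires the fits to share a dataset tag.

## qPCR

Standard curves regress CT on log10 copies; replicate CTs at the same
dilution are averaged before fitting (configurable). Efficiency is
`E = 10^(−1/slope) − 1`; a perfect doubling assay has slope −1/log10 2 ≈
−3.3219 and E = 1. The QC flag accepts E ∈ [0.9, 1.2] (90–120%), a window
containing the 98–108.9% range reported for the reference assays.
Unknowns are quantified by curve inversion; rRNA is obtained from cDNA
templates by subtracting the matched rDNA count, clamping negative
differences to zero with a warning (noisy biological samples), never
erroring.

## Variant pools

Identity between two variants is computed from a Needleman–Wunsch global
alignment with unit mismatch/gap costs (edlib): matches divided by
alignment columns, terminal gap runs excluded, each internal gap position
counting as one column. Because costs are tied, an optimal alignment can
occasionally trade a terminal substitution for terminal gaps; fixtures that
need exact divergences therefore use interior substitutions.

Clustering is deterministic greedy centroid assignment: variants sorted by
descending count with lexicographic sequence tie-break; each joins the
first centroid matching at ≥ threshold, else founds a cluster. This is a
from-scratch reimplementation of the greedy strategy used by published
clustering tools; exact agreement with any particular tool at boundary
identities is not guaranteed. The threshold scan runs over 0.89–1.00 in
0.01 steps. The **leveling threshold** is the largest cutoff at which the
pool collapses to one OTU; `(1 − leveling) − residual_error_rate`, floored
at 0, is the error-corrected maximum intraindividual divergence. Residual
error rates are supplied per pool (1% for the Colpoda assays, 0 for the
marine species, per clone-library controls); denoising itself is out of
scope.

Rarefied richness subsamples reads without replacement (a multivariate
hypergeometric draw over OTU counts), default depth 1600 and 100 seeded
repetitions; the analytic hypergeometric expectation
`E[S] = Σ(1 − P(absent))` serves as its independent check. Whether the
original per-1600-read richness used replacement or how many repetitions
is not stated anywhere; without-replacement × 100 is this package's
assumption. The richness–copy-number regression leaves the OTU count
untransformed (small integers) and logs only the copy number.

## Synthetic data

Generators are deterministic under a seed and encode the study conditions:

- `gen_cells`: stage-specific log-normal CV (the default profiles carry
  the printed per-stage means for the two Colpoda species at 18 °C, e.g.
  lag-phase C. inflata ≈ 2.14e5 μm³, resting cysts ≈ 2.0e3 / 2.0e4 μm³);
  MV = 0.14·CV^0.83; rDNA and rRNA from the generating power laws with
  multiplicative log-normal noise (default log10 sd 0.25, which yields the
  R² ≈ 0.84–0.93 range seen in the reference fits); resting-cyst rRNA
  multiplied by a suppression factor (1e-2 for C. steinii, 1.2e-3 for
  C. inflata — chosen so generated cyst rRNA matches the printed ≈3.4e4 and
  ≈3.1e4 copies, giving the ~200–5000× vegetative/cyst contrast).
- `gen_population`: N cells of one ESD, a known fraction resting cysts
  with equal rDNA and suppressed rRNA. With zero noise the estimator
  recovers the fraction to within the suppression factor exactly — the
  designed validation identity.
- `gen_dilution_series`: CT from the efficiency model plus Gaussian noise
  (default sd 0.1 CT), triplicate reactions per dilution as on real plates.
- `gen_variant_pool`: the template (random fixed-seed sequence, V4-like
  373/374 nt; no real 18S sequence needed) as dominant variant; minor
  variants substituted at `round(d·L)` positions for each profile
  divergence (C. steinii 3% and 10% true divergence); optional error
  singletons branching off the most divergent variant at
  `round(error_rate·L)` fresh positions, so apparent divergence = true +
  error — the structure the correction removes.
- `gen_power_law_sample` draws log10 CV uniformly over [2.5, 5.5], the
  span from small resting cysts to the largest lag-phase cells, wide
  enough that exponent recovery is informative at realistic noise.
- `gen_growth_dataset` uses a fixed 12-point design (t ∈ 16–28 °C, trait
  spanning >2 decades) mirroring the reference data structure, whose
  per-point table is not published.

What the generators do **not** emulate: real sequence composition and
chimeras, plate-position qPCR effects, non-log-normal trait dispersion,
taxon differences in rDNA content (the marine species' ~30–80× higher
rDNA per cell is represented only through separate profiles/registries).
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical assumptions, not robustness to
every feature of field data.

## Numerical choices

- All fits via `scipy.stats.linregress`/statsmodels OLS; no refitting of
  printed registry coefficients.
- Clamping (cyst fraction to [0,1], rRNA subtraction to ≥0) is always
  flagged, never silent.
- Clustering ties: stable insertion order; dominant-OTU ties resolve to
  the earlier-founded (more abundant centroid) cluster.
- Seeds: every stochastic routine takes an explicit seed and uses
  `numpy.random.default_rng`; derived child seeds stay below 2³¹.
- Problem sizes in the validation suite (100 replicates × n = 200 for
  exponent recovery; 100 dilution series; 2000-read variant pools; 12
  bootstrap replicates of 400-cell pools) were chosen as the smallest
  sizes at which the stochastic checks are stable across seeds.

## Known limitations

- The baseline ratio constants are Colpoda-derived; applying them to taxa
  with different rDNA ploidy (e.g. spirotrichs) requires re-calibration
  via the injectable baseline.
- The greedy clustering is not guaranteed to match published tools within
  one identity step of a threshold boundary.
- The cyst estimator assumes a single characteristic vegetative cell size;
  strongly size-structured mixed populations violate that assumption.
- Growth-rate models are correlative; they extrapolate poorly outside the
  16–28 °C, 10³–10⁶-copy domain they encode.
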