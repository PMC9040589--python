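# Methods

This note documents the models, parameter choices and numerical decisions
behind `crossfeednet`, and what the synthetic-data tests do and do not show
about real data.

## Experimental design the package assumes

Two culture types, both sampled through the growth phase and profiled by
untargeted negative-mode FIA-MS plus OD measurements:

* **Fresh-medium monocultures**: every species alone in the rich growth
  medium, 3–4 replicates, 8–10 supernatant samples per curve.
* **Spent-medium cultures**: cell-free supernatant of a producer harvested
  in stationary phase, mixed 1:1 with fresh medium, inoculated with each
  other species.

All tables are TSV. The ion time-course dialect is
`species  medium  replicate  time_h  od` plus one intensity column per
annotated ion; media are identified as `fresh` or `spent:<producer>`.

## Accurate-mass annotation

Ions are treated as singly deprotonated, [M − H]⁻: the candidate m/z of a
formula is its monoisotopic neutral mass minus the proton mass 1.007276 Da
(the proton, not the hydrogen atom, since the species is an anion; the
electron-mass difference of ~0.55 mDa is far below the tolerances used and
is ignored). The default matching tolerance is 0.003 Da for FIA annotation;
expected masses of fully ¹³C/¹⁵N-labeled species (isotope shifts 1.003355
and 0.997035 Da per atom) are intended for LC-MS tracer data, where
0.001 Da is the customary tolerance. Candidates are ordered by |mass error|
with alphabetical tie-break, so output is reproducible. Compounds with the
same formula are isobaric and are never collapsed — the annotation is
level 4 by construction. No adducts beyond [M − H]⁻, no isotope-pattern
scoring, no MS2.

## Growth model

OD(t) = A + (K − A)/(1 + e^(−r(t−t₀))) — four-parameter logistic with
baseline A (OD), asymptote K (OD), shape rate r (1/h) and inflection t₀
(h). Fitting is bounded least squares (trust-region reflective), initialized
with A = min OD, K = max OD, t₀ at the steepest log-slope and r from a
log-linear fit of the middle third of the series. At least 5 distinct time
points and strictly positive OD are required; non-convergence is flagged on
the result, never silent.

The reported specific growth rate μ is **max d ln OD/dt of the fitted
curve** (evaluated on a 2001-point grid over the data span), not the shape
parameter r: μ is what "specific growth rate" means on a log-OD plot, and it
is invariant to rescaling OD while r is a curvature parameter. A fitted
K − A below 0.05 OD units is classified "no growth" (μ = 0) — batch OD
readings rarely resolve smaller gains.

Spent-medium benefit is summarized as max OD relative to the fresh-medium
max OD of the same species; 0.5 is the neutral expectation under a pure 1:1
medium dilution. Supplementation effects are ratios of per-replicate means
(μ, max OD, trapezoid AUC of raw OD normalized to the control mean), with
two-sided Welch t tests on the per-replicate μ and max OD. Welch rather
than pooled-variance is a deliberate choice: arm variances are routinely
unequal and the cost at equal variance is negligible. With a single
replicate per arm the p-values are reported as missing; the ratios are
still returned.

## Consumption/secretion calling

Replicates of a culture are averaged per time point before testing
(per-replicate pooling is available behind a flag). For each ion series x(t)
against the culture OD(t):

* **Correlation branch**: Pearson |r(x, OD)| > 0.7 with two-sided p < 0.05
  (p from the exact t distribution of the sample correlation under r = 0).
* **Fit branch**: OLS of x on t, or of log x on t (the "exponential" fit),
  with R² > 0.7 and slope p < 0.05. This branch exists for metabolites
  exhausted before the end of the experiment or produced at a constant
  rate, whose correlation with the sigmoid OD is weak.
* **Fold-change gate**: the maximum fold change between the first time
  point and any later point must reach 1.37 (decrease, consumed) or 1.20
  (increase, secreted).

An ion is called consumed/secreted when a statistical branch passes *and*
the fold-change gate passes in the direction of the passing statistic; the
trend sign is taken from the correlation when that branch passes, else from
the passing fit's slope (linear before exponential — a fixed, documented
precedence). Everything else is "unchanged". Zero intensities are floored
at half the smallest positive value in the series (flagged
`intensity_floored`); all-zero or constant series are flagged `degenerate`
and left unchanged. No multiple-testing correction is applied — each ion is
a separate hypothesis about one culture and the fold-change gate is the
practical false-positive control.

Fold-change sign convention: increases are reported as x_max/x₀ ≥ 1,
decreases as −x₀/x_min ≤ −1, and the stored `max_fc` is the extreme
consistent with the called direction.

The same thresholds are applied to fresh- and spent-medium cultures
(consistency over literalism; the calling criteria are a property of the
measurement, not of the medium).

### Threshold calibration

The asymmetric fold-change defaults (1.37 consumed / 1.20 secreted) reflect
ion suppression in flow injection: a known 2-fold dilution of a rich medium
produces a smaller-than-2-fold intensity change, and the empirically
observed change across a 2-fold window is the smallest change worth
believing. `calibrate_thresholds` reproduces this on any dilution series:
ions with Pearson r < −0.75 against the dilution factor are medium-derived
(background ions are flat and excluded); the consumed threshold is the mean
fold change across the 40×→80× window, the secreted threshold across
20×→40×. On an ideal, noise-free 1/dilution response both come out exactly
2.0 — the synthetic oracle. Note that a perfectly hyperbolic response over
a very wide dilution range (20–720×) correlates with the dilution factor
less strongly than real, partially saturated responses do; the synthetic
calibration series therefore spans 20–160×, where the ideal ion passes the
−0.75 filter with margin.

## Network construction

* **Fresh-medium prediction**: a metabolite is potentially cross-fed iff
  secreted by ≥ 1 species and consumed by ≥ 1 *different* species. A
  species may legitimately appear in both the producer and consumer sets
  (transient overflow metabolism), but self-pairs never count, and a
  metabolite whose sole producer is its sole consumer is excluded.
  Interaction type from (|producers|, |consumers|): (1,1) one-to-one,
  (1,≥2) one-to-many, (≥2,1) many-to-one, (≥2,≥2) many-to-many — the four
  counts partition the cross-fed metabolites.
* **Spent-medium edges**: (P, C, m) iff m has a secreted call for P in
  fresh medium and a consumed call for C in `spent:P`, with P ≠ C. Each
  triple counts once, even if supported by several calls. A spent medium
  referencing a producer absent from the fresh-medium calls is an error.
* **Goods and scores**: public good ⇔ ≥ 2 distinct consumers over the
  edges. Species score = consumed-edge count / secreted-edge count; a pure
  producer scores 0, and the ratio of a species that secretes nothing is
  flagged NaN rather than inflated.
* **Statistics**: class enrichment among public goods uses the two-sided
  Fisher exact test (minimum-likelihood two-sidedness: the sum of
  probabilities of all tables, at fixed margins, no more probable than the
  observed one — verified against exhaustive hypergeometric enumeration for
  every table with N ≤ 30). Metabolites without a compound class are
  excluded from the enrichment denominators. The covariate correlation
  (e.g. consumed-interaction count vs genome size) is a plain Pearson r and
  requires ≥ 3 species and non-degenerate variance.

## Elemental flow networks

Edge quantity is the **consumer-side** consumed amount: the concentration
of the metabolite at the start of the consumer's spent-medium culture minus
the minimum it reaches (mM). That is what an arrow from producer to
consumer physically represents; producer-side secretion is kept as
metadata only. Flow = mM consumed × atoms of the element per molecule,
in element-mmol per liter of culture; edges at or below 0.1 element-mmol/L
are dropped from the displayed network, and unquantified edges are counted
and excluded, never imputed. Conservation (Σ out-totals = Σ in-totals =
Σ edge flows) holds exactly by construction and is asserted to machine
precision in the tests.

## Metabolic modules

A module is an ordered list of steps, each an any-of set of ortholog ids;
coverage = satisfied steps / total steps, and presence requires coverage
**strictly** greater than the threshold (default 0.5, i.e. ">50%"). Nested
boolean module grammars are out of scope — definitions must be
pre-flattened into alternative sets.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package assumes.

* Growth: 4PL per species; default sampling 10 evenly log-spaced times over
  0.5–24 h (dense early where dynamics are fast), 3 replicates.
* Consumed metabolite: x(t) = x₀ (1 − y·(OD(t) − OD(0))/(K − OD(0))) with
  consumption fraction y of the initially available amount — coupling to
  normalized biomass gain makes exhaustion-before-stationary-phase cases
  generatable, exercising the caller's exponential branch.
* Secreted metabolite: x(t) = x₀ + s·(OD(t) − OD(0)) with yield s per unit
  OD gained.
* Noise: multiplicative lognormal with mean 1 and a chosen CV, drawn
  independently per measured value (ion counts are positive and
  heteroscedastic). No batch effects, drift or missingness are simulated.
* Spent medium: the producer's noiseless supernatant at the last sampling
  time, mixed exactly 1:1 with fresh medium, so the mixing-conservation
  invariant (initial spent level = (fresh + end-point)/2) holds to the bit.
* The randomized-consortium helper draws consumption fractions in
  0.6–0.95 (a ≥ 2.5-fold depletion at completed growth, comfortably past
  the 1.37 cutoff) and secretion yields of 1–3× the fresh-medium baseline
  over the OD gain (past the 1.20 cutoff), with ~30% of medium components
  left as inert background and some secreted metabolites absent from the
  fresh medium.

**What passing the synthetic tests shows — and does not.** Exact noiseless
recovery and ≥ 0.9 precision/recall at 5% noise demonstrate that the
statistical chain is implemented correctly and is robust to the modeled
noise. Real FIA data additionally carry matrix effects that vary between
media, annotation ambiguity (isobars), metabolites secreted then
re-consumed (non-monotone trajectories), and replicate-level batch
structure — none of which the generator produces, so real-data performance
is expected to be lower and threshold calibration on a real dilution series
matters.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run desk-scale problems:
consortia of 4–6 species × 20 metabolites, 20 seeds for the noisy-recovery
average, 500 random series for the caller/oracle comparison, all 2×2 tables
with N ≤ 30 for the Fisher check, 100 noiseless curves for logistic
recovery — sizes chosen so the whole suite completes in about a minute
while keeping the Monte Carlo averages stable. Tolerances: logistic
recovery 1e−3 relative (observed ~1e−8), calibration oracle exact to
1e−12, flow conservation asserted at 1e−12 absolute. Optimizer bounds keep
A, K positive and r ≤ 1000/h; exponents are clipped at ±700 to avoid
overflow; fits canonicalize K ≥ A.

## Known limitations

* The caller tests replicate means; replicate-level variance is not used in
  the test statistics (a deliberate mirror of the method it implements).
* Edges are unsigned evidence of transfer; no rates, no dynamic community
  model, no genome-scale reconstruction.
* The annotation module cannot separate isobars, and compound classes come
  from the user's database, so enrichment results inherit its curation.
* The bundled formula database is a small curated fixture for examples and
  tests; real analyses should supply their own database.
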