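# Methods

## Problem and model

`richgap` estimates the *lower bound* of species richness for a region from
specimen/observation occurrence records, and expresses the difference between
that estimate and the number of currently described species as a *taxonomic
gap* — how many species remain to be described, what percentage increase that
represents, and how many years of taxonomic work it corresponds to at the
recent description rate.

The statistical core is the Chao family of nonparametric estimators, which
use the abundance frequency counts f_k (the number of species observed
exactly k times in a sample of n individuals covering S_obs species):

- **Chao1**: S_obs + f1²/(2 f2), or the bias-corrected
  S_obs + f1(f1−1)/2 when f2 = 0. A lower bound for true richness whose
  correction is driven entirely by singletons and doubletons.
- **iChao1**: Chao1 + (f3/(4 f4))·max(f1 − f2 f3/(2 f4), 0), with f4
  replaced by f4+1 when f4 = 0. Uses tripletons and quadrupletons to sharpen
  the bound; by construction S_obs ≤ Chao1 ≤ iChao1.
- **Rarefaction/extrapolation of Hill number q = 0**: the exact
  hypergeometric expectation Ŝ(m) = S_obs − Σ_k f_k·C(n−k,m)/C(n,m) for
  m ≤ n and the Chao1-anchored exponential extrapolation for m > n, whose
  m → ∞ limit is Chao1. Binomial ratios are computed via log-gamma to stay
  stable at large n. The pipeline's "iNEXT-style" richness value is the
  asymptotic q = 0 estimate (equal to Chao1), reported alongside iChao1.

Two confidence intervals are offered: the standard log-transformed interval
for Chao-type estimators (analytic Chao1 variance; the interval never falls
below S_obs) and a coverage-based bootstrap, in which detected species are
assigned probabilities proportional to their frequencies rescaled to the
estimated sample coverage Ĉ = 1 − (f1/n)·(n−1)f1/((n−1)f1 + 2 f2) and
⌈Chao1 − S_obs⌉ undetected species share 1−Ĉ equally, followed by B
multinomial resamples of size n. The default interval in the iteration
engine is the log interval: the analytic delta-method variance of iChao1 is
intricate, and the log interval keeps a 100-iteration run effectively
instantaneous; the bootstrap (default B = 100–200) is available via
`ci="bootstrap"`.

## Occurrence cleaning

Six removal rules with union semantics (one flag removes the record; every
firing rule is tallied): invalid binomial, improper basis of record,
coordinate/country mismatch, absence record, non-open license, and species
off the country checklist. "Invalid binomial" is operationalised as the
minimal testable reading: two alphabetic tokens, capitalised genus,
lowercase epithet, infraspecific markers stripped. Basis-of-record reject
list and license accept list are configuration, defaulting to common
occurrence-cleaning practice (`FOSSIL_SPECIMEN`, `LIVING_SPECIMEN`,
`MATERIAL_CITATION`, `UNKNOWN` rejected; `CC0`, `CC-BY`, `CC-BY-NC`
accepted). Rules that cannot be evaluated because fields are missing do not
flag (conservative retention), except ABSENCE, which requires an explicit
"absent". Out-of-range coordinates raise a record-level validation error
and are counted separately in the report, never silently dropped. The
coordinate→country resolver is an injected callable, so tests use toy
longitude-band countries and no polygon library is required.

## Literature curve and augmentation

Checklist species with no occurrence records enter each assemblage with a
specimen count drawn from a power-law frequency curve fitted to literature
sample sizes (how many specimens recent revisions had available per
species). The curve is y(x) = a·x^(1−ln b), fitted by nonlinear least
squares on the untransformed frequencies (initialised from a log-log
regression; residual standard error uses denominator N−2). The `log` in
this parameterisation is the natural log: with base-10 the exponent would be
≈ −0.03 — a near-flat curve inconsistent with a singleton-dominated
frequency fit — while natural log gives ≈ −1.37, matching a distribution in
which species described from a single specimen are the mode. Draws are
taken from the curve normalised over {1..cap}, cap being the region's
maximum empirical per-species count (a configurable default of 100 with a
warning when a region has no empirical counts at all — the degenerate case
is not otherwise defined). Counts are redrawn fresh in every iteration of
the resampling engine.

## Iteration engine, exclusions, gap

Because augmentation is stochastic, augmentation + estimation is repeated R
times (default 100), iteration i using the i-th child seed of the master
seed, and the point estimate and CI bounds are summarised by component-wise
medians (the "median 95% CI" reading; the alternative — a CI of medians —
is inconsistent with extracting per-iteration bounds). Failed iterations
are recorded and excluded from the medians; more than 50% failures aborts.

Regions are excluded when they have fewer than 30 occurrence records
(SMALL_SAMPLE) or when the median estimate exceeds observed richness more
than 10-fold (DIVERGENT — the literal reading of "an order of magnitude").
Gap arithmetic: gap = CI − described (floored at 0 with a warning),
pct = round(100·gap/described), years = round(gap/rate), rounding half away
from zero; the default rate is 117 species/year. CI overlap uses closed
intervals (touching endpoints overlap).

## Synonym deduplication and accumulation

Orthographic variants are removed by grouping synonyms by accepted id and
bracket-stripped author-year, stripping digits from names, linking pairs
whose optimal-string-alignment (OSA, restricted Damerau–Levenshtein)
distance is ≤ 2 (threshold configurable; no canonical value exists, so it
is always explicit), taking connected components, and keeping the first
member of each component in input order. OSA is implemented directly as
the standard dynamic program. Accumulation curves are prefix sums of
description years (valid names and synonyms — synonyms counted at their
original description, not at synonymisation) and of first-occurrence years;
the description rate is the OLS slope of the cumulative curve from a start
year (default 1960).

## Synthetic data

Every fixture is generated with its ground truth attached:

- **Communities**: lognormal(meanlog 0, sdlog 1.5) relative abundances by
  default — heavy-tailed enough to make singleton/doubleton corrections
  matter at realistic sample sizes; a rank power-law option is provided.
  The real assemblages' abundance distribution is unknown; the lognormal is
  a stand-in for a plausibly heterogeneous community, not a claim about any
  taxon. Species are spread over toy countries that are 10° longitude
  bands grouped into two synthetic continents.
- **Occurrences**: each record is clean by construction, then each defect
  is planted independently with its configured rate (union semantics).
  Country mismatches are planted by displacing coordinates into another
  band (keeping the stated country), so planted labels equal evaluated
  flags exactly. The single incompatible pair — invalid binomial +
  off-checklist, since an unparseable name has no species key to test —
  resolves in favour of the invalid binomial.
- **Taxonomies**: Poisson-distributed synonyms per accepted name, with
  planted variants at ≤ 2 OSA edits from their parent. Because OSA
  violates the triangle inequality, mutated variants are verified (and
  redrawn if needed) to sit within the threshold and > 2 edits from every
  other cluster; base epithets within a species are kept > 6 edits apart,
  so dedup at threshold 2 must recover the planted clusters exactly.
- **Literature sizes**: drawn from P(x) ∝ x^(−exponent) on {1..cap}
  (default exponent 1.37, cap 100).

A master seed spawns independent child streams per generator through
`numpy.random.SeedSequence`, so fixtures are bit-reproducible and
uncorrelated across generators.

What the synthetic data does *not* emulate: spatial clustering and
georeferencing error, taxon-specific abundance structure, database-specific
metadata quirks, and the many additional quality flags real cleaning
pipelines apply beyond these six rules. Passing tests therefore demonstrate
algorithmic correctness against planted truth, not performance on any real
occurrence database.

## Verified behaviour and known limitations

- Under the default community model (S_true = 200, n = 2000), the median
  iChao1 over 100 independent samples sits within a few percent below the
  truth (lower-bound behaviour), and the 95% log-interval contains the
  truth in ≥ 80% of replicates — under-coverage relative to nominal is
  expected of lower-bound estimators under heterogeneous abundances.
- When every community species is on the checklist, augmentation makes the
  whole checklist observed, so the engine's median estimate is bounded
  below by the checklist size and its Chao-type surplus *above* the
  checklist plays the role of the estimated undescribed gap. On toy
  communities where truth equals the checklist this surplus (≈ +25% at the
  default settings) is overshoot by construction, not an estimator defect;
  tests assert the bound, not a symmetric error band.
- Problem sizes in the test-suite simulations (communities of 40–300
  species, samples of 300–2000 records, 10⁴ Monte-Carlo subsamples, 200
  coverage replicates) were chosen as the smallest at which the statistical
  checks are stable; all estimator code paths are exercised identically at
  any scale, and the frequency-count representation keeps memory flat in n.
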