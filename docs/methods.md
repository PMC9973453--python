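# Methods

## The measurement model

A recording of one reader reading one poem is represented as a
chronological sequence of syllable tokens with onset/offset times in
seconds.  Two articulation measures are derived per token:

- **SOI (syllable onset interval, ms)** — from a syllable's onset to the
  onset of the next syllable of the same verse line.  Any within-line
  speaking pause is thereby attributed to the SOI of the syllable that
  precedes it, which is what makes the SOI a rhythm measure rather than a
  pure articulation-duration measure.  The pause after the last syllable of
  a line is not part of any SOI: the line-final token's SOI is its own
  duration.  The line-final token is kept (not dropped) so that line-level
  aggregation can use all m syllables of a line.
- **Mean intensity (dB)** — consumed as a per-interval table (in practice
  produced by a Praat script over the annotated intervals); the package
  joins it by (participant, poem, syllable index) and treats a missing or
  duplicated key as an error rather than guessing.

Rows with SOI strictly greater than 2000 ms are flagged and excluded from
all models ("exceeded" is read literally, so exactly 2000 ms survives).
The flag is applied after SOI computation, so it can only hit within-line
pauses; line-final pauses never enter an SOI in the first place.

Line-level rhythmicity is the normalized pairwise variability index over a
line's SOIs or intensities,

    nPVI = 100/(m-1) * sum_k |d_k - d_{k+1}| / ((d_k + d_{k+1})/2),

with the pairwise *mean* in the denominator.  (A difference in the
denominator, which sometimes appears in print, would make every term +-2
regardless of the data; the mean form of the Grabe & Low lineage is the
only meaningful reading and the only one implemented.)  The index is 0 for
a constant sequence, bounded by 200, scale- and reversal-invariant, and
decreases when adjacent values are leveled — which is exactly the
mechanism by which leveled-out tack syllables lower a line's score.

## Models

All models are Gaussian linear mixed models with sum-coded (+-1) binary
factors, so the intercept is the grand mean and the predicted difference
between a factor's two levels is twice its coefficient.  Positive levels:
strong stress, musically active, iambic meter, tack-free line.  Continuous
covariates (tack index within line, tacks per line, line number, syllable
count) are centred, not standardised, so slopes keep per-unit
interpretations; centring happens once, before the outlier pass.  The
three-level instruction factor, where used, expands to two sum-contrast
columns; because instruction group and musical activity have empty design
cells by construction, their mutual interactions are excluded while both
interact with the other predictors.

Four canonical families:

1. regular syllables: SOI (or intensity) ~ stress x musical x meter,
   random participant (intercept + stress slope, correlated) and syllable
   type (intercept);
2. tack syllables: the same plus the centred tack index in the full
   factorial; no syllable term (every tack is the same syllable, so a
   syllable intercept is meaningless);
3. lines, binary: nPVI ~ tack-line x musical x meter, random participant
   (intercept + tack-line slope) and poem (intercept);
4. lines, graded: tack-line replaced by the centred tack count.

Each family is fitted twice: pass 1 on all rows, then rows whose
conditional residual lies outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the
pass-1 residual distribution are removed and pass 2 on the remainder is
reported.  Under a correct Gaussian model this trims roughly 1% of rows
symmetrically; it shrinks the residual variance a few percent and leaves
fixed effects unbiased.

### Estimation

The fitter is a dense profiled-REML implementation: each random term's
covariance is parameterised by its lower-triangular Cholesky factor
relative to the residual SD; fixed effects and the residual variance are
profiled out; the profiled criterion is minimised by bounded Powell search
(tolerance 1e-8).  The random-effects dimension of every model here is a
few hundred, so one criterion evaluation is one Cholesky factorisation of
a q x q matrix.  Satterthwaite denominator degrees of freedom come from
finite-difference derivatives of the coefficient covariance with respect
to the variance parameters, with the variance-parameter covariance taken
from the finite-difference Hessian of the unprofiled REML criterion (the
lmerTest construction); a residual-df fallback exists for speed and for
boundary cases, and df values outside (0, n-p] are clamped to n-p.
p-values are two-sided t; no multiplicity correction is applied.  Fits
with a variance component at zero or a correlation at +-1 warn
("singular") but return estimates — with 13 participants and small slope
variances this is a normal occurrence, not a failure.  The fitter agrees
with lme4/lmerTest to at least four significant figures on coefficients,
SEs, Satterthwaite df, variance components and the REML criterion
(cross-checked in the test suite via Rscript).

Reported alongside the coefficients: variance components (tau00 per
grouping factor, tau11 per slope, rho01), ICC = sum of intercept variances
over total variance, Nakagawa-style marginal/conditional R^2 (fixed-effect
variance, and fixed plus average realised random-effect variance, over
total), AIC on the REML criterion, and Cohen's d = 2t/sqrt(df)
(conventionally reported when |d| > 0.1).

## The synthetic reading

No public corpus of tack-manipulated poetry recordings exists, so the
package carries a generative mirror of the models above, with defaults
that reproduce published mixed-model estimates from a study of 13 German
readers and six poems (three iambic, three trochaic).  What the generator
emulates, and what it does not:

- **Stimuli.**  Six poems with syllable totals 273, 270, 76, 68, 154, 150
  (991 slots); lines allocated proportionally (33/33/9/8/19/18 = 120
  lines) with 8-9 syllables each, since only the totals and the line count
  are recorded.  Stress alternates strictly with the meter; real poems'
  occasional annotated exceptions are not modelled.
- **Tacks.**  Per-slot Bernoulli substitution on lines three and later,
  capped at 5 per line.  The substitution rate is not recorded anywhere;
  0.17 is fixed once because it reproduces the recorded row counts
  (~158 tack tokens per reader out of 991 slots) and the observed 0-5
  per-line range.
- **Syllable types.**  Regular slots draw their lexical identity from a
  pool of 431 recurring types (the recorded number of syllable-type
  levels), assigned uniformly at random under the run seed so that a
  recurring type occurs in strong as well as weak positions, as recurring
  lexical syllables do in natural verse.  This crossing matters: if types
  were locked to one stress level, the between-type variance (which is
  large, ~77 ms SD) would enter the stress contrast and its standard
  error, which is incompatible with the published SEs.  All tacks share
  the single type "tack" and receive no type effect, mirroring the tack
  model.
- **Responses.**  SOI and intensity are drawn from the sum-coded linear
  predictor plus participant (intercept, stress-slope) pairs with the
  published correlation, syllable-type intercepts (regular rows only), and
  Gaussian residuals.  Regular and tack rows use their respective
  parameter sets, as the study fitted them separately.  Line-level nPVI
  tables can also be drawn directly from the line-model structure
  (participant intercept + tack slope, poem intercept) for
  parameter-recovery work.
- **Timeline.**  Generated SOIs are laid out as abutting intervals
  (duration = SOI) with lognormal line-final pauses (mean 300 ms, SD
  150 ms — unrecorded; chosen only to exercise the line-final exclusion)
  and, optionally, rare long within-line pauses (probability 0.005,
  >=2500 ms) to exercise the 2000 ms filter.  SOIs are floored at 10 ms to
  keep the timeline monotone; at the default parameters this touches well
  under 1% of draws and shifts means by ~0.1 ms.  The timeline can be
  emitted as TextGrids and re-ingested; both paths agree exactly once
  times are rounded to the 1 microsecond serialisation precision.

What passing recovery tests therefore shows: the pipeline — grid
construction, annotation ingestion, SOI computation, exclusion rules,
aggregation, coding, two-pass REML fitting — recovers the parameters of
data that truly follow the hierarchical Gaussian model.  It does not show
that real oral reading follows that model: the generator has no
autocorrelation within lines beyond the random effects, no
heteroscedasticity, no reader drift over a session, and treats the
published estimates as generative truth (the standard, but unverifiable,
identification).

## Numerical and design choices

- Intervals are closed-open [xmin, xmax) seconds; times serialise at
  microsecond precision.
- The tack index is the 1-based ordinal of a tack among the tacks of its
  line (consistent with the 0-5 per-line range); it enters models centred.
- Strict ingestion (token count must match the grid) is the default;
  lenient alignment for recordings with omitted syllables is opt-in,
  because silently guessing which tack was skipped is unsafe.
- Effect sizes use d = 2t/sqrt(df) exactly; published tables computed this
  way reproduce some printed values to the digit and differ slightly for
  others, and no attempt is made to chase individual printed cells.
- Recovery summaries in `scripts/acceptance.py` average the recovered
  coefficient over seeded study-scale replicates (10 for the syllable
  model, 60 for the cheap line model); averaging reduces Monte-Carlo noise
  in the reported recovery without changing the study conditions of any
  single replicate.
- The replicate suites in the tests use a reduced corpus (two poems,
  ~150 syllables, 60 types) so that 200 two-pass crossed-REML fits run in
  a few minutes; the methods are size-independent.

## Known limitations

- Single-threaded dense linear algebra; models with many thousands of
  random-effect levels would need sparse factorisations.
- Satterthwaite df relies on finite differences; at variance boundaries it
  falls back to residual df rather than attempting a constrained Hessian.
- The generator's lognormal pause model and tack-rate choice are
  conventions, not estimates; only the quantities the models condition on
  (counts, ranges, variance components) are anchored to recorded values.
- No audio processing of any kind: forced alignment, intensity extraction
  and pitch are out of scope; the package starts at annotation tiers and
  an intensity table.
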