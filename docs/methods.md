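# Methods

## Response bias

Each probabilistic-reward-task block yields a 2×2 table of retained trials —
rich/lean role × correct/incorrect — and the response bias

RB = ½·ln[(Rich<sub>correct</sub>·Lean<sub>incorrect</sub>)/(Rich<sub>incorrect</sub>·Lean<sub>correct</sub>)],

in natural-log units. When any cell is zero, 0.5 is added to all four cells
before taking the ratio (the standard log-linear continuity correction) and
the result is flagged `corrected`. The statistic is antisymmetric under
exchanging the rich and lean labels and is exactly zero whenever the rich
and lean correct:incorrect ratios coincide.

Trial retention: RTs must lie in [200, 2000] ms (bounds inclusive — the
removals are responses *under* 200 or *over* 2000 ms) and a response must
have been made. Missing responses count toward the 10% violation budget
alongside out-of-range RTs, since both are unusable trials of the same
kind. A participant is excluded when the violating fraction exceeds 0.10
(strictly), when all of a session's responses used one key, or when a
session is missing. `filter_trials` reports per-participant exclusion
records and returns the retained trials of everyone; the pipeline drops
flagged participants using those records, which keeps the filter
idempotent at the trial level.

## Informed-prior Bayes factors

All confirmatory tests reduce to a one-df summary (M, SE, df). The
likelihood of the observed M given a true effect δ is a t density with the
data's df, location δ and scale SE; H1 places a shifted, scaled t prior on
δ and H0 is the point null:

BF₁₀ = ∫ f(M | δ) π(δ) dδ / f(M | 0).

A "two-tailed" prior is the untruncated shifted t itself; a directional
prior is the same t truncated at zero on the predicted side and
renormalized by the exact tail mass.

**Prior scale conventions.** Each registered source study carries both its
SE and its SD (SD ≈ SE·√n when not recorded separately). Two conventions
coexist in the replication literature this package serves, and both are
supported explicitly rather than silently merged:

* `SourceStudy.prior()` — scale = the source study's **SD**. This is the
  convention under which the package reproduces the published Bayes factors
  of the replication report it models (e.g. BF = 0.696 for the primary
  block-1 effect), including all mood-index values.
* `SourceStudy.design_prior()` — scale = the source study's **SE**. This is
  the convention of the sequential design analysis (expected BF under the
  null ≈ 0.14 at n = 30 after scaling SE 0.063 by √(18/30) = 0.049).

The registered sources are: primary effect (M = .14, SE = .063, SD = .26,
n = 18); 2×3 interaction (M = .16, SE = .08, n = 18); covariate-adjusted
2×2×3 interaction (M = .14, SE = .07, SD = .33, n = 21); block-3
manipulation checks (M = .19, SE = .061, SD = .26, n = 18 and M = .26,
SE = .070, SD = .32, n = 21); mood-treatment effects for positive and
negative affect (M = 4.91 and 5.92 PANAS points, SE = .82 and .94, n = 96,
with the negative-affect magnitude mapped onto the positive index
direction).

**Quadrature.** Adaptive quadrature (relative tolerance 1e-10) over the
prior location ± 12·max(prior scale, data SE), widened to cover the
likelihood's own mass, with breakpoints at the data mean and prior location
because the integrand can be sharply bimodal when prior and likelihood are
far apart (heavy t tails make the product non-negligible in between). A
`BayesNumericalError` is raised if the reported error bound exceeds 1e-6 of
the H1 marginal. The test suite checks the engine against an independent
dense-trapezoid evaluation of the same integral.

**Default one-sample BF.** The JZS variant integrates the noncentral-t
likelihood of the observed t statistic against a zero-centred
Cauchy(scale = √2/2 by default) prior on the standardized effect size, and
reports both BF₁₀ and BF₀₁; the caller chooses which orientation to print.

**Design analysis and stopping.** `scale_se` maps a source SE to a planned
sample size via SE·√(n_source/n_planned); `expected_bf_under_null` runs the
informed BF at M = 0 with that scaled SE. The sequential rule stops for H1
when every monitored BF exceeds 6, for H0 when every one falls below 1/6,
and at the participant cap (30) otherwise; thresholds and cap are
configuration.

## Contrasts

The unit of analysis is the per-participant contrast score, so every
reduction yields mean = Σdᵢ/n, SE = sd(d)/√n and df = n−1, matching the
paired-t form the Bayes tests expect:

* paired difference: a − b per participant;
* double-baselined mood index: (post−pre)<sub>active</sub> −
  (post−pre)<sub>sham</sub>. The published analysis this models applies the
  index in this raw orientation for both affect scales (its prose describes
  a sign flip for negative affect, but its printed values — index +.167 from
  per-condition changes +.033 and −.133 — are the unflipped difference, so
  the default here is unflipped and a `sign_flip` flag is provided);
* 2×3 interaction: (A1−S1) − ½(A2−S2) − ½(A3−S3);
* 2×2×3 interaction: that contrast at post minus the same at pre,
  computed on covariate-adjusted cell values.

Covariate adjustment regresses each cell on the grand-mean-centred
covariate and removes the fitted component per participant. In a
fully-within design every participant occupies every cell, so cell means
are unchanged; what the adjustment changes is the participant-level spread
and hence the SEs of downstream contrasts. Constant covariates are
rejected. Contrast scores with zero variance raise
`DegenerateContrastError` rather than passing an SE of 0 to a Bayes test.

## Frequentist statistics

Paired/one-sample t-tests come straight from the summary (t = M/SE,
two-sided p, d = t/√n). ANOVA effect sizes use partial eta squared
η² = F·df₁/(F·df₁+df₂) and its d equivalent 2√(η²/(1−η²)) — the reporting
conventions of this task's literature.

The repeated-measures ANOVA is a fully-within sums-of-squares partition
(balanced designs, one observation per subject and cell, no imputation);
each effect is tested against its interaction with subjects. Effects with
more than one df carry Mauchly's test on the orthonormalized contrast
covariance; when its p < .05 the Greenhouse–Geisser corrected p is reported
(no Huynh–Feldt option). Bonferroni post-hocs cover the pairwise block
comparisons (family of 3). The partition is verified in tests against
explicit marginal-mean formulas, against pingouin and against statsmodels'
repeated-measures ANOVA.

The RM-ANCOVA (within factors plus one between-subject covariate, the
consummatory-pleasure score) regresses each effect's per-subject
orthonormal contrast scores on the grand-mean-centred covariate: the effect
tests the pooled intercept, the effect × covariate term the pooled slope,
both against the pooled residual on df·(n−2) error df; the between-subject
part tests the covariate against the subject-mean residual. With a
covariate orthogonal to the cells this reproduces the plain ANOVA's sums of
squares, with F scaled only by the error-df change (n−2 vs n−1).

## The generative study model

The simulator emulates the registered design: 30 participants, two
sessions (active/sham, order counterbalanced 15/15 — the balanced split the
study reports, in place of its coin-toss initialization), pre and post task
administrations per session, three 100-trial blocks each, 50 long/50 short
stimuli per block, 40 planned rewards (30 rich, 10 lean), rich mapping
drawn at random per session and reversed post-stimulation.

Responders are criterion-learning signal-detection agents:
P(respond long) = lapse/2 + (1−lapse)·σ(d′·x + c) with x = ±1 the stimulus,
c the criterion in log-odds units. After every delivered reward c moves by
`learn_rate` toward the rich response, saturating at ±3 (the logistic form
gives closed-form choice probabilities for tests; the bound prevents
divergence in long simulations). A planned reward landing on an incorrect
trial is re-queued to the next correct same-role trial and dropped at block
end, approximately preserving the 30/10 asymmetry for accurate responders.
RTs are lognormal, truncated to [1, 5000] ms. `stim_effect` adds a known
criterion shift, oriented toward the rich response, in post-active
administrations only.

Population defaults emulate a healthy sample: d′ ≈ 1.2 (≈77% accuracy,
between-SD 0.25), learn_rate 0.002 log-odds per reward (between-SD 0.001),
which accumulates to a block-3 RB around 0.2 — the regime healthy samples
show — lapse 0.05, per-administration criterion jitter SD 0.15, median RT
≈ 450 ms (lognormal μ = 6.1, σ = 0.35). Questionnaire items are generated
from latent normal mood, rounded and clipped to the 1–5 Likert range:
positive affect around a sum score of 28 (between-SD 6), latent negative
affect *below* the scale floor (baseline 5, between-SD 4) so realized NA
sums cluster at the minimum of 10 — reproducing the strongly floor-limited
NA distributions healthy samples show and exercising the floor-effect
screen (>15% of measures at the minimum). Declared mood effects shift the
post-stimulation latent per condition. The "pseudo-random" stimulus
sequences are unconstrained shuffles; run-length constraints of the
original software are unknown and not modelled.

Randomness: one root seed; per-participant streams are spawned from it and
recorded in the ground-truth sidecar, so any participant is reproducible
independently. All per-trial randomness is pre-drawn per participant,
which makes the vectorized multi-agent stepper exactly equivalent to
simulating participants one at a time.

What the generator does **not** emulate: stimulation neurophysiology,
discomfort-driven dropout, RT–accuracy coupling (RTs are independent of
choices, so RT filtering only thins trials at random), item-level
questionnaire structure beyond a common latent, and day-to-day baseline
drift. Passing tests therefore certify the statistical machinery and the
recoverability of injected effects under these idealized conditions, not
the behaviour of the pipeline under real-data pathologies.

## Problem sizes used in tests

Distributional properties use 200 agents (unbiased-agent bias bound,
learning monotonicity, learn-rate recovery regression), 500 agents for the
null active/sham distribution match, 60–100 replicate n = 30 studies for
the detection-power property, 1000 Gaussian null cell tables for the ANOVA
type-I calibration, 2000 replicates for the Bayes-factor false-evidence
calibration, and a 50-case random grid for the quadrature oracle. These
sizes put Monte-Carlo error comfortably inside each asserted margin while
keeping the suite quick to run.

## Known limitations

* The two prior-scale conventions (SD for reporting, SE for design
  analysis) are both exposed; choosing between them is the caller's
  scientific decision, made explicit in `SourceStudy`.
* The RM-ANCOVA follows the pooled contrast-score construction above;
  other software may adjust differently (e.g. cell-mean ANCOVA), and the
  covariate-adjusted interaction contrast is defined by the per-participant
  residualization described here.
* Only fully-within, balanced, complete designs are supported; missing
  cells abort rather than impute.
* No posterior estimation — the engine computes Bayes factors only.
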