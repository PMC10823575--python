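# rewardbias

Analysis toolkit for **reward responsiveness** measured with the
probabilistic reward task (PRT) in within-subject brain-stimulation
studies, built around **informed-prior Bayes factors** for one-degree-of-
freedom effects.

## The problem

The PRT presents, in three 100-trial blocks, two hard-to-discriminate
stimuli (a "long" or "short" cartoon mouth). Correct identifications of one
stimulus — the *rich* role — are rewarded three times as often (30 vs 10 of
the 40 rewards per block). Healthy responders drift toward the rich
response; that drift is the signal-detection **response bias**

```
RB = ½ · ln( (Rich_correct · Lean_incorrect) / (Rich_incorrect · Lean_correct) )
```

a log-odds preference for the rich response irrespective of accuracy.
Blunted RB is a behavioural marker of anhedonia, and changes in RB are used
to evaluate whether excitatory stimulation of prefrontal cortex enhances
reward responsiveness.

Every hypothesis in this design reduces to a one-df effect summary
*(M, SE, df)* — a paired difference of cells, a double-baselined mood index
*(post−pre)_active − (post−pre)_sham*, or a linear interaction contrast such
as *B1 − ½B2 − ½B3* applied to active−sham differences. Evidence is
quantified as a Bayes factor with H1 informed by a prior study's effect:

```
BF10 = ∫ f(M | δ) π(δ) dδ  /  f(M | 0)
```

where *f(·|δ)* is a t density (the data's df, scale SE) and *π* is a
shifted, scaled (optionally zero-truncated) t distribution taken from the
source study. A default JZS one-sample Bayes factor (zero-centred
Cauchy(0.707) prior on the standardized effect) covers exploratory tests,
and SE scaling `SE·√(n_source/n_planned)` gives the design-analysis BF
expected under a true null at a planned sample size, feeding a sequential
stopping rule (stop when all monitored BFs > 6 or < 1/6, or at the sample
cap).

The package implements the full registered pipeline — trial filtering and
exclusions, RB tabulation, contrasts, informed and default Bayes factors,
the frequentist companions (paired/one-sample t, repeated-measures
ANOVA/ANCOVA with Mauchly/Greenhouse–Geisser handling, Bonferroni
post-hocs), questionnaire scoring (PANAS, TEPS) with a floor-effect screen —
plus a generative study simulator with known ground truth.

## Worked example

```python
from rewardbias import EffectSummary, informed_bf, default_onesample_bf
from rewardbias.study import SOURCE_STUDIES

# Block-1 active-minus-sham RB difference observed in a 30-participant study
effect = EffectSummary(mean=-0.253, se=0.187, df=29)

# H1 informed by the source study's effect (M=.14, SD=.26, df=17)
prior = SOURCE_STUDIES["primary_ahn"].prior()
res = informed_bf(effect, prior)
print(f"BF10 = {res.bf10:.3f}, BF01 = {res.bf01:.3f}")

# Exploratory: is post-active block-1 RB below zero? (default Cauchy prior)
jzs = default_onesample_bf(-0.232 / 0.124, n=30, scale=0.707)
print(f"JZS BF01 = {jzs.bf01:.2f}")
```

prints

```
BF10 = 0.692, BF01 = 1.446
JZS BF01 = 1.11
```

The first line says the observed difference is about 1.4 times more likely
under the point null than under the informed H1 — inconclusive, leaning
null. The second says the exploratory drop below zero is likewise
inconclusive (BF01 ≈ 1.1).

A complete synthetic study runs through the same pipeline end to end:

```python
from rewardbias import RewardResponsivenessStudy, generate_fixture

data = generate_fixture("null", seed=3)          # 30 participants, no true effects
results = RewardResponsivenessStudy.from_frames(
    data.trials, data.questionnaires
).fit()
print(results.summary())                         # all effects, BFs, t-tests, ANOVA
results.plot_response_bias()                     # RB by cell
```

or from the shell:

```
rewardbias simulate --kind effectful --seed 7 --out study/
rewardbias analyze --trials study/trials.csv --questionnaires study/questionnaires.csv --out report/
rewardbias bf --mean -0.253 --se 0.187 --df 29 \
    --prior-location 0.14 --prior-scale 0.26 --prior-df 17
```

## Layout

- `rewardbias.task` — trial-log schema, RT/exclusion filtering, block
  tabulation, the RB statistic
- `rewardbias.questionnaires` — PANAS/TEPS scoring, floor-effect screen
- `rewardbias.contrasts` — one-df reductions (paired differences, mood
  indices, interaction contrasts, ANCOVA-adjusted cells)
- `rewardbias.bayes` — informed and JZS Bayes factors, SE scaling,
  stopping rule
- `rewardbias.frequentist` — t-tests, effect sizes, RM-ANOVA/ANCOVA
- `rewardbias.simulate` — criterion-learning agents, schedules, full
  synthetic studies with ground truth
- `rewardbias.study` — `RewardResponsivenessStudy` / `StudyResults`
- `rewardbias.cli` — `rewardbias analyze | bf | simulate`

See `docs/methods.md` for the modelling details and design choices.
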