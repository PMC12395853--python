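# Methods

## The task being modelled

The package analyses a head-fixed go/no-go **temporal pattern sensory
discrimination** (TPSD) task.  Two audio-visual temporal patterns differ only
in pulse duration: the rewarded ("preferred") pattern is four 200 ms pulses,
the unrewarded ("nonpreferred") pattern four 900 ms pulses, both with 200 ms
gaps (total durations 1.4 s and 4.2 s).  Licking inside the trial-relative
response window [1, 2) s counts as a response; a water reward is available on
preferred trials from 1.2 s to 2 s; errors trigger a 6.5–8 s timeout; trials
are separated by a 4 s inter-trial interval and lick-port beam breaks are
sampled at 250 Hz.  Main sessions run 250 trials on day 1 and 350 afterwards
at a 70:30 preferred:nonpreferred ratio (60:40 on a probe session);
pretrial sessions present only the rewarded pattern (150 trials on day 1,
250 after).  All times in the package are seconds from stimulus onset with
half-open intervals [a, b).

## Trial scoring and d′

A trial is a Hit / Miss (preferred, lick / no lick in the window) or FA / CR
(nonpreferred).  The default response criterion is one lick; an
individualized criterion derived from pretrial licking (mean response-window
lick count in the last pretrial session minus one sample SD, floored at 0)
is available but deliberately not used for offline scoring — in the task it
serves as an online learning aid.

Sensitivity is the signal-detection index

    d′ = Φ⁻¹(hit fraction) − Φ⁻¹(false-alarm fraction)

where a fraction that is **exactly** 0 or 1 is replaced by 1% or 99% before
the probit transform (avoiding infinite z-scores); intermediate fractions are
never altered.  As a consequence the clamp bound 2·Φ⁻¹(0.99) ≈ 4.653 applies
only to rates clamped at the extremes; a rate such as 149/150 legitimately
produces a slightly larger |z|.

Session-level performance is the maximum clamped d′ over a sliding
150-trial window (stride 1, earliest window on ties, windows must contain
both stimulus types; sessions shorter than 150 trials are evaluated whole).
The same best window defines the trial subset used by the profile and
decoding analyses.

**Selection bias of the best window.**  The maximum over ~200 overlapping
windows of a noisy statistic is biased upward; at naive performance
(true d′ ≈ 0.5, per-window SD ≈ 0.3–0.4) the bias is roughly +0.4–0.5.
First crossings of the intermediate learning threshold (d′ > 1) computed
from the best-window curve are therefore noise-dominated — in simulation
*both* genotypes "cross" within one or two sessions.  The package
consequently computes sessions-to-threshold from the **full-session** d′
(both columns are always exported; learning-curve reporting keeps the
best-window statistic).

## Synthetic behavior generator

Because no raw animal data accompany the analyses, a two-level generative
model stands in for a cohort:

1. **Response level.** On each trial a Bernoulli draw with probability
   p_hit (preferred) or p_fa (nonpreferred) decides whether the mouse
   responds.  Across sessions s (1-based),

       p_hit(s) = p_hit_final + (p_hit_initial − p_hit_final)·exp(−(s−1)/τ)
       p_fa(s)  = p_fa_final + (p_fa_initial − p_fa_final)·σ((m − s)/w)

   with σ the logistic function, m the false-alarm midpoint (sessions) and
   w its scale.  Learning in this task is carried almost entirely by
   false-alarm suppression: hits are near ceiling from the start because
   pretrial training teaches licking to the stimulus.

2. **Lick-train level.** Conditional on responding, a renewal train with
   gamma inter-lick intervals (shape 4, mean 1/7 s ⇒ ~7 Hz) starts at a
   uniform anticipatory latency in [0.3, 0.9] s and continues to reward
   offset (2.0 s) on rewarded trials or to a uniform false-alarm stop time
   (WT-like [1.2, 1.6] s; KO-like [1.6, 2.4] s — prolonged licking on FA
   trials).  Sparse baseline licks (0.2 Hz) are superimposed over the
   [0, 3) s trial epoch.  All times are quantized to the 4 ms (250 Hz) grid
   and a 50 ms refractory floor is enforced (physiological licking tops out
   near 10 Hz).

The Bernoulli draw *is* the response model: responding trials are guaranteed
at least one response-window lick, and baseline licks falling inside the
window on withholding trials are censored (after quantization, so rounding
cannot re-introduce one).  This makes the scored hit/FA fractions exact
binomial estimates of (p_hit, p_fa) — parameter recovery is testable against
Clopper–Pearson intervals, and the expected naive full-session d′ is the
closed form Φ⁻¹(p_hit) − Φ⁻¹(p_fa).

### Default presets

| preset | p_hit | τ | p_fa | midpoint | scale |
|---|---|---|---|---|---|
| WT_like | 0.97 → 0.995 | 2 | 0.915 → 0.236 | 4.5 | 0.8 |
| KO_expert_like | 0.96 → 0.975 | 4 | 0.915 → 0.30 | 12 | 2 |
| KO_nonexpert_like | 0.96 → 0.975 | 4 | 0.915 → 0.55 | 13 | 3 |
| naive | 0.97 (flat) | — | 0.915 (flat) | — | — |

Endpoint rates anchor to the cohort statistics the task reports on the best
session (WT hit ≈ 99.5%, FA ≈ 23.6%; KO hit ≈ 97%, FA ≈ 30% for eventual
learners and ≈ 55% for non-learners).  The KO curve midpoints were
calibrated — with a binomial-level simulation of d′ crossing times, before
any pipeline test — so that the true intermediate-threshold crossing lands
near session 10 for KO versus ~3 for WT, matching the reported
sessions-to-threshold gap (≈ 3.4 vs ≈ 10.4) and giving both genotypes a
naive session-1 d′ near 0.5.  The expert (d′ > 2) crossing then falls in the
mid-teens for KO learners and is unreachable for non-learners
(asymptotic d′ ≈ 1.8).

Unimodal probe sessions scale the logit-scale discrimination
(logit p_hit − logit p_fa) about its midpoint by a per-modality multiplier
(WT {multi 1.0, audio 0.45, visual 0.35}; KO {1.0, 0.30, 0.80}) — invented
values ordered so that WT benefit from multimodality while KO-like mice
perform as well with visual-only stimuli, and a no-stimulus control collapses
discrimination to zero.

All point-process parameters (rates, latencies, stop times) are invented:
the source analyses report no lick-rate or latency statistics.  Per-mouse
randomness is split from the master seed with
`SeedSequence(master, spawn_key=(mouse_index,))`, stable across versions.

### What the generator does not emulate

No running/pupil covariates, no within-session motivation drift (trials are
i.i.d. given the session), no stimulus-locked lick modulation during the
pattern, no biomechanics.  Most importantly, the lick "events" are discrete
(≤ ~10 Hz), whereas a lick-port IR beam sampled at 250 Hz yields dense
beam-break sample counts.  Passing tests therefore demonstrate correctness
of the analysis pipeline under a faithful response-probability model, not
that real lick data carry the same per-bin information (see Decoding).

## Lick-probability profiles

For one mouse, the profile is the fraction of trials with ≥ 1 lick per
0.1 s bin over the [0, 3) s epoch (the epoch end is a rendering choice).
With ~7 Hz licking a 0.1 s bin rarely holds two licks, so P(≥ 1 lick) is
nearly the mean count while staying in [0, 1].  Group profiles average
mouse-level vectors and carry a normal-approximation band
(mean ± z·SEM, truncated to [0, 1]); a bootstrap band is available as an
option.  Outcome-conditioned profiles restrict each session to its best
150-trial window first; empty strata are excluded with a warning.  The
unconditioned profile is exactly the trial-count-weighted mixture of the
outcome-conditioned ones.

## Time-resolved decoding

Per 0.067 s bin, the lick count is the single predictor of a binary class
(preferred vs nonpreferred; or FA vs CR among nonpreferred trials for the
outcome variant).  An RBF-kernel SVC (scikit-learn defaults, no tuning) is
refit on stratified 80/20 train/test splits — 10,000 replicates per bin per
mouse at full scale — and the per-mouse accuracy distributions are pooled
across mice into a grand distribution per bin.  Chance is defined
empirically by an otherwise-identical run with labels permuted uniformly
before every replicate; class imbalance is deliberately not rebalanced, so
the null concentrates near the majority fraction.  Splits are stratified
because unstratified 20% test draws from a 30% minority frequently contain a
single class.

**Exact fast fitting.** The per-bin feature takes a handful of small integer
values, so each fit runs on deduplicated (value, label) points with sample
weights equal to their multiplicities and γ fixed to scikit-learn's
`'scale'` value computed on the replicated training set.  The dual problem
is identical (box constraints aggregate across duplicates), so this is the
same estimator — verified prediction-for-prediction against plain `SVC` in
the tests — at roughly a tenth of the cost.

**Limitation under imbalance.** With discrete ~7 Hz lick events,
P(≥ 1 lick in a 0.067 s bin | responding) ≲ 0.5, so for 70:30 sessions no
per-bin rule on stimulus type can beat the 70% majority class and decoding
sits at the empirical chance level even for expert simulated mice.
Above-chance stimulus decoding emerges on balanced sessions (and FA-vs-CR
decoding works at natural imbalance, because the minority class is the
licking one).  Dense beam-break sample counts would not have this ceiling.

## Group comparisons

Each group is screened with a Lilliefors test at 0.05 (statsmodels'
table-based implementation; groups of n = 3, below the table's range, and
zero-variance groups route conservatively to the non-parametric branch).
Both groups normal ⇒ Student t-test (paired or unpaired); otherwise
Wilcoxon signed-rank (paired) or rank-sum/Mann–Whitney (unpaired), with the
implementations' standard tie corrections.  With k planned comparisons the
working alpha is α/k (Bonferroni) and stars follow * p < α, ** p < α/10,
*** p < α/100, all strict.  Mixed-effects/multilevel modelling is out of
scope: the pipeline exports a tidy (mouse, genotype, session, d′) table for
fitting elsewhere.

## Numerical and engineering choices

- Inverse normal CDF: `scipy.stats.norm.ppf` (well below the 1e−9 accuracy
  requirement on [0.01, 0.99]).
- Trial-count rounding: `round(preferred_fraction · n_trials)` preferred
  trials — exact for every ratio the task uses.
- Tie-breaks: earliest window; bins half-open; the response window excludes
  its right edge (a lick at exactly 2.0 s is not a response).
- Serialization: events TSV (one lick per row) plus a companion trials TSV
  so zero-lick trials stay representable; writing is deterministic and
  round-trips byte-identically.
- Desk-scale defaults: the demo pipeline runs 16 mice × 6 sessions, decodes
  the learned session over a 0.5–2.0 s epoch at 200 replicates per bin
  (~4 minutes on one CPU); full-scale decoding (10,000 replicates, full
  epoch, all sessions) is the library default and scales linearly.

## Known limitations

- Cohort statistics printed by the source study come from real animals; the
  simulator's presets are anchored to them but only reproduce their
  qualitative structure (ordering, separation), not the exact values.
- The best-window d′ retains its selection bias by design (it is the task's
  reporting convention); threshold-crossing analyses use full-session d′
  for the reason above.
- Per-bin stimulus decoding under natural 70:30 imbalance is chance-bound
  for discrete lick events (see Decoding) — a property of the feature
  model, not a bug in the decoder.
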