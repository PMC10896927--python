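# Methods

This note documents the models, generators and inferential choices behind
`chronoval`, in the package's own terms: what each component assumes, which
parameters matter, and what passing tests do and do not establish.

## 1. The interactive-activation account of the match effect

### Architecture

Four nodes represent past time, future time, negative valence and positive
valence. Antagonist pairs (past-future, negative-positive) are coupled by
mutual inhibition of magnitude `beta`; agonist pairs (past-negative,
future-positive) by mutual excitation of magnitude `gamma`. A stimulus
injects constant input `I` into its category's node. Only supra-rest
activation propagates: `O_j = max(a_j - rest, 0)`, the standard
interactive-activation output convention, which also prevents runaway
inhibition loops.

Model 1 keeps both agonist pairs (a symmetric time-valence association);
Model 2 sets the past-negative excitation to zero, leaving future-positive
as the only agonist pair (an association carried entirely by an optimistic
future-positive link). Model 2 nests exactly inside Model 1: restoring the
removed weights reproduces Model 1's trajectories bit for bit, which the
test suite checks.

### Dynamics and numerics

Activations follow a saturating Euler scheme with clipping to
`[min_activation, max_activation]`; the update gain is proportional to the
remaining headroom toward the ceiling (for net excitation) or the floor (for
net inhibition), plus exponential decay toward rest. Response accumulators
integrate the wired node outputs without leak (a leak-free accumulator is
assumed because nothing in the paradigm constrains a response-level decay),
and the predicted decision time is the first threshold crossing of the
winning accumulator, linearly interpolated between the bracketing steps.

Defaults: `gamma = beta = 0.10`, `I = 0.40`, `rest = 0`, bounds `[-0.2, 1]`,
`decay = 0.10`, `gain = 1`, `threshold = 0.5`. The Euler step is `h = 0.05`
with `max_steps = 4000` (a model-time horizon of 200). The step was chosen
so that successive step halvings change crossing times by well under 1%,
the package's stated integration-accuracy contract; at `h = 0.1` the first
halving changes them by just over 1%. Crossing times are reported in model
time units; `time_to_milliseconds` provides an affine display mapping only —
the model's claims are ordinal (which conditions are faster) and relational
(which effects are larger), never absolute RTs.

With these defaults Model 1 predicts equal positive match effects for both
response categories (0.054 time units mismatch - match), and Model 2
predicts a zero effect for past/negative responses and an unchanged positive
effect for future/positive responses. These are structural consequences of
the wiring, robust across broad parameter ranges; the tests assert the sign
pattern and the model-2 asymmetry rather than specific magnitudes.

Simulation computes node trajectories for the full horizon and the response
stage truncates at threshold; because the network is feedforward into the
response stage, this is exactly equivalent to stopping the integration at
the crossing.

## 2. Synthetic reaction-time experiments

### Generative model

A trial's expected RT is an additive sum on the millisecond scale:

    E[rt] = base + match_effect·[mismatch] + congruency_effect·[incongruent]
            + domain_effect·[time word] + practice_slope·block_position
            + subject_offset + item_offset

The trial residual is a shifted lognormal: `rt = 200 + LogNormal` with the
lognormal mean pinned to `E[rt] - 200` and log-scale SD `residual_sigma`.
This keeps RTs strictly positive and right-skewed while making every effect
parameter exactly the expected cell-mean contrast; `residual_sigma = 0`
degenerates to the deterministic cell mean, which several exactness tests
exploit.

Defaults are calibrated to the manual-keypress experiment's published
condition means: `base = 680`, `match_effect = 170` (785 vs 955 ms),
`congruency_effect = 48` (847 vs 895 ms), `domain_effect = 158` (792 vs
950 ms), `practice_slope = -10` ms per block, `subject_sd = 80`,
`item_sd = 25`, `residual_sigma = 0.35` (a within-cell SD around 215 ms),
error rates 5% plus 4 points in mismatch blocks.

Item offsets are drawn once per experiment and shared across subjects, then
**centred within each stimulus category**. Uncentred offsets would plant a
realized domain difference in every finite item sample even with
`domain_effect = 0` (the language-as-fixed-effect problem), making a zero
effect parameter a false null for between-item factors; centring makes the
generator's effect parameters true conditional nulls, which the
permutation-validity guarantees require.

Errors are independent Bernoulli draws per condition, generated separately
from RT, because the analyses treat RT and percent correct separately.

Design templates mirror the three experiments: a between-subject Match
design with congruent/incongruent manual blocks, and a within-subject vocal
design with four alternating match/mismatch blocks. Block order is
counterbalanced by alternating over the subject index; trial order within a
block is a uniform shuffle of the item list; the experiment half is derived
from block position (first 50% of a subject's blocks in presentation order).
Word identities are abstract tokens (`PAST01`, `NEGA01`, ...).

### What the generator does not emulate

No sequential effects, no fatigue beyond the linear practice slope, no
speed-accuracy coupling, no voice-key onset artifacts, no participant
replacement. Passing tests therefore demonstrate that the analysis chain is
correct and calibrated for data of this structure — not that it is robust to
every pathology of real lab data.

## 3. Trial-level RT analysis

Outlier filtering discards RTs below 250 ms or above 2000 ms (strict
inequalities, boundaries retained), before accuracy partitioning; fractions
are reported against all input trials. Filtering is idempotent. Note a
deliberate, documented property: because the RT distribution is heavy-tailed,
the upper cut trims the slower condition more than the faster one, so the
filtered match-effect estimand sits a few milliseconds below the generative
parameter. Condition means use correct trials only for RT and all retained
trials for percent correct.

Effect estimation aggregates item -> subject -> condition: each subject
contributes one mean per factor level (the mean over item means), and the
estimate is the difference of level means. Inference is by subject-level
permutation instead of mixed-effects likelihood-ratio tests: within-subject
factors flip each subject's level labels (sign-flipping the paired
differences), between-subject factors reshuffle the group assignment, and
`p = (1 + #{|perm| >= |obs|}) / (1 + B)` with `B = 5000` by default and a
mandatory seed. This is exact in finite samples under subject
exchangeability and estimates the same level-mean contrast as the
mixed-model fixed effect.

The half-split analysis reports, per experiment half, the mismatch - match
difference for RT and for percent correct (one sign convention for both:
positive RT effects and negative PC effects both favour match), and tests
the Half x Match interaction by permutation (sign-flips of subject-level
interaction scores within subjects, or group reshuffling when Match is
between subjects). The speed-accuracy check passes when the RT-faster level
is at least as accurate (weak inequality).

## 4. Rating analysis

Participant means are arithmetic averages of each participant's past-word
and future-word ratings. The mixed ANOVA (between: age group; within: time)
is computed from first-principles sums of squares — the between-subject
stratum on participant averages, the within-subject stratum on past-future
difference scores, group means observation-weighted — and agrees exactly
with standard library implementations on balanced and unbalanced designs.
Degrees of freedom derive from the design: `(1, N - 2)` for every effect
with two groups. A zero error stratum is flagged as degenerate and any
nonzero effect reported as `F = inf, p = 0` rather than dividing by zero.

Cohen's *d* for the time effect is defined on the within-subject difference
scores, `mean(d_i) / SD(d_i)`, pooled across both age groups — the natural
companion of a within-subject contrast. The formula is stated here because
paired effect sizes are often ambiguous between the difference-score and
pooled-SD conventions.

The rating generator rounds latent values (category mean + participant
offset + word noise) to the 1..7 integer scale. `from_standardized_effect`
converts a target *d* into a mean shift analytically, accounting for the
variance the rounding adds (`+1/12` per rating) and placing the two means
symmetrically around the scale midpoint so clamping stays symmetric. With
defaults (`sigma_between = 0.8`, `sigma_within = 1.0`, 15 words per
category) the recovered *d* is within about 2% of the target at the study's
sample sizes; the residual attenuation comes from tail clamping.

## 5. Distributional semantics

LSA builds the word-by-document count matrix (optional log-entropy
weighting, off by default since raw counts are the simpler baseline) and
takes word vectors as `U_k s_k` from the SVD; at full rank all pairwise
cosines equal those of the raw count rows, a property the tests verify to
1e-10. HAL counts context words within a +/-5-token window by default,
unweighted and summed over directions; distance weighting is exposed but
off. Tokens are case-folded, no stemming. A third recipe slot for a
predict-style (cbow) space is deliberately left empty: neural training is
out of scope for this toy stage. Cosine similarity of a zero vector is an
error, never silently zero.

The category analysis is a two-way ANOVA (time x valence) on the pair-level
cosine table, reported with classical F, dfs and p to match the field's
presentation style. However, pair cosines sharing a word are strongly
correlated, and the classical main-effect F is anti-conservative under that
dependence for any corpus with word-level sampling noise. `category_anova`
therefore also computes **word-label permutation** p values: category labels
are permuted over the time words (for the time and interaction tests) or
over the valence words (for the valence test), preserving group sizes. These
are exact under word exchangeability, and they are what the package's
type-I-error guarantees refer to. With 5 words per category the time-margin
permutation has 252 distinct labellings (minimum two-sided p about 0.008);
fewer than 4 words per category leaves too little resolution to reach
alpha = .05.

### Corpus generator

Documents carry a latent valence theme (alternating negative/positive, so
the two themes are exactly balanced). A themed document draws half its
tokens from the theme's filler context set, a quarter from valence words
(80% theme-consistent), and a quarter from time words. The designed
association enters twice: a paired time category is drawn into its partner
theme's documents with probability `(1+s)/2` (so it inhabits the partner's
characteristic contexts — the mechanism that moves both LSA and HAL
cosines), and each such time word is immediately followed by a
partner-category valence word with probability `s` (so at `s = 1` every
time-word occurrence is accompanied by its partner category, the exact
limiting case). `direction = "none"` emits fully exchangeable uniform
tokens with no theme structure, the null the calibration checks rely on.
Defaults: 200 documents of 60 base tokens, 5 words per category, 40
fillers.

`category_pair_counts` summarises a corpus as a 2x2 table of
adjacent-token (window 1) time x valence pairs. Adjacency pairs keep each
time token's contribution to one or two observations, so a chi-square
independence test on the table is calibrated under the exchangeable null;
wider windows or per-document count products are overdispersed and would
inflate it.

## 6. Pipeline and reproducibility

Every run is driven by a single integer seed; derived stages offset it
deterministically. Generators are bit-reproducible for a fixed seed, and a
run's manifest records the config echo and SHA-256 checksums of every
output file, so reruns can be verified byte for byte. Problem sizes in the
shipped test suite are scaled to what the checks need statistically:
200-replicate null-calibration runs at 16 subjects, 100-replicate recovery
runs at the design's 40 subjects, 50-replicate rating calibrations at the
survey's full 826 + 221, and corpus nulls at 80 documents; all are the
package's own choices of smallest informative size.

## 7. Known limitations

* The interactive-activation model is deterministic; it predicts mean-RT
  ordering, not RT distributions, and no parameter fitting to data is
  provided (out of scope by design).
* Permutation inference treats subjects as the only random factor;
  item-level generalisation (minF'-style) is not attempted. The generator's
  category-centred item offsets are what make zero effects true nulls.
* The classical F values in `category_anova` are reported for comparability
  but are not trustworthy p values under word-level dependence; use
  `p_perm`.
* The rating scale's clamping slightly attenuates extreme standardized
  effects (about 2% at d = 0.53 with default SDs); the analytic calibration
  corrects for rounding but not clamping.
* The corpus generator produces category-level structure with interchangeable
  words inside each category; it does not emulate word frequency skew,
  polysemy, or document-length variation.
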