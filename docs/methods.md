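# Methods

This note documents the models, algorithms, defaults and design choices
behind `gazestrat`, and what the synthetic-data experiments do and do not
establish about real eye-tracking data.

## Gaze metrics

Input is a log of AOI-tagged dwells (matrix / options / other) plus a trial
log with response accuracy and response time. Per trial:

- `T_item` is taken from the trial log RT, not from summed fixation
  durations: blinks and off-screen time belong in the denominator of the
  rate metrics. Fixations overrunning RT are truncated at RT with a warning.
- **PTM** = summed matrix-dwell time / RT; **LFT** = onset of the first
  options dwell (RT if the options are never viewed, giving RLT = 1 and
  NOT = 0 as the limiting constructive-matching case); **RLT** = LFT / RT;
  **NOT** counts label changes in the dwell sequence restricted to
  {matrix, options} — both directions count, and `other` dwells are
  transparently skipped so off-AOI fixations cannot inflate the toggle
  count; **ROT** = NOT / RT.
- Standardization for the mixture model is within item across participants,
  with the sample (n−1) standard deviation. A zero-variance metric on an
  item standardizes to all zeros with a warning; an item observed by fewer
  than two participants is an error.

## The mixture model (MEM)

A two-component mixture IRT model. Component 1 (constructive matching)
succeeds with probability `expit(theta_i - b_j + e_j)`; component 2
(response elimination) with `expit(theta_i - b_j)`. The constraint
`e_j >= 0` means CM never hurts: its success curve dominates RE's for every
ability, which identifies the component labels. Selection between the
components is a logistic function of per-item-standardized eye metrics,
`P(m=1) = expit(sum_k omega_k f_kij)`; the default metric set is
(PTM, ROT, RLT), with (PTM, RLT, LFT) available as a preset for re-fitting
on the forest-selected subset.

**Priors.** `theta ~ N(0,1)` (fixes the latent location/scale, standard
Rasch-type identification), `b ~ N(0, 2)`, `e ~ HalfNormal(2)`,
`omega ~ N(0, 2)`. All weakly informative; the half-normal enforces the
dominance constraint in the sampler (proposals below zero are rejected,
which is exact for a prior with no mass there).

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs, fully
vectorized: all theta_i are updated in parallel against their own likelihood
rows, b_j and e_j against their columns, and each omega_k against the whole
table. Per-parameter proposal scales adapt towards a 0.44 acceptance rate
with a decaying Robbins-Monro step during burn-in only, so the retained
chain is a valid fixed-kernel sampler. Defaults: 4 chains × 5,000
iterations, first half burn-in, over-dispersed N(0,1) initial values.
Split-R̂ and bulk ESS come from `arviz`; any R̂ > 1.1 triggers a warning
(never an error — degenerate data should still return a posterior).
Missing cells are masked out of the likelihood.

**Identification rules.** The cut-off rule thresholds the posterior mean of
`P(m=1)` (≥ c → CM, < 1−c → RE, otherwise IE; at c = 0.5 the partition is
binary, ties at exactly 0.5 falling to CM). The HPD rule computes the
shortest interval containing 95% of the `P(m=1)` draws per trial
(sliding-window scan over the sorted draws): interval above 0.5 → CM, below
→ RE, straddling → isolate-and-eliminate. Because an HPD interval always
contains its bulk, HPD-CM trials necessarily have posterior mean above 0.5,
making HPD a conservative refinement of the cut-off rule. `P(m=1)` depends
on the draws only through omega, so per-trial draws are reconstructed
on demand item-by-item rather than stored (S × I × J would not fit in
memory at full scale).

## Random forest, MDI, recursive elimination

Implemented from scratch because the impurity bookkeeping is itself part of
the method (scikit-learn appears only as an independent cross-check in the
tests). Trees grow on bootstrap samples (size n, with replacement), with a
fresh uniform draw of `ceil(sqrt(k))` candidate features per split;
candidate thresholds are midpoints between consecutive distinct sorted
values; the best split maximizes the Gini impurity decrease
`I(N) - (N_L/N) I(N_L) - (N_R/N) I(N_R)`. A feature's MDI is the average
over trees of its sample-weighted impurity decreases, normalized to sum to
one. Determinism everywhere: per-tree seeds derive from the forest seed;
split ties break to the lowest feature index and threshold; prediction ties
to the lowest class label; MDI ties in the elimination loop drop the
feature latest in the canonical order (ra, rt, ptm, lft, rlt, not, rot).
Defaults: 500 trees, unlimited depth, `min_samples_split = 2`. A
`bootstrap=False` switch exists because exact-memorization behaviour (one
tree reproducing its training labels) is only guaranteed without
resampling.

Cross-validation is stratified 10-fold (per-class shuffled indices dealt
modulo the fold count, so overall and per-class fold sizes differ by at
most one), falling back to an unstratified split with a warning when a
class has fewer members than folds. MDI is computed from a forest fit on
the full current table; CV is used only for the accuracy track — the two
are parallel measurements, not nested ones. Elimination proceeds to a
single feature; the optimal subset is the accuracy argmax with ties to
fewer features. Two-class runs use only CM/RE-labelled trials; three-class
runs include IE.

## Clustering validation

Per item, participants are clustered on the selected features, z-scored
within item first (LFT is in seconds and would otherwise dominate the two
proportions). K-means uses k-means++ seeding, Lloyd iterations, 10
restarts, and reseeds any empty cluster at the farthest point. K ∈ 2…10 is
chosen by the mean silhouette (ties to the smaller K); singleton clusters
and degenerate 0/0 points score silhouette 0. For strategy mapping every
item is (re)fit at K = 2 regardless of its preferred K, so each item
contributes a two-cluster contrast; the cluster with higher raw mean PTM is
CM (ties fall back to RLT, then LFT, else the mapping is NA with a
warning). Agreement with the mixture-model labels defaults to the
`cm_re_only` scope — trials the MEM calls IE have no clustering
counterpart, since K-means never emits a third label at K = 2 — with an
`all` scope available.

## Association analyses

Paired per-item contrasts use `t = mean(d)/(sd(d)/sqrt(n))` and the
difference-score Cohen's `d = mean(d)/sd(d)` (so `t = d*sqrt(N)`); this is
the convention consistent with very large d at moderate t over 36 items. A
zero-variance nonzero difference is flagged as overflow rather than raising.
Item difficulty for the difficulty-vs-RE-usage rank correlation is the
posterior-mean `b_j` — the pipeline's only difficulty estimator. p-values
come from scipy (Student t, Spearman t-approximation) and are reported at
machine precision.

## Synthetic-data generator

The generator defines the study conditions for all experiments: 192 × 36 by
default (200 × 36 in the recovery experiments), difficulty rising linearly
on the logit scale from −1.0 by 0.06 per item with N(0, 0.15) item noise,
sensitivities `e_j` half-normal with scale 1, and a latent per-trial
strategy choice `P(CM) = expit(0.5 + theta_i - b_j)` — able participants
prefer constructive matching and harder items push towards elimination.
Metrics are drawn conditional on the chosen strategy (the model's
metric-driven selection equation is thus an estimable proxy, mirroring how
real data arise while keeping ground-truth labels well defined):

| metric | CM | RE |
|---|---|---|
| PTM | Beta(16, 4), mean 0.80 | Beta(6, 9), mean 0.40 |
| pre-toggle fraction | Beta(8, 2), mean 0.80 | Beta(2, 6), mean 0.25 |
| RT (s) | LogNormal(log 18, 0.35) | LogNormal(log 28, 0.35) |
| NOT | 1 + Poisson(2) | 1 + Poisson(9) |

RLT is the pre-toggle fraction times PTM (not an independent Beta): this
guarantees `LFT = RLT·RT <= PTM·RT`, so every generated row is realizable
as an alternating fixation sequence, while preserving the ordinal CM > RE
contrast on RLT. Single-toggle trials set RLT = PTM exactly (all matrix
time precedes the only toggle). The profiles were chosen once as plausible
for college students on the APM — solve times tens of seconds, strong but
overlapping separation — since only the ordinal contrasts are
substantively constrained. Responses are Bernoulli from the mixture-model
success curves; isolate-and-eliminate trials (optional) draw metrics from
the midpoint profile and succeed with the average of the two curves.

Fixation synthesis emits the first matrix dwell of length LFT, splits the
remaining matrix time equally across the later matrix dwells and options
time equally across options dwells — only the aggregate metrics matter
downstream, so the within-sequence distribution is deliberately simple.

**What passing does not show.** The generator draws metrics independently
across trials given the strategy, uses clean two-sided profiles, and has no
eye-tracker noise, no distractor-level AOIs, no within-trial strategy
shifts, and no participant-level metric idiosyncrasies. Recovery rates and
agreement levels measured here are therefore upper bounds on what identical
settings would achieve on real recordings; the tests establish correctness
of the machinery, not field performance.

## Problem sizes and numerical choices

The recovery experiments run at 200 participants × 36 items with 4 chains ×
5,000 iterations — enough for split-R̂ ≈ 1.02 and stable posterior means at
roughly half a minute of sampling. The planted-feature experiment uses
100 × 36 trials (3,600 rows) and 100-tree forests: MDI rankings on signal
this strong are already stable well below the 500-tree library default.
Round-trip tolerances are 1e−9 (metric synthesis), 1e−10 (likelihood vs
extended precision), 1e−9 (MDI vs independent tree walk). K-means
convergence: assignment fixpoint or center movement below 1e−6, max 300
iterations. The long-format posterior CSV is thinned (default every 10th
draw) purely for file size; all in-memory computation uses every draw.

## Known limitations

- The sampler is random-walk based; very large studies would mix faster
  with gradient-based kernels.
- The selection weights omega are only jointly identified when the
  standardized metrics are not too collinear; at small scale the fitted
  selection probability discriminates strategies even when individual
  weight signs are unstable.
- IE is an identification outcome (posterior ambiguity), not a third
  generative component of the fitted model; the generator's hybrid group is
  correspondingly a midpoint profile, not a separate psychological model.
- K-means with the silhouette criterion can prefer K > 2 on heavy-tailed
  items; the pipeline's forced K = 2 refit is a reporting convention, not a
  claim about the true cluster count.
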