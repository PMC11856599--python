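# gazestrat

Identifying cognitive strategies on Raven's Advanced Progressive Matrices
(APM) from eye-tracking data.

When people solve matrix-reasoning items they tend to use one of two
strategies: **constructive matching** (CM) — mentally building the answer
from the matrix before consulting the response options — or **response
elimination** (RE) — ruling out options through repeated matrix–options
comparison. These strategies leave distinct gaze signatures. `gazestrat` is a
tested, reusable implementation of a full strategy-identification pipeline
for researchers in psychometrics and cognitive modelling:

1. **Gaze metrics** — from AOI-tagged fixation logs, compute the seven
   per-trial features: response accuracy (RA), response time (RT),
   proportional time on matrix (PTM = T^matrix / T^item), latency to first
   toggle (LFT), its rate (RLT = LFT / T^item), number of matrix–options
   toggles (NOT), and the toggle rate (ROT = NOT / T^item).
2. **Mixture model (MEM)** — a Bayesian two-component mixture IRT model:

       P(Y_ij = 1 | θ_i) = P(m_ij=1) σ(θ_i − b_j + e_j) + P(m_ij=2) σ(θ_i − b_j)
       P(m_ij = 1)       = σ(Σ_k ω_k f_kij)

   with ability θ_i, difficulty b_j, CM success gain e_j ≥ 0 and
   per-item-standardized eye metrics f (by default PTM, ROT, RLT). It is
   estimated by adaptive Metropolis-within-Gibbs MCMC; trials are labelled
   CM / RE / isolate-and-eliminate (IE) by a cut-off rule on the posterior
   mean of P(m=1) or by a 95% HPD-interval rule.
3. **Feature selection** — a from-scratch random forest with Gini
   mean-decrease-in-impurity (MDI) importance, and recursive feature
   elimination with stratified 10-fold cross-validated accuracy.
4. **Clustering validation** — per-item K-means (k-means++/Lloyd) with
   silhouette-guided choice of K ∈ 2…10, mapping of the two clusters to
   CM/RE by mean PTM, and agreement with the mixture-model labels.
5. **Associations** — paired t-tests with difference-score Cohen's d,
   Spearman correlation of item difficulty with RE usage, Pearson
   correlation of total score with CM usage.

A synthetic-data generator emulates the structure of a real eye-tracked APM
study (192 participants × 36 items by default) with known ground truth —
abilities, a rising difficulty trend, latent per-trial strategy choices, and
strategy-specific metric distributions — so every stage is testable without
any data download. It can also synthesize fixation streams that reproduce a
feature row exactly, giving an exact round-trip test of the metric formulas.

## Worked example

Simulate a small study, fit the mixture model, and identify strategies:

```python
import numpy as np
import gazestrat as gs

cfg = gs.simulate.SimConfig(seed=12, n_participants=60, n_items=12)
truth = gs.simulate.generate_truth(cfg)
features = gs.simulate.simulate_features(truth, cfg)
data = gs.mem.MemData.from_features(features)          # standardizes PTM/ROT/RLT per item
post = gs.mem.fit(data, gs.mem.SamplerConfig(chains=4, iterations=2000, seed=1))
print("max split-Rhat:", round(post.diagnostics["max_rhat"], 3))
print("omega posterior mean (ptm, rot, rlt):", post.omega_mean.round(2))
labels = gs.mem.identify_hpd(post, level=0.95)
vals, counts = np.unique(labels.labels, return_counts=True)
print("HPD labels:", dict(zip(vals.tolist(), counts.tolist())))
print("agreement with simulated truth:",
      round(gs.clustering.consistency(labels.labels, truth.strategy), 3))
```

prints

```
max split-Rhat: 1.03
omega posterior mean (ptm, rot, rlt): [-0.03 -0.44  1.92]
HPD labels: {'CM': 300, 'IE': 245, 'RE': 175}
agreement with simulated truth: 0.983
```

The chains have converged (split-R̂ close to 1). The selection weights point
the expected way — higher standardized RLT raises, and higher ROT lowers,
the probability of constructive matching (PTM and RLT are strongly
collinear at this small scale, so PTM's own weight is near zero while RLT
carries the shared signal). The HPD rule labels 300 trials CM and 175 RE
with high confidence and declares 245 ambiguous (IE); on the trials it does
commit to, it agrees with the simulated ground truth 98.3% of the time.

The same pipeline is available from the shell:

```bash
gazestrat all --seed 12 --outdir runs/demo        # simulate → … → analyze
gazestrat simulate --seed 12 --out runs/raw       # or stage by stage
gazestrat metrics --fixations runs/raw/fixations.csv \
    --trials runs/raw/trials.csv --out runs/raw/features.csv
```

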