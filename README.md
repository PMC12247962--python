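# cytoGPNet

Subject-level clinical outcome prediction from longitudinal single-cell
cytometry (flow, CyTOF, or an scRNA-seq input mode), with built-in global
marker-importance explanation and a synthetic cohort simulator for fully
reproducible benchmarking.

## The problem

A longitudinal immune-profiling study measures, for each of N subjects at
timepoints t = 1..T, a sample X⁽ⁿ'ᵗ⁾ ∈ ℝ^{m(n,t)×p}: m(n,t) cells (the row
count varies freely across samples) by p protein markers, plus one
subject-level outcome yₙ (responder / non-responder, protected / infected,
…).  Predicting yₙ from raw cell sets is hard: samples are unordered sets
of varying size, cohorts are small (tens of subjects) while cells are
plentiful (millions), visits go missing, and batch effects distort marker
scales.

## The model

cytoGPNet composes four stages, trained end to end:

1. **Autoencoder** — an MLP encoder g maps each cell x to a latent
   embedding h = g(x) ∈ ℝ^q (q = 4 by default).  It is pretrained by
   reconstruction over all cells pooled across subjects — no outcome
   labels — so the abundant cell count is exploited even when N is tiny.
2. **Sparse variational GP** — a zero-mean GP prior f ~ 𝒢𝒫(0, k) with
   squared-exponential kernel k(h, h′) = v·exp(−‖h−h′‖²/2σ²) maps each
   embedding to a scalar while sharing information across all cells,
   subjects and timepoints through the kernel.  O inducing points Z with
   variational posterior q(u) = N(μ, Σ) reduce inference from O(M³) to
   O(O³); the marginal q(f) = N(μ_f, Σ_f) has closed form
   μ_f = K_HZ K_ZZ⁻¹ μ, Σ_f = K_HH − K_HZ K_ZZ⁻¹ (K_ZZ − Σ) K_ZZ⁻¹ K_ZH.
3. **Attention pooling** — per timepoint, a gated-attention layer pools a
   sample's per-cell f values into one scalar s_nt (softmax-weighted sum:
   permutation invariant, any m ≥ 1); the T scalars concatenate into the
   subject representation sₙ, zero-padded for missing visits.
4. **Outcome head** — logistic regression on sₙ (plus optional subject
   covariates); softmax for multiclass outcomes.

All parameters — encoder, Z, kernel lengthscale, (μ, Σ), attention,
head — maximize the evidence lower bound
E_q(f)[log p(y|f)] − KL[q(u)‖p(u)], with the likelihood term estimated by
Monte Carlo through the reparameterization f = μ_f + L_f ε.

**Explanation.**  After training, a global mask assigns each marker j a
Bernoulli keep-probability P_j; sampled masks perturb the data as
X_m = X⊙M + X̄(1−M) (masked columns → analysis-set mean) and P is
optimized to minimize masked-prediction loss + λ·Σ_j P_j through the
binary-concrete (Gumbel-Softmax) relaxation.  P_j is the importance score:
the markers the model cannot afford to lose.

Everything differentiable runs on a small reverse-mode autodiff engine
over numpy (`cytogpnet._autodiff`), gradient-checked against finite
differences — no deep-learning framework required.

## Worked example

```python
import cytogpnet as cg
from cytogpnet.experiments import benchmark_train_config

sim = cg.SimConfig(n_subjects=30, n_timepoints=2, n_markers=10,
                   informative=(0, 1, 2), effect=1.5,
                   cells_range=(100, 300), seed=7)
cohort, truth = cg.simulate_cohort(sim)
table, summary = cg.cross_validate(cohort, benchmark_train_config(seed=7))
print(table[["fold", "auc"]].to_string(index=False))
print(f"mean AUC {summary['auc']['mean']:.3f}")
```

prints

```
 fold  auc
    0  1.0
    1  1.0
    2  1.0
    3  1.0
    4  1.0
mean AUC 1.000
```

Each row is one held-out fold of subjects: an AUC of 1.0 means every
held-out class-1 subject scored above every class-0 subject, i.e. the
+1.5 shift on three of ten markers is fully recovered from cells alone.
With `effect=0.0` the same pipeline returns chance-level AUC (~0.5).
`examples/` contains analogous scripts for marker importance, the
batch-effect diagnostic and the scRNA-seq preprocessing mode, each
printing and explaining its output.

A thin CLI covers the shell workflows:

```bash
cytogp simulate --out-dir cohort_dir --subjects 30 --seed 7
cytogp cv --manifest cohort_dir/cohort.yaml --folds 5
cytogp explain --manifest cohort_dir/cohort.yaml --lambda 0.05
```

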