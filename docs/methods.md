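# Methods

## Data model

A cohort is a set of samples keyed by (subject, timepoint), each a
cells × markers matrix with freely varying cell counts (the ragged
contract), one outcome label per subject, and optional per-subject
covariate vectors (e.g. condition dummies entering the classification
head).  Missing visits are recorded in an explicit registry rather than
as empty matrices, so the zero-padding applied downstream is a visible,
deliberate step.  Timepoints are 1-based integer indices; calendar
metadata is not modeled.

Ingestion is delimited text (comma/tab autodetected from the header
line), one file per sample, tied together by a YAML/JSON manifest.  Cell
row order within a file carries no meaning anywhere in the pipeline.

## Preprocessing

**Cytometry.**  Raw intensities x are transformed as y = arcsinh(x/c):
logarithmic for large x, linear near zero, defined for the zero and small
negative values that fluorescence compensation produces.  Default
cofactors: c = 5 (mass cytometry), c = 150 (flow).  No per-marker
standardization is applied after the transform; users wanting it can
standardize before assembling the cohort.

**scRNA-seq.**  In order: (1) drop genes detected in fewer than
`min_cells_per_gene` = 10 cells; (2) scale each cell's counts to a total
of `target_depth` = 10,000 (a cell with zero total is an error, not a
silent drop); (3) log1p; (4) keep the `n_hvg` = 1,000 most variable
genes.  The dispersion statistic is the plain variance of the
log1p-normalized expression with ties broken toward the lower gene index;
binned mean–dispersion selectors (Seurat/cell-ranger flavors) are
deliberate non-defaults since the variance rule is deterministic and
order-free.  The chain agrees with scanpy's `normalize_total` + `log1p`
on dense input (cross-checked in the tests).

## Model

**Autoencoder.**  Encoder widths p → 16 → q = 4 for cytometry (p is the
marker count), p → 256 → 64 → 16 → q for scRNA-seq.  Hidden layers are
ReLU; latent and reconstruction layers are linear, since targets are
real-valued arcsinh-scale intensities.  The decoder mirrors the encoder's
widths in reverse without weight tying.  Pretraining minimizes mean
squared reconstruction over cells pooled across all samples (labels are
never read), Adam, seeded fan-in initialization.  Published-scale
schedules are batch 128 / lr 1e-6 / 1000 epochs (cytometry) and batch
256 / lr 1e-3 / 200 epochs (scRNA-seq); the benchmark configuration below
uses far shorter schedules appropriate to its data volume.  Only the
encoder participates in fine-tuning; the decoder exists solely for
pretraining.

**Sparse GP.**  Squared-exponential kernel k(a,b) = v·exp(−‖a−b‖²/(2σ²))
with v fixed at 1 and σ trainable (as log σ).  The variational posterior
over the O inducing outputs is parameterized by μ and a lower-triangular
factor L with softplus-free positive diagonal (diagonal stored in log
space), so Σ = LLᵀ is positive definite by construction.  Inducing
inputs Z are initialized at k-means centroids of (at most) 10,000
randomly subsampled pretrained embeddings and remain trainable.  The
default initial lengthscale is 0.1; the benchmark configuration instead
initializes σ at the median pairwise embedding distance (the standard
median heuristic), because embedding scales vary across datasets and a
fixed 0.1 can start the kernel in a near-diagonal regime where gradients
are weak.  Training uses the diagonal-only marginal posterior — no M × M
matrix is ever formed — with per-cell variances floored at 1e-8.  All
Gram-solve paths share one jitter policy: start at 1e-6·v, escalate
tenfold to at most 1e-2·v, then fail with a condition estimate.

**ELBO.**  Mini-batches are whole subjects (all their cells, all
timepoints), so attention always pools complete samples.  The likelihood
term Σₙ log p(yₙ|sₙ) is estimated with B Monte Carlo draws of
f = μ_f + √diag(Σ_f)·ε (B = 8 by default, 4 in the benchmark) and
rescaled by N/|batch|; the KL term KL[q(u)‖p(u)] is added once per step.
At inference the deterministic path (f = μ_f) is used, so predictions are
reproducible; the MC path exists only to carry gradients during training.
B is not stated by any external constraint — it trades gradient variance
against time linearly.

**Attention and head.**  Per timepoint t, cell score
e_i = wᵀ(tanh(V f_i) ⊙ sigm(U f_i)) with hidden width 8, weights
softmax(e), pooled value s_nt = Σ w_i f_i.  Weights are convex
(nonnegative, sum to 1), so pooling is permutation invariant and well
defined for any m ≥ 1.  Missing visits contribute s_nt = 0 at the pooled
level (not at the cell or embedding level), keeping cell sets ragged
while the head always sees a length-T input.  The head is a full logistic
layer σ(wᵀsₙ + cᵀzₙ + b) over sₙ and covariates zₙ — with T = 1, w = 1,
b = 0 it reduces to plain σ(s) — or row-wise softmax for C > 2 classes.
Loss: binary/categorical cross-entropy (the Bernoulli/categorical
log-likelihood inside the ELBO).  Classification threshold for
F1/precision/recall: 0.5.

**AE-only baseline.**  Identical pipeline with the GP removed: latent
vectors feed attention directly (input width q instead of 1) and the head
takes T·q features.  It shares the data path exactly, giving a controlled
ablation of the GP stage.

## Training, evaluation, cross-validation

Fine-tuning defaults mirror the published-scale schedule (Adam, lr 1e-4,
subject batch 10, 100 epochs).  Cross-validation is subject-level k-fold
(k = 5), stratified by outcome by default — small cohorts otherwise risk
single-class test folds; stratification is a package choice, disabled by
a flag.  Everything inside a fold — AE pretraining, inducing
initialization, all fitting — sees only that fold's training subjects;
per-fold seeds are base_seed + fold index with full reinitialization.
AUC uses the rank/concordance definition with half credit for ties;
single-class folds report AUC as missing (never 0).  Robustness protocols
are one flag away: retain 50% of every sample's cells, or drop the second
visit for 10% of subjects.

## Explanation

The mask objective is optimized on the Bernoulli logits θ (P = σ(θ),
initialized at the maximum-entropy point P = 0.5), Adam on MC estimates
of the masked-prediction loss plus the relaxed L1 penalty λ·Σ_j P_j
(penalizing the expected mask rather than sampled masks keeps the penalty
smooth and unbiased).  Temperature anneals geometrically 1.0 → 0.1 over
the run; the reported P averages the per-epoch probabilities over the
last 10 epochs to damp stochastic-mask jitter.  Column means X̄ are
computed over the analysis set's preprocessed cells (recomputed within a
subset when explaining gated populations).  λ defaults to 0.01;
`explainer.lambda_sweep` exposes the tradeoff, and the benchmark uses
λ = 0.05, where informative and uninformative markers separate most
sharply on the synthetic cohorts.  One shared mask spans all timepoints
by default; per-visit importance is obtained by restricting masking to
one timepoint (`timepoint=` flag).  The model is frozen throughout —
only θ moves.

## Batch-effect diagnostic

Each sample is summarized at four stages — input, AE latent, GP output
μ_f, attention output s_nt — by the mean over its cells and output
dimensions (the attention stage is already a scalar).  Kruskal-Wallis
(tie-corrected, chi-square p with groups−1 df; identical values give
p = 1 with a warning) across batches per stage quantifies heterogeneity;
falling −log10 p across stages means the network attenuates batch
structure while extracting outcome signal.  Exact small-sample p-values
are out of scope.

## Synthetic cohorts

The simulator draws, per subject and present visit, m ~ U[m_lo, m_hi]
cells from a K-component Gaussian mixture on an arcsinh-like scale —
simulated values are treated as already preprocessed, so cohorts feed the
model directly.  Class-1 subjects have every population mean shifted by
+δ on the designated informative markers (optionally only at chosen
timepoints; multiclass outcomes scale the shift by class index).
Optional additive per-marker batch offsets (shared by a batch's samples)
and independent missing-visit events complete the nuisance structure.
Mixture weights default to (1,2,3)/6-style increasing weights shared by
both classes.  The ground-truth record (labels, informative set, batch
map, per-cell population labels) scores recovery experiments
automatically.

What the simulator does *not* emulate: spillover/compensation artifacts,
doublets, acquisition drift within a run, heavy-tailed marker noise, or
class-dependent population *abundance* shifts (the signal is purely a
mean shift).  Passing benchmarks therefore demonstrates the pipeline's
mechanics — signal recovery, calibration, robustness, explanation — under
a known generative law, not performance on any real cohort.

## Benchmark configuration and problem sizes

The reference benchmark (`cytogpnet.experiments`) uses N = 60 subjects,
T = 2, p = 10 markers, K = 3 populations, three informative markers at
δ = 1.5, and 200–800 cells per sample (~54,000 cells per cohort); the
null condition sets δ = 0.  Training at this scale: AE pretraining 4
epochs (batch 256, lr 1e-3) on a 15,000-cell subsample; fine-tuning 15
epochs, lr 0.02, subject batch 10, B = 4, O = 32 inducing points,
median-heuristic lengthscale init.  Signal/null use 5 simulation seeds;
robustness 3; the explainer runs 10 optimizer seeds against one model
trained with a longer schedule (40 epochs, lr 0.05) on a 20% cell
subsample of the cohort (sample-level resolution suffices for a global
mask).  These sizes were chosen so the whole suite runs on one CPU core
in minutes while every effect of interest is far from its decision
boundary.

## Numerical notes and limitations

* All numerics are float64 on a small in-repo reverse-mode autodiff
  engine (`cytogpnet._autodiff`); gradients are finite-difference-checked
  in the tests.  K_ZZ is inverted explicitly inside the differentiable
  path (O ≤ a few hundred), with the same jitter as the numpy path.
* Fixed seeds make pretraining, fine-tuning and explanation bit
  reproducible on one machine; across BLAS builds results may differ at
  ULP level.
* The deterministic (μ_f) prediction path and the MC training path can
  differ in logit scale — attention is nonlinear in f — so predicted
  probabilities are ranking-faithful but not guaranteed calibrated;
  threshold-based metrics inherit this.
* Subsampling retains ⌈fraction·m⌉ cells so nonempty samples never empty;
  masking a visit fraction uses round(fraction·N) subjects.
* Hyperparameter search is exposed as configuration, not automated; the
  additive per-timestep GP variant, multi-output kernels, and non-SE
  kernels are out of scope.
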