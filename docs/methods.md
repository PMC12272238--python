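# Methods

This note records the models, conventions, and design choices behind
`metamatch`, in the order data flows through the package.

## Features and kernel

An FC matrix is a symmetric P × P array of edge weights; symmetry is
enforced to max |M − Mᵀ| ≤ 1e−8 (FC matrices are correlation-like, larger
asymmetry indicates an upstream error). Vectorization takes the strict
lower triangle row-major over rows i > j — (1,0), (2,0), (2,1), … — and
this single edge order is used everywhere: feature vectors, Haufe maps,
serialized containers. The diagonal is ignored.

Per-participant normalization subtracts the vector mean and divides by the
L2-norm **of the demeaned vector**. The norm-after-demeaning reading is a
package convention (the operation is then exactly idempotent and normalized
vectors are exactly zero-mean/unit-norm, so the correlation kernel reduces
to a plain dot product on them); the alternative norm-before-demeaning
reading differs only by a per-participant scalar, which the correlation
kernel ignores anyway. The kernel itself standardizes each row internally,
making it invariant to any per-participant affine rescaling — this is why
the FC-centering differences between processing pipelines (a
global-signal-regressed dataset centers edges at zero; others do not) do
not affect any kernel-based learner, and the synthetic generator's
`feature_shift` knob exists to exercise exactly that contract.

## Base learners

**KRR** (correlation kernel) centers targets before the dual solve and adds
the mean back at prediction — a correlation kernel has no intercept
pathway. **LRR** fits per-phenotype weights with an unpenalized intercept
(centering parameterization). Both tune λ by grid search with 5-fold CV
over {0} ∪ logspace(−4, 4, 20); folds are a seeded random equal partition;
the CV score is validation MSE (Pearson r is undefined on the 2-participant
folds that K = 10 produces); ties prefer the **largest** λ, the safer
choice in the small-sample regime the tool targets. For a fixed fold, all
grid solutions come from one symmetric eigendecomposition with eigenvalue
shifts; shifted eigenvalues numerically at zero are dropped
(pseudo-inverse convention), so λ = 0 yields the minimum-norm interpolant
instead of failing.

**MLP**: a NumPy multi-output feedforward network (one output per source
phenotype). Defaults: hidden layers 256/128/64, ReLU, inverted dropout 0.3,
Adam (lr 1e−3, β 0.9/0.999), batch 128, ≤100 epochs, early stopping on the
20%-split validation loss with patience 10 and best-weights restore. The
loss is masked MSE: squared errors are multiplied by the observedness mask
and normalized by observed-cell count, so missing phenotype entries
contribute exactly zero gradient; output-layer columns are initialized
column-wise from per-column seeded streams, so an all-missing phenotype can
be added or removed without disturbing the other outputs' training
trajectory (asserted bit-exactly in the tests). These architecture numbers
are package defaults standing in for a per-dataset hyper-parameter search,
chosen to preserve the algorithmic structure; all are overridable.

Phenotypes are z-scored with train-split statistics before any base learner
is fit (predictions are de-standardized on output). This puts the
multi-output MLP's losses on one scale across heterogeneous phenotype
units; confound regression is deliberately out of scope.

Training splits are completely random 80/20 with no demographic matching.
The extra-large dataset trains its MLP on the 80% split (20% for early
stopping) and CV-tunes its LRRs within the 80% split; large/medium datasets
CV-tune and refit their LRRs on the full dataset.

## Meta-matching and the multilayer cascade

The stacking meta-learner is always correlation-kernel KRR over
prediction-feature vectors, λ CV-tuned on the K adaptation participants,
refit on all K, with **all** feature columns retained at any K. Column
labels are (dataset, family, phenotype) triples in canonical order: dataset
(extra-large, large, medium; input order within a class), then family
(mlp, lrr, stack), then phenotype order.

Intermediate stackers (a large dataset's phenotypes from the extra-large
block; a medium dataset's from extra-large + large-LRR blocks) are trained
per phenotype on the **full** corresponding dataset, rows with that
phenotype observed — no inner K-shot; the smaller datasets are scarce and
this uses all of them. Missing entries are dropped row-wise per phenotype
throughout.

Single-source stacking defaults to the extra-large MLP's outputs only
(67-style); including the LRR family (134-style) is a flag. Size classes
are explicit configuration; the convenience thresholds are N ≥ 10,000 →
extra-large, ≥ 2,000 → large, else medium.

A subtlety worth knowing: the correlation kernel centers each participant's
prediction *profile*, so information that shifts all columns equally is
invisible to the stacker; it is the differential response across columns
that carries signal (the test suite demonstrates this with a constructed
instance).

## Transfer-learning baseline

The pre-trained network is adapted by replacing the output layer with a
freshly initialized (seeded, same He-normal family) single-output head and
updating only the last two layers — the new head and the last hidden layer;
all earlier parameters are frozen and bit-identical afterwards. A fixed
learning rate is chosen from {1e−4, 1e−3, 1e−2} by 5-fold CV (ties → the
smallest rate); finetuning runs ≤10 epochs with an inner 80/20 split for
early stopping, patience 3, Adam, batch 16, dropout off (at K of order
tens, early stopping is the regularizer, and a deterministic trunk lets its
activations be precomputed once per dataset — the finetune then touches
only the two trainable layers, which keeps repeated protocol runs cheap
without approximation). The optimizer and patience are package choices; the
protocol (10-epoch cap, 80/20 early stopping, CV'd fixed rate) is fixed.

## Evaluation protocol

For each target phenotype and K ∈ {10, 20, 50, 100, 200} (configurable),
shots are drawn uniformly from participants with the phenotype observed;
all approaches within a repetition share the identical split (paired
design); metrics are computed on the held-out participants with the
phenotype observed. Default 100 repetitions; summaries average over
repetitions, then phenotypes. Predictive COD uses the K-shot target mean as
baseline — the only baseline a K-shot model legitimately has. Undefined
metrics (constant truth or predictions, n < 3) are recorded as missing and
excluded from means, never coerced to zero.

Approach comparison: per-(phenotype, repetition) paired differences,
**phenotype-cluster bootstrap** (resample phenotypes with replacement,
repetitions stay with their phenotype), two-sided
p = 2·(minority + 1)/(B + 1) with B = 1000. A two-stage scheme that also
resamples repetitions within phenotypes was evaluated and rejected: under a
null simulation it roughly doubles the bootstrap variance of the mean and
yields conservative p-values (KS vs uniform ≈ 0.18 vs ≈ 0.09 for the
cluster bootstrap). FDR is Benjamini–Hochberg pooled over all K, all
approach pairs, and both metrics.

## Haufe importance

Importance of edge j for a model is cov(x_j, ŷ) across participants
(unbiased n−1 denominator; map correlations are denominator-invariant). A
positive value means higher connectivity at the edge pushes predictions up.
Approach-level maps at K use the K adaptation participants' raw edge values
and predictions; the pseudo ground truth is the Haufe transform of a
full-sample CV-tuned KRR model's in-sample predictions (in-sample rather
than cross-validated: the reference model's fit, not its generalization, is
the quantity of interest).

## Synthetic data generator

Per participant, latents z ~ N(0, I_L) drive both sides:
x = rownorm(A_d) z + shift_d·1 + ε with A_d = A₀ + 0.25·D_d (common core,
dataset tilt; rows unit-norm so per-edge signal variance is 1), and
y_t = b_{d,t}·z + η with b_{d,t} = unit(c·s_{t mod L} + (1−c)·u_{d,t}):
shared prototypes s make phenotype batteries latently correlated across
datasets with strength c (`cross_loading_strength`). Missingness is
completely at random, minimally repaired so every participant/phenotype
retains one observation. FC matrices are rebuilt symmetric with unit
diagonal. Everything derives from one seed via keyed streams
(`metamatch._seeds`), so collections are bit-reproducible.

The **canonical suite** fixes the study conditions: five sources with
N = 4000/1500/300/300/300 (extra-large / large / 3 medium; a ~13:1 size
ratio), phenotype batteries T = 20/12/8/8/8 with 10% missingness, target
N = 600 with T = 10, P = 40 (E = 780), L = 6, c = 0.7, phenotype noise SD
0.5 (reliability ≈ 0.89, typical of cognitive scores), per-edge feature
noise SD 8. The edge noise was set so the suite sits in the regime the
method exists for — K ≪ E, classical KRR at K = 100 around r ≈ 0.4 and
full-source models substantially better, magnitudes comparable to real
connectome-phenotype studies — rather than a near-noiseless regime where
direct KRR saturates and there is nothing to transfer. The extra-large
source is centered (shift 0); the others carry shift 0.3, exercising the
normalization contract. Acceptance-scale runs use K ∈ {10, 100} with 20
repetitions across all 10 target phenotypes so the full grid fits in a few
minutes on one CPU.

What the generator does **not** emulate: realistic fMRI noise spectra,
motion artifacts, site/scanner covariance beyond the loading tilt and mean
shift, informative missingness, and harsh covariate shift between source
and target populations. Consequences observed in the package's own checks:
the meta-matching orderings (multilayer ≥ dataset stacking ≥ single-source
stacking > classical KRR at K = 100, multilayer-vs-KRR gap positive at 95%
bootstrap confidence) replicate cleanly, and transfer learning shows the
expected small-K instability as a variance effect (across-repetition COD
variance at K = 10 two orders of magnitude above classical KRR's) — but its
*mean* COD at K = 10 stays slightly positive rather than dropping below
classical KRR's, because the mildly-shifted synthetic target lets the
pretrained trunk transfer better than harsh real-world dataset shift
allows. Passing the suite therefore demonstrates the machinery and the
stacking advantage, not that transfer learning would be this benign on real
multi-site data.

## Numerical and degenerate-input conventions

Constant feature vectors are rejected (correlation undefined) rather than
silently zeroed; constant predictions make metrics/importance missing or
raise, depending on context. Kernel values are clipped to [−1, 1] against
rounding. Dual solves at user-fixed λ use Cholesky and advise λ > 0 on
singularity; grid-search paths use the eigen-shift pseudo-inverse route.
Serialization (HDF5 + CSV) round-trips models and datasets bit-exactly
(CSV is re-parsed with round-trip float precision); containers carry a
version field and the edge-order convention, and refuse unknown versions.

## Known limitations

Besides the generator gaps above: no confound regression; no demographic
matching in splits (deliberate); no GPU path (the NumPy MLP is sized for
desk-scale problems); the multilayer cascade depth is fixed at the
extra-large → large → medium grouping; λ grids and MLP/finetune
hyper-parameters stand in for per-dataset searches on real data.
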