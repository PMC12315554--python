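# Methods

## Problem setting

The package predicts *A–A–B triplets*: ternary relations between two entities
of the same molecular type A (miRNAs, drugs) and one context entity of type B
(a disease, a cell line). Examples are disease-specific miRNA–miRNA
co-regulation and cell-line-specific drug–drug synergy. The data are encoded
as a third-order tensor X ∈ R^{n_A × n_A × n_B}, symmetric in its first two
modes, with X_{ijk} = 1 for a known interaction and unobserved cells to be
completed. Because the relation is symmetric in (i, j), triplets are stored
canonically (i ≤ j) and mirrored only when the tensor is materialised.

## Stage 1 — multi-constraint tensor decomposition (MCTD)

The multilinear stage fits a CP/INDSCAL model X ≈ [[M, C, D]] with
M, C ∈ R^{n_A×r} (driven to consensus, so the symmetric-mode factor is
effectively shared) and D ∈ R^{n_B×r}, under three constraints:

- **similarity reconstruction**: (μ/2)‖S_A − M A_m Mᵀ‖²_F and
  (η/2)‖S_B − D A_d Dᵀ‖²_F tie the factors to externally supplied similarity
  matrices through learned r×r projections A_m, A_d;
- **graph smoothness**: (α/2) tr(Mᵀ U M) and (β/2) tr(Dᵀ V D) with U, V the
  graph Laplacians Deg − S of the similarity matrices, penalising embedding
  differences between similar entities;
- **column sparsity and ridge**: a λ-weighted sparsity penalty on the factor
  columns plus a Frobenius ridge on A_m, A_d.

Optimisation is ADMM: consensus copies C = Z = H = M and P = F = D decouple
the constraints, each block then has a closed-form update of the augmented
Lagrangian, and scaled dual variables are updated by gradient ascent with the
penalties multiplied by ε = 1.15 after each sweep (capped at 1e8 so the
geometric growth cannot overflow). The projection matrices are updated by
conjugate gradients on the normal equations
μ MᵀM A MᵀM + λA = μ MᵀS M, starting from A = 0. Between sweeps, unobserved
cells are imputed with the current model (X̂ = X on observed cells,
[[M, C, D]] elsewhere), so later sweeps see a complete tensor — an EM-style
treatment of missingness.

Numerical conventions worth stating explicitly:

- **Data-term scaling.** The augmented Lagrangian implemented here carries a
  factor ½ on the data term ½‖X̂ − [[M, C, D]]‖²_F. This is the objective
  whose block minimisers the closed-form updates are; the unit-tests verify
  each update by central-difference stationarity against exactly this
  function.
- **Sparsity surrogate.** The column-sparsity penalty enters through a
  diagonal weight W(k,k) = ½‖column k‖₂ treated as a frozen-weight
  (iteratively reweighted) quadratic surrogate, recomputed from the incoming
  block before each M/D update. The classical majorisation weight
  1/(2‖·‖ + 1e−12) is available as `l21_convention="standard"`.
- **Unfolding convention.** Mode-n matricisation is fixed so that
  T_(1) = M·kr(C, D)ᵀ, T_(2) = C·kr(M, D)ᵀ, T_(3) = D·kr(M, C)ᵀ hold exactly,
  with kr the column-wise Kronecker (Khatri–Rao) product whose row (a, b) is
  a-major. Any self-consistent convention yields identical fits; this one is
  asserted against triple-loop oracles.
- **Smoothness/ridge solves.** The Z and F updates require the left solve
  (αU + ρI)⁻¹(ρM + Y); U, V are positive semidefinite so the system is
  well-posed for any ρ > 0.
- **Initialisation.** M, D ~ 0.1·U(0,1) i.i.d. (seeded), consensus blocks
  start equal to their parent factor, multipliers at zero, projections at
  zero. Convergence is declared when the relative change of the observed-cell
  RMSE drops below `tol` (default 1e−5), or after `max_iters` (default 300).

### Hyperparameters and defaults

| parameter | default | role |
|---|---|---|
| r | 4 | factor rank (components) |
| μ, η | 0.1 | similarity-constraint weights |
| α, β | 0.1 | Laplacian-smoothness weights |
| λ | 0.1 | column-sparsity + projection ridge |
| ρ₁..₃, θ₁..₂ | 1.0 | initial consensus penalties |
| ε | 1.15 | penalty growth per sweep |

All weights are unitless multipliers on squared-Frobenius terms. The penalty
growth schedule means the consensus constraints harden geometrically: the
data term dominates the early sweeps (where the fit happens) and consensus
dominates the late ones. Consequently, for *noiseless exact-recovery*
exercises the natural configuration disables the constraints (μ = η = α = β
= 0, λ → 0) and starts the penalties at 0.01 so the data term governs more
sweeps; the recovery tests use that configuration and reach <1% observed-cell
error on a 20×20×10 rank-2 instance with 30% of cells observed. With the full
default regularisation the same instance plateaus near 24% observed error —
expected, since the constraints deliberately trade data fit for prior
consistency and are meant for sparse noisy binary data, not noiseless
continuous tensors.

## Stage 2 — neural tensor decomposition (NTD)

Each query cell (i, j, k) is represented twice:

- **index embeddings** e_i, e_j from a trainable table shared by the two
  symmetric modes, and e_k from a second table (rows of dimension r,
  initialised N(0, 0.01));
- **factor embeddings** — rows M_i, C_j, D_k of the fitted multilinear
  factors, frozen by default (`finetune_factors` unfreezes them).

Both 1×r×3 stacks pass through a *shared* two-layer convolutional encoder:
n_C filters of shape (1, 3) mix the three mode vectors componentwise (the
analogue of the elementwise product underlying a rank-one term), then n_C
filters of shape (r, 1) collapse the rank axis; ReLU follows each layer. Each
branch's n_C-vector code feeds its own single-layer FastKAN head: layer
normalisation (trainable gain/shift by default), Gaussian radial basis
features exp(−((x − c_g)/h)²) on n_g centers uniformly spaced on [−2, 2] with
bandwidth equal to the grid spacing (normalisation keeps inputs inside that
domain), a linear read-out w_s of the flattened (feature-major) RBF features,
plus a SiLU-gated linear base path w_b applied to the raw code. The two
branch scores are mixed as γ·y_factor + (1−γ)·y_index and squashed with a
logistic function — the heads produce unbounded scores while the loss needs
probabilities, so the logistic is the minimal calibration step. γ = 0 and
γ = 1 reproduce the no-factor and no-index ablation variants exactly.

Training minimises binary cross-entropy with Adam (lr 1e−3, batch 256), a
stratified 10% validation split, and early stopping after 10 stale epochs;
the best-validation weights are restored. w_b and w_s are linear read-outs
(n_C→1 and n_C·n_g→1) rather than scalars — the shapes of the head only
close under linear maps. The heads of the two branches are independent; only
the encoder is shared. The whole stage is NumPy with hand-written
reverse-mode gradients, verified against central differences to ~1e−8; with
a fixed seed training is bitwise reproducible.

Prediction symmetry in (i, j) is *not* architecturally enforced; the
pipeline always feeds canonical (i ≤ j) triplets, which is the documented
contract.

## Evaluation protocol

Seven metrics per scored split: AUROC (probability a random positive
outranks a random negative, ties ½), AUPRC (step-wise interpolation, i.e.
average precision — linear interpolation would inflate it), and F1, accuracy,
recall, specificity, precision at threshold 0.5 on the logistic output (the
threshold is exposed). Cross-validation is k-fold (default 5) with
repetitions (default 5), at triplet level or entity level; entity-level
(cold-start) folds partition the entities of one axis and assign every
triplet touching a held-out entity to the test side. Negatives are drawn
once per fold×repetition from canonical cells absent from the *full*
dataset, so a sampled negative can never coincide with a held-out positive;
any negatives already present in an input dataset are set aside by the CV
harness, which resamples its own. Training-fraction robustness keeps
floor(f·n) of the training positives; negative-ratio robustness scales the
sampled negatives per fold. Leakage is asserted programmatically inside the
harness: test triplets never enter the observed tensor or a training batch,
and in entity modes no training triplet touches a held-out entity. Paired
t-tests on fold-wise metric values are two-sided; identical inputs return
p = 1.0 with a warning, and a constant nonzero shift with zero variance
returns p = 0 (the t statistic diverges).

## Synthetic study conditions

The generator plants nonnegative factors M* ∈ R^{n_A×r}, D* ∈ R^{n_B×r}
(i.i.d. U(0,1)) and scores every canonical cell with the symmetric
multilinear form s(i,j,k) = Σ_ℓ M*_{iℓ} M*_{jℓ} D*_{kℓ}. Positives are the
top `pos_frac` of canonical i<j cells by score — quantile thresholding that
mirrors how continuous synergy scores are binarised at a fixed cutoff in
real screens. The dataset reveals `obs_frac` of the positives plus an equal
number of uniformly sampled negatives. Similarity matrices are the cosine
normalisation D^{-1/2}(F Fᵀ)D^{-1/2} of the planted Gram matrix (symmetric,
unit diagonal — a row normalisation would break symmetry), perturbed with
symmetric Gaussian noise of s.d. `sim_noise` and min-max scaled to [0, 1].

Defaults — n_A = 40, n_B = 15, r_true = 4, pos_frac = 0.05, obs_frac = 0.8,
sim_noise = 0.05, 1:1 negatives — are the desk-scale study conditions used
by the test suite and the acceptance script; they keep a full 5-fold CV of
both stages under a few minutes on one CPU. What the generator does *not*
emulate: the size and sparsity of real screens, non-multilinear interaction
structure, measurement noise on labels, and block structure or annotation
bias in real similarity matrices. Passing recovery tests therefore
demonstrates correctness of the machinery and identifiability under the
planted model, not biological performance.

## Known limitations

- Dense tensors internally: fine at desk scale, not for 10³-entity screens.
- The late-sweep penalty freeze means MCTD's final fit quality depends on
  the initial penalty scale relative to the data Gram matrices; the defaults
  suit binary-incidence data of O(1) scale.
- The MCTD scoring path returns raw reconstruction values (not squashed);
  thresholded metrics on that path use the same 0.5 cutoff, which is
  meaningful for 0/1 tensors only.
- Single-layer FastKAN heads; deeper KAN stacks and non-RBF bases are out of
  scope, as are GPU execution and sparse-native ADMM updates.
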