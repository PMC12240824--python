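# Methods

## Model

Every connectome flavor — one combination of parcellation, modality (SC or
FC) and estimation method — is represented by the strict upper triangle of
its symmetric region × region matrix, stacked row-major (i < j) into an
edge vector. The model assumes a shared subject-level "connectomic
backbone": a low-dimensional latent vector from which every flavor's edge
data is an (approximately) affine observation. Accordingly each flavor *i*
has:

1. a **fixed PCA reduction**: edge vectors are mean-centered with the
   training mean μ_tr,i, projected on an orthonormal basis fitted on
   training subjects only, and divided by the per-component training
   standard deviation (whitening). Whitening equalizes the contribution of
   flavors whose native dimensions differ by orders of magnitude (3,655 to
   96,141 edges at full scale). The transform is affine and exactly
   invertible on its subspace, which is how predictions return to native
   edge dimensions. Component signs are fixed (largest-magnitude loading
   positive) so refits are bit-reproducible.
2. a **linear encoder** (single fully connected layer) followed by L2
   normalization onto the unit hypersphere, and a **linear decoder**
   (single fully connected layer) back to reduced space. All flavors share
   one latent dimension (128 by default; 16 in the desk-scale experiments).

Translation i → j composes reduce_i → encode_i → decode_j → restore_j.
Fusion averages a subject's latent vectors over a flavor subset (all /
FC-only / SC-only / all-but-the-target-parcellation). The fused average is
decoded **without re-normalization** by default — the decoder is affine, so
feeding the literal mean keeps fusion a linear operation on latents; a
`renormalize` switch re-projects onto the sphere for users who prefer
decoder inputs to match the training distribution (unit norm). The averages
of well-aligned latents have norms near 1 anyway, which is why the default
makes little practical difference.

## Losses and training

Each epoch has two stages.

**Path-wise stage.** For every ordered flavor pair (i, j), in an order
reshuffled every epoch, batches of n_batch subjects are encoded with
Encoder_i and decoded with Decoder_j. With C the batch matrix of Pearson
correlations between predicted subject a and true subject b (in reduced
space), the loss is

    w_rm · L_r.mse + L_r.corrI + L_r.marg + w_z · (L_z.corrI + L_z.dist)

- L_r.mse — elementwise mean squared error;
- L_r.corrI — mean squared deviation of C from the identity;
- L_r.marg — mean over ordered pairs a ≠ b of max(0, m_r − (C_aa − C_ab))²,
  a contrastive margin (default m_r = 0.1) forcing each subject's own
  reconstruction to out-correlate other subjects' by a gap;
- L_z.corrI / L_z.dist — the analogous terms on the latent batch: the
  cosine-similarity matrix's deviation from identity, and
  max(0, m_z − ‖z_a − z_b‖)² pushing pairwise latent distances above
  m_z = 1 (orthogonal unit vectors sit at √2, so the margin only binds on
  crowded pairs).

Only Encoder_i and Decoder_j receive updates for path (i, j). Exact
algebraic forms of the correlation/margin terms are committed package
defaults, registered by name so alternates can be swapped without touching
the trainer. Default weights w_rm = 1000, w_z = 10, w_zs = 10000.

**Consistency stage.** Latents are recomputed for all flavors on the full
training cohort and w_zs · Σ_{i<j} MSE(z_i, z_j) is backpropagated through
all encoders. The pairwise-sum form is equivalent (up to a constant factor)
to the MSE to the mean latent. This stage uses the full cohort in one step
and applies no dropout; dropout (when enabled) acts on encoder and decoder
inputs during the path-wise stage only.

Optimization is AdamW (decoupled weight decay, β = (0.9, 0.999)).
Because the model is a handful of small linear maps, both the forward pass
and gradients run on a compact NumPy reverse-mode autodiff core
(`conncodec.autodiff`); every op is verified against central finite
differences in the test suite, and the AdamW update against the update
formula.

**Determinism.** Every random draw of epoch *e* (path order, batch
shuffles, dropout masks) comes from `default_rng([seed, e])`, so loss
traces are bitwise reproducible and resuming from a checkpoint (which
stores model weights, optimizer moments and traces) continues the exact
uninterrupted trajectory.

**Schedules.** The full-scale defaults mirror the reference setting
(lr 1e-4, weight decay 1e-2, dropout 0.5, n_batch 41, thousands of
epochs). For desk-scale synthetic cohorts (tens of regions, a few hundred
subjects) `desk_train_config()` uses lr 1e-3, weight decay 1e-3, no
dropout, 200 epochs: at this size heavy dropout mostly injects noise, and
the higher learning rate lets the near-linear problem converge within a few
hundred epochs on one CPU (the canonical 6-flavor run takes about a
minute). Checkpoint selection defaults to the epoch maximizing validation
avgrank + avgcorr_demean.

**New-flavor extension.** Given edge data for a new flavor on subjects
whose fusion latents are already computed, a new encoder/decoder pair is
trained as an autoencoder with an extra alignment term
w_zs · MSE(z_new, z_fusion); the base model is never touched. Alignment at
desk scale needs a few hundred epochs (seconds of CPU).

## FC estimation

Pearson FC correlates (censored, filtered, nuisance-regressed) regional
time series; GSR FC first regresses the mean regional signal and its
backward derivative (first difference, first element 0). Censoring flags
timepoints with |z| > 5 of the global signal or framewise motion derivative
above 0.9 mm; censored rows are excluded from every fit and from the final
correlation but carried through pipelines unchanged. High-pass filtering
projects out DCT basis functions below the cutoff (basis k spans frequency
k / (2 T TR)), fit on non-censored rows.

Regularized partial correlation is Ω̂ = (FC + λI)⁻¹ rescaled to
−Ω̂_ij/√(Ω̂_ii Ω̂_jj) with unit diagonal. λ is a population-level
parameter: a grid search (default 0 plus 40 log-spaced points in
10⁻³..10¹) minimizes the per-subject mean Frobenius distance between Ω̂_a
and the population mean Ω̄ of the *unregularized* (pseudo)inverse FCs —
Frobenius being the natural elementwise reading of a mean-squared-error
objective on matrices; whether the sum is normalized per subject does not
change the argmin. Ties break toward smaller λ. For rank-deficient FCs the
target is built from pseudoinverses.

Zero-variance regions get correlation 0 with a warning rather than NaN
propagation — the same convention used when scoring the population-mean
pseudo-prediction, whose demeaned residual is identically zero.

## Metrics

avgcorr, avgcorr_demean (demeaned by the training-population mean only),
top1acc and avgrank are defined in the README. Two tie conventions matter
only for degenerate inputs: top-1 ties count against the subject
(conservative), and avgrank counts ties as 1/2 (midrank), so the constant
population-mean pseudo-prediction scores exactly 0.5 — its chance level —
rather than 0 under a strict inequality; a `ties="strict"` flag restores
the strict reading. The per-subject rank normalizes by n − 1 (fraction of
*other* subjects), so perfect predictions score exactly 1. The direction is
"measured subject s against all subjects' predictions"; the transposed
reading differs only in which axis is scanned and is available by swapping
arguments.

Graph-metric preservation computes weighted node strength (signed sum),
betweenness centrality, characteristic path length (distance = 1/weight)
and Louvain modularity per connectome, then Spearman-correlates measured vs
predicted values across subjects. Negative edges are dropped for the
path-based metrics and modularity, retained in strength; both choices are
configurable. Path length over a disconnected graph averages reachable
pairs with a warning.

## Cohort analyses

Latent (or observed-data) inter-subject similarities are grouped by
relationship; each related pair gets an unrelated pair matched on sex
pairing and closest age difference. Group separability is the Mann-Whitney
AUC (ties 1/2); latent-vs-observed separability differences are tested with
matched permutations (pair-wise swaps of the latent/observed scores;
exhaustive enumeration available for ≤ 20 pairs), and multiple comparisons
are Benjamini–Hochberg corrected. Demographic models are a linear SVC
(sex, balanced accuracy) and linear-kernel ridge regression (age,
cognition; Pearson r and MAE), with hyperparameters from a nested
family-blocked GroupKFold grid search over 10⁻⁴..10⁴ so siblings never
span folds. Bootstrap intervals resample held-out subjects (default
n = 100, seeded). Network masking replaces every edge whose two endpoints
both fall outside the chosen network with the training-mean edge value and
re-scores fusion predictions and (re-fitted) demographic models; the
non-masked reference row reproduces the unmasked pipeline exactly.

Domain adaptation for out-of-distribution cohorts is a pure mean shift,
x − μ_new + μ_train, per flavor, applied before the (frozen) reduction and
encoder; no variance matching is attempted.

## Synthetic cohorts

The generator draws subject latents u_s on the unit d-sphere
(default d = 16). Family pairs mix a shared family direction f with an
individual direction: u = √ρ f + √(1−ρ) ε, renormalized, so the expected
latent cosine of a pair is ≈ ρ. Defaults ρ_MZ = 0.85, ρ_DZ = 0.5,
ρ_sib = 0.45 follow the twin-study picture of high MZ similarity and
roughly half-shared genetics for DZ/siblings while keeping the three groups
distinguishable at desk-scale sample sizes. Age (uniform 22–37 y) and sex
shift designated latent directions (effect 0.4 per SD); cognition
composites are linear readouts of the latent plus noise (SD 0.3). Families
never span splits.

Each flavor observes an affine image of the latent restricted to its
modality's subspace: a fraction `overlap` (default 0.7) of dimensions is
shared between FC and SC, the remainder split into modality-private halves.
Edge noise SD is 0.2 relative to the unit-variance latent signal — a
plausible measurement-noise level given that same-subject retest
connectomes correlate highly but not perfectly. FC edges are squashed into
[−1, 1] by tanh around a base correlation template; SC edges are
exponentiated to nonnegative pseudo-counts. Both squashings can be disabled
(`fc_squash="none"`), in which case zero-noise full-overlap data is an
exact affine function of u_s and a rank-d PCA reconstructs it to machine
precision — the information-complete limit in which trained models reach
avgrank 1.0 on every path. Retest sessions redraw measurement noise only.

The canonical desk spec (2 atlases of 16/32 regions × (2 FC + 1 SC) = 6
flavors, 250 subjects split 200/20/30, 30 MZ + 20 DZ + 30 sibling pairs,
retests for 20 training subjects) is sized so a full train-and-evaluate
cycle runs in about a minute on one CPU while leaving enough test subjects
for stable rank metrics.

**What passing desk-scale tests does and does not show.** The generator
matches the model's structural assumptions (shared latent, near-affine
observations, modest noise), so recovery there validates the
implementation — the losses, optimization, reductions, metrics and
analyses — not the scientific adequacy of a linear codec for real imaging
data, whose edge distributions, site effects and nonlinearities the
generator deliberately does not imitate beyond range and sign constraints.

## Numerical choices and limitations

- Correlations and L2 normalizations are eps-guarded (1e-12); zero-variance
  rows warn and score 0; a zero pre-normalization latent raises.
- PCA adapts n_comp downward to min(n_comp, n_train − 1, n_edges) with a
  warning so small cohorts work.
- Batches keep a final partial batch only if it has ≥ 2 subjects
  (contrastive terms need pairs).
- λ grids containing singular points skip them; an all-singular grid is an
  error naming the fix.
- The trainer is CPU-only NumPy: perfectly adequate at desk scale, not
  intended for the full 15-flavor, high-resolution regime.
- FC matrices use diagonal fill 1.0 and SC 0.0 on devectorization; the
  diagonal never enters edge vectors.
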