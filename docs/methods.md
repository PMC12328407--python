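# Methods

This note records the model as implemented, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## Label-graph pipeline (DAME)

Given a binary annotation matrix `Y ∈ {0,1}^{n×C}`:

1. **Co-occurrence** `M = Yᵀ Y`; the diagonal holds per-label totals.
2. **Conditional probabilities** `M'[i,j] = M[i,j] / M[i,i]`, i.e. row
   conditioning `P(j | i)`.  Labels that never occur become isolated
   self-loop nodes (`M'` row zero off-diagonal, one on the diagonal) rather
   than raising on the zero division.
3. **Thresholding** `A = 1[M' ≥ τ]`, default `τ = 0.4`; the boundary maps
   to 1.  Raising τ can only remove edges (monotone).
4. **Reweighting** `N[i,i] = 1 − p`, `N[i,j] = p·A[i,j] / Σ_{k≠i} A[i,k]`,
   default `p = 0.2`.  The numerator carries `A[i,j]` so absent edges get
   no weight; each non-isolated node therefore has off-diagonal row mass
   exactly `p`, making `N` row-stochastic.  `p → 0` degenerates to the
   identity (self-connections dominate), `p → 1` to pure neighbour
   averaging.
5. **Attention refinement.**  Each of `k` blocks (default 2) computes `h`
   heads (default 4) of scaled-dot-product attention at dimension
   `D_h = 64`: `[Q,K,V] = N [W^Q, W^K, W^V]`,
   `head = softmax(QKᵀ/√D_h) V`.  The heads are concatenated and projected
   back to `C×C`, and the block output is the identity-at-init residual

       G_j = relu(N + γ_j · Concat(head_1 … head_h) W_O),   γ_j init 0.

   The final adjacency is the ordered product `P = ∏_j G_j`, rectified and
   row-normalized to unit row sums.  Because `N` is row-stochastic, at
   initialization `P = N^k` exactly, so the statistical graph structure
   (e.g. planted co-occurrence blocks) is preserved before any training and
   the attention pathway fades in as the gains `γ_j` grow.  The residual
   form is this package's resolution of an underdetermined design: a pure
   `Concat(heads)·W_O` output under random initialization is an arbitrary
   matrix and would discard the statistics it is meant to refine.
   `P` is recomputed from the current attention parameters on every forward
   pass (not cached per epoch).

The standalone `build_subgraph` operation implements the non-residual form
(zero parameters give the zero matrix) for direct inspection; the trainable
`DynamicGraph` module uses the residual form above.

The attention stage costs `C²·D_h` weight multiplications
(`complexity_estimate`): 25,600 for 20 labels, 230,400 for 60, at
`D_h = 64`.

## Label semantics and the GCN head

Label names are lowercased, split on non-alphanumerics, filtered against
scikit-learn's English stop-word list, and reduced with an in-repo
implementation of Porter's classic suffix-stripping algorithm (no stemmer
ships with the scientific stack used here).  If filtering would empty a
label, its raw lowercased tokens are kept.  Each label node's embedding is
the mean of its tokens' 300-d word vectors from a GloVe-format text table;
out-of-vocabulary tokens receive a seeded random unit vector (logged) so
the pipeline is deterministic under a fixed seed.

Two stacked GCN layers map `H0 ∈ R^{C×300}` through a hidden width of
1024 (configurable; the reduced profile uses 128) to `W ∈ R^{C×D}`:
`H^(l+1) = σ(D̃^{-1/2} Ã D̃^{-1/2} H^(l) W^(l))` with `Ã = P + I`.  The
self-loop guarantees `D̃_ii ≥ 1` for isolated nodes.  σ is LeakyReLU with
slope 0.2 after layer 1 and absent after layer 2, the convention of the
graph-based multi-label classifiers this architecture follows.

Pairwise cosine similarities of the label embeddings are computed and
exported for inspection but do not enter the default graph construction,
which is purely co-occurrence-statistical; `graph.init: cosine` with a
`cosine_weight` blends a cosine-edge seed graph into `N` for
experimentation.

## Wavelet-convolution backbone

`WTConv` is depthwise and shape-preserving: a base 3×3 per-channel kernel
filters the input directly, while a cascade decomposes the running
low-frequency band with an orthonormal Haar DWT (`levels` = 2 by default),
filters each of the four subbands with its own small depthwise kernel, and
reconstructs upward through the inverse transform.  The output is the
average of the two paths with a learnable per-channel gain on the cascade,

    out = (base + gain ⊙ cascade) / 2,    gain init 1,

so Dirac kernels reproduce the input exactly while the frequency-selective
path is active from the first forward pass.  Depthwise (rather than dense)
subband kernels keep the parameter increase per level slight.  The
differentiable cascade supports the Haar family; the public `dwt2`/`idwt2`
functions accept any orthogonal PyWavelets family and reflect-pad odd
extents before the periodized transform.

The backbone is DenseNet-like: a 7×7 stride-2 stem with 3×3 stride-2 max
pooling, four dense blocks of six composite layers (BN → ReLU → 1×1
projection to the growth width → 3×3 WTConv), transitions of 1×1
compression (θ = 0.5) plus 2×2 average pooling between blocks, and a final
1×1 projection to exactly `D = 2048` channels.  The projection reconciles
the dense-block channel arithmetic (growth 48 from a 64-channel stem gives
548 channels after block 4) with the 2048×14×14 / `D = 2048` contract; a
448×448 input reaches 14×14 before global average pooling.  All
convolutions and wavelet steps use reflection padding to avoid border
artifacts.  Batch normalization uses batch statistics in training and
running statistics in evaluation.

A **reduced profile** (112-px input, 24-channel stem, two blocks of two
layers at growth 16, one wavelet level, `D = 64`) keeps every mechanism —
stem, dense connectivity, wavelet cascade, transition, projection, 14×14
pre-pool map — at roughly 1/500 the compute, and is the profile used by
the test suite's training checks.

## Fusion, loss and training

Per-label logits are `ŷ = W x`.  The loss is multi-label binary
cross-entropy on sigmoid probabilities, averaged over labels and over the
batch.  The class-mean reduction (rather than the class-sum sometimes
printed for this loss) matches the convention of the training recipe this
package follows and keeps gradient scale independent of the label count;
`bce_loss(..., reduction="sum")` provides the summed form.

The optimizer is SGD with momentum 0.9 and weight decay 1e-4 in two
parameter groups — graph branch (attention + GCN) at lr 0.5, CNN branch at
lr 0.03 — with both rates multiplied by 0.1 every 30 epochs, batch size
16, up to 100 epochs, and early stopping (patience 10) on validation mAP
with best-checkpoint restoration.  A global gradient-norm clip (default
1.0, disable with `clip_norm: null`) stabilizes the high graph-branch rate
at small batch counts; at desk scale the recipe is otherwise at the edge
of stability and oscillates.  Optional augmentation follows the standard
multi-label recipe: random horizontal flip and multi-scale random crops
(scales 1.0/0.875/0.75/0.66) resized back; it is off by default for the
deterministic synthetic checks.

Metrics: AP per label by all-points interpolation over the
descending-score ranking (ties broken by stable index order; verified
against scikit-learn on tie-free data), mAP in percent over labels with at
least one positive; rank-based (Mann–Whitney) AUC with half-credit ties;
pooled OP/OR/OF1 and class-averaged CP/CR/CF1 at a 0.5 sigmoid threshold,
with F1 always the harmonic mean of the aggregated precision and recall
and undefined ratios reported as 0.  Labels with no positives (or a single
class, for AUC) are excluded from the means and listed in the report.

## Synthetic data

The generator plants the two properties the architecture is built to
exploit:

* **Co-occurrence blocks.**  Labels are partitioned into blocks (default:
  two halves of C = 8).  Each sample picks a block uniformly and activates
  in-block labels with `p_within = 0.6` and out-of-block labels with
  `p_between = 0.05`; all-zero rows are resampled.  These rates give the
  conditional-probability matrix a clear block structure at the default
  τ = 0.4 threshold.
* **Frequency-localized lesions.**  Each label contributes a Gaussian
  envelope (σ = image_size/6) at a label-specific grid location whose
  carrier is a label-specific low-frequency oriented cosine, at peak
  amplitude 0.8; active templates add, iid Gaussian pixel noise
  (σ = 0.05) supplies the high-frequency component, and values clip to
  [0, 1], replicated to three channels.  The label-specific carrier
  frequency is essential: a location-only blob is invisible to a
  translation-equivariant CNN after global average pooling, so labels must
  differ in frequency content to be detectable at all — which is also
  precisely the regime the wavelet backbone targets.

The fixture embedding table assigns each preprocessed token a seeded
random vector scaled to the typical magnitude of real 300-d GloVe vectors
(per-coordinate spread 0.38, norm ≈ 6.5); tokens of same-block labels
share an added block component (mixing weight 0.5) so within-block cosine
similarity exceeds between-block by a clear margin.  The realistic scale
matters: unit-norm embeddings shrink the graph branch's gradients by more
than an order of magnitude and the published learning rates then cannot
train the head.

What the generator does **not** emulate: anatomical appearance,
inter-patient variation, label noise, class imbalance beyond the block
design, or resolution/quality variation.  Passing the synthetic checks
therefore demonstrates that the mechanisms work as specified — statistics
recovery, frequency sensitivity, end-to-end trainability — not that the
model reaches any particular accuracy on real retinal or chest-X-ray data.

## Numerical infrastructure

All trainable components run on an in-repo reverse-mode autodiff engine
over NumPy `float64` arrays (`meddgtn.autodiff`), with dense convolution
via im2col, a dedicated depthwise-convolution primitive, and slice-based
Haar transforms; every primitive is verified against numeric gradients.
Parameters are Xavier-uniform from a seeded generator; all randomness
(initialization, sampling, shuffling, OOV fallbacks) flows from explicit
seeds, and two runs with identical seeds are bitwise identical.
Checkpoints are single-file `.npz` archives with a version field.

Known limitations: CPU-scale only (a default-profile forward pass takes
tens of seconds; training beyond the reduced profile is impractical); the
trainable wavelet cascade is Haar-only; no pre-trained backbone weights,
so results on real datasets are not comparable to transfer-learning
pipelines; detail-subband orientation conventions of the internal Haar
transform differ from PyWavelets by sign/role (approximation and diagonal
bands agree exactly).
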