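# meddgtn

Multi-label classification of medical images with a **dynamically learned
label-dependency graph** and a **wavelet-convolution dense backbone**
(Med-DGTN).

A single fundus photograph or chest radiograph often carries several
findings at once, and those findings co-occur in structured ways (diabetic
retinopathy with macular edema, age-related macular degeneration with
choroidal neovascularization).  Treating each label as an independent
binary problem throws that structure away, and ordinary convolutions tend
to wash out the low-spatial-frequency content where subtle pathology lives.
This package addresses both with a dual-branch design aimed at researchers
who work on multi-label medical imaging and want a fully inspectable,
CPU-friendly implementation:

* **Graph branch.** From a training split's annotations it builds a label
  co-occurrence matrix `M`, conditional probabilities
  `M'[i,j] = P(j | i) = M[i,j] / M[i,i]`, a thresholded binary graph
  `A = 1[M' >= τ]` (τ = 0.4), and a reweighted correlation graph `N` with
  self-weight `1 − p` and neighbour mass `p` (p = 0.2).  A multi-head
  scaled-dot-product graph transformer then refines `N` into the dynamic
  adjacency `P = ∏_j G_j`, where each subgraph
  `G_j = relu(N + γ_j · Concat(head_1 … head_h) W_O)` is learned during
  training.  A two-layer GCN, `H^(l+1) = σ(D̃^{-1/2} Ã D̃^{-1/2} H^(l) W^(l))`
  with `Ã = P + I`, maps 300-d GloVe-style label embeddings to a classifier
  matrix `W ∈ R^{C×D}` — one classifier row per label.
* **CNN branch.** A DenseNet-style backbone whose composite layers are
  BN → ReLU → WTConv: features are decomposed with a cascaded orthonormal
  Haar wavelet transform, each subband filtered with a small depthwise
  kernel, and recombined through the inverse transform, widening the
  receptive field cheaply and emphasising low-frequency structure.  A
  448×448 input ends as a 2048×14×14 map, pooled to `x ∈ R^2048`.
* **Fusion.** Per-label logits are `ŷ = W x`, trained with multi-label
  binary cross-entropy and two SGD parameter groups (graph branch lr 0.5,
  CNN branch lr 0.03, momentum 0.9, weight decay 1e-4, ×0.1 decay every
  30 epochs, early stopping on validation mAP).

Everything runs on NumPy via a compact in-repo reverse-mode autodiff
engine — no GPU or deep-learning framework required — and a seeded
synthetic-data module generates multi-label images with planted
co-occurrence blocks and frequency-localized lesions so the whole pipeline
is testable offline.

## Worked example

```bash
# 1. a seeded synthetic dataset: 32 images, 8 labels in two co-occurrence blocks
meddgtn synth --n 32 --labels 8 --seed 7 --image-size 112 --out data/

# 2. export the label-graph pipeline (M, M', N, P) with a heatmap of P
meddgtn build-graph data/labels.csv --out graphs/

# 3. train the reduced desk-scale profile and evaluate on the training split
cat > config.yaml <<'YAML'
backbone: {profile: reduced}
gcn: {hidden: 128}
train: {epochs: 30, patience: 30}
seed: 7
YAML
meddgtn train data/ --config config.yaml --out run/
```

The training command ends with a metric table like

```
mAP    99.777
OP     0.6818
OR     0.8621
OF1    0.7614
CP     0.7959
CR     0.8446
CF1    0.8195
AUC    0.9985
best epoch 28 (val mAP 99.78); outputs in run
```

mAP is the mean over labels of the area under each label's
precision–recall curve (in percent); OP/OR/OF1 pool every (image, label)
decision while CP/CR/CF1 average per label; AUC is the rank probability
that a positive scores above a negative.  A training mAP near 100 on this
32-image set shows the fused pipeline can learn the planted label signals;
the exported `graphs/adjacency_P.png` shows the two planted co-occurrence
blocks as a block-diagonal pattern.

The same `meddgtn eval` and `meddgtn predict` commands score held-out
directories and individual images from a saved checkpoint.

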