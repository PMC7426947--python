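# Methods

## The model

The package implements a training framework in which free-text radiology
reports act as auxiliary supervision for an image classifier.  Three
components share a single latent code **z** (64-D by default):

* **Encoder** `f: image -> z` — a configurable CNN.  The default
  `small-cnn` backbone is a stride-2 stem convolution followed by three
  conv/max-pool blocks (widths 8/16/32/64), a flattening head, dropout,
  and a dense projection to z.  An `inception-like` backbone with mixed
  multi-kernel blocks is available for fidelity experiments; it honors
  the identical latent contract.
* **Decoder** `g: (z, report tokens) -> per-step vocabulary
  distributions` — a bidirectional LSTM (128 units per direction by
  default) run under teacher forcing.  z is projected by learned linear
  maps into the initial hidden and (by default) cell states of both
  directions.  Because the decoder is bidirectional the objective is
  report *restoration*, not autoregressive generation; input-embedding
  dropout (0.5) forces the decoder to rely on z for tokens it cannot
  copy.
* **Classifier** `h: z -> 7 logits` — two fully-connected layers
  (64 -> 32 -> 7).

Training regimes:

* `baseline` — encoder + classifier on the classification loss only;
  reports are never read.
* `m1` — stage 1 trains encoder + decoder on the reconstruction loss
  alone; stage 2 trains the classifier on latents from the (by default
  frozen) encoder.
* `m2` — joint: every step minimizes `L = L_cls + lambda * L_rec`
  (default lambda = 0.5) from the same latent code.

Inference in every regime is a pure function of the image: the encoder
and classifier alone produce softmax class probabilities.

## Losses

`classifier_loss` is the one-hot cross-entropy, summed over classes and
averaged over the batch.  `focal_loss` is
`-alpha_t (1-p_t)^gamma log p_t` with gamma = 2 and per-class alpha =
inverse class frequency normalized to mean 1 by default; with gamma = 0,
alpha = 1 it reduces exactly to the cross-entropy.  Probabilities are
clamped at 1e-12 inside logarithms.

`encoder_decoder_loss` is the masked per-step cross-entropy between the
decoder's distributions and the one-hot token targets; PAD steps
contribute exactly zero.  The printed per-vector objective does not fix
how steps aggregate, so the scalar function supports both a `sum` (the
default) and a per-sample `mean` over real tokens.  The **trainer uses
the mean**: with the summed form the reconstruction gradient into the
encoder is roughly an order of magnitude (≈ number of report tokens)
larger than the classification gradient, and joint training degenerates
to reconstruction-only at the desk-scale optimization budget.

## Text pipeline

Reports are lowercased, split on whitespace, and stripped of flanking
punctuation (class codes like `a1` survive).  The vocabulary keeps the
300 most frequent tokens (ties broken lexicographically, making the
vocabulary order-free) plus PAD/START/END/UNK, with PAD = 0.  Sequences
are padded to the decoder's step count — 40 by default, set in practice
to the observed maximum report length of the corpus, mirroring the rule
that the step count equals the dataset's maximum word length.

Embeddings (128-D) are fit on the global word-to-word co-occurrence
matrix (symmetric window, 1/distance weighting) by full-batch gradient
descent on the weighted least-squares objective
`sum f(X_ij) (w_i . w~_j + b_i + b~_j - log X_ij)^2` with
`f(x) = min((x/x_max)^0.75, 1)`; the step is halved whenever it would
increase the objective, so the recorded trace is non-increasing.  The
embedding layer is GloVe-initialized and fine-tuned by default
(`glove-frozen` and `scratch` are selectable).

## Synthetic data generator

Institutional radiographs with paired reports are protected patient
data, so the package ships a phantom generator that emulates the
dataset's *structure*:

* a stylized pelvis (bright ring, two femoral heads/necks/shafts) on a
  noisy background, with anatomy jitter (±2 % position) and additive
  Gaussian noise (default sd 0.10 gray-levels);
* fracture motifs drawn as dark lucent lines in the designated region —
  trochanteric for A subtypes (A1 single oblique line, A2
  multifragmentary branches, A3 reverse obliquity) and femoral neck for
  B subtypes (B1 subcapital, B2 transcervical, B3 displaced double
  line);
* class-consistent template reports with a constrained lexicon
  (≤ 457 distinct words; each class carries a distinctive keyword, so a
  keyword matcher recovers the class of clean templates);
* strong non-fracture edge confounders (abdominal-fat-like arcs) on 30 %
  of normal images;
* ground-truth fracture masks for saliency scoring — an affordance real
  data does not have.

The femur geometry is deliberately large (the neck spans about a quarter
of the image) so that subtype distinctions remain several pixels at the
64-px benchmark size; the noise default was calibrated so a pixel-space
linear probe reaches ≈ 50 % validation accuracy on the 7-class task —
well below the noiseless ceiling but learnable.  What the generator does
**not** emulate: real radiographic texture, osteopenia, projection
variation, descriptive free-text variability.  Passing benchmarks on the
phantom therefore demonstrate that the training machinery behaves as
designed, not clinical performance.

The augmentation policy mirrors the stated grids — rotation −10..10° in
1° steps, scale 90..110 % in 1 % steps, translation ±10 px in 1-px steps,
bilinear interpolation with zero fill, composed about the image center —
and expands each non-exempt training class to exactly 4x its original
count (1 original + 3 transforms); normals are exempt and
validation/test splits untouched.

## Optimization defaults and the desk-scale budget

Adam with learning rate 1e-4 and dropout 0.5.  Epochs
default to 30 per stage and the batch size to 8.  The batch size matters
more than usual here: Adam's per-parameter step is bounded by the
learning rate, so the total movement available in a run is roughly
`steps x lr`; at n = 700 and 30 epochs, batch 8 yields 2,640 steps,
without which even the classifier head cannot traverse its
initialization scale.  These sizes keep a full three-regime,
three-replicate benchmark within minutes on one CPU core.

Reproducibility: a single master seed fans out via named blake2b-derived
streams to data generation, weight init, dropout masks, shuffling and
augmentation.  Components share streams by name, so the baseline and an
m2 run with lambda = 0 produce bit-identical encoder/classifier updates.
Training logs are reproducible to 1e-6 under a fixed seed and thread
count.

## Evaluation

Confusion matrices have rows = actual, columns = predicted, class order
(normal, A1, A2, A3, B1, B2, B3).  Accuracy, precision, recall and F1
follow the printed one-vs-rest formulas; `Avg. F1` is the unweighted
macro mean; zero-denominator ratios are reported as 0 with an explicit
flag (needed for the 5-sample rare class).  The 7-class matrix collapses
to 3 classes (normal / A / B) and 2 classes (normal / fracture); the
collapse conserves totals and commutes.  One-vs-rest AUC uses the
Mann-Whitney rank formula (ties count ½) on softmax scores.  Latent
codes are exported as a table for external embedding (e.g. t-SNE), which
is out of scope here.

Grad-CAM: for class score y^c taken **before** the softmax, neuron
importance alpha_k is the global average pool of dy^c/dA^k over the
chosen convolutional layer's feature maps, and the map is
`ReLU(sum_k alpha_k A^k)`, upsampled bilinearly and max-normalized for
the overlay.  The default target layer is the encoder's last
convolution.  The lesion-hit fraction (saliency mass inside the
ground-truth mask, compared with the mask's area fraction as the uniform
chance level) quantifies lesion localization; note that models trained
only at the desk-scale budget are too far from convergence for this
statistic to be meaningful, and an untrained model's ReLU map can be
identically zero.

## Design choices that were genuinely open

* Encoder head: flatten-then-dense rather than global average pooling,
  because the labels are positional by construction (see above); GAP
  remains available.
* Dropout placement: once at the encoder head and in the decoder
  (embeddings + hidden concat) rather than after every convolution;
  rate 0.5 throughout.
* M1 stage 2 freezes the encoder (literal reading of "an additional
  classification network was trained"); unfreezing is a flag.
* Reports longer than the step count are truncated with a warning; real
  corpora under the 40-token cap never trigger this.
* `Avg. F1` is macro (unweighted); a weighted variant was considered and
  rejected for comparability across the hierarchy levels.

## Known limitations

* At the fixed desk-scale budget the two-stage regime (m1) stays near
  chance on the 7-class task: its reconstruction-shaped latents carry
  class signal (a linear probe finds it) but the frozen-encoder
  classifier stage cannot exploit it within the step budget.  The
  benchmark's comparative claim concerns the joint regime versus the
  image-only baseline.
* The numpy implementation is single-threaded and CPU-oriented; it is
  not intended for images larger than 128 px or datasets beyond a few
  thousand samples.
* GloVe fitting is dense (V x V); fine for constrained report lexicons,
  inappropriate for open vocabularies.
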