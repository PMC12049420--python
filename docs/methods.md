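# Methods

`protospec` implements an interpretable, prototype-based classification
pipeline for 1-D Raman spectra with transfer learning from a large
"mineral-like" source domain (narrow, isolated lines) to a small
"biological-like" target domain (broad, overlapping bands). This note
records the model, the choices that were genuinely open, and what the
synthetic test bed does and does not establish.

## Preprocessing

Spectra are interpolated (piecewise-linearly) onto a uniform grid of
`n_points = 950` samples over the closed window `[600, 1640]` cm⁻¹,
endpoints included. The resampling step itself enforces the trim window; a
separate `trim` operation (closed interval) is available for explicit
cropping. No extrapolation is ever performed — a spectrum must cover the
window or it is rejected.

Two normalisation paths follow, matching the two model families:

* **Encoder path**: per-spectrum min–max scaling to `[0, 1]` (a constant
  spectrum maps to all-zeros by convention). No per-feature statistics are
  involved, so this step cannot leak across folds.
* **Chemometrics (PCA/LDA) path**: per-feature standardisation
  `z = (x − μ)/σ` with **population** σ. Zero-variance columns are set to
  zero and flagged rather than dropped, preserving grid alignment. μ and σ
  are fitted on training rows only and re-applied to held-out rows.

Each spectral domain is resampled to 950 points over *its own* configured
window; the encoder consumes shape, not absolute wavenumber. This matters
when the source domain's acquisition range differs from the target's — the
two domains are aligned by index, not by cm⁻¹.

## The encoder

A small 1-D CNN `φ(·; θ)` maps a 950-point spectrum to a 2048-D feature
vector: three blocks of convolution → batch normalisation → ReLU → max-pool
(÷2) → dropout, then an adaptive max-pool to 16 positions and a flatten
(128 channels × 16 = 2048). Channel counts (32, 64, 128), kernel sizes
(9, 7, 5) and the final pool length are configuration, constrained only by
`channels[-1] × final_pool_length == feature_dim`; the 2048 product is the
fixed contract, its factorisation is not. ReLU placement (after BN) and
dropout placement (after each pool) are standard choices.

The network is implemented as a compact numpy layer stack (`protospec.nn`)
with hand-written backward passes, gradient-checked against central
differences in the test suite. Training is mini-batch SGD with momentum 0.9;
dropout is 0.55 by default (off at inference), batch norm uses running
statistics at inference. Everything is deterministic given the seed.

Three transfer regimes:

* **full** — all encoder parameters finetune on target data (convention:
  lr 0.001, batch 20, 250 epochs at production scale);
* **linear** — only the third conv block trains; earlier blocks are frozen
  *including their batch-norm statistics* (the trainable block keeps
  updating its own statistics);
* **none** — the encoder is bitwise untouched; a frozen feature extractor.

The default training loss is cross-entropy through a disposable linear head.
An alternative `prototype_distance` loss is provided: softmax cross-entropy
over logits `−‖φ(x) − p_c‖²` with per-class mean-feature prototypes
recomputed each epoch — the conceptual nearest-prototype objective expressed
as a differentiable batch loss.

## Prototypes

Prototypes are always **real training samples**. Clustering proposes
centroids; `select_medoids` then takes the nearest training row to each
centroid (ties → lowest index; duplicate winners collapse). Back-ends:

* **k-means**: Lloyd iterations with kmeans++ init, 10 seeded restarts, and
  a logged inertia trajectory (non-increasing by construction; the tests
  assert this and cross-check the final objective against scikit-learn).
* **mean-shift**: scikit-learn's implementation; `bandwidth="auto"` uses
  half the median pairwise distance (subsampled at n > 500).
* **density/typicality peaks (ADP-style)**: Cauchy density
  `D(x) = 1/(1 + ‖x−μ‖²/σ²)` with μ the sample mean and σ² the mean squared
  distance to μ; typicality is D normalised over the sample. Rows are ranked
  by typicality (ties → row index) and greedily accepted as prototypes when
  farther than `radius_factor·σ` (default 1.0) from every accepted one. The
  greedy radius rule and its default are this package's reconstruction of
  the density-peak idea in batch form; both are configurable.
* **plugin**: any callable mapping a feature matrix to centroids, so other
  clustering families can be slotted in unchanged.

Labeled mode clusters each class separately (prototypes inherit the label);
in this high-level path the requested k is capped at the number of distinct
rows per class, so a degenerate feature set (e.g. a collapsed encoder
mapping every spectrum to the same point) yields one prototype and an
honest near-chance accuracy rather than an error — calling the k-means
primitive directly on identical rows with k > 1 still errors, since that is
a genuine misuse. Unlabeled mode clusters everything and a small labeled subset then names
each prototype by majority vote of its nearest-prototype partition cell
(empty cells fall back to the single nearest labeled sample). The
labeled/unlabeled distinction is surfaced, not hidden, because the mapping
from unlabeled clusters to class names is a genuine modelling step.

## Classifiers

* **Nearest-prototype (IDEAL)**: label = class of the prototype minimising
  `‖φ(q) − φ(p)‖²` (equivalently maximising the negative squared distance);
  ties → lowest prototype index. An optional `exp(−d²)` transform reports
  similarities in (0, 1]. With all training samples as prototypes this is
  exactly 1-NN, which the tests exploit as an oracle.
* **xDNN-style density classifier**: per class, the Cauchy density above and
  its normalised typicality (sums to 1 per class); prototypes are the
  class-wise typicality peaks; confidence is
  `λ_c(q) = max_p exp(−‖q − p‖²/σ_c²)` and the decision is winner-takes-all
  over λ (ties → earlier class in the vocabulary). Each class carries one
  "IF similar-to p₁ OR … THEN class" rule; the maximising prototype is
  returned as the firing witness. A single-sample class becomes its own
  prototype with σ² borrowed from the global mean scatter (flagged). The
  density/typicality recursions are condensed to their offline batch forms.
* **PCA/LDA baseline**: standardisation → PCA (no whitening, 1–100
  components, capped at the achievable rank with an explicit error) → LDA
  (SVD solver) → nearest class mean in discriminant space. It consumes
  preprocessed raw spectra, never encoder features — it is the independent
  baseline, not a head on the network.

## Explanations

The explanation artifacts *are* the decision rule, not post-hoc stories:

* `explain_query` reports each class's nearest prototype with both the
  feature-space and the raw-spectral-space ℓ² distance; the winner is the
  same argmin the classifier uses. If the raw-spectral nearest class
  disagrees with the feature-space winner, the record carries an explicit
  note — the decision is never overridden.
* `radar_table` gives per-band distances `√Σ_{w∈b}(q_w − p_w)²` on the
  preprocessed grid, origin-at-query convention. The default banding is 16
  equal-width bands over the window (a partition, so band energies sum
  exactly to the squared full distance — asserted to 1e-10); named ±15 cm⁻¹
  bands at 960/1070/1240/1270/1450 cm⁻¹ are available for annotation.
* `voronoi_projection` projects prototypes and samples to the top-2
  principal axes and tessellates the projected prototypes. The 2-D cell
  assignment can disagree with the 2048-D nearest prototype; the
  disagreement rate is always reported, because the map is a visualisation,
  not the decision.

Radar distances are computed in raw preprocessed spectral space while
classification runs in feature space; both are reported per class.

## Cross-validation harness

Stratified k-fold (10 folds for the prototype classifiers, 6 for PCA/LDA, by
convention), seeded and deterministic. Every fold refits the *entire*
pipeline — standardisation statistics, clustering, prototype selection, any
finetuning — on the fold's training rows. The harness enforces this
mechanically: a fitted model must carry a SHA-256 fingerprint of exactly the
data it saw, and the harness recomputes the fold's fingerprint and
hard-errors on mismatch. Fitting on the full dataset and reusing the model
across folds is therefore an error, not a silent bias. Refitting inside
every fold is deliberately conservative; with a frozen encoder the feature
transform is label-independent, so extracting features once up front does
not violate fold hygiene. The fold summary is mean accuracy ± a Student-t
95% half-width over folds (the interval method is a package choice); the
per-fold maximum is also exposed.

## Synthetic data

The generator draws spectra as Σ peaks (Gaussian or Lorentzian, per-spectrum
jittered center and amplitude) + cubic-capped polynomial baseline + additive
Gaussian noise, with one rng substream per (seed, class, replicate) so
datasets are order-independent and byte-reproducible.

* **Mineral-like presets** (12): one or two narrow lines (FWHM 5–15 cm⁻¹) at
  distinct centers in 600–1100 cm⁻¹ — the pretraining source domain.
* **Ivory-like presets** (2): shared broad bands (FWHM 25–60 cm⁻¹) at 1070,
  1240, 1270, 1450 and 1665 cm⁻¹ (the last deliberately outside the default
  trim window, exercising the trim), differing **only** in the 960 cm⁻¹
  phosphate band: center 960 vs 966 cm⁻¹ and amplitude 1.0 vs 0.95. The
  center shift is deliberately the dominant cue: the phosphate band is each
  spectrum's global maximum, so per-spectrum min–max normalisation maps its
  height to 1 for both classes, and an amplitude-only difference would be
  redistributed into the shared bands by the normalisation instead of
  staying at 960.
* Default noise_sd 0.02 (≈2% of the dominant peak), center jitter 1 cm⁻¹,
  relative amplitude jitter 5% — separable but not trivially so at the
  default preprocessing resolution.

The generator emulates band positions, relative widths and the location of
the class difference; it does **not** model fluorescence backgrounds, cosmic
rays, detector response, wavenumber calibration drift, specimen-level
correlation between replicates, or realistic class overlap. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
transfer ordering holds under these controlled conditions — not that any
particular accuracy will be attained on real dentine spectra.

## Study conditions for the end-to-end checks

Chosen once, as the package's desk-scale experiment: source = 10
mineral-like classes × 200 spectra, 30 pretraining epochs (batch 20,
lr 0.01, dropout 0.55); target = 2 ivory-like classes, 30 train / 100 test
spectra per class; full finetuning and from-scratch training both use 50
epochs (lr 0.001 and 0.01 respectively); results average 5 independent
target resamplings of a single pretrained encoder (pretraining randomness is
not the quantity under test; target sampling and finetuning randomness are).
Frozen-encoder classification uses labeled per-class k-means (k = 3) with
medoid prototypes.

## Numerical notes and limitations

* Training runs in float32; gradient checks run the same code in float64.
* Batch invariance of feature extraction holds to ~1e-4 absolute (float32
  accumulation order), asserted in tests.
* `exp(−d²)` similarities underflow to exactly 0 for very distant pairs;
  the (0, 1] bound is a real-arithmetic property.
* k-means empty clusters are re-seeded at the worst-fitted point; all ties
  throughout (medoids, typicality ranking, winner-takes-all) break toward
  the lowest index / earliest class, so results are permutation-stable.
* Multi-class LDA beyond nearest-class-mean prediction, evolving/streaming
  prototype updates, and vendor binary spectral formats are out of scope.
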