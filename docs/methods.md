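# Methods

## Problem setting

Given site-centered RNA windows labeled as carrying or not carrying a
5-hydroxymethylcytosine (5hmC) modification, learn a binary classifier
from sequence alone. The package assumes pre-deduplicated input (any
redundancy reduction, e.g. similarity-based filtering, happens upstream)
and balanced or near-balanced classes; no class weighting is applied.

## Sequence encoding

Seven encoders map a sequence of length `L` over {A,C,G,U} to a fixed
vector; their concatenation (in the fixed order Kmer, RC-Kmer, PseDNC,
PseTNC, TAC, TCC, DCC) is the 174-dimensional hybrid vector.

**Composition blocks.** The k-mer block is the sliding-window frequency
`count(w)/(L−k+1)` over all 4^k words in lexicographic order (k = 2 by
default, 16 features; configurable). The reverse-complement k-mer block
pools counts over reverse-complement equivalence classes (canonical form
= lexicographic minimum of word and its reverse complement; 10 classes at
k = 2), making the encoding strand-agnostic: it is invariant under
reverse complementation of the input, which plain k-mer composition is
not. PseDNC and PseTNC are implemented as the pure composition tier
(16 and 64 features, numerically identical to k = 2 and k = 3
composition); no correlation-tier terms are included, since the target
dimensionalities (16, 64) are exactly the plain composition sizes. All
composition blocks are non-negative and sum to 1.

**Covariance blocks.** For a physicochemical property `u` at granularity
`g` (di- or trinucleotide), the profile `P_u(i)` is the standardized
property value of the g-word starting at position `i`
(`i = 1..N`, `N = L−g+1`). The auto-covariance at lag `l` is

    AC(u,l) = 1/(N−l) · Σ_{i=1}^{N−l} (P_u(i)−P̄_u)(P_u(i+l)−P̄_u)

and the cross-covariance couples two distinct properties, ordered pairs
kept separate. TAC/TCC use 2 trinucleotide properties, DCC uses 6
dinucleotide properties, all at lags 1..2, giving 2×2 = 4, 2×1×2 = 4 and
6×5×2 = 60 features. The `1/(N−l)` normalisation is a deliberate choice
(the lagged-average convention of this descriptor family); covariances
vanish identically on homopolymers.

**Property tables.** The dinucleotide table ships as CSV with six RNA
conformational parameters (shift, slide, rise, tilt, roll, twist) drawn
from molecular-dynamics-derived values in the pseudo-composition
literature. The trinucleotide table (roll, twist) is derived as the mean
of a trinucleotide's two overlapping dinucleotide steps. Every table is
standardized to zero mean / unit variance across its 4^g words before
profiles are built, so descriptor magnitudes are comparable across
properties. The specific property sets and the lag bound are constrained
only by the target block dimensions (4/4/60); other property/lag
combinations of the same product would be admissible, so numeric parity
with any particular published feature matrix is not claimed. Users can
substitute their own CSV tables via `EncoderConfig`.

## Feature selection

Unsupervised PCA on the hybrid matrix, keeping 75 components by default
(alternatively a variance-retention fraction). Features are mean-centered
but not variance-scaled (covariance PCA; a `standardize` flag gives
correlation PCA). Component signs follow a deterministic convention — the
largest-magnitude loading of each component is positive — so serialized
models compare across runs. Inside cross-validation, PCA is fitted on each
fold's training rows only; fitting on pooled data leaks held-out
information into the variance structure and inflates CV estimates. A
`pooled_pca` flag reproduces the pooled variant for comparison, and an
integration test asserts that fold-specific models genuinely differ.

## Classifier

A fully connected network `input → 64 → 32 → 16 → 8 → 1`, ReLU hidden
activations (tanh available), sigmoid output, binary cross-entropy loss
with an L2 penalty `λ Σ‖W‖²` (λ = 1e-4), inverted dropout 0.4 on hidden
activations during training, He-uniform initialisation
(U[±√(6/fan_in)], zero biases), Adam (lr 0.01, β₁ = 0.9, β₂ = 0.999) on
mini-batches of 32 for 700 epochs with no early stopping. The
implementation is direct NumPy with explicit forward/backward passes; all
stochastic elements (init, batch order, dropout masks) draw from one
generator seeded by `DnnConfig.seed` (default 1234), so training is
bit-reproducible for a fixed config and data. Batch size and the BCE/Adam
pairing are this package's choices where the architecture description
leaves them open; four hidden layers and ReLU are the defaults because
they are the tuned optimum of the reference configuration, with tanh as
the documented alternative.

Grid search evaluates the Cartesian product of a parameter grid (default:
learning rates {0.008, 0.009, 0.01, 0.02, …, 0.07} × {ReLU, tanh}, 18
cells) by mean K-fold CV accuracy through the full pipeline. Failed cells
are recorded, not fatal. Ties break toward the lower learning rate, then
the first-listed activation — a fixed, documented rule so the argmax is
deterministic.

## Evaluation

Standard confusion-matrix metrics: Acc, Sn, Sp as percentages, MCC on
[−1, 1], recall and F1 as proportions (F1 also conventionally read ×100
in comparison tables; Sn ≡ recall×100 by construction, and both are
reported to keep the recall/F1 distinction explicit). Ratios with zero
denominators are NaN-with-warning, never silently 0 — a silent 0 would
corrupt grid-search selection. ROC curves come from a threshold sweep
with tied scores grouped, so the trapezoidal AUC equals the Mann–Whitney
pair-counting statistic (ties ½); a brute-force pair-counting oracle
cross-checks this in the tests. Cross-validation is stratified K-fold
(K = 10 by default and configurable, since the canonical fold count for
this task is not fixed; every report records K and the seed). Fold means
are arithmetic means over folds where the metric is defined. The ablation
harness produces one row per encoder plus the hybrid with/without PCA;
baseline classifiers (NB, SVM, KNN, RF, DT) are thin scikit-learn
adapters behind the same interface, included only for comparison tables.

## Synthetic data generator

`SyntheticSpec` generates balanced two-class sets of equal-length
sequences (default 41 nt — a typical site-centered window; default shape
662+662 mirroring the published benchmark scale). Positives carry
(a) a planted motif (default `GGCAUGCCGG`) at a uniform random position
with probability `motif_prob`, and (b) a first-order Markov
dinucleotide-composition bias of magnitude `composition_shift` (default
0.3) that boosts Watson–Crick-paired steps (CG/GC/AU/UA), so signal
reaches the covariance blocks and not only the composition blocks.
Negatives are i.i.d. from the background (default uniform). The defaults
were chosen once so that `motif_prob = 1` constitutes a strong,
comfortably recoverable signal (pipeline 10-fold CV accuracy well above
90% at n = 400) while `motif_prob = 0, composition_shift = 0` (the
`null_dataset` route) is exactly label-independent, giving chance-level
accuracy and near-zero MCC. What passing these tests shows is that the
pipeline recovers planted compositional/motif structure and does not
hallucinate signal from noise; it does not show that real 5hmC sites are
predictable at any particular accuracy — real-sequence performance
depends on the biology and the benchmark, which the generator does not
model.

## Numerical and design choices

* Input normalisation uppercases and maps T→U; ambiguity codes are
  rejected rather than skipped, because every encoder assumes a complete
  profile.
* Minimum sequence length is `3 + lag` so every covariance encoder is
  computable; violations raise errors naming the offending sequence.
* The stratified hold-out split rounds per class (`round(f·n_class)`), so
  a 662+662 set at 10% yields exactly 66+66 = 132.
* Sigmoid is computed in a numerically stable split form; training loss
  records cross-entropy plus the L2 penalty per epoch.
* PCA `n_components` must satisfy `n ≤ min(rows−1, cols)`; the CV driver
  pre-checks the per-fold bound and reports it.
* Problem sizes in the test suite and acceptance script (n = 400 for
  signal recovery, 5 seeds × n = 400 for null calibration, reduced-epoch
  configs in unit tests that only need a trained model) are the package's
  own choices to keep the default runs fast while leaving the study
  conditions — full 700-epoch training for the headline runs — intact.

## Known limitations

* The physicochemical tables are one defensible instantiation; descriptor
  values (TAC/TCC/DCC blocks) change under a different property set even
  though dimensions are preserved.
* The NumPy network is CPU-only and single-threaded per fold; it targets
  datasets of thousands of sequences, not millions.
* PseDNC/PseTNC omit the classic correlation-tier (λ > 0) pseudo
  components by design.
* No statistical significance testing between classifiers; the comparison
  harness reports point metrics only.
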