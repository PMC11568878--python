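# Methods

## Problem setting and data model

A sample is a 41-nucleotide RNA window centered on a candidate
2'-O-methylation site (flank 20; the site is position 21 of 41, 1-based).
Positives come from verified site lists; negatives are windows centered
on unmodified residues drawn uniformly within a ±500-nt vicinity of each
positive (15 per positive by default) so that local composition is
matched without restricting the center base — per-base (Am/Cm/Gm/Um)
stratification happens on the finished windows. Windows running off a
sequence end are rejected rather than padded; T is normalized to U and
lowercase to uppercase on input; a window whose center is N is an error.
Datasets are split 60/10/30 (positives; floor rounding, remainder to
train) with validation and test negatives drawn to exactly 10× their
positive counts, mirroring realistic imbalance at evaluation time.
Training subsets TS_1..TS_10 contain all training positives plus k×
positives negatives; the negative sets are nested across k (one fixed
shuffle, prefixes of increasing length) so that ratio effects are not
confounded by resampling noise. Every stage is a pure function of its
seed; the whole dataset build is bit-reproducible.

Redundancy removal is delegated: the builder accepts a pre-deduplicated
id list and records the similarity threshold (40%) in the run manifest
only; no clustering tool is run.

## Feature encodings

* **One-hot**: L×4 indicators, column order (A, C, G, U); N maps to the
  all-zero row (zero-information convention).
* **Z-curve**: rows n = 1..L of the cumulative walk
  x_n = (A_n+G_n)−(C_n+U_n), y_n = (A_n+C_n)−(G_n+U_n),
  z_n = (A_n+U_n)−(G_n+C_n). The origin row is not stored. N advances no
  count (coordinates repeat). Coordinates are fed to the network as raw
  integers; a 1/L scaling is available behind `ModelConfig.z_scale`
  (off by default — batch normalization after the first convolution
  absorbs the scale). The mapping is invertible:
  A_n = (n+x+y+z)/4 etc.; `z_curve_invert` validates integrality and
  nonnegativity and is used as the round-trip test of the encoder.
* **Pairing matrix**: symmetric binary L×L with zero diagonal and row
  sums ≤ 1, built from a dot-bracket string by stack matching.

## Secondary structure

Two backends stand behind one `fold()` entry point. The **builtin**
backend is Nussinov base-pair maximization: dynamic programming over
spans with a minimum loop of 3 unpaired bases (pairs only when
j − i > 3), allowed pairs {AU, UA, GC, CG, GU, UG}, N never pairing, and
a deterministic traceback (prefer unpaired j, then the smallest partner
k) so the structure is a function of the sequence alone. It maximizes
pair count, not free energy; that makes it exactly checkable against
brute-force enumeration, which the tests and the acceptance script do
for all sequences of length ≤ 12. The **vienna** backend shells out to
`RNAfold` (MFE structure, backend-default temperature) when the
executable is on PATH and is the recommendation for real transcripts,
since thermodynamic folding is closer to physiological structure than
pair-count maximization. The builtin backend is the default so that
results are reproducible with no external binary.

## Model

Per window: the one-hot (L×4) and Z-curve (L×3) channels each pass
through a two-layer same-padded 1D CNN block; the pairing matrix passes
through a two-layer 2D CNN block and is collapsed to per-row tokens by
mean over the partner axis. Batch normalization follows every
convolution; PReLU (one learned slope per channel) is the activation
everywhere; each branch ends in a 1×1 projection to d_model channels.
The branch token maps are concatenated along the token axis and pass
through 4-head scaled-dot-product self-attention
(softmax(QKᵀ/√d_k)V per head, concatenated, projected by W^O) with a
residual connection Y = X + MultiHead(X). The attention output is
**flattened** (position-preserving) into an MLP with strictly
decreasing hidden sizes, dropout 0.05 and PReLU between layers, a final
2→1 projection, and a sigmoid. The flattened readout is a deliberate
design choice: site context
is position-specific relative to the window center, and a globally
pooled readout makes the convolutional branches translation-invariant —
in controlled experiments a pooled model plateaued near AUROC 0.92 on
data a logistic regression solved at 0.99, while the flattened readout
closed the gap. Mean and max readouts remain available
(`ModelConfig.token_pool`).

Two presets exist. `ModelConfig.default()` is the full-width
architecture (1D channels 32/64, 2D 16/32, d_model 64, MLP 128→…→2).
`ModelConfig.small()` is the desk-scale preset used by the end-to-end
pipeline and all shipped experiments: channels 8/16 and 4/8, d_model 32,
MLP 32→…→2, window-mean pooling by 2 after each convolution and on the
pairing input. Published tools of this family do not document their exact filter
counts, so neither preset claims equivalence to any of them; the small
preset is sized so a full five-fold run trains in minutes on one CPU core
(~9.4k parameters, ~60 ms per 64-window training batch).

The network, its layers and all gradients are implemented on numpy in
float64; every layer and the assembled model are verified against
central finite differences in the test suite. Initialization is
He-normal, seeded; a model built twice from one seed is bit-identical.
Checkpoints serialize the config plus every tensor (including
batch-norm running statistics) and reload bit-exactly.

## Loss and training

The asymmetric loss is the batch mean of (1 − p_t)^γ · WBCE(p, y) with
p_t = p·y + (1−p)(1−y) and WBCE = −[w·y·log p + (1−y)·log(1−p)].
γ = 2 by default; w re-weights the positive class (scanned over 0.1–2.0 and
selected on validation data).
Probabilities are clipped to [10⁻⁷, 1−10⁻⁷] inside the loss; the
analytic gradient (finite-difference-verified) is zero in the clipped
region. Optimization: AdamW (lr 10⁻³, decoupled weight decay 10⁻⁶),
cosine annealing with period = max_epochs (no warm restarts), global gradient-norm
clipping at 10, batch size 64. The output bias of the final projection
is initialized to the training-set log-odds so the first epochs are not
spent learning the base rate — standard practice for rare-positive
detection; under 1:10 imbalance it removes roughly eight wasted epochs.

Early stopping monitors MCC on the fold-internal hold-out (patience 10);
the unified validation set is reserved for ensemble weighting and
threshold calibration, keeping the two roles separate. A configuration
flag switches the monitor to the unified set. Folds are class-stratified
so both classes appear in every fold at 1:10 imbalance; fold assignment,
initialization and batch shuffling all derive from the run seed.

## Ensemble and decision threshold

The five CV models are combined as ŷ = Σ w_i f_i(x), w on the 4-simplex.
Weights are found by Bayesian optimization of validation MCC: a
Gaussian-process surrogate (Matérn 5/2, observation noise 10⁻⁶,
normalized targets) over the box [0,1]⁵ whose points are normalized onto
the simplex (the all-zero point is rejected), expected-improvement
acquisition (ξ = 0.01) maximized over a random candidate pool, 50
iterations after an initial design of 10 points that always contains the
equal-weight vector and the five vertices. By construction the returned
MCC is at least that of soft voting and of every single model on the
optimization set. Hard voting (odd model counts only) and soft voting
are provided as baselines. MCC during the search thresholds ŷ at 0.5.
After the weights are fixed, the final classification threshold is
calibrated on the same validation set (MCC-maximizing scan over score
midpoints); models trained under heavy imbalance are systematically
under-confident, and the calibrated cutoff converts good ranking into
good thresholded decisions without touching test data. Calibration can
be disabled (`calibrate=False`), reverting to 0.5.

## Metrics

ACC, Recall, PRE, MCC, AUROC and F1 from the thresholded confusion
matrix (probability ≥ threshold ⇒ positive call); AUROC by the
Mann–Whitney rank statistic with the ½-tie convention, which equals
trapezoidal integration of the ROC curve (asserted to 10⁻¹² against
sklearn). Degenerate cases are total: PRE/F1 with no predicted positives
report 0 and are flagged; an MCC with a zero marginal reports 0; AUROC
on single-class input raises where required and is flagged in the
aggregate report.

## Synthetic data

The generator emulates the geometry of the real task — 41-nt windows,
configurable imbalance up to 1:10 — with a planted, tunable signal.
Positives carry a 6-nt motif at offsets −3..+2 (overlapping the center,
so the center base is informative); each motif position carries the
motif base with probability `motif_fidelity` and otherwise a uniform
draw from the other three bases, making fidelity 0.25 exactly the null
under the uniform background and fidelity 1.0 the exact motif. The
default motif length (6) is short enough for CPU training and long
enough that the 1:10 task is nontrivial. With `structure_bias="hairpin"`
positives additionally carry complementary 6-nt arms at ±(11..16) so a
stem spans the center and the structure channel becomes class-informative.
`signal_check` reports the per-position total-variation distance between
class base frequencies and flags positions above 0.2. What the generator
does not emulate: real human Nm context statistics, transcript
composition gradients, or sequence redundancy — so passing the
end-to-end checks demonstrates that the pipeline can extract a planted
local signal under imbalance, not field performance on real data.

## The end-to-end protocol and problem sizes

The shipped end-to-end run (pipeline defaults, also used by the
acceptance script) is: 200 positives + 2000 negatives at fidelity 0.9,
60/10/30 split, training on the TS_10 rung, builtin folding, five-fold
CV with the small preset, positive weight w = 2.0 (selected by unified-
validation MCC, the same route the ratio/weight grid search uses),
max_epochs 60 / patience 10, Bayesian weighting and threshold
calibration on the unified validation set, metrics on the untouched test
partition (60 positives / 600 negatives). One such run takes roughly two
minutes on a single core. Across seeds 1–5 the measured test MCC was
0.69–0.83 (AUROC 0.97–0.99); the null-fidelity control (fidelity 0.25)
yields MCC ≈ 0. For reference, the Bayes-optimal motif-likelihood
classifier on this task scores MCC ≈ 0.93 and a logistic regression on
the one-hot channel ≈ 0.81–0.90, bracketing the network's desk-scale
performance.

## Numerical choices and degenerate inputs

float64 throughout the network; probability clipping 10⁻⁷ in the loss;
batch-norm ε 10⁻⁵, momentum 0.1, inference on running statistics;
softmax stabilized by row-max subtraction; ties in the Nussinov
traceback broken deterministically; empty sequences fold to empty
structures; empty batches, out-of-domain labels, single-class
validation sets, unbalanced dot-brackets, out-of-bounds windows and
N centers all raise named exceptions.

## Known limitations

The builtin folder maximizes pair count, which overpairs relative to
thermodynamic structures; use the ViennaRNA backend for biological
structure. The numpy implementation is single-core and desk-scale —
training the full-width preset on realistic dataset sizes calls for a
GPU framework. Ensemble-weight optimization and threshold calibration
share one validation set; with very few validation positives both can
overfit it (the pipeline's validation partitions keep ≥ 20 positives).
The synthetic generator's independence assumptions (i.i.d. background,
single motif) make its tasks easier than real transcriptome context.
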