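# nm-sitekit

Prediction of 2'-O-methylation (Nm) sites in RNA from local sequence and
structure context.

Nm is a ubiquitous post-transcriptional modification of the ribose
2'-hydroxyl that can occur on any base (Am, Cm, Gm, Um) and modulates RNA
stability, secondary structure and innate-immune recognition. Experimental
mapping (Nm-seq and relatives) is laborious, so computational screening of
candidate sites matters — but verified sites are vastly outnumbered by
unmodified residues, which makes precision under class imbalance the hard
part. This package is for computational biologists who want a
transparent, CPU-only, fully testable implementation of a modern Nm-site
classifier: every stage from dataset construction to ensembled prediction
is an importable, seeded function.

## The method

A candidate site is represented by its **41-nt window** (20 nt of flank on
each side; the site is position 21). Each window is encoded three ways:

* **one-hot** — an L×4 indicator matrix, columns (A, C, G, U);
* **Z-curve** — the cumulative 3-D walk (x_n, y_n, z_n) with
  x_n = (A_n+G_n) − (C_n+U_n), y_n = (A_n+C_n) − (G_n+U_n),
  z_n = (A_n+U_n) − (G_n+C_n), where A_n..U_n are base counts of the
  length-n prefix (purine/pyrimidine, amino/keto, weak/strong axes; the
  mapping is exactly invertible);
* **pairing matrix** — the symmetric binary L×L base-pair matrix of the
  window's secondary structure, from either a built-in Nussinov
  base-pair-maximization folder (deterministic, exactly testable) or
  ViennaRNA's `RNAfold` when installed.

The classifier is a hybrid network: two-layer 1D CNN branches for the
one-hot and Z-curve channels, a two-layer 2D CNN branch for the pairing
matrix (collapsed row-wise to per-position tokens), batch normalization
and PReLU throughout; the branch tokens are concatenated, passed through
4-head scaled-dot-product self-attention with a residual connection
(Y = X + MultiHead(X)), flattened, and classified by an MLP ending in a
sigmoid. Training minimizes an **asymmetric loss**

    L = mean_i (1 − p_t,i)^γ · ( −[ w·y_i·log p_i + (1−y_i)·log(1−p_i) ] ),
    p_t,i = p_i y_i + (1−p_i)(1−y_i),

i.e. focal modulation (γ = 2) of a weighted BCE (positive-class weight w),
with AdamW (lr 10⁻³, weight decay 10⁻⁶), cosine-annealed learning rate,
gradient-norm clipping at 10, batch size 64, and early stopping on
validation MCC (patience 10). Five-fold cross-validation yields five
models whose probabilities are combined as ŷ = Σ w_i f_i(x) with
nonnegative weights on the simplex, found by **Bayesian optimization**
(Gaussian-process surrogate, expected improvement) of the Matthews
correlation coefficient on a validation set; because the initial design
contains the equal-weight point and all five vertices, the optimized
ensemble never scores below soft voting or any single model there. The
network and its backpropagation are implemented directly on numpy and
verified against finite differences.

## Worked example

```python
from nmsitekit import SyntheticSpec, z_curve_encode
from nmsitekit.pipeline import end_to_end

print(z_curve_encode("GGACU").tolist())
# [[1, -1, -1], [2, -2, -2], [3, -1, -1], [2, 0, -2], [1, -1, -1]]
# row n is (x_n, y_n, z_n): two G's drive x up (purines) and y, z down.

spec = SyntheticSpec(n_pos=200, n_neg=2000, motif_fidelity=0.9, seed=2)
res = end_to_end(spec, ratio_k=10, seed=2)
print({k: round(v, 3) for k, v in res.report.as_dict().items()})
# {'ACC': 0.973, 'Recall': 0.783, 'PRE': 0.904, 'MCC': 0.827, 'AUROC': 0.983, 'F1': 0.839}
```

The pipeline generates a 1:10-imbalanced synthetic dataset with a planted
center-proximal motif (retained per position with probability 0.9), splits
it 60/10/30, folds and encodes every window, trains the five-fold ensemble
and reports metrics on the untouched test partition: MCC 0.83 with
precision 0.90 means the ensemble recovers most planted sites with few
false alarms despite the imbalance; AUROC 0.98 says the ranking is nearly
perfect. The run takes about two minutes on one CPU core.

The same stages are available as a thin CLI —
`nm-sitekit synth | make-dataset | fold | encode | train | predict |
evaluate` — and as short narrative scripts under `examples/`.

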