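# Methods

## Problem setting

The package infers population structure in panels of inbred (near-fully
homozygous) lines genotyped at biallelic SNPs. Because selfed lines are far
from Hardy–Weinberg equilibrium, model-based Bayesian clustering is either
inapplicable or extremely slow; the route implemented here is entirely
assumption-free: numeric encoding → dimensionality reduction → unsupervised
clustering → internal validity indexes → (optionally) supervised scoring
against known subpopulation labels.

## Input filtering

Loci are kept when the minor allele frequency is **strictly** greater than
`maf_min` (default 0.15) and the missing fraction is at most `max_missing`
(default 0, i.e. no missing data). MAF is the count of the second most
frequent observed allele over the non-missing count; monomorphic loci have
MAF 0 and are always dropped at the default threshold. Boundary loci
(MAF exactly 0.15) are dropped. Heterozygous and IUPAC-ambiguous calls are
mapped to missing on input — the inbred-line convention; `strict=True`
raises instead. The missing sentinel is `N` (`-` and `.` accepted on
input).

## Encodings

One-hot uses the fixed channel order (A, T, G, C) — not alphabetical —
with missing calls encoded as the all-zero 4-block; columns are
locus-major. Label encoding maps A:0, T:1, G:2, C:3 with the reserved code
−1 for missing, which numeric downstream stages reject. Decoding is
per-block argmax with ties broken toward the earlier channel and all-zero
blocks mapping back to missing.

## Autoencoder

A symmetric dense network: input 4L → encoder widths (default 2000, 700) →
bottleneck (default 40) → mirrored decoder → 4L, ReLU on every hidden layer
including the bottleneck, and a per-locus 4-way softmax output head. The
loss is the mean, over samples and non-missing loci, of the categorical
cross-entropy −Σ_c y_c log p_c; missing blocks carry no target mass and are
excluded from the denominator. An element-wise sigmoid head with binary
cross-entropy is available as a configuration alternative (`loss="binary"`).

Training is minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at learning
rate 0.001, sample order reshuffled each epoch from the seed. Defaults are
200 epochs with batch size 32; early stopping on the training loss is
available but off by default. There is no train/validation split by
default (the task is unsupervised reconstruction); `depth_search` accepts
an optional holdout fraction and ranks encoder depths 1–4 via a geometric
width schedule between the first and last default widths.

Everything is plain NumPy with explicit backpropagation. Weights are
He-uniform, seeded; analytic gradients are verified against central finite
differences in the test suite (< 1e−5 relative error). Identical seeds give
bit-identical runs in a fixed BLAS configuration.

**Initialisation of biases.** Hidden biases start at +0.01 rather than 0.
With zero biases, any sample whose bottleneck activations are all zero
produces decoder pre-activations exactly at the ReLU kink, and whole
embedding rows can collapse to a single point. The small positive offset
keeps units initially active. Dead-unit collapse can still occur during
training on very narrow bottlenecks (e.g. 8 units over small panels): the
decoder-bias-only solution — reproducing per-locus marginal frequencies,
loss ≈ the mean locus entropy — is an early attractor, and units that go
negative for every sample never recover. Partial unit death is common and
harmless (surviving units carry the structure); a fully collapsed
embedding triggers a `RuntimeWarning` from `encode()`. Practical guidance:
keep the bottleneck ≥ 16 and widths ≥ [128, 64] for panels of 50–200
lines.

**Training length.** The loss has a natural reference point: the mean
per-locus entropy of allele frequencies (the best sample-independent
predictor, ≈ 0.5–0.6 nats for MAF-filtered biallelic loci). Training well
past that point makes the network memorise individual lines, which inflates
within-cluster spread in the embedding and can fragment clusters; training
that stops around it captures population-level structure. For desk-scale
panels (≈ 120 lines × 1,000 loci) the package's study configuration uses
encoder widths [256, 64], bottleneck 16, batch 16, and 25 epochs, which
lands near that reference point and yields silhouette values at K = 2
around 0.6–0.8 on separable panels.

## PCA baseline

SVD of the column-centered one-hot matrix (no scaling). Component signs
are fixed so each component's largest-magnitude loading is positive,
making fits bit-reproducible. Default 40 components, matching the
autoencoder bottleneck for a like-for-like comparison. Label-encoded input
is accepted with a warning: it imposes an artificial ordinality A<T<G<C.

## Clustering

K-means is Lloyd's algorithm with k-means++ seeding, best of 10 seeded
restarts by within-cluster sum of squares, a 300-iteration cap, and
empty-cluster repair by reassigning the farthest point; the WCSS is
asserted non-increasing across iterations on every run. Hierarchical
clustering delegates to scipy's agglomerative linkage (Ward default;
average/complete/single configurable) on Euclidean distances, cut at K by
`maxclust`; labels are renumbered by first appearance. Distances are
Euclidean in the embedding space for both methods.

## Validity indexes and K selection

Silhouette and Davies–Bouldin are computed natively (vectorised NumPy) in
the same space used for clustering, and are cross-checked in the tests
against both brute-force reference implementations (agreement to 1e−12)
and scikit-learn. Conventions: singleton clusters get s(i) = 0; the
degenerate a = b = 0 case gives s(i) = 0; coincident centroids make the
Davies–Bouldin ratio undefined and raise. The K scan covers 2–9 by
default. Selection is argmax silhouette (ties toward smaller K); argmin
Davies–Bouldin is available, and `selection_report` flags disagreement
between the two rather than resolving it silently. For the label-encoding
baseline the indexes are computed on the label matrix itself (no
reduction).

## Assignment scoring

Predicted clusters are matched to true subpopulations by the injective map
maximising the matched count (Hungarian assignment; identity-order mapping
preferred on ties). %CA = 100 · matched / n, reported unrounded and
rounded half-up to an integer percent. When K ≠ G, unmatched clusters
contribute zero correct assignments.

## Synthetic panels

The generator draws, per locus, an ancestral frequency uniform over the
configured MAF range (reflected into (0,1) with probability ½), then
subpopulation frequencies from the Balding–Nichols Beta distribution with
differentiation parameter F (exactly p_k = p at F = 0). Each line is fully
homozygous — the selfing limit — drawing one allele per locus; the two
alleles of a locus are two distinct nucleotides sampled without
replacement, so all four letters occur across loci. Defaults emulate a
two-subpopulation maize panel (97 + 86 lines, 4,812 loci, MAF > 0.15, no
missing data). A Hudson-style FST estimator (ratio of averages across
loci, averaged over subpopulation pairs) serves as a self-check; at the
study scale (60+60 lines, 1,000–2,000 loci) it recovers the simulated F
within ±0.05.

What the simulator does **not** emulate: linkage disequilibrium between
loci (draws are independent), admixed individuals, residual
heterozygosity, genotyping-error structure beyond uniform missingness, and
unequal locus information content along chromosomes. Passing recovery
tests on these panels therefore demonstrates that the pipeline machinery
works and scales as intended, not that real GBS panels of any given FST
will reach the same accuracies.

## Study configuration used in tests and the acceptance script

Panels: 2 subpopulations × 60 lines, 1,000 loci, FST 0.3 (separable
regime) and 0.0 (null), seeds 1–5, filtered at the default thresholds
(≈ 700–750 loci survive). Autoencoder: widths [256, 64], bottleneck 16,
25 epochs, batch 16. Measured on these conditions: the silhouette scan
selects K = 2 for the autoencoder + hierarchical route on all five seeds;
autoencoder-HC and PCA-HC median %CA = 100 at FST 0.3 and 53–57 at FST 0
(chance regime); silhouette at K = 2 orders autoencoder ≈ 0.6–0.8 > PCA
≈ 0.29 > label encoding ≈ 0.17.

## Numerical choices and degenerate inputs

* Rounding of %CA: half-up to integer percent (`floor(x + 0.5)`).
* K-means ties and restarts: deterministic from the seed; empty clusters
  repaired by farthest-point reassignment.
* Softmax is computed with per-block max subtraction; cross-entropy adds
  1e−12 inside the log.
* Non-finite training loss aborts immediately with a diagnostic.
* All-missing loci have undefined MAF, are flagged, and are always
  filtered; filtering that removes every locus raises.
* t-SNE (visualisation only) is delegated to scikit-learn with
  perplexity 30, 1,000 iterations, learning rate 200, and requires
  perplexity < (n−1)/3; the pipeline skips the t-SNE panel (with a
  manifest note) when infeasible.

## Known limitations

* The native autoencoder is CPU-bound and single-threaded-deterministic;
  paper-scale panels (183 × 4,812 at widths 2000/700) train in minutes,
  not seconds, and GPU backends are out of scope.
* Hierarchical clustering inherits scipy's tie-handling; for data with
  exactly tied distances the cut can return fewer than K clusters (ties
  are merged), which downstream validation reports as an error.
* The label-encoding baseline is included for comparison only; its
  ordinality artefact is documented and warned about in PCA.
* VCF support covers biallelic SNP records with GT fields; multi-allelic
  records and indels are rejected rather than coerced.
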