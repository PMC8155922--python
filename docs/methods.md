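# Methods

This note documents the models, defaults and design choices behind
`mrsport`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A *study* is one CSI session: a `grid_rows × grid_cols` voxel grid
(default 16×16 = 256 voxels, the typical 2D-CSI acquisition), a voxels ×
34 metabolite intensity table, an optional raw spectrum per voxel
(ppm axis + intensities), and a per-voxel segmentation label drawn from
{NAM, LESION, TUMOR, CONTRAST, NECROSIS, FLAIR, VENTRICLE, EXCLUDED}.
Grid coordinates are 0-based and row-major. The 34-metabolite list is a
standard short-TE basis (NAA, NAAG, Cr, PCr, GPC, PCh, Ins, Lac, …); only
its length is structural — the list is configurable. All study I/O is
plain TSV/JSON and round-trips losslessly to 1e-12.

## Synthetic phantoms

Real cohorts of this kind are available only on request from clinical
sites, so phantoms are first-class. Each phantom paints tissue regions in
painter's order — NAM background, a ventricle rectangle, and for glioma
subtypes a tumor disc (radius ~3 voxels) with a FLAIR/edema annulus and,
for `wt`, a necrotic core. Per-voxel metabolite vectors are drawn
log-normally around the tissue mean (metabolite intensities are positive
and right-skewed; default CV 0.2); the stored table adds clipped Gaussian
quantitation noise (sd 0.3 intensity units). Raw spectra are sums of
Lorentzian basis peaks scaled by the true per-voxel amplitudes, plus a
random low-order polynomial baseline and white noise (sd 0.05); the ppm
axis is 0.2–4.2 ppm, 512 points, covering every region of diagnostic
interest (NAA 2.0, choline 3.2, lactate 1.3, lipids/macromolecules
0.6–1.0 ppm).

Tissue signatures encode the qualitative in-vivo picture: NAA/Cr dominate
normal matter; tumor voxels lose NAA; `wt` (glioblastoma-like) tumors gain
lactate, lipids and macromolecules; both IDH-mutant groups gain
glycerophosphocholine; edema gains myo-inositol; necrosis is dominated by
lactate and lipids. The two IDH-mutant groups are deliberately also
separated in Gly/Cit/NAAG — in vivo these two groups overlap strongly and
are the hardest pair to distinguish, but identifiable signatures are
required for the generator to serve as ground truth for end-to-end
recovery tests. **Consequently, passing the recovery tests shows the
pipeline machinery is correct, not that real IDH-mutant vs codeleted
discrimination is this easy.** The generator also ignores J-coupling
multiplets, relaxation weighting, shim/field artifacts and partial-volume
mixing at region boundaries.

The default basis assigns each metabolite 1–3 Lorentzian peaks at
standard 3T short-TE positions. Near-degenerate species (Cr/PCr at 3.03
ppm; lactate vs. lipid-1.3) are given distinct secondary peaks and
linewidths so that the linear system is identifiable — a precondition for
amplitude-recovery guarantees (condition number of the 512×34 template
matrix ≈ 11).

## Preprocessing

* **Baseline correction**: iteratively-reweighted polynomial fit
  (10 iterations, asymmetric weights 1 below / 0.01 above the current
  fit). Assumes positive peaks over a smooth low-order baseline.
* **Quantitation**: non-negative least squares against the basis template
  matrix. This is a deliberately simple stand-in for full time-domain
  fitting (no lineshape, phase or frequency-shift estimation, no
  water-reference scaling).
* **Quality filter**: voxel passes iff its fit residual RMS ≤ 3× the
  study median. Clinical practice reviews residuals manually; a relative
  rule is the only automatable analogue, and it is scale-invariant by
  construction. Failing voxels are relabeled EXCLUDED.
* **Normalization**: per-metabolite min-max to [0, 1]. Constant columns
  map to zero (an absent metabolite stays at the low end of the sigmoid
  range). Statistics are learned on training data only and reused for
  held-out data (clipped to [0, 1]) to prevent leakage.

## Autoencoder

Mirrored architecture 34→32→16→8→(6)→8→16→32→34, sigmoid activations
throughout, batch normalization after the affine transform and before the
sigmoid on the three encoder hidden layers, dropout 0.1 on the encoder
hidden activations (training only; not the bottleneck, decoder or
output — dropout inside the decoder measurably blurs small-variance
structure, such as subtle subtype signatures, out of the reconstruction
while also worsening held-out reconstruction loss).
Loss is the mean squared reconstruction error over matrix entries (a
norm divided by size, so thresholds are size-independent). Training:
Adam, learning rate 1e-3, mini-batch 32, 500 epochs, internal 2/3–1/3
row split for the loss history. Weights are Glorot-uniform, biases zero.
Everything — forward pass, backpropagation through batch norm, Adam — is
implemented directly on NumPy arrays, which keeps training bit-for-bit
reproducible for a fixed seed on one thread; matrices of a few thousand
voxels train in seconds to a couple of minutes.

Bottleneck selection retrains over widths 4–10 and scores each denoised
matrix by the variance share of its first two principal components; ties
break toward the smaller network. Candidate widths not strictly smaller
than the last encoder hidden width drop the conflicting hidden layers
(e.g. widths 8–10 use a 32→16 encoder), since a bottleneck must be the
narrowest layer.

## Unsupervised characterization

PCA keeps the first 30 components (sign convention: largest-magnitude
loading positive). *Non-trivial* components are selected by parallel
analysis: each metabolite column is permuted independently (20
randomizations), and a component is kept while its eigenvalue exceeds the
95th percentile of the permuted spectrum at the same rank (contiguous
leading run). The 95th percentile, not the ensemble mean, is used: on a
pure-noise matrix the observed eigenvalues are exchangeable with the
permuted ones, so a mean threshold would flag a spurious leading
component about half the time. A fixed component count can override the
adaptive rule (`fixed_n_components`).

SNN clustering builds a k=20 Euclidean kNN graph (neighbor sets include
the point), weights edges by Jaccard overlap of neighbor sets, prunes
weights < 1/15, and runs Louvain on the weighted graph. Two non-obvious
choices: (1) Louvain resolution defaults to 0.2, because at resolution 1
modularity maximization fragments large internally-homogeneous kNN
components into arbitrary sub-communities; (2) points are reordered
canonically (lexicographic) before community detection, making the
labeling invariant to input row order. Cluster count is emergent, not
fixed. The 2-D embedding is UMAP (n_neighbors 15, min_dist 0.1, fixed
random state).

Cluster markers: per (cluster, metabolite), a two-sided Wilcoxon
rank-sum test of in-cluster vs rest (exact for small groups), effect size
log2 ratio of means (floored at machine epsilon), Benjamini–Hochberg
adjustment across all pairs; a marker has adjusted p < 0.05 and positive
effect. Clusters with fewer than 3 voxels are skipped with a warning.

## Prediction model

Features for both discriminant layers are the autoencoder-denoised
normalized metabolite vectors (a latent-space variant can be assembled
from `encode`, but the denoised space is the default). The Fisher
discriminant uses the unweighted between-class scatter
Σ_b = (1/C) Σ (μᵢ−μ)(μᵢ−μ)ᵀ with μ the unweighted mean of class means,
and pooled within-class scatter Σ/(n−C) with ridge λ·trace(Σ)/p
(λ = 1e-4), because small synthetic cohorts can make Σ rank-deficient.
Directions are the top C−1 generalized eigenvectors, unit-normalized with
a deterministic sign. Posteriors are softmax over shared-covariance
Gaussian log-densities in the projected space; argmax ties break by class
order.

Layer 1 classifies regions. Segmentation labels map to training classes
as NAM→NAM, LESION→LESION, TUMOR/CONTRAST/NECROSIS→TUMOR, and
FLAIR/VENTRICLE→OTHER. The catch-all OTHER class exists because a region
model that never saw CSF will force ventricle voxels into one of its
classes at prediction time and contaminate the tumor mask — with it, an
all-normal study correctly yields an empty mask and a "no tumor detected"
outcome. The tumor-mask threshold is a posterior of 0.5.

Layer 2 is trained on tumor-region voxels of patients with known subtype.
Its scores are calibrated per class against the training-score
distribution (Gaussian center/scale, i.e. z-scores; parameters stored for
reuse — calibration is monotone per class and never changes within-class
rankings). The patient score is the per-class mean of calibrated scores
over the tumor mask; the predicted subtype is its argmax.

Evaluation: the cohort is split 2/3–1/3 *by patient* (stratified by
subtype), so no voxel of a held-out patient influences normalization,
autoencoder or discriminant training; a voxel-level split mode exists
behind a flag for comparison, since within-patient correlation makes
voxel-level splits optimistic. Reported metrics: held-out patient-level
subtype accuracy, voxel-level region accuracy, one-vs-rest rank-based AUC
per subtype (midrank tie handling), and the confusion matrix.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  run configuration; derived seeds stay below 2³¹.
* Pipeline artifacts (TSV/JSON) are written with fixed float formatting
  and sorted keys; two runs with the same config and seed are
  byte-identical (asserted in the test suite).
* Degenerate inputs: constant metabolite columns are flagged and mapped
  to zero; rank-deficient basis matrices warn and return the least-norm
  NNLS solution; an all-failing quality filter, an empty cohort request,
  a class with fewer than two samples, and zero score variance in
  calibration are hard errors.
* Problem sizes in tests and the acceptance script are chosen for
  single-CPU runs: 200–300-row matrices and 200 epochs for the denoising
  benchmark trials, a 30-patient cohort (256 voxels each, tables only,
  no spectra) for end-to-end recovery, 20 patients for the paired
  two-layer comparison, 100 trials for component-selection rates and 200
  simulations for marker null calibration.

## Known limitations

* The quantitation stand-in is linear and frequency-domain; it cannot
  model phase errors, lineshape distortion or baseline/metabolite
  cross-talk the way full time-domain fitters do.
* The phantom's subtype effect sizes make the classification problem
  nearly separable; accuracy/AUC numbers on phantoms say nothing about
  clinical discriminability of glioma subtypes.
* The autoencoder treats the 34 metabolite intensities as exchangeable
  features; no spatial context (neighboring voxels) is used anywhere in
  the model.
* UMAP determinism is guaranteed per installed library version and
  platform, not across versions.
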