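# Methods

This note documents the modelling choices, defaults, and limitations of
the package, in the order the pipeline runs.

## Input model and preprocessing boundary

The pipeline begins at parcellated data: one delimited-text matrix per
scan, M timepoints × N ROIs, holding ROI-mean BOLD signals. Everything
upstream — slice-timing and motion correction, nuisance regression,
registration, spatial smoothing, atlas parcellation, and motion-based scan
exclusion — is assumed done by standard imaging tools and is out of scope;
quality-control rules defined on image-space quantities (e.g. frame
displacement) have no representation at the ROI-series level and must be
applied upstream. The only temporal preprocessing performed here is the
discard of the first `k` volumes (default 3, configurable; pass 0 for
already-trimmed inputs), applied at load time so that all downstream
arithmetic sees the trimmed length (140 → 137 with the defaults).

## dFC construction

Windows are rectangular, 0-based, half-open, of length L (default 70
timepoints) at stride S (default 2); a trailing partial window is dropped,
so T = ⌊(M−L)/S⌋+1 (34 for M=137). Tapered windows, Fisher z-transforms,
thresholding and sparsification are deliberately absent: the raw Pearson
matrices feed the model. Zero-variance window segments (possible in
degenerate or synthetic data) would produce NaN correlations; instead every
entry involving a constant column — including its diagonal — is set to 0
and a warning is logged, keeping tensors finite while marking the ROI as
carrying no correlation information in that window.

## Network

The three convolutions are all "valid" (unpadded); the printed shape chain
(T → T−1 → T−3 → T₁ = 13 with kernels 2/2/8 and third-layer temporal
stride 2) is only consistent with no padding, which fixes that choice.
Kernels are shaped to the connectome geometry: S₁×N×1 (per-ROI features
across S₁ consecutive networks), S₂×1×N (whole-network features), S₃×1×1
(temporal). ReLU follows every convolution and hidden FC layer.

The LSTM cell is written out explicitly (four gates, input weights U,
recurrent weights W, biases b; the cell-state update gates the tanh
candidate by the σ input gate, and the hidden state is tanh(s)⊙o). Written
this way the equations coincide with the classic LSTM cell, and the
scalar-loop oracle test pins the implementation to them at 1e−10. The
sequence readout is the final hidden state, width 64 — the reported
sequential-feature count — rather than the full 13-step hidden sequence;
the hidden width itself is a free parameter and 64 is the default. The
CNN ablation swaps the LSTM for a mean over the T₁ steps (32 features) and
shares every other component, so CRNN−CNN differences isolate the value of
window order. Note that the conv stack itself has temporal kernels, so the
ablation is only order-invariant with respect to permutations of the
T₁-step sequence entering the pooling stage — not of the raw input windows;
the invariance contract is asserted at exactly that interface.

Everything — forward pass, backpropagation (including BPTT through the
cell), Adam — is implemented directly on NumPy arrays. Correctness rests on
two independent checks in the test suite: central finite-difference
gradient checks over every parameter tensor of both architectures, and the
scalar-loop LSTM oracle. Initialisation mirrors common framework defaults:
Glorot-uniform kernels, orthogonal LSTM recurrence, zero biases with the
forget-gate bias at 1, all drawn from the run's seeded generator.

## Training and evaluation protocol

Adam with recommended parameters (lr 1e−3, β₁ 0.9, β₂ 0.999), cross-entropy
loss, 200 epochs and batch size 16 by default. Dropout (rate 0.25) applies
to the two hidden fully connected layers only and is disabled at
evaluation. Per epoch, training and validation losses are recorded; the
weights from the epoch with minimal validation loss are retained for
testing (the selection criterion on the validation split is otherwise
unspecified, and minimal-validation-loss is this package's choice).

Cross-validation is at the subject level: subjects owning a baseline scan
are shuffled with a seeded generator and dealt round-robin into k subsets
(sizes differ by ≤1). Per fold, the held-out subset contributes only its
baseline scans to the test set; all scans of the remaining subjects plus
all scans of subjects without a baseline form the training pool, from
which 20% of subjects (not scans) are moved to validation — subject-level
carving avoids the leakage that scan-level carving would reintroduce.
Sensitivity treats the patient class (the later disease stage) as
positive; this convention is recorded in the outputs. Binary tasks report
ACC/SEN/SPE and trapezoid AUC; the four-class task reports overall and
per-class accuracy; fold metrics are summarised as mean ± SD.

## Baselines

Both baselines use the stationary (whole-series) correlation network.
"Strength" features are the N(N−1)/2 strictly-upper-triangle entries in
row-major pair order; signed values are kept, since a negative correlation
is informative as a feature. Clustering coefficients use Onnela's weighted
formula on absolute, max-normalised weights with the diagonal excluded
(via networkx, cross-checked against an exhaustive triangle sum): triangle
"intensity" is ill-defined for signed weights, hence the absolute value,
and max-normalisation makes the coefficient scale-invariant. Feature
selection is a per-feature two-sample t-test at p < 0.05 fitted on training
scans only (one-vs-rest union for the four-class task, where a binary
selection rule does not directly apply); if nothing survives, the single
smallest-p feature is kept so the SVM always has input. The classifier is
a linear SVM with default regularisation on train-standardised features.

## Interpretation

Region features are the conv1 activations averaged over the T−1 output
time positions: K₁=8 N-vectors per scan, one per channel. Group
differences are Student (pooled-variance) t-tests by default — Welch is
selectable — computed per fold with that fold's trained weights; a
(channel, ROI) pair is discriminative when p < 0.05 in at least 3 of 5
folds. No multiple-testing correction is applied: the raw-p threshold with
the ≥3-fold repetition rule is the procedure being implemented, documented
here as such rather than endorsed as a calibrated error rate. Connectivity
strength for pair-wise tests is the per-subject mean over the T windows of
a dFC edge (a stationary-FC alternative is available behind a flag); each
subject is represented by its baseline scan, or its first scan when no
baseline exists. For display, p-values above 0.05 are set to 1; the raw
matrix is kept alongside. ROI names map to the shipped AAL-116 label list
when N=116 and to generic `ROI_###` labels otherwise.

## Synthetic cohorts

The generator emulates exactly what the method consumes — second-order
windowed statistics — and nothing more: each subject is a concatenation of
zero-mean multivariate Gaussian segments (one covariance "state" per
scheduled run) plus isotropic measurement noise, with no hemodynamic
response, autocorrelation, motion artifacts or scanner noise spectra.
Passing tests therefore demonstrate that the pipeline recovers covariance
structure and its ordering from data of the assumed form, not that it
handles real BOLD confounds.

Default study conditions, chosen once: 20 subjects per group, 30 ROIs, 140
timepoints (trimmed to 137 before analysis), exchangeable background
correlation 0.1, measurement-noise sd 0.2 (which attenuates observed
correlations by ≈1/1.04), ~30% of subjects with a follow-up scan, 10%
lacking a baseline. The separable regime raises ten disjoint ROI-pair
correlations by δ=0.5 in the disease group — disjoint pairs keep the
matrix SPD without projection and make the ground truth unambiguous. The
sequence-only regime gives both groups the same two states (pair blocks in
opposite halves of the ROI set) visited in opposite 70+70 orders, so
stationary statistics match across groups while the windowed sequence
differs; the null regime makes both groups identically distributed.
Covariance shifts that would break positive definiteness are repaired by
eigenvalue clipping at 1e−6 followed by rescaling to unit diagonal. All
randomness derives from one integer seed via SeedSequence hashing of
(seed, group, subject, scan), so any single scan is reproducible in
isolation.

## Problem sizes in the test suite

The statistical acceptance checks use the default cohort conditions with
training runs scaled to the study's needs: 60 epochs for the separable
cohort (validation loss plateaus well before that, consistent with the
fast convergence the method shows), 40 epochs × 5 seeds for the
CRNN-vs-CNN sequence comparison, 100 simulated cohorts (10 ROIs) for
effect-edge recovery power, and 500 null cohorts (8 ROIs, 10 subjects per
group) pooling all edges for the type-I error estimate. Unit tests use
miniature architectures (channel counts 2–8, hidden width 4–8) where only
mechanics, not learning capacity, are under test.

## Known limitations

* No GPU or mixed-precision path; the NumPy implementation targets
  desk-scale cohorts (hundreds of scans) and is single-threaded apart from
  BLAS.
* The four-class baseline selection strategy (one-vs-rest union) is one
  reasonable reading of a procedure specified only for binary tasks.
* The manifold-regularised multi-task feature-selection comparison method
  from the prior literature is not implemented.
* Brain-surface rendering is out of scope; interpretation outputs are CSV
  tables keyed by ROI label.
* Statistical guarantees (power, type-I error) are demonstrated on the
  Gaussian generator above; real rs-fMRI autocorrelation would lower the
  effective number of independent samples per window and weaken them.
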