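# Methods

## Data model

A run is a point cloud of (RT, *m/z*, intensity) triples pooled over
all MS1 centroid scans, sorted by (RT, *m/z*), with RT stored in
seconds regardless of the on-disk unit.  Fragment-level (MS ≥ 2)
spectra in data-dependent acquisitions are skipped: the classifier
consumes one intensity map per sample.  mzML is the only supported
dialect (the maintained open standard); the reader covers the
centroided-MS1 subset — 32/64-bit float arrays, zlib or no compression,
scan start times in minutes (the mzML default), seconds or
milliseconds.  Profile-mode centroiding and vendor formats are out of
scope.

## Pseudoimage binning

Binning maps each point into a predefined RT × *m/z* grid and keeps the
**maximum** intensity per bin; empty bins are zero.  Bins are half-open
`[e_i, e_{i+1})` with a closed final bin, so the span's upper bound
belongs to the grid; points outside the span are dropped and counted
(the pipeline logs the tally).  The max (rather than sum or mean)
preserves apex heights and is insensitive to how many centroids an
elution profile contributes to one bin.

The adaptive grid sets the RT bin width to the instrument's scan
interval — one row per sampling step, the finest RT resolution the data
supports — and takes *m/z* widths from an explicit *density prior*: an
abutting list of (mz_lo, mz_hi, bin_width) regions, finer where more
metabolites are expected.  `estimate_density_prior` derives such a
prior from pooled data by splitting the *m/z* span at quantile
boundaries and assigning the fine width to regions above the median
point density.  A uniform grid is available when no prior knowledge
exists.

Min–max scaling is applied per sample and, by default, **per *m/z*
column** over the RT dimension: each column becomes a trace in [0, 1],
so every channel of the depthwise convolution sees the same dynamic
range and multiplicative instrument sensitivity differences cancel.
Constant columns map to zero.  A per-image global mode is provided as a
config switch for pipelines that want to preserve relative channel
amplitudes.

## The classifier

Each ensemble member is, in order:

| stage | role |
|---|---|
| batch norm (per channel) | standardizes each *m/z* channel; 2·n_mz trainable parameters |
| depthwise 1D conv along RT, kernel `kernel_len`, valid padding | one independent kernel per channel — no cross-channel mixing; smooths traces and absorbs small RT shifts |
| max pool along RT, window = stride = `pool_len` | extracts the strongest local signal (peak apex) per channel |
| spatial dropout (rate `spatial_dropout_rate`, training only) | drops whole channels so no single *m/z* slice can be memorized |
| flatten → dense softmax, L1 penalty `l1_coeff` | the only cross-channel stage; L1 drives irrelevant channel weights to zero |

There is deliberately no nonlinearity between the convolution and the
pooling: the max pool itself is the nonlinearity, and a linear
convolution keeps the identity-kernel contract (a kernel of
`(…,0,1,0,…)` with pool window 1 reproduces the normalized input)
exactly testable.

Training minimizes cross-entropy plus the L1 penalty with Adam
(β₁ = 0.9, β₂ = 0.999), batch size `batch_size`, early stopping on the
loss of a per-member stratified `val_fraction` hold-out with patience
`early_stop_patience` and best-weight restore.  Each member gets its
own seed-derived initialization, validation split, shuffling and
dropout stream; class balance is enforced per member by random
oversampling to the majority count.  The ensemble prediction is the
arithmetic mean of the member softmax vectors; argmax ties break toward
the lowest index in the sorted class order.  The whole network is
NumPy, runs in single precision (it is memory-bandwidth bound on one
core), and repeated training with the same configuration is
bit-identical.

Defaults (all config-exposed; chosen for the default acquisition scale
of a 12-min, 1 Hz gradient with 900 adaptive *m/z* bins): K = 5
members, `kernel_len` = 9 (≈9 s of RT context), `pool_len` = 64,
dropout 0.1, L1 1e-4, learning rate 1e-3, batch 32.  At that scale one
member has 60,305 trainable parameters and the 5-member ensemble
301,525 — the architecture stays deliberately small because each *m/z*
channel is processed independently and only the final dense layer mixes
channels.

## Augmentation and oversampling

RT-shift augmentation draws one delta per copy uniformly from
[−`max_shift`, +`max_shift`] (default 10 s, the magnitude of drift the
method is expected to absorb) and applies it to the **raw point cloud
before binning** — continuous shifts exercise the real binning path
rather than being quantized to whole bins.  Points shifted outside the
acquisition span are dropped (no wrap, no clamp).  Copies are generated
once per dataset build, not per epoch, for reproducibility.  An
integer bin-translation mode (`shift_bins_max`/`shift_copies` on
`train_ensemble`) exists for pipelines whose inputs are already binned.
Oversampling duplicates minority-class items uniformly with replacement
up to the majority count, keeping all originals.

## Decision rule

The confidence margin is top-1 minus top-2 probability.  With a
threshold t, a sample is rejected iff margin < t (t = 0 never rejects).
`select_threshold` searches a candidate grid (default 0, 0.05, …, 0.95)
on a validation split — by convention 10% of the training data — and
returns the candidate maximizing **macro specificity over the accepted
samples**; rejected samples are excluded from the confusion counts (a
rejected sample receives no label, so it can contribute neither a false
nor a true positive), candidates rejecting the entire validation set
are disqualified, and ties break toward the smallest threshold (fewest
rejections).

## Evaluation protocol

Binary metrics come from the confusion counts: accuracy
(TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP),
F1 2TP/(2TP+FP+FN).  Zero denominators yield an explicit NaN flagged in
the report, and such per-class values are excluded from macro means
(not treated as 0) with a count of exclusions.  Multiclass reporting is
one-vs-rest per class plus the unweighted macro average; the overall
multiclass accuracy (fraction of exact matches) is reported separately
because the large one-vs-rest "negative" group inflates per-class
binary accuracy on imbalanced data.

Stratified splitting (75/25 single split or k-fold) delegates to
scikit-learn and preserves per-class proportions within one sample.

Classifier comparison: per-fold performance differences d_i from
stratified 10-fold cross-validation feed the Wilcoxon signed-rank test.
Zero differences are dropped (standard practice), |d| is ranked
ascending with mid-ranks for ties, R+ and R− are the rank sums of
positive and negative differences, and T = min(R+, R−).  The p-value is
exact — full 2^N′ sign enumeration, valid under mid-ranks — for
N′ ≤ 15 nonzero differences, and a normal approximation with tie and
continuity corrections beyond that; the method used is recorded in the
result.  The default alternative is one-sided (does the first
classifier outperform the second?), configurable.  Benjamini–Hochberg
adjustment is the usual step-up `q_(i) = min_{j≥i} p_(j)·m/j`, capped
at 1.

## Synthetic data generator

The generator emulates a centroided Q-TOF-style untargeted metabolomics
acquisition: a gradient of `acquisition_span` seconds (default 720 s ≈
a 12-min method) sampled every `scan_interval` seconds; each compound
elutes as a Gaussian RT profile (σ drawn in 2–5 s) sampled at every
scan time, producing one centroid per scan at a fixed *m/z* —
chromatographic peaks are Gaussian in RT and delta-like in *m/z*, which
matches centroided data.  Per-scan intensities get lognormal noise with
coefficient of variation `height_cv` (default 0.3) and are truncated
below 1% of the compound's mean apex height (the detection threshold,
applied before batch intensity scaling so scaling stays exactly
multiplicative); marker apex heights are log-uniform over one decade
(10³–10⁴ counts).  Classes are separated by disjoint sets of marker
compounds drawn uniformly over the central 90% of the gradient and the
*m/z* span; peaks shared by all classes can be added.  Each sample gets
a Normal(0, `rt_drift_sd`) RT drift (default 2 s) applied uniformly to
all its peaks — the drift the augmentation is designed to absorb — plus
uniform background points (default 3 per scan) with exponential
intensities around the batch noise floor.  Batch/instrument effects are
systematic per-batch RT offsets, *m/z* offsets and multiplicative
intensity scales.  The full dataset is a pure function of the seed via
spawned per-sample seed sequences.

Deliberately **not** modeled: isotope patterns, adducts, ion
suppression, realistic metabolite libraries, gradient nonlinearity.
Passing tests on this generator therefore demonstrate that the pipeline
recovers class-discriminating elution/mass patterns under drift, noise
and batch effects — not that it handles the full chemical complexity of
real biofluids, where class differences are subtler and confounded.

## Benchmark sizing

The shipped 5-class benchmark (`benchmark_config`) uses the generator's
stated noise (height CV 0.3, drift SD 2 s, 3 background points/scan)
with 100 samples per class and 10 markers per class, on a shortened
600 s gradient sampled every 2 s and binned at 9 Th (300 × 100
pseudoimages); the batch-robustness study uses 3 classes × 30 samples
over two batches (RT offset 5 s, intensity scale 1.5) at 1 s scans,
kernel 5 and pool 4 so that the 5 s offset exceeds the architecture's
built-in pooling tolerance and the contribution of RT-shift
augmentation is actually measurable.  These sizes keep the full suite
trainable on a single CPU core while preserving the structure the
method exploits.

## Known limitations

- The mzML writer emits a minimal (valid, uncompressed, 64-bit)
  centroided MS1 document; it does not index the file or write
  chromatogram lists.
- No probability calibration: margins are used as-is for rejection.
- The per-column min–max scaling erases absolute intensity differences
  between samples; tasks where total ion current itself is informative
  should use the global scaling mode.
- Explainability (which *m/z*/RT regions drive a prediction) is not
  implemented; the dense-layer L1 weights give only a coarse channel
  ranking.
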