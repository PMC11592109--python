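# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the tests demonstrate.

## Synthetic vesicle images

Extracellular vesicles (30–200 nm) are far below the diffraction limit of
a 20x objective, so each stained vesicle renders as the microscope's
point-spread function.  The generator models spots as isotropic 2-D
Gaussians with width sigma drawn uniformly from 0.9–1.6 px and peak
amplitude 0.3–0.9 of the dynamic range over a flat background of 0.1
(optionally with a linear tilt to stress the contrast-enhancement step).
Noise is additive Gaussian read noise (sd 0.02 of the range by default)
with optional Poisson shot noise.  Defaults produce 5–50 spots per
128 x 128 frame with a minimum centre separation of 8 px, emulating a
well-dispersed vesicle preparation; with the separation floor disabled,
overlapping vesicles merge in the ground-truth mask and the mask's
component count drops below the planted count, which is recorded rather
than hidden.  The ground-truth mask marks pixels within 2 sigma of a
centre.  The 8 px floor sits above 4 sigma_max = 6.4 px, the separation
beyond which threshold segmentation provably splits neighbouring spots,
so noise-free counting recovers planted counts exactly.

What the generator does **not** model: optical aberrations and defocus,
flat-field/vignetting artefacts, autofluorescent debris, and the
intensity–size correlation of real vesicles.  Passing tests therefore
show that the pipeline recovers counts under PSF-limited imaging with
realistic noise, not that it handles every real-microscope artefact.

## Classical segmentation

The automated mask pipeline derives its threshold from the image's own
intensity distribution: background mode = median, background spread =
1.4826 x MAD, threshold = median + max(k·spread, f·(max − median)) with
k = 3 and relative floor f = 0.15.  The MAD term adapts to noise; the
floor keeps the rule meaningful in the noise-free limit where the MAD
vanishes (Gaussian tails otherwise bridge neighbouring spots).  Otsu's
criterion is available as an alternative rule.  Components smaller than
3 px are discarded (single-pixel noise), connectivity is 8, coordinates
are row-major, 0-based, with half-open tile intervals.  CLAHE uses a
clip limit of 2.0 (in multiples of the uniform histogram bin height,
converted to scikit-image's fractional convention) on an 8 x 8 grid;
denoising defaults to a small Gaussian (sigma 0.7) in the counting
pipeline because a 3 x 3 median can erase the faintest 1-sigma spots,
while the median filter remains the default of the standalone `denoise`
operation for salt-type noise.

## Multitask network

The network is a compact U-Net: `depth` double-conv encoder stages
(base_filters x 2^d channels) with 2 x 2 max pooling; a connection block
(1 x 1 convolution to base_filters x 2^depth channels, instance
normalisation, ReLU) adapting encoder features for the decoder; a decoder
of nearest-neighbour upsampling, skip concatenation and double-conv
blocks; a 1 x 1 segmentation head; and a counting head that global-
average-pools the connection-block output through one hidden dense layer
to a softplus output.  `residual=True` adds identity (or 1 x 1-projected)
shortcuts around each double-conv block.  The counting head predicts
log1p(count), so the softplus keeps counts non-negative by construction;
its output bias is initialised to the training-set base rate, which
removes a long plateau in which the head would slowly learn the mean.

Losses: segmentation = soft Dice + binary cross-entropy on logits (Dice
handles the ~1–6% foreground fraction, BCE keeps gradients informative);
counting = squared error on log1p counts; total = 1.0·seg + 0.5·count.
Optimiser: Adam, lr 2e-3, batch 16, at most 12 epochs with early stopping
(patience 4) on the composite validation score Dice − 0.5·(count MAE /
mean true count), restoring the best epoch's weights.  Forward and
backward passes are hand-written NumPy (convolutions as one GEMM per
kernel tap); backpropagation is verified against float64 central
differences in the test suite.  Everything is seeded: identical data,
configuration and seed reproduce the training history bit for bit.

A pretrained named-family encoder (e.g. a VGG-style stack) is part of the
configuration surface but rejected at construction time because no
pretrained weights are bundled; the tiny from-scratch encoder is the
supported and tested path.

Problem sizes: the standard training run uses 40 training images tiled to
128 x 128 and augmented 10-fold (400 tiles) against 10 validation images,
chosen so a full run takes a few minutes on one CPU; the acceptance
script reports the validation Dice and count error this run achieves.
The single-batch overfit check (8 tiles, up to 200 epochs) guards the
optimisation loop itself.  Hyperparameter search is seeded random search
over list-valued (categorical) and 2-tuple (log-uniform) dimensions,
selecting by the same composite score; divergent trials score −inf.

## qPCR quantification

Quantification follows 2^−ΔΔCt: per-sample ΔCq = mean replicate Cq of the
target minus mean replicate Cq of the reference assay; ΔΔCq subtracts a
calibrator, by default the **median ΔCq of the healthy-donor controls**
(configurable); fold change = 2^−ΔΔCq.  Replicates at the 45-cycle run
length are treated as undetected and excluded from means; a sample whose
target never amplified is dropped with a warning, a missing reference is
an error naming the sample.  Spike-in recovery is 2^(refCq − Cq_spike)
against the run-mean spike-in Cq by default, with advisory flags outside
[0.25, 2.0] (one cycle high, two cycles low) — flagged, never dropped.
Expression is dichotomised at the median of a reference cohort; values
exactly at the cut go to "high" and are logged.  The cohort generator
plants a fold change as a −log2(FC) shift of the case target Cq, so the
whole chain is checked by recovery: exact at zero Cq noise, mean log2 FC
within ±0.1 at sd 0.2 cycles and n = 200.

## Survival analysis

`km_estimate` is the product-limit estimator; `logrank` the standard
two-group test (O − E over hypergeometric variance, chi-square with 1 df).
Both are implemented directly and validated against `lifelines` as an
independent reference — on the bundled 32-patient cohort they agree to
numerical precision at every event time.  Disease-free intervals use
relapse as the event; death without relapse censors.  The survival
generator draws exponential event times with a planted hazard ratio
between expression groups; censoring is independent exponential with rate
lambda·c/(1−c), which hits the requested censoring fraction exactly in
expectation (a uniform follow-up window cannot without root-finding).
Calibration is checked empirically: at HR = 1 the log-rank rejection rate
over 200 simulated cohorts stays within binomial bounds of 0.05.

## Cross-omics integration

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) with N = |universe|, K = |pathway ∩ universe|, n = |selected|,
verified against exhaustive enumeration for small universes.  Universes
are declared explicitly: all miRNAs in the edge list for the miRNA arm,
all level-1/2a annotated metabolites for the metabolite arm.  Cut-offs
are strict (p-adj < 0.05, |FC| > 2).  Multiple-testing adjustment is
Benjamini–Hochberg by default with Bonferroni available.  Metabolomics
normalisation is sample-median division, log10, and Pareto scaling
((x − mean)/sqrt(sd), sample sd with ddof = 1); zeros are imputed to half
the minimum positive intensity and constant features are centred but not
scaled, both with warnings.  m/z annotation matches features to
[M+H]+/[M−H]− adduct masses within 3 ppm; ties keep all matches flagged
ambiguous.  The metabolite pathway test keeps only pathways with at least
3 significant members, filtering **before** adjustment.  The mummichog
idea is deliberately simplified to top-k feature selection → ppm
annotation → hypergeometric test; the permutation null of the full
algorithm is out of scope and results should be read accordingly.

The omics fixture isolates one signal chain: the planted miRNA is the
only miRNA targeting any filtered DEG (selected set of size 1 in a
150-miRNA universe; with 5 pathways the planted pathway's BH-adjusted
p is 5/150 ≈ 0.033, deterministically significant), its pathway carries
8 strongly shifted metabolites out of 10 members, and a planted lncRNA
regulates one of the pathway's DEGs.  The planted metabolite shifts
alternate in sign so the sample median — the normalisation denominator —
is not dragged by the signal, which would otherwise leak a spurious shift
into every null feature.  Decoy miRNAs, lncRNAs, pathways and metabolites
carry no signal.  This fixture demonstrates end-to-end recovery of a
known chain, not performance under correlated or weak real-data signals.

## Known limitations

- The network is CPU-sized; it demonstrates the multitask architecture
  and its training dynamics, not state-of-the-art segmentation capacity.
- Merged vesicles are counted as one object by the classical pipeline
  (no watershed/multi-Otsu instance splitting).
- The rank-sum test is the independent-samples (Mann–Whitney) form;
  paired designs need the signed-rank variant, which is not provided.
- No Cox regression and no >2-group log-rank.
- Pathway enrichment here is membership-based ORA; it does not model
  inter-gene correlation or pathway topology.
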