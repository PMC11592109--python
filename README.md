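# evquant

Quantification of plasma extracellular vesicles (EVs) and cross-omics
biomarker nomination for early-stage non-small-cell lung cancer (NSCLC),
as a tested, fully synthetic-data-driven pipeline.

EVs released into blood carry miRNA and metabolite cargo that can flag
minimal residual disease before imaging does.  A liquid-biopsy workflow
built around them has three computational stages, all implemented here:

1. **Imaging** (`evquant.imaging`, `evquant.mtl`) — DiO-stained EVs imaged
   by fluorescence microscopy appear as diffraction-limited spots.  The
   package provides the classical pipeline (green-channel extraction,
   CLAHE, denoising, intensity-distribution thresholding, connected-
   component counting, 128 x 128 tiling, augmentation) and a multitask
   U-Net — encoder, 1 x 1 connection block, skip-connected decoder with
   optional residual blocks, plus a regression head — trained jointly with
   a Dice + binary cross-entropy segmentation loss and an MSE loss on
   log1p counts.  Masks are scored by Dice = 2|A∩B|/(|A|+|B|) and
   IoU = |A∩B|/|A∪B|.  The network, its backpropagation and the Adam
   optimiser are pure NumPy; training runs in minutes on one CPU.
   An sklearn-style facade (`MultitaskSpotCounter`) exposes
   `fit`/`predict`/`score` and composes with sklearn model selection.
2. **Expression and survival statistics** (`evquant.expstats`) — relative
   qPCR quantification by the Livak–Schmittgen 2^−ΔΔCt method (ΔCq against
   a reference assay, calibrated to the median ΔCq of healthy-donor
   controls), spike-in recovery QC (cel-miR-39-style external control),
   median dichotomisation into high/low expression, the Kaplan–Meier
   product-limit estimator, the two-group log-rank test, and Cohen's
   kappa for inter-rater agreement.  A 32-patient example cohort with
   DFS/OS follow-up is bundled.
3. **Cross-omics integration** (`evquant.integrate`) — differential-
   expression filtering (p-adj < 0.05, |FC| > 2), gene–miRNA–lncRNA
   network construction from validated edge lists, one-sided
   hypergeometric pathway over-representation with BH/Bonferroni
   adjustment, metabolomics normalisation (sample-median, log10, Pareto),
   3-ppm m/z annotation, metabolite pathway enrichment restricted to
   annotation levels 1/2a and pathways with ≥ 3 significant members, and
   finally the nomination step: pathways significant in *both* the miRNA
   and the metabolite arm yield candidate miRNAs and network-linked
   lncRNAs with their evidence chains.

Every stage is driven by the seeded generators in `evquant.simgen`
(fluorescence images with known spot ground truth, Cq tables with planted
fold changes, survival cohorts with planted hazard ratios, omics fixtures
with one planted enriched pathway), so correctness is checked as
parameter recovery rather than against unavailable raw data.

## Worked example

```python
from evquant.simgen import ImageSimConfig, simulate_image_dataset, CohortSimConfig, simulate_cq_table
from evquant.imaging import segment_and_count
from evquant import expstats

ds = simulate_image_dataset(ImageSimConfig(), 5, seed=7)
for i, (im, gt) in enumerate(zip(ds.images, ds.truths)):
    _, n = segment_and_count(im)
    print(f"image {i}: planted {gt.true_count:2d} vesicles, counted {n:2d}")

tab = simulate_cq_table(CohortSimConfig(planted_fold_change=0.25, seed=7))
d = expstats.delta_cq(tab)
groups = tab.groupby("sample_id")["group"].first()
fc = expstats.fold_change(d, expstats.control_calibrator(d, groups))
print("median case fold change: %.3f (planted 0.25)" % fc[groups.reindex(fc.index) == "case"].median())

co = expstats.load_example_cohort()
chi2, p = expstats.logrank(co.os_months, co.death, co.histology == "AdenoCA")
print("OS log-rank by histology: chi2=%.3f, p=%.3f" % (chi2, p))
```

prints

```
image 0: planted 25 vesicles, counted 25
image 1: planted 45 vesicles, counted 45
image 2: planted 26 vesicles, counted 26
image 3: planted 22 vesicles, counted 22
image 4: planted 45 vesicles, counted 45
median case fold change: 0.264 (planted 0.25)
OS log-rank by histology: chi2=0.024, p=0.877
```

The counts recover the planted ground truth exactly on these images; the
2^−ΔΔCt estimate recovers the planted four-fold down-regulation to within
Monte-Carlo noise; and overall survival in the example cohort does not
differ by histology at this sample size.

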