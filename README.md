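# ngahic

Quantitative nuclear histomorphometry for recurrence prediction in
node-negative gastric adenocarcinoma (NGA) from H&E tissue-microarray spots.

Node-negative gastric adenocarcinoma usually carries a good prognosis, so
whether a patient should receive adjuvant chemotherapy after resection is
genuinely uncertain; an image-based marker of recurrence risk computable
from routine H&E slides would let that decision be personalized. This
package implements such a pipeline end to end: from a TMA spot image it
segments every nucleus, computes a 189-feature quantitative-histomorphometry
vector describing nuclear shape, texture, orientation disorder and tissue
architecture, selects the most discriminative features by stability
selection, trains a grid of classifiers, calls recurrence from the best one
(the **NGAHIC** — NGA histomorphometric image classifier), and runs the
downstream survival and immunohistochemistry statistics. Because the
original patient images are not public, a first-class synthetic-data module
generates TMA spots and outcome cohorts with the statistical structure the
analysis assumes, and every quantitative claim in this repository is
computed on that synthetic material.

## The model in brief

* **Segmentation** — Beer–Lambert color deconvolution onto the H&E stain
  basis isolates the hematoxylin density; Otsu thresholding, a distance
  transform and marker-controlled watershed segment individual nuclei.
* **Features (189)** — per spot: 100 nuclear shape features (25 descriptors
  × {mean, SD, median, min/max}, including Hu invariant moments computed
  exactly from the boundary polygon and Fourier descriptors of the
  centroid-distance signature), 30 texture features (GLCM contrast, energy,
  entropy, inverse variance and an intensity invariant moment, {mean, SD} ×
  3 channels), 39 cell-orientation co-occurrence features (13
  Haralick-family descriptors of quantized-angle co-occurrence over
  k-nearest-neighbor graphs, {mean, SD, range}), 12 Voronoi and 8 Delaunay
  architecture features aggregated with the disorder statistic
  1 − 1/(1 + SD/mean).
* **Selection & classification** — Wilcoxon rank-sum, MRMR and
  random-forest rankings under stratified 3-fold × 100-iteration stability
  selection give three 5-feature bins; crossing them with LDA, regularized
  QDA, a calibrated linear SVM and a random forest gives 12 combinations;
  the best cross-validated AUC defines the NGAHIC, and probability > 0.5
  (strict) calls recurrence.
* **Survival statistics** — Kaplan–Meier curves, log-rank tests, univariate
  and multivariate Cox proportional-hazards models (Efron ties), and
  Fisher/chi-square association of calls with HER2 and Ki67 (positive at a
  labeling index ≥ 14%).

## Worked example

The numbered drivers under `analysis/` run the full study design on
synthetic cohorts (D1 = 60 training patients, D2 = 100 test patients, D3 =
a second punch per D2 patient) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py 1
python analysis/02_extract_image_features.py
python analysis/03_select_and_train.py 1
python analysis/04_predict_and_survival.py 1
python analysis/05_heterogeneity.py 1
```

With seed 1 this prints (abridged):

```
WRST bin: shape:perimeter_ratio:sd (1.00), orient:energy:range (0.99),
          orient:intensity_average:sd (0.79), ...
NGAHIC = MSV + WRST bin (training AUC 1.00 ± 0.01)
D2 held-out: AUC=0.98 accuracy=0.92 specificity=1.00 sensitivity=0.67
log-rank NGAHIC+ vs NGAHIC-: chi2=51.43, p=7.42e-13
multivariate ngahic HR 10.04 (4.78-21.11), p=1.17e-09
her2_positive: 87.5% vs 2.4% positive (NGAHIC+ vs NGAHIC-), fisher p=3.12e-13
D2 vs D3 call agreement: 0.90
```

Reading this: stability selection recovers the five features whose
distribution the generator shifts between recurrence groups (three of the
five are orientation-disorder features); the SVM-on-Wilcoxon-bin combination
wins the training grid; on held-out patients the classifier separates
recurrence strongly, its positive call is a large independent hazard factor
in the multivariate Cox model, it associates with both IHC markers, and its
calls are 90% reproducible on a second simulated punch of the same tumors.

The same pipeline is scriptable as one command (`ngahic run --seed 1
--out-dir results/run`) or stage by stage (`ngahic simulate|segment|
features|select|survival`), and every stage is importable from
`ngahic.*` — the feature extractor for a single image is
`ngahic.extract_spot_features`.

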