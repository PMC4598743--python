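# sdmclust

Segmentation and classification of single white-blood-cell microscope
sub-images for acute lymphoblastic leukaemia (ALL) screening.  Given a
pre-cropped image containing one lymphocyte or lymphoblast, the package
separates **nucleus**, **cytoplasm** and **background**, extracts an
80-descriptor morphology/texture/colour profile of the cell, and
classifies it as normal or blast with single or ensemble classifiers
under holdout, k-fold and .632-bootstrap validation.  A synthetic cell
generator with exact ground-truth masks makes the whole pipeline
testable without clinical image data.

## Who it is for

Researchers building or benchmarking blood-smear image analysis:
the segmentation stage is useful on its own (it also implements FCM,
LDA-scatter and two fuzzy compactness-and-separation baselines under
the identical optimiser, for controlled comparisons), and the
validation layer reproduces the classical evaluation protocols used in
the ALL-classification literature.

## The method

Clustering operates on the CIELAB L\* plane, where chromatin makes the
nucleus dark, cytoplasm mid-toned and the slide background bright.  A
candidate segmentation is a threshold pair `t1 < t2` splitting pixels
into three clusters.  A real-coded genetic algorithm (stochastic
universal sampling, single-point crossover p=0.7, Gaussian mutation
p=0.3, generation gap 0.9, 100 generations, one individual seeded from
a converged fuzzy C-means run) minimises a **stimulating discriminant
measure** ratio

```
J = S_W / S_B,
S_W = Σ_j  max_{x∈j} (x − c_j)²                       (worst-case within-cluster spread)
S_B = Σ_{j<l} min( min_{x∈j}(x−c_l)², min_{x∈l}(x−c_j)² )   (boundary-to-centre separation)
```

summed over the R(R−1)/2 cluster pairs.  Unlike the summed scatter of
FCM/LDA, `S_W` tracks the single worst member per cluster, and `S_B`
measures how close the *boundaries* of two clusters approach each
other's centre rather than how far the centres sit from the global
mean.  Anatomical constraints enter as a fitness penalty: nucleus and
cytoplasm areas must each be ≥10% of the other, and the background may
not exceed the membrane (nucleus+cytoplasm) area.  Cluster roles are
assigned by luminance order, and a morphological pass fills small holes
and dissolves "salt-and-pepper" specks.

Features: 16 nucleus/cytoplasm shape descriptors, 13 grey-level
co-occurrence statistics at 0°/45°/90°/135° plus skewness/kurtosis
(54 texture values), and 10 a\*/b\* chroma statistics — 80 in all,
min–max scaled to [−1, 1] on the training rows.  Classifiers: an MLP
(logistic hidden layers, linear output, Levenberg–Marquardt or momentum
gradient descent, MSE termination 0.01), an RBF-kernel SVM tuned by
grid search over exponential (σ, Co) sequences with stratified 10-fold
CV, and bagged-MLP ensembles under nine combination rules including
Dempster–Shafer evidence fusion.

## Worked example

```python
from sdmclust.synth import generate_cell, low_contrast_spec
from sdmclust.clustering import GaConfig, segment, FcmConfig, fcm_segment
from sdmclust.evaluation import evaluate_segmentation

cell = generate_cell(low_contrast_spec(seed=0))   # nucleus ~4 L* units from cytoplasm
mask, thresholds, trace = segment(cell.lab.L, GaConfig(seed=0))
score = evaluate_segmentation(mask, cell.truth)
print(f"thresholds: t1={thresholds.t1:.2f}, t2={thresholds.t2:.2f}")
print(f"CorrN={score.corr_nucleus:.3f}  CorrC={score.corr_cytoplasm:.3f}")

fcm = fcm_segment(cell.lab.L, FcmConfig(seed=0))
s2 = evaluate_segmentation(fcm, cell.truth)
print(f"FCM baseline: CorrN={s2.corr_nucleus:.3f}  CorrC={s2.corr_cytoplasm:.3f}")
```

prints

```
thresholds: t1=57.71, t2=72.72
CorrN=0.841  CorrC=0.947
FCM baseline: CorrN=0.622  CorrC=0.890
```

`CorrN`/`CorrC` are 2-D Pearson correlations between the predicted and
true region indicator images (1.0 = pixel-perfect).  On this
deliberately hard cell — nucleus body only 4 L\* units darker than the
cytoplasm, with strongly contrasted chromatin speckles — plain FCM
spends a cluster on the dark chromatin mode and truncates the nucleus,
while the constrained GA search keeps the whole nucleus together.

The same steps are available from the shell:

```
sdmclust synth --n-normal 30 --n-blast 30 --seed 1 --out data/
sdmclust segment data/cell_000.png --objective sdm --seed 1 --out mask.png
sdmclust features data/cell_000.png mask.png --out features.csv
sdmclust classify features.csv labels.csv --model svm --validate cv10 --out report.json
sdmclust pipeline data/manifest.csv --seed 1 --out run/
```

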