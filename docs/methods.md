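# Methods

## Problem setting and scope

The package operates on pre-cropped sub-images containing exactly one
white blood cell.  Upstream detection of cells in a full smear field
(e.g. marker-controlled watershed membrane extraction) is out of scope;
the synthetic generator therefore produces tight single-cell crops in
which the cell membrane occupies more than half of the frame, matching
the anatomical constraints the fitness function assumes.

## Colour conventions

RGB inputs are assumed sRGB with D65 white point — the de facto standard
for camera microscopy files; the conversion to CIELAB keeps L\* on its
native [0, 100] scale so that thresholds are directly interpretable as
luminance levels.  Masks use 0=background, 1=cytoplasm, 2=nucleus, so
"object" labels are truthy.

## The clustering objective

A threshold pair (t1, t2) induces a hard 3-way partition of the L\*
values with half-open intervals (a pixel exactly at a threshold joins
the upper cluster).  Let c_j be the mean of cluster j.  The two scatter
statistics are

* within: `S_W = Σ_j max_{x∈j} (x − c_j)²` — the worst-case member, not
  the average, so a cluster harbouring even a few far-out pixels is
  penalised in full;
* between: for each unordered pair (j, l),
  `d_jl = min(min_{x∈j}(x − c_l)², min_{x∈l}(x − c_j)²)`, i.e. the
  closest approach of either cluster's boundary to the other's centre;
  the R(R−1)/2 = 3 pairwise separations are **summed** (the additive
  aggregate keeps every pair's information and mirrors classical
  between-scatter; a min-aggregate is available as a switch, and the
  per-pair list is exposed).

The GA minimises `S_W / (S_B + ε)` with ε = 1e−9.  A ratio realises the
"small S_W, large S_B" trade-off with no extra weight hyper-parameter.
Squared Euclidean distance on scalar L\* is used uniformly across S_W,
S_B, FCM, the LDA scatters and both FCS variants.

Anatomical constraints: area(nucleus) ≥ 0.10 · area(cytoplasm) and vice
versa, and area(background) ≤ area(nucleus) + area(cytoplasm).  A
violated constraint adds a constant penalty; by default the penalty is
10³ × the median unpenalised fitness of the initial population, which
scales with the image at hand.  Empty clusters contribute 0 to S_W and
their pairs 0 to S_B; the area constraints then take care of penalising
such chromosomes, keeping the fitness finite everywhere.

## Genetic algorithm

Real-coded individuals (t1, t2) with sort-repair after every operation.
Population 50, initialised uniformly on [0, 100]²; one individual is
replaced by the FCM seed — thresholds at midpoints between adjacent
sorted FCM centres, which is the hard-assignment boundary of 1-D FCM as
the fuzzifier tends to 1.  Selection is stochastic universal sampling
on linear rank weights; crossover (probability 0.7) is single-point at
the gene boundary, i.e. the parents exchange t2; mutation (probability
0.3 per offspring) adds N(0, 5²) L\* units, reflected back into range.
With generation gap 0.9, 90% as many offspring as parents are bred and
an elitist ranked merge keeps the best 50 of the union, so the best-ever
fitness trace is monotone non-increasing.  100 generations by default.
All randomness flows from one integer seed.

## Baseline objectives

Run under the *identical* GA so only the discriminant measure differs:

* LDA scatter: `Σ_j Σ_{x∈j}(x−c_j)²  /  Σ_j N_j (c_j − c̄)²`;
* FCS1/FCS2: `compactness − η · separation` with FCM-style memberships
  of all pixels w.r.t. the partition centres (the standard inverse
  distance form, which is non-negative by construction — this replaces
  membership definitions that can go negative when a sample sits closer
  to a centre than the mutual centre).  FCS1 measures separation with
  membership-weighted distances of all samples to the mutual centre;
  FCS2 with cluster-mass-weighted distances of the fuzzy sample means
  to the mutual centre.  η = 1/C (C = 3 clusters) by default, an adopted
  convention rather than a tuned value; η = 0 recovers plain FCM
  compactness in both variants.
* FCM itself (fuzzifier m = 2, tolerance 1e−5, ≤100 iterations,
  k-means++-style 1-D seeding) doubles as a direct baseline: its hard
  partition by maximum membership is relabelled anatomically.

## Role assignment and morphological refinement

Clusters sorted by centre luminance become nucleus / cytoplasm /
background (darkest to brightest); exact ties make the larger cluster
the brighter role.  With two non-empty clusters the middle role is
empty; with one, everything is nucleus — both degenerate cases are then
caught by the area constraints.

Refinement first dissolves isolated nucleus/cytoplasm components
smaller than 30 px (8-connected) into the surrounding label, then fills
enclosed holes smaller than 30 px (4-connected interiors, the classic
fill-holes convention), removing filled pixels from whichever class
held them.  Two deliberate choices: (a) specks are dissolved *before*
holes are filled — on a noisy mask a fragmented nucleus would otherwise
be swallowed piecemeal as small "holes" of the surrounding cytoplasm;
(b) hole size is measured on 8-connected groups, so a legitimate
nucleus fragment is not split into several sub-threshold 4-connected
cavities and erased.  The pass is idempotent, and the pipeline falls
back to the unrefined mask if refinement would erase an anatomical
region entirely.

## Features

* Shape (16): areas and the nucleus:cytoplasm ratio, plus nucleus region
  properties from normalised second central moments.  Perimeter uses the
  4-direction Crofton estimator, which has far less rasterisation bias
  on smooth outlines than pixel-edge counting (a digital disc's form
  factor evaluates to ≈1.01 rather than ≈0.95).  The two compactness
  variants are P²/(4πA) and P²/A; "length-to-diameter" is major axis
  over the equivalent circular diameter √(4A/π).  All are established
  definitions chosen where the descriptor names admit several.
* Texture (54): co-occurrence matrices of the nucleus L\* quantised to
  16 levels (min–max within the nucleus), offset 1, four angles,
  symmetric, each normalised to sum 1; only pixel pairs fully inside the
  nucleus are counted.  13 statistics per angle (correlation, sum
  variance, normalised inverse difference moment, sum average, contrast,
  difference variance, entropy with log₂ and 0·log0 := 0, cluster
  prominence, cluster shade, dissimilarity, energy = Σp², homogeneity,
  normalised inverse difference) plus skewness and plain (non-excess)
  kurtosis of the raw nucleus intensities.  Texture is computed on the
  nucleus only: chromatin pattern, nucleoli and vacuoles — the
  discriminative textures — are nuclear.
* Colour (10): mean and population SD of a\* and b\* per region and the
  cytoplasm/nucleus ratios of the two means (ε-guarded).

Scaling maps each feature linearly to [−1, 1] using the training rows'
min/max; constant columns map to 0 and held-out values are not clipped.

## Classifiers

The MLP has logistic hidden layers and a single linear output trained
on 0/1 targets; mean squared error at or below 0.01 terminates
training.  Two trainers: damped Gauss–Newton (Levenberg–Marquardt) on
the per-sample residuals with an analytic backpropagated Jacobian
(default for the standalone model), and full-batch gradient descent
with learning rate 0.1 / momentum 0.8 (default for ensemble members —
LM uses neither a learning rate nor momentum, so those settings are
honoured by the momentum trainer).  Hard labels threshold the linear
output at 0.5; probabilities pass it through a logistic link centred on
the threshold, so the decision boundary maps to p = 0.5.

The SVM uses an RBF kernel with gamma = 1/(2σ²); σ ∈ {2⁻⁴…2⁶} and
Co ∈ {2⁻⁵…2¹⁵} are searched exhaustively by stratified 10-fold CV on
the training partition only, ties resolved toward smaller Co then
smaller σ.

Ensembles bag n identically configured MLPs (diversity = per-member
weight seeds + bootstrap resampling of the training rows) and combine
per-model class probabilities by one of nine rules.  Dempster–Shafer
builds per-model basic probability assignments m(c) = p_c·(1−u),
m(Θ) = u with uncertainty u = 1 − max_c p_c — parameter-free, reducing
to certainty for confident members — and fuses them with Dempster's
conflict-normalised rule; the decision maximises singleton belief.
Bayesian combination uses per-member training confusion matrices;
decision templates use nearest mean decision profiles.

## Validation protocols

Class-balanced holdout at 75:25, 50:50 and 25:75; stratified 10-fold
CV; and the .632 bootstrap: n draws with replacement train, the
out-of-bag rows test, resamples with empty out-of-bag or single-class
training sets are redrawn, and
`acc_boot = mean_i(0.632·acc_test_i + 0.368·acc_orig_i)`.  The expected
out-of-bag fraction is (1 − 1/n)ⁿ → e⁻¹ ≈ 0.368.

## Synthetic fixtures: what they emulate, and what not

A cell is an elliptical nucleus (optionally lobulated) inside an
elliptical cytoplasm ring on a bright background, with per-region L\*
targets, chromatin modelled as single-pixel speckles of fixed L\*
offset at a given density, per-region (a\*, b\*) chroma, and i.i.d.
Gaussian pixel noise.  Blast cells differ from normal ones by a larger
nucleus:cytoplasm ratio, denser chromatin, darker nuclei and a stronger
basophilic chroma shift; the "hard" difficulty narrows every gap.  The
low-contrast preset places the nucleus body 4 L\* units below the
cytoplasm with dense, strongly contrasted chromatin: a purely
within-scatter objective then spends a cluster on the dark chromatin
mode and truncates the nucleus, while the area-constrained GA cannot —
this is exactly the regime the boundary-aware objective is designed
for, and the fixture makes that comparison observable.

Not emulated: stain variability and illumination gradients, touching
red cells and platelets, partial cells at crop borders, spatially
correlated noise, and multi-cell fields.  Passing tests demonstrate the
algorithmic properties (recovery, ordering of methods, estimator
identities) on controlled data; they are not evidence of clinical-grade
accuracy on real smears.

## Problem sizes and numerical choices

Test and acceptance runs use 48×48 fixtures, population 50 and 100
generations (the exhaustive-oracle checks use 12×12 images where brute
force over all integer threshold pairs is exact), 20 random seeds for
segmentation statistics, and b = 50 bootstrap resamples with a (10,)
hidden layer at desk scale — sizes chosen so the whole suite runs in a
few minutes on one CPU while keeping every statistic comfortably away
from its decision boundary.  Degenerate inputs are defined, not
special-cased ad hoc: correlation of two identical constant images is
1, of one constant image 0; singleton clusters contribute no within
scatter; a sample coinciding with an FCM centre takes membership 1.
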