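# Methods

## Overview

`subtypeforge` implements a complete molecular-subtyping workflow of the kind
used to stratify hepatocellular carcinoma (HCC) cohorts from reverse-phase
protein array (RPPA) and microarray data:

1. **Subtype discovery** — resampling-based consensus clustering of the
   protein matrix with CDF-guided selection of the number of clusters k;
2. **Signature extraction** — subtype-specific marker selection by all-pairs
   Student t-tests with a two-of-three rule;
3. **Transfer classification** — a Bayesian compound covariate predictor
   (BCCP) that carries the subtype labels to independent mRNA cohorts;
4. **Survival stratification** — Kaplan–Meier curves, the k-group log-rank
   test and Cox proportional-hazards regression.

Because the real patient cohorts behind this design are access-restricted,
the package ships a synthetic cohort generator that emulates their
statistical structure; every downstream stage is validated against it.

## Consensus clustering

For each candidate k (default 2–7), `build_consensus` draws
⌈0.8·n⌉ samples without replacement `n_resamples` (default 100) times,
clusters each draw with average-linkage agglomerative clustering on the
1 − Pearson correlation distance between sample profiles, and accumulates
for every sample pair the number of co-draws and co-clusterings.  The
consensus matrix M is their elementwise ratio; pairs never co-drawn get
M = 0 and are flagged (vanishingly rare at 100 resamples × 80%).

The empirical CDF of the off-diagonal consensus values is evaluated on a
fixed grid (step 0.01) so areas are data-independent.  The **ambiguity
score** CDF(0.9) − CDF(0.1) — the proportion of ambiguous clustering —
operationalizes "the flattest CDF mid-section": a literal slope estimate
would depend on the grid, while the band mass is its exact integral.
`select_optimal_k` takes the k with minimal ambiguity.  When several k tie
*exactly* (crisp nested structure: a stable two-way merge of three true
clusters is as crisp as the three-way split), the tie is resolved by the
delta-area plot: the selection advances to the larger tied k while the
relative gain in area under the CDF is at least 0.1.  In our simulations a
real extra cluster gains ≈ 0.5 relative area while splitting noise gains
≈ 0.02, so the threshold sits in a wide gap.  A scan whose best ambiguity
exceeds 0.5 is flagged low-confidence.

Final labels are obtained by re-clustering 1 − M (average linkage, cut at
the chosen k) and are renumbered 1..k by descending cluster size.  The
subsample fraction, linkage and distance are configurable since the
upstream tools' defaults are conventions, not published choices.

## Marker selection (two-of-three rule)

For k = 3 subtypes, each feature gets a pooled-variance two-sample t-test
for each of the three subtype pairs on log2 data.  A feature is a marker of
subtype s iff in **both** pairs involving s the two-sided p ≤ p_cut and the
absolute mean log2 difference ≥ the fold cutoff, with a consistent
direction relative to s.  Platform defaults reflect the very different
feature counts: mRNA arrays use p ≤ 0.001 and a 2-fold (1 log2 unit)
difference, protein arrays p ≤ 0.01 and 1.3-fold (≈ 0.379 log2 units).
Direction consistency is required because a feature up versus one subtype
and down versus another characterizes the *other* subtypes, not s; the
rule's collisions (a feature qualifying for two subtypes) are resolved
toward the subtype with the smaller worst-case p and logged.  Fold change
is evaluated on log2 means, matching the scale on which the data are
analyzed.  No multiple-testing correction is applied to the selection (the
raw-p threshold is part of the procedure); a Benjamini–Hochberg column is
reported alongside for transparency.

## Bayesian compound covariate predictor

For a binary contrast, each signature feature's training t-statistic t_i is
its weight, and a sample's compound covariate is c = Σ t_i x_i over
z-scored values.  The class-conditional distributions of c are modeled as
Gaussians (sample moments), and Bayes' rule converts c into a posterior;
computation is in log space so extreme c never underflows.  Multi-class
assignment is one-vs-rest with argmax posterior — the minimal extension of
a dichotomizing classifier, reported per model so alternative schemes can
be compared.  Priors are equal (0.5/0.5) by default because the subtype
prevalence of a validation cohort is unknown at transfer time;
class-proportional priors are available.

Normalization convention: a validation cohort is z-scored per feature
*within itself* before classification (so the predictor survives platform
and location shifts); a single held-out LOOCV sample is standardized with
the training fold's parameters instead.  Classification is therefore
invariant to feature-wise affine rescaling of the target cohort.  Samples
whose best posterior is below 0.5 are flagged low-confidence but still
assigned — every sample gets a class.  Up to 10% of a signature may be
missing from a target cohort (the model restricts itself to the present
features, logged); beyond that the transfer is refused.

Leave-one-out cross-validation re-selects the signature and re-fits all
models inside every fold, so the held-out sample never influences feature
selection.  When no feature clears the thresholds for a class (routine
under label permutation), the fit falls back to the top-ranked features by
worst-pair p so that a classifier is always defined; the fallback is
recorded on the estimator.

## Survival analysis

Kaplan–Meier estimation and Cox proportional-hazards regression are
delegated to lifelines (Efron tie handling; Wald CIs and p-values to match
the "HR (95% CI), P" reporting convention).  The k-group log-rank test is
implemented directly from the hypergeometric moments at each distinct event
time, because the package needs the per-group O − E vector and its
covariance: the Cox partial-likelihood score at β = 0 for a single binary
covariate must equal the log-rank numerator (a classical identity asserted
in the tests, where lifelines also serves as an independent oracle for the
statistic itself).  Samples censored exactly at an event time are counted
at risk for that event.  Scalar biomarkers are dichotomized at the median
(values equal to the median go to "low", a deterministic convention);
all-tied inputs are refused rather than split arbitrarily.  Monotone
likelihood in the Cox fit (|β| > 15) is flagged, not silently returned.

## Synthetic cohort generator

The generator emulates the structure of a three-subtype tumor cohort:

| parameter | default | meaning |
|---|---|---|
| n_per_subtype | (40, 40, 40) | samples per latent subtype |
| n_protein_features / n_mrna_features | 200 / 2000 | RPPA-scale vs array-scale platforms |
| markers_per_subtype | 30 | disjoint up-regulated block per subtype (both platforms) |
| effect_size | 1.5 | mean log2 up-shift of a marker in its subtype |
| noise_sd | 1.0 | i.i.d. Gaussian log2 noise |
| survival_medians | (20, 40, 60) months | subtype 1 is the poor-prognosis (mesenchymal-like) group |
| censor_rate | 0.2 | expected fraction censored |
| driver | freq 0.7, slope 0.8, r 0.83 | copy-number → mRNA → protein cascade |

Survival times are exponential with subtype-specific medians.  Censoring is
an independent uniform window U(0, W) with W solved per subtype so the
censoring probability equals `censor_rate` exactly in expectation.  The
per-subtype survival medians are illustrative (the source cohorts publish
no numeric medians); they imply hazard ratios of 2 and 3 against the
poor-prognosis subtype, which Cox fits on the true labels recover.

The driver feature ("DRIVER", present in the protein, mRNA and copy-number
matrices) is amplified (copy number 3–5) in 70% of subtype-1 samples only;
its mRNA follows 0.8 log2 units per extra copy plus noise, and its protein
is constructed to correlate with the mRNA at Pearson r = 0.83 — the
correlation strength reported for the driver protein in the motivating
cohort.  The knockdown generator defaults (2000 genes, 500 dependent,
3 replicates per arm, effect 3.0, noise 0.2) are sized so a typical planted
responder clears P < 0.001 at df = 4 — the regime in which a triplicate
knockdown screen reports hundreds of dependent genes.

All draws come from one seeded generator in a fixed documented order, so
equal seeds give bit-identical cohorts.

What the generator deliberately does **not** emulate: probe/batch effects,
tumor purity, subclonality, correlated noise between features, mixed-
direction signatures (planted markers are up-only; the selection code
handles both directions).  Passing recovery tests therefore demonstrates
correctness of the machinery under clean planted structure, not expected
performance on real cohorts.

## Problem sizes used in the validation suite

The statistical acceptance tests run the default cohort (120 samples,
2000 mRNA features) over 20 seeds for subtype recovery and transfer, 200
replicates for t-test calibration and for Cox coverage (n = 500 per
replicate, true HR 2), 50 label permutations for the LOOCV null, and 1000
random models for the posterior brute-force check — sizes at which the
binomial tolerances stated in each test are meaningful.

## Known limitations

* Breslow tie handling is not available (lifelines implements Efron only);
  with the continuous synthetic survival times ties never arise.
* One matrix is clustered at a time; joint multi-platform clustering is out
  of scope.
* The BCCP's Gaussian class-conditional model is not recalibrated
  (no isotonic/Platt step); posteriors should be read as model-based
  scores, not calibrated probabilities.
* Quantile normalization refuses missing values; the load-time policy
  (drop features > 20% missing, median-impute the rest) must run first.
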