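# subtypeforge

Consensus-clustering subtype discovery, compound-covariate transfer
classification and survival stratification for tumor expression cohorts.

## The problem

Molecular subtyping studies of hepatocellular carcinoma (and many other
tumors) follow a common statistical arc: cluster a protein (RPPA-style) or
mRNA expression matrix into subtypes, check that the subtypes separate
patient survival, distill each subtype into a marker signature, and carry
that signature to independent cohorts with a classifier so the prognostic
claim can be validated externally.  `subtypeforge` packages that arc as a
tested, seeded, reusable pipeline for anyone who needs to run — or audit —
such an analysis:

* **Consensus clustering** (`ConsensusCluster`, scikit-learn API): for each
  candidate k, B subsampled runs of average-linkage hierarchical clustering
  on 1 − Pearson distance; the consensus matrix entry M(i,j) is the fraction
  of co-drawn runs in which i and j co-cluster.  k is chosen by minimizing
  the CDF ambiguity CDF(0.9) − CDF(0.1) (the proportion of ambiguous
  clustering), with exact ties resolved by the delta-area plot.
* **Subtype signatures** (`SubtypeMarkerSelector` / `select_subtype_markers`):
  all-pairs pooled t-tests; a feature marks subtype s iff both comparisons
  involving s pass p ≤ p_cut and |Δlog2| ≥ fold_cut with consistent
  direction (mRNA defaults p ≤ 0.001, 2-fold; protein p ≤ 0.01, 1.3-fold).
* **Bayesian compound covariate predictor** (`BCCPClassifier`): per subtype,
  a one-vs-rest score c = Σᵢ tᵢxᵢ over z-scored signature features weighted
  by training t-statistics; Gaussian class-conditional densities of c are
  combined by Bayes' rule into posteriors, argmax assigns the class.
  Leave-one-out cross-validation re-selects features inside every fold.
* **Survival** (`km_estimate`, `logrank_test`, `cox_fit`,
  `stratified_km_report`): Kaplan–Meier product-limit curves, the k-group
  log-rank test with exposed O − E vector and covariance, and Cox
  proportional hazards reported as HR (95% CI), P.
* **Synthetic cohorts** (`generate_cohort`, `generate_knockdown`): linked
  protein/mRNA/copy-number matrices with planted subtype blocks, a
  copy-number-driven driver feature, and censored exponential survival, so
  the whole pipeline is testable without any data download.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from subtypeforge import (CohortConfig, ConsensusCluster, Platform,
                          generate_cohort, stratified_km_report, zscore_rows)

cohort = generate_cohort(CohortConfig(seed=1))       # 3 x 40 samples
protein = zscore_rows(cohort.matrices[Platform.protein])

cc = ConsensusCluster(k_min=2, k_max=7, n_resamples=100, random_state=1)
cc.fit(protein.values.T)                             # samples x features
print("chosen k:", cc.chosen_k_)
print("ambiguity by k:", {k: round(v, 3) for k, v in cc.scan_.ambiguity.items()})

truth = [cohort.true_labels[s] for s in protein.sample_ids]
print("ARI vs planted subtypes:", adjusted_rand_score(truth, cc.labels_))

_, lr = stratified_km_report(cc.labels_, cohort.clinical, dichotomize=False)
print(f"log-rank: chi2={lr.chi2:.2f}, df={lr.df}, p={lr.p:.2g}")
```

prints

```
chosen k: 3
ambiguity by k: {2: 0.517, 3: 0.0, 4: 0.035, 5: 0.073, 6: 0.119, 7: 0.167}
ARI vs planted subtypes: 1.0
log-rank: chi2=15.84, df=2, p=0.00036
```

The scan's ambiguity (mass of consensus values between 0.1 and 0.9) drops
to zero at k = 3 — every sample pair is either always or never
co-clustered — so three subtypes are selected; the labels recover the
planted subtypes exactly, and the discovered subtypes separate overall
survival (subtype 1 is generated with the shortest survival median).

The same workflow is available from the shell:

```bash
subtypeforge run-all --seed 1 --out runs/demo
```

which writes consensus matrices, the k-selection report, labels, protein
and mRNA signatures, KM/log-rank tables, the serialized classifier, and a
checksum manifest under `runs/demo/discovery/`, then classifies a second,
independently seeded cohort and stratifies its survival by predicted
subtype under `runs/demo/transfer/`.

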