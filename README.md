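# crossmet

Multilevel OPLS-DA and tree-ensemble analysis of crossover NMR
metabolomics trials.

In a randomized crossover feeding trial every volunteer receives every
treatment, so each subject is their own control — but between-subject
biological variation still dwarfs the treatment signal in serum ¹H-NMR
profiles. `crossmet` implements the inference stack built for exactly
this design:

* **Variation splitting** — two sequential centerings decompose the
  feature matrix into offset, between-subject and within-subject blocks,
  `X = Xm + Xb + Xw` (exact at machine precision).
* **OPLS-DA on the within block** — one predictive component carries all
  Y-related variation (`X = Tp Pp′ + To Po′ + E`), with back-scaled
  loading coefficients cov(x_j, y) coloured by r², subject-stratified
  7-fold cross-validated Q²Y = 1 − PRESS/TSS, and within-subject
  permutation testing (add-one p, floor 1/(n_perm+1)).
* **Forest validation** — random-forest classification with mean
  minimal-depth importance, exact TreeSHAP attributions (local accuracy
  holds on every sample; verified against brute-force Shapley on small
  trees), and Boruta shadow-feature selection with an exact two-tailed
  binomial decision rule at Bonferroni-corrected α.
* **Associations** — Spearman correlation tables between metabolites and
  clinical cardiometabolic variables (fixed Bonferroni threshold
  p < 0.002) and a two-block PLS association map.
* **Synthetic study generator** — a 33-subject, 3-oil crossover emulator
  with Lorentzian spectra, planted treatment effects in paired-effect
  units, and a Gaussian copula linking metabolites to clinical
  covariates, so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
from crossmet import (AnalysisConfig, default_study_config,
                      generate_dataset, run_pairwise)

ds = generate_dataset(default_study_config(seed=7, n_points=2048))
cfg = AnalysisConfig(n_perm=199, ntree=300, boruta_iter=30,
                     grid_step=0.004, seed=1)
rep = run_pairwise(ds, ("FOO", "VOO"), cfg)
print(f"Q2Y = {rep.q2y:.3f}, permutation p = {rep.perm_p:.3f}")
print(rep.metabolite_table[["covariance", "r2", "boruta_status",
                            "direction"]].head(6))
```

prints

```
Q2Y = 0.979, permutation p = 0.005
                   covariance        r2 boruta_status  direction
metabolite
glutamine           -0.002056  0.931593     confirmed         -1
histidine           -0.001307  0.902508     confirmed         -1
creatinine          -0.002771  0.900783     confirmed         -1
creatine            -0.002695  0.900111     confirmed         -1
3-hydroxybutyrate    0.001265  0.890134     confirmed          1
acetone              0.001537  0.874703     confirmed          1
```

The model separates the two oils almost perfectly (Q²Y near 1), and no
permuted relabelling matches it, so p sits at its floor
1/(n_perm+1) = 1/200. The consolidated table ranks metabolites by r² against the
treatment contrast: amino acids and methylamines fall under the
phenol-enriched oil (direction −1) while ketone bodies rise (+1),
matching the effects the generator planted.

The same workflow is available from the shell:

```bash
crossmet simulate --seed 7 --out-dir data/
crossmet analyze  --in-dir data/ --out-dir results/ --seed 1 \
                  --n-perm 199 --ntree 300 --boruta-iter 30
crossmet associate --in-dir data/ --out-dir results/
crossmet report   --in-dir results/ --out-dir figures/
```

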