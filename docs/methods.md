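# Methods

`crossmet` implements the statistical core of a serum-metabolomics
analysis for randomized crossover feeding trials: every subject is
measured once after each treatment, so treatment effects live *within*
subjects while most biological variance lives *between* them. The
package separates those levels explicitly and validates everything it
claims on synthetic studies with known ground truth.

## Multilevel variation splitting

For a feature matrix **X** (L spectra × p variables) with K treatments
per subject, two consecutive centerings give

    X = Xm + Xb + Xw

where **Xm** is the rank-1 column-mean offset, each row of **Xb** is its
subject's centered mean (between-subject, "biological" variation), and
**Xw** centers each subject's K rows around that mean (within-subject,
"treatment" variation). Both steps are exact subtractions, so the
reconstruction identity holds at machine precision and, for balanced
designs, ⟨Xb, Xw⟩ = 0. Balanced designs are required by default;
`allow_unbalanced=True` switches to per-subject K_i. Subjects with a
single row are always rejected — they carry no within-subject
information. The module never imputes; incomplete subjects are the
caller's problem.

## OPLS-DA on the within-subject block

Discrimination between two treatments uses the within block restricted
to the pair, with y = ±1. The fit is NIPALS-based orthogonal signal
correction: the predictive weight w ∝ X′y is fixed first; each
orthogonal component removes the part of the dominant loading direction
orthogonal to w (scores T_o, loadings P_o); one predictive component
(T_p, P_p, Y-loading c) is fitted on the filtered matrix. All Y-related
variation is thereby forced into the single predictive component. By
construction the predictions of OPLS with 1 + a components equal those
of PLS with 1 + a components for a single response — the test suite
asserts this equality to 1e-8 on random data, which pins down the
filtering algebra.

Defaults: `n_orth=1` (selectable); mean-centering only (the within
block is already centered; unit-variance scaling is available behind a
flag but off by default since spectral data keep their intensity
units); component signs are normalised so the largest-|w| entry is
positive, making fits bit-reproducible.

Loading plots use the back-scaled convention: per variable, the
covariance cov(x_j, y) on the original intensity scale (signed
magnitude) coloured by r², the squared Pearson correlation with y.

### Validation respects the paired structure

* **Q²Y** = 1 − PRESS/TSS from 7-fold cross-validation whose folds
  partition *subjects*: both of a subject's paired rows leave together,
  otherwise the held-out half of a pair leaks its twin's subject effect.
  Training folds re-center X and y; held-out rows are filtered through
  the training orthogonal components before prediction.
* **Permutation testing** relabels treatments *within* each subject —
  the exchangeability group of a crossover — and recomputes the
  cross-validated Q²Y per permutation. The p-value uses the add-one
  estimator (#{Q²_perm ≥ Q²_obs}+1)/(n_perm+1), so with 1000
  permutations the smallest reportable value is 1/1001 ≈ 0.001; p = 0 is
  never reported. Calibration is checked by simulation: under null
  generators the rejection rate at 0.05 stays inside the exact binomial
  95% band.

## Forest-based feature selection

Forests are scikit-learn `RandomForestClassifier` ensembles
(bootstrap per tree, `mtry = floor(√p)` candidate features per split,
5000 trees at full scale). Three importance layers sit on the exposed
tree structure:

* **Mean minimal depth** — per tree, the depth of the shallowest node
  splitting on a feature (root = 0). Trees that never use a feature
  contribute that tree's maximal depth + 1 (the surrogate-free fill-in;
  the convention is recorded in the report object). Smaller mean =
  more important; the report is sorted ascending.
* **Exact TreeSHAP** — additive per-sample attributions of the forest's
  class-1 probability, computed by the polynomial-time path-weight
  recursion with cover-weighted (path-dependent) conditional
  expectations. Implemented in-package against the sklearn tree arrays;
  correctness is enforced two ways: local accuracy (baseline + row sum
  = prediction) on every sample of every forest, and equality with
  brute-force Shapley enumeration over all coalitions on small trees.
* **Boruta shadow-feature selection** — per iteration, every active
  feature gets a row-permuted shadow copy; a forest on
  [originals, shadows] yields OOB permutation-importance Z-scores
  (per-tree accuracy drop normalised by its standard error; features a
  tree does not use have an exact zero drop). A feature scores a *hit*
  when its Z strictly exceeds the maximum shadow Z (MZSF; ties count as
  no hit). Status is decided by an exact two-tailed binomial test (null
  hit rate 0.5) at a Bonferroni-corrected 0.005; the divisor is the
  number of features undecided at the first test and is held fixed so
  decisions are monotone across iterations. Rejected and shadow
  features are dropped between iterations; features whose hit count can
  no longer reach either threshold before the iteration cap are frozen
  as tentative early (a pure cost optimisation — their final status is
  already determined). Defaults: 500 iterations, α = 0.005.

Two different importance measures coexist deliberately: the headline
ranking uses minimal depth (structure-only, error-independent), while
Boruta's internal VIM is the permutation Z-score.

## Associations

Spearman correlations (average ranks; t-approximation p-values) between
each metabolite and each clinical variable, flagged significant at a
fixed p < 0.002 — the Bonferroni level corresponding to 25 assessed
variables; an override recomputes 0.05/m from the actual matrix if
desired. Constant columns yield undefined rho, reported NS. Correlations
pool post-intervention values across treatments by default; restricting
to one arm is a flag. A two-block PLS (metabolites as predictors,
clinical panel as multi-response) supplies biplot coordinates for a
joint association map; the first latent covariance equals the leading
singular value of the cross-covariance matrix, which the tests assert
against a direct SVD.

## Spectral preprocessing

Spectra are two-column ppm/intensity traces, stored ascending. The
preprocessing chain is: (1) chemical-shift referencing — translate the
axis so the tallest peak in a search window around the α-glucose
anomeric proton sits at 5.223 ppm; (2) excision of the residual-water
band, default 4.5–5.1 ppm (the community-standard artefact window,
deliberately below the anchor); (3) digitisation — interpolation onto a
common full-resolution grid (default 0.001 ppm, configurable) or exact
piecewise-linear bin integrals of configurable width, whose sum equals
the full-range trapezoid integral by construction. No normalisation is
applied by default; total-area and probabilistic-quotient normalisers
exist behind explicit flags and are logged loudly when enabled. Phase/
baseline correction and peak alignment beyond global referencing are out
of scope (synthetic spectra are generated phased).

## The synthetic study generator

The generator emulates a 33-subject, 3-treatment (VOO / FOO / FOOT)
crossover. True concentrations follow a two-level Gaussian model:
baseline_m + subject effect N(0, σ_b²) + residual N(0, σ_w²), with
defaults σ_b = 0.15, σ_w = 0.075 (between-subject SD twice the
within-subject SD, the regime that motivates multilevel analysis).
Treatment effects are planted additively on the *concentration* scale
before spectral rendering, so peak overlap is an honest nuisance for
every downstream stage. Effect sizes are specified on the
paired-difference scale (Cohen's d_z): a planted d shifts the two arms
by ±d·√2·σ_w/2, so the paired mean difference divided by the paired SD
recovers d in expectation. Spectra are sums of Lorentzian resonances
(the canonical NMR lineshape) from a 17-metabolite serum library with
nominal literature shifts, plus i.i.d. Gaussian noise; the α-glucose
anomeric doublet is always present so referencing is exercisable.

Clinical covariates come from a Gaussian copula on the standardized
true concentrations: a requested Spearman ρ_s maps to a latent Pearson
loading 2·sin(π·ρ_s/6). The mapping is exact for jointly Gaussian
margins; planted treatment effects make metabolite margins finite
mixtures, which can raise the realized rank correlation above the
requested target in the fully loaded default study — the copula
recovery guarantee (±0.1 at n = 200) is stated, and tested, for
configurations without planted effects on the loaded metabolites.
Sequence/period effects default to zero — the washed-out crossover is
modelled as order-free — and an additive period knob exists for
sensitivity analyses.

What the generator does *not* emulate: J-coupling multiplets, baseline
and phase artefacts, peak-position drift with pH/ionic strength,
non-Gaussian biological heavy tails, and missingness. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated model, not robustness to every artefact of real serum spectra.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of the
full-scale defaults: forests of 120–1000 trees instead of 5000,
199–200 permutations instead of 1000, Boruta capped at 18–30 iterations
instead of 500, and a 0.004-ppm analysis grid on 2048-point spectra
instead of the 0.001-ppm default. These sizes were chosen so the whole
validation battery runs on a laptop while leaving every statistical
margin wide: planted effects are detected with Q²Y > 0.9, far above the
0.5 bar the recovery tests enforce. Degenerate inputs fail loudly: empty peak
libraries, single-row subjects, constant feature matrices, single-class
responses, folds without both classes (folds are redrawn a bounded
number of times, then error). Ties in the Boruta hit rule count against
the feature; ties in referencing resolve to the first grid apex.

## Known limitations

* The OPLS implementation is single-response (two-class pairwise
  models); multi-class single-model OPLS-DA and O2PLS are out of scope.
* TreeSHAP is pure Python; it is exact but not fast — at the 5000-tree
  full-scale setting, SHAP computation is the pipeline's slowest stage,
  and desk-scale forest sizes are recommended for interactive use.
* Minimal-depth fill-in and the Boruta Bonferroni bookkeeping follow
  stated conventions among several defensible ones; both are surfaced
  in result objects rather than hidden.
* Clinical copula targets are guaranteed only marginally (pairwise
  metabolite–clinical); the joint correlation structure among clinical
  variables is whatever the shared metabolite latents induce.
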