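# Methods

`ctcpredict` implements a complete discovery workflow for qRT-PCR
expression profiling of CellSearch-enriched circulating tumor cells (CTCs):
normalization and quality gating of raw cycle-threshold (Ct) data,
cross-validated discovery of a gene signature separating good from poor
responders, significance assessment by label permutation, diagnostic 2x2
test performance, and survival analysis of the resulting dichotomous
profile. This note documents the models, the defaults and their
rationale, and what the synthetic cohorts do and do not establish.

## Normalization and quality control

Relative expression is the delta-Ct,

    dCt(g, s) = mean( Ct of detected reference genes in s ) - Ct(g, s),

with reference genes *HMBS*, *HPRT1* and *GUSB*. Higher dCt means more
transcript; a one-cycle increase in a target's Ct lowers its dCt by
exactly one, and adding a constant to every Ct of a sample leaves all of
its dCt values unchanged (both properties are asserted by tests). The
reference mean uses the *detected* references only; a sample is
unevaluable only when none of the three amplifies. Undetected targets
are imputed at Ct = 40 cycles before normalization — the common qPCR
detection-limit convention — so they stay finite and rank lowest. Both
the imputation Ct and the reference set are configurable.

Two sample gates run in fixed order:

1. **Reference gate** — mean reference Ct must be <= 26 cycles (the
   boundary value passes). This screens out samples with too little
   intact RNA.
2. **Epithelial gate** — among reference-passing samples, at least
   `min_detected` (default 1) genes of a 12-gene epithelial cluster must
   be detected with dCt >= `min_delta_ct` (default −15, i.e. within 15
   cycles of the reference mean). Lack of epithelial signal indicates the
   enriched fraction contained essentially no CTCs, only leukocyte
   background.

The published account of the epithelial criterion is qualitative
("sufficient expression"), so the default rule here is an explicit,
configurable operationalization, not a reconstruction of the original
threshold. Exclusion accounting is reported gate by gate so a cohort's
attrition (e.g. 78 → 73 → 45) is auditable.

Before signature discovery, genes are reduced to the top 75 % most
variable (unbiased variance of dCt across samples, ties broken by panel
order, `ceil(0.75 * G)` kept — 70 of 93 targets). The filter is applied
once, before cross-validation: it is label-blind, so re-applying it per
fold would change nothing about selection bias while complicating
provenance.

## Signature discovery

Responder classes come from the clinical table: a *poor responder* has
progression or death before 274 days (9 months at 365.25/12 days per
month, rounded; configurable). A sample censored before the cut-off has
an unknown 9-month status and is excluded from training with a warning
rather than silently labeled.

Per-gene differential expression uses the pooled-variance two-sample
t-statistic, signed good-minus-poor (negative t = higher expression in
poor responders), with a two-sided p from the t distribution on n − 2
degrees of freedom. Genes with p < 0.1 are selected, ordered by
ascending p and then panel order for determinism.

The classifier is a soft-margin linear SVM (cost C = 1) on per-gene
standardized features; the training center and scale are stored in the
model and re-used verbatim at prediction time. A positive decision score
calls the sample a poor responder ("unfavorable profile"). Linear kernel
plus standardization is the small-n convention and keeps the gene weights
interpretable; the cost parameter is exposed but not tuned — with tens of
samples there is no spare data to tune it on honestly.

**Leave-one-out cross-validation (LOOCV)** nests the entire selection
inside each fold: the held-out sample is removed *before* the t-tests, so
its values cannot influence which genes that fold's classifier sees (a
test perturbs the held-out sample and asserts the fold's gene list is
unchanged). A fold whose training split selects no gene still emits a
call — the training majority class — so the error estimate is always
defined on all n samples.

**Permutation significance.** Class labels are permuted uniformly
(B = 100 by default) and the full nested LOOCV is rerun per permutation.
The add-one estimator

    p = (1 + #{permuted error <= observed error}) / (B + 1)

never returns zero; its floor at B = 100 is 1/101 ≈ 0.0099, i.e. a
best-possible observed error reports p ≈ 0.01.

**The reported signature** comes from selection and training on the full
cohort (`finalize_predictor`), while the error estimate and its
permutation p come from the nested folds. This separates the two roles:
the folds provide an (approximately) unbiased error, the full-cohort fit
provides the single model one would carry to an independent cohort.

## Test performance and survival

The profile is tabulated against the observed 9-month outcome with the
poor responder as the positive class and the unfavorable profile as the
positive call. Sensitivity, specificity, PPV and NPV are the usual 2x2
ratios; a zero denominator reports the metric as undefined (NaN), never
as 0. The association test is Pearson's chi-square **without** Yates
continuity correction on df = 1 — the uncorrected statistic is what
reproduces the published values (10.93 from counts 22/4/7/12; 0.016,
p = 0.899 from 16/19/17/19) exactly.

Survival uses lifelines: Kaplan-Meier product-limit curves per profile
group, the unweighted logrank test (cross-checked against a hand-rolled
O-minus-E implementation in the tests), and Cox proportional-hazards
models by partial-likelihood maximization with Efron tie handling
(lifelines' default; the original analysis software's tie method is not
recoverable). The standard covariate encoding is: CTC count dichotomized
at 5 per 7.5 mL, disease-free interval as two dummies (>5 y,
metastatic-at-diagnosis) against the <=5 y reference, dominant relapse
site as visceral vs non-visceral, and the unfavorable-profile indicator.

## Clustering

Heatmap-ready output: per-gene median centering (sign encodes
above/below the across-sample median), then average-linkage (UPGMA)
agglomeration of both samples and signature genes under the
1 − centered-Pearson-correlation distance — the conventional default of
the Cluster 3.0 lineage, whose CDT/GTR/ATR file conventions the export
follows. A zero-variance item has no defined correlation and is assigned
the maximal dissimilarity 1 (logged). No optimal leaf reordering is
applied; ties break by input order, so output is deterministic. Linkage
heights are verified against an exhaustive brute-force agglomeration
oracle on all small instances.

## Synthetic cohorts

The generator produces cohorts with exactly the structure the analysis
assumes, with responder classes drawn first and everything else
conditioned on them:

* **Panel**: 96 genes — 3 references, 12 epithelial, 81 targets, of which
  8 are informative (all counts configurable).
* **References**: Ct ~ Normal(22, 0.8) cycles for every sample — stable
  by construction.
* **Epithelial cluster**: expression rises with the sample's CTC count
  (Ct ≈ 36 − 1.2·log2(count + 1) plus gene offsets); in samples with
  fewer than 5 CTCs each epithelial gene independently drops out
  (undetected) with probability `dropout_rate_low_ctc` (default 0.5).
  CTC counts are lognormal around the cohort-typical median of 8, heavier
  in poor responders. Undetected values are stored as missing with a
  detection flag — never as a numeric stand-in — so downstream code must
  own its imputation policy.
* **Informative genes**: shifted by `effect_size` cycles (default 2.5)
  between classes with mixed directions — roughly three quarters higher
  in poor responders and the rest higher in good responders, the
  mixed-sign structure real responder signatures show. A same-direction
  signature would be a uniform level shift across the signature, which
  the centered-correlation clustering distance is provably blind to.
* **Survival**: consistent with the class definition, as in a cohort
  whose censored patients were all followed beyond the response cut-off.
  Poor responders always have an observed event, at a time drawn from an
  exponential with nominal median `median_pfs_poor_days` (default 150 d)
  conditioned on falling before 274 d — the realized class median is
  therefore ≈ 96 d at the default. Good responders fail at 274 d plus an
  exponential tail scaled so the class median equals
  `median_pfs_good_days` (default 550 d), and are independently censored
  after the cut-off with probability `censor_rate` (default 0.1). The
  default medians put the two-group hazard ratio and the overall cohort
  median PFS (~1 y) on the scale the discovery setting assumes.
* **Null cohorts** force the effect to zero and drive CTC counts and
  survival by an independent permutation of the classes, preserving all
  marginal distributions while breaking every label link.

Everything is reproducible bitwise from the seed.

What the simulations do *not* emulate: leukocyte background transcripts,
pre-amplification bias, inter-plate calibration, enrichment efficiency,
correlated co-expression among target genes, and non-exponential
survival. Passing tests therefore demonstrate that the *procedure* is
correct and calibrated under its stated assumptions — not that any
particular gene list would replicate in patients.

## Numerical choices and degenerate inputs

* Constant gene with equal class means: t = 0, p = 1 (not NaN); a gene
  with zero pooled variance but unequal means gets p = 0.
* Zero-scale features at standardization use scale 1 (no division by 0).
* All-constant expression matrix in the variance filter keeps the first
  `ceil(fraction · G)` genes in panel order with a logged warning.
* Boundary reference mean exactly at the cutoff passes the gate.
* The permutation p is reported with its floor 1/(B+1); it can never be
  0 and is monotone non-increasing in the observed separation.
* Cox non-convergence or separation raises a diagnostic error rather
  than returning coefficients.

## Problem sizes used in the shipped checks

The packaged verification runs use the discovery-scale geometry
throughout: n = 45 samples (19 poor / 26 good), 96-gene panels, 100
permutations; 50 replicate cohorts for signal recovery, 100 (25 in the
quick suite) null cohorts for calibration, and 100 replicates of n = 500
for Cox parameter recovery. These sizes give the binomial noise on each
reported rate a standard error well inside the bands being checked.

## Known limitations

* The epithelial gate and undetected-Ct conventions are explicit
  stand-ins for rules the original study defines only by reference.
* The 8 published gene identities cannot be recovered — no patient-level
  data are public — so recovery claims are about planted synthetic
  signals only.
* Hazard ratios from n = 45 with a handful of covariates are fragile;
  the Cox fit warns on near-separation, which a perfectly discriminating
  profile on a small cohort will trigger.
* LOOCV error on tiny cohorts has high variance; the permutation test
  quantifies significance but not stability of the gene list (per-fold
  lists are exposed for exactly that inspection).
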