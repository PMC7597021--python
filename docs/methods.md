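# Methods

This note documents the models, estimators and numerical choices behind
`acehap`, and what the synthetic-data experiments do and do not show.

## The selection model

Haplotype classes at the resistance locus are treated as alleles of a
single locus: the window behaved as tightly linked haplotype blocks, so
recombination within it is ignored for the duration of the experiment.
With per-class selection coefficients `s_i` (relative fitness
`w_i = 1 + s_i`) and dominance `h`, diploid genotype fitness is

    w_ii = 1 + s_i,       w_ij = 1 + h (s_i + s_j)   (i ≠ j),

so `h = 0.5` (co-dominance, the default throughout) makes heterozygote
fitness the arithmetic mean of the homozygotes. One generation of
deterministic viability selection maps class frequencies as
`p_i' = p_i (Σ_j p_j w_ij) / w̄`. For two classes this is the textbook
recursion `p' = p (p(1+s) + q(1+hs)) / w̄` implemented in
`expected_trajectory`.

### Fitting s

`estimate_s` fits the two-parameter deterministic model `(p0, s)` to an
observed frequency trajectory by least squares on the frequency scale
(`scipy.optimize.least_squares`, box bounds `s ∈ [−0.5, 0.5]`,
tolerances 1e-15; the initial `s` is the logit-frequency slope divided
by `2h`). Frequencies exactly at 0 or 1 are replaced by the
pseudo-frequency `1/(2 · pool haplotypes)`. Drift is **not** part of
the objective — the fit is to the deterministic expectation, with Ne
carried only as metadata. Two consequences, both visible in the
calibration experiments (`analysis/07_calibration.py`):

* per-replicate estimates scatter with the full drift noise
  (sd ≈ 0.04–0.05 per replicate at Ne = 250 over ~50 generations;
  ≈ 0.02 for the mean of five replicates) — this is a property of the
  experiment, not of the optimizer, and is essentially identical for
  every estimator variant we tried;
* a small positive bias (≈ +0.004 on the contrast at the default
  scenario) remains because the expectation of a drifting trajectory is
  not the deterministic path of its expected parameters.

### Marginal versus joint fits, and why the contrast needs the latter

The classical procedure fits each class marginally against the pooled
"rest" and subtracts: contrast = ŝ_1a − ŝ_1b. In a three-class system
with a strongly selected class 2 this is structurally biased: the mean
fitness of each class's background changes over the experiment, and it
changes *differently* for 1a and 1b (1b's background contains the
declining 1a, and vice versa). On noise-free default trajectories the
marginal contrast is −0.076 when the generating contrast is −0.055.

`estimate_s_joint` therefore fits all classes at once: one selection
coefficient per class (anchored at the reference class 1b = 0) plus the
founder composition (softmax-parameterised), least squares over the
full generation × class frequency matrix. On deterministic data it is
exactly self-inverse; on stochastic data its contrast is unbiased to
within Monte-Carlo error. The pipeline reports both: the joint contrast
as the headline, the marginal fits for comparability with the classical
procedure.

## Class calling

1. **Failed crosses.** Haplotypes are derived from line × reference
   strain F1s, so a valid haplotype shows heterozygous calls wherever
   it carries a non-reference allele. A haplotype with only homozygous
   calls (no alternative allele at any non-missing site) is a failed
   cross and is excluded before clustering. Note the corollary: a
   genuinely all-reference haplotype is indistinguishable from a failed
   cross under this rule.
2. **Clustering.** Average-linkage agglomerative clustering on the
   fraction of differing non-missing sites, computed on **shared**
   polymorphisms only (minor allele in ≥ 2 haplotypes). Private
   variants carry no information about deep class structure, and in the
   diverse class they would otherwise push within-class distances to
   the same magnitude as the between-class distance. The dendrogram is
   cut into its two top-level groups; the cut is accepted only if the
   mean between-group distance is at least twice the larger mean
   within-group distance (recombinant chimeras legitimately merge at
   intermediate heights, which is why a merge-gap rule is not usable).
3. **Recombinants.** On the provisional clusters, per-cluster consensus
   sequences define diagnostic sites; a haplotype whose diagnostic
   alleles contain a run of ≥ `min_block` = 5 consecutive class-1-type
   sites *and* a run of ≥ 5 class-2-type sites is excluded as a
   class-1/class-2 recombinant. The block criterion is a design choice;
   the source procedure states the rule's purpose but no threshold.
4. **1a/1b.** Within class 1 (the cluster containing the
   resistance-triple carriers; fallback: the lower-diversity cluster),
   carriers of all three resistance alleles are 1a, non-carriers 1b; a
   strict subset contradicts the observed haplotype structure and is an
   error by default (`allow_anomalous` downgrades it to a flag).

**Markers** are sites at which every retained class-1 haplotype carries
one allele and every retained class-2 haplotype the other; missing
calls are ignored but any conflicting call disqualifies the site, and
the resistance sites (which tag 1a *within* class 1) are excluded.

**Nucleotide diversity** is the mean pairwise difference count over all
n(n−1)/2 sequence pairs divided by L; pairs skip sites missing in
either sequence. L defaults to the 36,265 bp gene length and is
configurable; diversity is reported for class 1 = 1a+1b pooled and for
class 2.

## Trajectories

Pool-seq SNPs are filtered to a pooled minor-allele count ≥ 5 and
coverage ≥ `min_coverage` (default 10) in every sample; markers failing
anywhere are dropped regime-wide, not per sample. Per sample,
`f_1` is the median class-1-allele frequency over usable markers (even
counts: mean of the central order statistics), `f_1a` the median of the
three resistance-allele frequencies, `f_1b = f_1 − f_1a` clamped at 0
(the clamp fires in ≲1% of default-coverage samples and is counted),
`f_2 = 1 − f_1`; the triple is renormalised to sum to one and the raw
values are kept alongside.

## Temporal Ne

Per site `F_c = (x − y)² / (z(1 − z))` with `z = (x + y)/2`; the
average over polymorphic sites is corrected by the two-stage sampling
variance share of each time point, `1/S + 1/R − 1/(S·R)` (pool of S
haplotypes, R reads), and `Ne = −t / (2 ln(1 − F_corr))`. Non-positive
corrected F means no detectable drift and returns +∞ with a flag; fewer
than 50 polymorphic SNPs triggers a warning. Calibration: median
estimate 246 at true Ne = 250 (1000 SNPs, t = 15, coverage 80×).

Ne must be estimated from *neutral* SNPs. Every site in the resistance
window is linked to the selected classes, and `analysis/04` shows the
consequence: the window-based estimate is ~4-fold too small because
selection masquerades as drift.

## CMH scans

Classic mode is the 1-df Cochran–Mantel–Haenszel χ² over the K
replicate 2×2 allele × generation tables, no continuity correction
(verified to 1e-10 against an independent textbook-formula oracle and
against `statsmodels.stats.contingency_tables.StratifiedTable`).
Adjusted mode is the score statistic
`(Σ_k (x_k − y_k))² / Σ_k Var_k` with

    Var_k = z(1−z) [ 1 − (1 − 1/(2 Ne_k))^{t_k}
                     + (1/S + 1/R0 − 1/(S·R0)) + (1/S + 1/Rt − 1/(S·Rt)) ]

referred to χ²(1). Under a simulated neutral null (1000 SNPs, 5
replicates, Ne 250, coverage 80×) the adjusted test's type-I error at
α = 0.05 is ≈ 0.047 and its p-values are uniform (KS ≈ 0.02), while the
classic test rejects ≈ 39% of neutral sites — drift makes it wildly
anticonservative on E&R time scales. The scan uses the first and last
generation of each replicate; raw p-values are reported, with an
optional Benjamini–Hochberg column (off by default).

## Dose–response

Probit GLM (`statsmodels`) of deaths/exposed on log₁₀ dose;
`LD50 = 10^(−a/b)` with a delta-method CI on the log-dose scale
(empirical 95% coverage 0.94 at the study's dose designs). Dose-0
controls are excluded from the fit (log undefined); Abbott's
natural-mortality correction is implemented but off by default.
Complete separation (no partial-mortality observation) leaves the slope
unidentified and returns a flagged fit with an unbounded CI instead of
crashing. A heterogeneity χ² against the pooled fit is reported; vials
are pooled rather than modelled with vial-level overdispersion.

## The synthetic generator

`SimConfig` defaults are the study conditions: 5 replicates per regime,
census 1000, Ne per replicate (cold 209/255/259/198/175, hot
252/229/268/209/245), sampling at generations 0/11/21/31/41/51 (cold)
and 0/15/37/59 (hot), founder haplotypes 19/8/5 (1a/1b/2, resistance
triple at 59%), 166 markers, within-class π targets 0.0004/0.0082,
Pool-seq of the whole census at Poisson(80×) coverage. Class fitness
defaults encode a resistance cost of −0.055 (cold) / −0.031 (hot)
relative to 1b, and a class-2 advantage of 1.7× the cost magnitude —
the diverse susceptible class is the fittest, as observed. The G368A
resistance variant is placed on all 1b and two class-2 haplotypes
(10/32 ≈ 31%) and takes no part in class fitness. Coverage is modelled
as Poisson(80) since the source reports no coverage distribution.

Construction details: class-2's archetype is the reference; class 1
carries the alternative allele at every marker; private mutations are
Poisson per haplotype at unique sites, with the per-haplotype rate
`M = (π_target · L − D_archetype)/2` chosen so expected π (including
the archetype differences at the resistance triple and G368A) matches
the target. Two failed crosses (all-reference rows) and two
class-1/class-2 chimeras (breakpoint between the 40% and 60% marker
quantile) are appended, mirroring the 36 → 32 founder design. Drift is
multinomial at 2·Ne haplotypes per generation (census size affects only
pool sampling); Pool-seq is a per-site binomial draw of 2·pool_size
haplotypes followed by binomial reads — the two-stage variance
`p(1−p)(1/R + 1/S)` is verified to ~10%. Within-class composition is
held at founder proportions through time (no drift *within* classes),
which is the price of simulating classes rather than 2N individual
haplotypes. One master seed feeds per-component `SeedSequence` streams;
identical config + seed reproduces the sync output bit for bit.

### What the synthetic experiments do not show

No recombination, migration, overlapping generations, sex-specific
selection or within-class drift; no mapping/variant-calling noise
(coverage is Poisson, not the long-tailed empirical distribution, and
there are no repeat-masking artefacts); starting frequencies of neutral
calibration panels are uniform on [0.1, 0.9] rather than an empirical
site-frequency spectrum. Passing recovery tests therefore validates the
estimators under the stated model, not robustness to these real-data
features.

## Known limitations

* The deterministic-expectation s-fit leaves drift-scale scatter in
  per-replicate estimates and a small positive bias (above); a
  diffusion-likelihood fit would remove the bias at substantial cost.
* The marginal-fit contrast is biased under strong background
  selection; it is reported for comparability but the joint fit is the
  headline.
* The Fc Ne estimator assumes unlinked neutral SNPs; applying it inside
  a selected window severely underestimates Ne.
* The all-homozygous exclusion cannot distinguish a failed cross from a
  truly reference-identical haplotype.

## Problem sizes

Default test-suite ensembles: 200 simulated experiments for contrast
recovery, 1000 neutral sites for CMH calibration, 200 × 1000-SNP panels
for Ne calibration, 200 simulated assays for LD50 coverage — sizes at
which Monte-Carlo error is comfortably below the assertion bands while
the whole suite stays interactive.
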