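# Methods

This note documents the models, parameter choices, and numerical
conventions behind `pdokit`, and what the synthetic-data tests do and do
not establish about real data.

## Copy-number indices and similarity

A sample is a set of non-overlapping allele-specific segments with
major/minor copy numbers cnA ≥ cnB ≥ 0. Allele-specific ploidy (asP) is
the segment-length-weighted mean of cnA+cnB; genomic burden (GB) is the
length-weighted fraction of the genome not in the wild-type state
(1, 1). The two are linked: asP = 2·(1−GB) + (mean total copy number
over aberrant territory)·GB, which the test suite uses as an internal
consistency check. Wild-type comparison uses an absolute tolerance of
1e−9 so that continuous segment estimates equal to 1 within rounding
count as wild-type.

For cohort similarity, continuous copy numbers are discretised per gene:
each gene takes the state of the segment containing its midpoint,
rounded half-away-from-zero and floored at 0. The midpoint rule (rather
than a length-weighted mode over overlapping segments) is deterministic
and order-independent; genes uncovered in *any* sample are dropped
cohort-wide so all distances compare identical vectors. Pairwise
distance is the Euclidean norm between concatenated (cnA, cnB) gene
vectors. Distances are min–max rescaled over **all** off-diagonal pairs
of the cohort — not only inter-patient pairs — so the closest pair
anchors similarity 1 and the most dissimilar pair anchors 0; a cohort in
which all pairwise distances coincide has no defined rescaling and is
rejected. Matched-pair similarities are compared against all remaining
cross-sample pair similarities (C(n,2) − n_matched of them) with a
two-sided rank-sum test.

Rank-sum p-values throughout the package are exact (full enumeration of
the null) when both groups have ≤ 10 observations and the pooled values
carry no ties, and use the normal approximation with tie correction
otherwise. Hierarchical clustering of the distance matrix uses average
linkage; the linkage choice is recorded in the similarity output
metadata since reasonable alternatives (complete, Ward) exist. Ordinal
trends across the three ordered tumor classes (low-grade NMIBC <
high-grade NMIBC < MIBC) use Kendall's tau-b with tie correction.

## SNV filtering, burden, and clonality

Quality filters are conjunctive and boundary-inclusive: tumor coverage
≥ 20 reads, allelic fraction ≥ 0.08, tumor alt reads ≥ 5, normal alt
reads = 0. Deleterious means predicted impact HIGH or MODERATE. Tumor
mutational burden is the filtered SNV count divided by the sequenced
territory in Mb; the territory is configurable (`territory_mb`, default
30) because capture-design size and effectively covered bases are both
defensible denominators.

SNV identity is the (chrom, pos, ref, alt) tuple; multi-allelic records
must be split upstream. Shared/private partitioning of a matched pair is
tested with a chi-squared statistic on the 2×2 table (shared, private) ×
(PT, PDO) without continuity correction — counts in the intended setting
are in the hundreds, where the correction only biases.

Clonality uses the standard multiplicity-corrected cancer-cell-fraction
estimate. With purity p, local total copy number CN_t and observed
allelic fraction AF, the expected DNA content at the locus is
D = p·CN_t + 2(1−p); multiplicity is m = clamp(round(AF·D/p), 1,
max(cnA, cnB)) and CCF = AF·D/(p·m). The raw value is kept up to 1.25
(values above 1 indicate noise or mis-specified copy number), and the
reported CCF is capped at 1. In the pure-diploid limit this reduces to
CCF = 2·AF. Loci outside any segment fall back to the diploid state.
Longitudinal comparisons use a paired Wilcoxon signed-rank test over
SNVs shared between baseline and relapse (identical paired values give
p = 1 by convention rather than an undefined statistic), an unpaired
rank-sum fallback when nothing is shared, and a rank-sum test of lost
(baseline-only) versus conserved baseline clonality.

## Over-representation and recurrence

Per sample, genes carrying ≥ 1 deleterious SNV are tested against each
gene set with the one-sided hypergeometric tail P(X ≥ k); the background
defaults to the union of collection genes and can be overridden with a
capture-design list. The "Q-value" is the Benjamini–Hochberg adjusted p
across the sets of that sample. Terms with q < 0.2 in at least
ceil(20% × n) of the included samples (recurrence uses the ceiling — at
least one fifth, rounded up, which is deterministic and conservative)
form the recurrent shortlist; excluded samples (e.g. relapses of a
patient already in the cohort) are removed from numerator and
denominator alike.

## Drug-screen statistics

z = (X_s − mean(X_v)) / SD(X_v) per treated replicate, with SD the
sample (n−1) standard deviation of the vehicle replicates — so vehicle
wells z-scored against themselves have mean 0 and sample SD 1 exactly.
Cisplatin, gemcitabine, and their combination are referenced to the H2O
vehicle; all other conditions to DMSO. Fold-change is readout over mean
vehicle readout; growth inhibition is 1 − fold-change. z-scores are
invariant under affine rescaling of the whole plate.

Hit calling runs a one-way ANOVA across all conditions sharing a
vehicle class, then Dunnett many-to-one comparisons of each drug
against its vehicle. The Dunnett p integrates the many-to-one
multivariate t via randomized quasi-Monte Carlo with a fixed internal
seed, making results reproducible to ~1e−3; both hit thresholds are
inclusive (mean z ≤ −1.5 AND adjusted p ≤ 0.05). Because the adjusted p
uses the pooled within-group variance of all conditions, it is bounded
below by the unadjusted pooled-variance contrast p, not by a two-sample
t-test with per-group variances. Missing drug × sample cells stay
missing (masked), never imputed; inter-drug Pearson correlations are
pairwise-complete and masked below 3 complete pairs.

## Pharmacogenomic association

Features are binary per sample: deleterious SNV per gene; copy-number
categories from the discrete (cnA, cnB) — homo-deletion (0,0),
hemi-deletion (1,0), gain when total copy number exceeds the sample's
rounded asP, amplification when it is ≥ rounded asP + 3 (the gain
baseline follows each sample's own ploidy so polyploid genomes are not
wholesale "gained"; both cutoffs are configurable); and pathway
enrichment (q < 0.2). A sample absent from an input is missing, not 0.

The association model is replicate z ~ intercept + feature with a
per-sample random intercept, fit by REML; the effect is the fixed
coefficient in z-score units with a two-sided Wald p. When the
random-intercept variance collapses to zero the optimizer can hit a
singular matrix; the fit retries with a gradient-free method and, if
still singular, falls back to OLS on per-sample mean z — where the
coefficient is exactly the two-group mean difference, which is also the
model's reduction when every sample has one replicate. Features with
fewer than two samples at either level are reported untestable rather
than fitted. FDR is Benjamini–Hochberg per drug across features
(matching a screen analysed drug-by-drug), flagged at the 10% level;
unadjusted p-values are also reported.

## Synthetic cohort generator

The generator emulates the cohort structure the analyses assume, at desk
scale. Defaults are the study conditions: 13 matched PT/PDO pairs,
purity uniform on (0.6, 0.9), 25% polyploid pairs, shared-SNV fraction
0.73, 400 SNVs per sample over 30 Mb of territory, coverage ~
Poisson(80) with binomial alt reads, 7 vehicle and 3 treated replicates
per plate condition, vehicle readouts Normal(mu=10 000, CV 8%). The
genome is abstracted to 200 equally spaced genes on 5 pseudo-
chromosomes, which is sufficient for every statistic computed and keeps
the suite fast. Private SNVs carry CCF = 0.4 — subclonal (their allelic
fractions sit stochastically below the shared ones) yet mostly above the
detection filters, as real private calls must have been to be observed
at all. Planted genotype–drug effects shift the treated wells of carrier
samples by the stated number of vehicle-SD units on top of a per-sample
sensitivity (SD 0.3 z-units) that induces the random-intercept structure
the LMM assumes; planted feature genes are reserved for carriers so the
downstream feature indicator reflects the planted truth exactly. All
draws derive from one seed through independent sub-streams.

What the generator does **not** emulate: mutational signatures, locus-
level coverage bias, segmentation error, purity-estimation error,
dose–response shapes, or plate spatial effects. Passing tests therefore
demonstrate that the statistics are implemented correctly and recover
planted structure under the stated noise model — not that the pipeline
is robust to artifacts of real sequencing or screening data.

One practical consequence surfaced by the end-to-end tests: z-scores
are normalized by each sample's *empirical* vehicle SD (7 replicates),
whose sampling error rescales every z of that sample by up to ~±30%.
Planted effects are therefore recovered in sign and significance, and
the LMM coefficient is unbiased only on the true-SD scale; tests of
coefficient accuracy use directly simulated z-scores, while cohort-level
tests assert sign and significance.

## Problem sizes and tolerances

The shipped suite runs the generator at 4–13 pairs and 50–400 SNVs per
sample, the LMM power study at 200 simulations (12 samples × 3
replicates, planted −2 z-units) and the type-I study at 500 null
simulations with a ±3·SE binomial acceptance band around 5%. Exact
rank-sum and hypergeometric paths are verified against brute-force
enumeration on universes small enough to enumerate (≤ 70 rank
assignments, ≤ C(14,5) draws). Floating-point comparisons use absolute
tolerances of 1e−9 to 1e−12 where exactness is expected.
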