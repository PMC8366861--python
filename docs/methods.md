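# Methods

`ssrphylo` implements the statistical machinery of a microsatellite
phylogeography study of a mountain conifer sampled along a west–east axis
(a Pyrenean-style design with Alpine reference populations): within- and
among-population diversity, phylogeographic-signal testing, coalescent/ABC
demographic inference over four divergence–admixture scenarios, and
environment–diversity association modelling. This note records the models,
the defaults and why, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Data model

Genotypes are co-dominant microsatellites: diploid nuclear loci (unordered
allele pairs) and haploid chloroplast loci (one allele per individual; in
firs the chloroplast is paternally inherited through pollen). Allele codes
are positive integers kept exactly as read — fragment sizes in bp or repeat
counts, declared per locus — and `0` is missing everywhere. Conversion to
repeat units (for R_ST and the mutation model) happens downstream by
dividing fragment sizes by the motif length; loci whose alleles do not
differ by whole motifs are flagged but not rejected, because real panels
contain off-ladder indel variants (e.g. an 18-bp indel on a mononucleotide
background).

## Null alleles and locus filtering

Null-allele frequencies are estimated per locus and population by maximum
likelihood under HWE with a single unobservable null allele: observed
homozygotes are a mixture of true homozygotes and visible/null
heterozygotes. The EM treats apparent homozygotes as partially null; when
missing genotypes are *not* taken as putative null homozygotes (the
default — the study's sub-option is not documented, so both are exposed),
the likelihood is conditioned on the genotype being observable and the EM
augments the data with the expected number of unobserved null homozygotes
(standard EM for a truncated multinomial). Convergence: |Δ log L| < 1e-8,
at most 10,000 iterations; monotonicity of the log-likelihood is asserted
at every step. A locus is discarded when its null frequency exceeds 0.05 in
strictly more than half of the populations scored.

## Diversity statistics

Per population and locus: allele number N_A; Nei's unbiased gene diversity
H_e = n/(n−1)(1 − Σp²) on n observed gene copies; effective allele number
N_Ae = 1/(1 − H_e) (the bias-corrected reciprocal-homozygosity reading of
the "effective alleles" statistic; the naive 1/Σp̂² is available by flag);
the unique-allele proportion A_u (alleles carried by exactly one individual
of the population — a homozygote in a single individual still counts once);
and F_i = 1 − H_o/H_e, with the multilocus value 1 − ΣH_o/ΣH_e. Population
summaries average loci unweighted.

Rarefied allelic richness uses exact combinatorics in log space:
AR(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)], and private richness multiplies each
allele's presence probability in the focal population's subsample by its
absence probability in every other population's subsample. Defaults follow
the study design: g = 50 gene copies for nuclear loci, g = 22 for
chloroplast haplotypes; populations with fewer copies are dropped from the
rarefaction. AR(g) is validated against brute-force enumeration of all
subsamples for N ≤ 8.

The individual-level PCA runs on allele-dosage vectors (0/0.5/1 for
diploids, 0/1 for haplotypes), centered, optionally unit-scaled; the
"principal correspondence analysis" wording of the source tool is resolved
as centered PCA on dosages (that tool's default), not correspondence
analysis. Missing genotypes are imputed by the population-mean dosage so no
individual is lost.

## Differentiation and phylogeographic signal

F_ST is Weir–Cockerham θ (1984): per-allele variance components a, b, c
summed over alleles and loci before the ratio; haploid loci contribute the
haploid (two-component) analogue from a one-way ANOVA on allele indicators.
R_ST follows Slatkin: ANOVA components of allele-size variance in repeat
units, summed over loci. The allele-size permutation test shuffles the size
labels among a locus's allelic states (identities preserved), recomputing
R_ST; a one-sided p with the +1 correction asks whether R_ST exceeds its
permutational (F_ST-like) null — the signature of stepwise-accumulated,
i.e. phylogeographic, divergence.

Isolation-by-distance regresses the lower triangle of the pairwise
statistic on great-circle distances (haversine, radius 6371.0 km); raw
F_ST is the default response (F/(1−F) and log-distance by flag).
Significance is a Mantel-style permutation of population labels, two-sided
on the slope; the F_ST/R_ST slope difference is tested under the same joint
permutations. The population tree is Saitou–Nei neighbour joining on the
F_ST matrix (small negative estimates clipped at zero), with bipartition
support from bootstrap resampling of loci — the only exchangeable unit for
a distance-matrix tree. Outgroups enter as extra rows of the distance
matrix.

## Coalescent simulator

Continuous-time coalescent in units of generations (adequate for effective
sizes in the thousands; no discrete Wright–Fisher), four sampled demes
(Alps reference, East and West Pyrenees, admixed contact zone), and four
scenarios: S1 simultaneous three-way split with later secondary contact;
S2 hierarchical split (Alps/Pyrenees, then east/west, then contact);
S3/S4 an early two-deme split with the third deme formed by admixture,
then contact. Backward events are resize, merge, and admixture (each child
lineage chooses parent 1 with probability r). Every sampled deme may resize
once on its terminal branch (times T_a..T_d), giving the current/ancestral
size pair that the θ-ratio interrogates. Between events demes coalesce
independently at rate C(k,2)/(2N) (nuclear) or C(k,2)/(cN) with chloroplast
copy-number factor c = 1 by default (paternal, one transmitted copy per
individual; exposed as a multiplier).

Mutation is the generalized stepwise model: Poisson events on branches at
rate µ per generation; each event moves the repeat count by ±(1 +
Geometric(P)), with P = 0 the strict single-step model; repeat counts
reflect at a floor of 2. Roots start at 100 repeats (nuclear) / 50
(chloroplast) so the floor is effectively inactive at realistic rates. The
three chloroplast loci share one gene tree (full linkage); the 18-bp indel
locus is treated as an ordinary stepwise locus whose low observed
variability is accommodated by the broad chloroplast rate prior.
Correctness anchor: a single panmictic deme under strict SMM reproduces the
stepwise-model equilibrium H_e = 1 − 1/√(1+8Nµ).

### Priors

Event times: normal(25,000, 12,500) truncated > 10 generations, with the
scenario's ordering (T1 > T2 > T3; each resize on its own terminal branch)
imposed by rejection. Deme sizes: normal(5,000, 2,500) truncated > 0.
µ_nuclear ~ log-uniform(1e-4, 1e-3); µ_chloroplast ~ log-uniform(1e-8,
1e-3). The GSM geometric parameter P ~ uniform(0, 0.9) and admixture
proportions ~ uniform(0.05, 0.95), the customary defaults of comparable
microsatellite ABC analyses. Per-locus rate heterogeneity (gamma across
loci) is off by default and available by flag.

## Summary statistics and ABC

The configurable catalog computes, per marker class, four single-population
statistics (mean allele number, mean genic diversity, mean allele-size
variance, mean Garza–Williamson M) and four two-population statistics
(WC F_ST, pooled-pair genic diversity, Goldstein's (δµ)², shared-allele
distance). Because the study's exact eight retained statistics are not
published, the default fitting set is {allele number, genic diversity;
F_ST, (δµ)²} with {size variance, M; pooled diversity, shared-allele
distance} held out for posterior-predictive checking; the two sets are
required to be disjoint, and the prior/scenario rank-PCA check reproduces
the screening step used to choose statistics.

ABC uses 1% tolerance with an Epanechnikov kernel on standardized Euclidean
distance throughout. Scenario choice: direct rejection proportions plus a
distance-weighted multinomial logistic regression (Newton–Raphson, small
ridge) on linear-discriminant axes of the statistics, evaluated at the
observed point; CIs come from the observed information by the delta method,
and a winner is "recovered" when its point probability exceeds all other
scenarios' 95% upper bounds. Error calibration draws pseudo-observed
datasets from each scenario's reference rows nearest the observation and
re-classifies them (direct estimate, own row excluded) to give type I/II
errors and the assignment-probability-weighted posterior error rate.

Parameter posteriors are Beaumont-style local-linear adjustments with a
logit map to per-parameter bounds taken from the scenario's prior draws in
the table (slightly expanded); a singular design falls back to rejection
only. When fewer retained rows than ~5 per coefficient are available the
regression runs on the leading principal components of the retained
statistics rather than the full vector — without this guard a small
retained set is interpolated exactly and the posterior collapses to a
point. Point summaries: weighted median, weighted quantiles, and the mode
of a Gaussian KDE (Silverman bandwidth). The θ-ratio θ0/θ1 = N_current/
N_ancestral cancels the unknown mutation rate under the constant-rate
assumption; it is treated as a derived parameter whose log is
regression-adjusted against the retained statistics directly (preserving
the within-draw correlation of the two sizes), and summarised by the KDE
mode on the log scale (making the statistic label-antisymmetric) and the
tail masses P(ratio > 1), P(ratio < 1). Calendar conversion multiplies
generations by the 30–40 year maturity interval.

Reference-table size defaults to a desk scale of 4 × 20,000 rows
(full-study scale, 4 × 10⁶, by configuration); the test-suite and acceptance runs
use 4 × 1,000–1,200 rows with 20 diploids per deme and a 10% tolerance
(the fixed 1% of the full-scale analysis retains fewer rows than the
regression has coefficients at these table sizes), chosen so the whole
pipeline — table, pods, posteriors — reruns from scratch in minutes while
leaving the calibration properties (coverage, error rates, θ-ratio
readout) measurable.

## Cluster number and representatives

ΔK is the absolute second difference of the mean clustering log-probability
across K divided by its replicate standard deviation; the peak selects K
(undefined where a neighbour is missing or the sd is zero, which is
flagged). Scenario demes are anchored to data by picking, per cluster, the
population with the highest membership Q, plus the population whose maximum
Q is closest to 0.5 as the contact-zone representative; an exclusion list
supports the replicate analysis with a second population set, and ties
break alphabetically.

## Environment association

Pearson correlations between each genetic variable and each environmental
candidate are transformed to z = atanh(r)√(n−3) and screened by an
empirical-Bayes local FDR with a theoretical N(0,1) null: π0 from the
central proportion of z-values, the marginal density by Gaussian KDE, lfdr
clipped to [0,1], optional isotonic monotonisation in |z|; with fewer than
50 tests the screen falls back to Benjamini–Hochberg (flagged). Candidates
passing lfdr ≤ 0.05 enter a forward stepwise search minimising
BIC = n ln(RSS/n) + k ln(n) from the intercept up, which is what makes the
final models robust to the strong multicollinearity that the VIF diagnostic
(1/(1−R²_j), threshold 10) invariably confirms among bioclimatic layers.
The final model is refit by OLS for coefficients, p-values and adjusted R².
Note the implied null behaviour: a candidate enters when its chi-squared
statistic exceeds ≈ ln n, so with many pure-noise candidates the first step
admits one with appreciable probability (≈ 0.68 for 20 candidates at
n = 40) — parsimony here comes from the BIC stopping rule, not from strong
familywise control, and the test suite asserts exactly this calibration.
Counts of significant temperature- vs precipitation-related variables are
compared by Pearson's chi-squared against equal expectation.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study's *shape*: 45 populations of 30 diploids
(8 nuclear + 3 linked chloroplast loci) partitioned among the four demes of
a known scenario, a west–east longitude axis with Alpine references, a
logistic Q_w cline with a central admixed band, environment tables of 19
bioclimatic variables × 4 periods plus geography with planted partial
correlations, and clustering tables with a known K. Defaults plant the
study's qualitative truths: a larger eastern than western effective size
(hence the east > west diversity gradient), an eastern expansion and
western contraction for the θ-ratio readout, and negative Q_w associations
with longitude and a last-interglacial temperature variable.

It does **not** emulate: real allele-size distributions or the deposited
genotypes; within-deme substructure (populations of a deme are exchangeable
samples, so within-deme F_ST is zero in expectation and isolation-by-
distance holds only between demes); post-divergence migration (absent from
the inference model by design); genotyping artefacts other than optional
null alleles; or spatial autocorrelation of the environmental noise.
Passing recovery tests therefore show the estimators work under the model's
own assumptions at study-like sample sizes — not that the model captures
every feature of the real data.

## Numerical choices and degenerate inputs

Exact binomial coefficients in log space for rarefaction; variance
components summed before ratios (F_ST, R_ST), with undefined statistics
reported as missing (NaN) in analysis functions but as 0-with-flag inside
the ABC statistic vector, which must be complete; permutation p-values use
the +1 correction; two-sided rank p-values apply the +1 correction on both
tails; NJ input distances are symmetrised and clipped at zero; EM
log-likelihood monotonicity is asserted with a 1e-9 slack; the weighted
multinomial logistic uses a 1e-6 ridge; logit-mapped draws landing on a
bound are nudged inside by 1e-12.

## Known limitations

Scenario times are identifiable only through mutation-scaled quantities, so
posteriors for times and sizes remain prior-dominated at realistic locus
counts (the study itself reports high scenario-confusion rates); the
θ-ratio is the robust readout. The simulator's per-deme sample sizes enter
the summary statistics' sampling noise, so reference tables and
observations should use matching sizes. The local FDR's theoretical null is
not refit to an empirical null, which matters if the screen's z-values are
correlated (they are, across bioclimatic layers); the stepwise stage, not
the screen, is what controls the final models.
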