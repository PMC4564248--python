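# Methods

This note documents the models, the numerical choices, and what the
synthetic panels do and do not emulate. All problem sizes quoted are the
package defaults, chosen as a desk-scale rendering of a large germplasm
study (a few thousand array markers, a few hundred accessions); larger
panels are reached through configuration.

## Genotype model and containers

Genotypes are biallelic array calls in {AA, AB, BB, NoCall}, stored as an
int8 samples × markers matrix. The A/B labels are the array's probe
alleles and carry no frequency meaning; every statistic in the package is
invariant to swapping them at any subset of markers (asserted in tests).
Coordinates are 1-based inclusive bp; BED exports are half-open 0-based.
Two numeric coders exist side by side:

* additive coding (minor-allele count 0/1/2, NaN missing) — used for LD,
  kinship, VIF and association, whose definitions presuppose allele
  counts;
* het-high coding (heterozygote 2, major homozygote 1, minor homozygote
  0) — used for PCA, where it emphasizes heterozygosity differences
  between breeding material and selfed landraces.

## Marker QC

Classes A–E are assigned by fixed precedence E → D → A → B → C with the
thresholds given in the README; anything unmatched falls back to E. Two
operationalizations were left open by the qualitative class definitions
and are fixed here: the class-C "heterozygote over-representation" is
ho > he + 0.2 with one homozygote class absent (at panel sizes ≥ 100 this
cleanly separates collapsed paralogs from Hardy–Weinberg noise), and a
marker satisfying both B and C resolves to B (precedence order).

The Hardy–Weinberg test is the exact conditional test: the distribution
of the heterozygote count given allele counts, summed over outcomes no
more probable than observed, computed with log-factorials. Markers are
discarded for MAF strictly below 0.05 (exactly 0.05 is kept) and HWE
p strictly below the configured alpha (default 1e-4).

**Caveat on the HWE filter.** In heavily selfing germplasm nearly every
marker shows a genuine heterozygote deficit, and at panel sample sizes
the exact test rejects almost everything: the filter, applied literally,
would empty the marker set without flagging any genotyping problem. The
package therefore treats the HWE cutoff as a configurable diagnostic and
runs its own end-to-end analyses with the filter disabled
(`hwe_alpha=0`), selecting on class A + MAF only; association scans
additionally require genotyping success ≥ 90% per marker. Sample
filtering removes accessions with call rate below the panel mean minus
0.1, with the mean computed once (not iterated).

## Clones and sports

Identity = fraction of co-called markers with equal genotype; pairs with
fewer than 500 co-called markers are incomparable. Groups are connected
components at identity ≥ 0.98 (single linkage, matching the transitive
way germplasm synonym groups are reported); the retained representative
is the member with the highest call rate, ties to the smallest id — a
plumbing choice, not a scientific one.

The sport scan slides a 25-marker window per chromosome and flags windows
with ≥ 3 co-called differences, a missing-call asymmetry ≥ 0.2 between
the pair, and ≥ 80% of differing loci heterozygous in the low-missing
member but homozygous in the high-missing member; overlapping flagged
windows merge. The window parameters are not derived from any published
value (studies report such regions post hoc); the defaults are sized so a
~5 Mb region carrying ~10 het→hom differences and ~40% missingness — the
magnitude seen in real sport pairs — is recovered as a single region, and
all four thresholds are exposed as flags.

## Diversity, trees, PCA, pruning

The fixation index is reported as F = (He − Ho)/He, the standard
heterozygote-deficit form; the formula string is printed in output
headers so reports are unambiguous. IBS similarity is the probability
that one allele drawn from each individual matches (1, 0.5, 0.5, 0 for
same-hom, hom-het, het-het, opposite-hom), distance 1 − IBS with
self-distance 0; UPGMA heights are half the merge distance, giving an
ultrametric rooted tree. PCA centers columns without scaling and uses
SVD; missing calls are imputed to the marker mean of the numeric code.
VIF pruning works on 50-marker windows advancing by 5: within a window
the marker with the largest VIF (1/(1−R²) from regression on the other
window markers) is removed until all VIF ≤ 10; removals are permanent.

## Admixture model and K selection

The clustering model is the classical admixture model: each allele copy
originates from one of K clusters, clusters have independent Beta(1,1)
allele frequencies, individuals have Dirichlet(α) admixture vectors
(α = 1 by default in the library; the CLI and the package's own
panel-scale experiments use α = 0.3, a sparse-ancestry prior appropriate
for collections in which most accessions are nearly pure — a flat prior
measurably drags posterior q away from the corners at a few hundred
markers). A Gibbs
sampler alternates the three conditionals; label switching is resolved by
Hungarian matching of cluster frequency vectors to the first post-burn-in
iteration, and posterior means of Q and the frequencies are returned with
the full data log-likelihood trace. This deliberately omits the
correlated-allele-frequencies prior and linkage model of the classical
software: independent priors are sufficient for cluster recovery on
array-scale data and keep the sampler small and exactly reproducible.
Desk-scale defaults are 500 burn-in / 2,000 sampling iterations;
published-scale settings (10,000 / 100,000) are reachable by flags. The
inner loop is compiled with numba when available (pure-numpy fallback
otherwise).

Evanno's ΔK uses L(K) = mean over replicate runs of the mean
post-burn-in log-likelihood, ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))
with the sd over replicates; ΔK is undefined at the endpoints and when
replicates agree exactly. Assignment uses max q strictly greater than
0.8, otherwise "ADM".

Fst is Weir–Cockerham θ with variance components summed across markers
before the ratio (the standard multi-locus combination); pairs of
clusters are compared with ADM excluded.

## LD

r² is the squared Pearson correlation of additive codes over
pairwise-complete samples (≥ 10 required). The corrected statistic
replaces each genotype vector by its generalized-least-squares residual
on the structure covariates S (intercept added automatically) under the
relatedness covariance V, and correlates residuals under the V⁻¹ inner
product; with V = I and S = intercept it equals plain r² exactly (tested
to 1e-12). A singular V raises with advice to add a diagonal ridge.

Decay fits bin intra-chromosomal pairs at 50 kb, fit a polynomial
(default degree 2) to the bin means, and search for the smallest crossing
of 0.2 inside the observed distance range only — extrapolated roots are
never reported. Whether published decay averages use all pairs or binned
means is generally unstated; binned means were chosen to keep the fit
insensitive to the quadratic growth of long-distance pair counts. Blocks
are called by greedy extension with two conditions: the run's median
pairwise r² and the entering marker's median r² against the run must both
stay ≥ 0.5. The second condition is this package's choice: with the
median-only rule a strong block drags equilibrium flankers along on the
strength of its internal pairs, over-covering planted blocks by several
markers.

## GWAS

The VanRaden relationship matrix is G = ZZᵀ / (2Σp(1−p)) with Z the
2p-centered allele counts (missing to 2p, markers MAF ≥ 0.05); on this
scale unrelated pairs sit near 0 and duplicate fully inbred genotypes
near 2. The mixed model y = Xβ + gδ + u + e, u ~ N(0, σ²_g K) is fitted
by the P3D convention: variance components are REML-estimated once on
the null model via the spectral decomposition of K (1-D optimization
over δ = σ²_e/σ²_g on a log grid refined by bounded Brent), then every
marker receives a GLS F test with components fixed. On a flat REML
profile (e.g. K = I, where δ is unidentifiable) the larger δ is
preferred: undetermined variance is attributed to the residual.
Binary traits are analyzed on the linear scale, the standard practice for
Mendelian traits in plant association studies. X contains the intercept
and the first K−1 admixture columns (the last is dropped against the
intercept). Pseudo-heritability h² = σ²_g/(σ²_g+σ²_e) and the squared
correlation of the top marker's fitted values with the phenotype are both
reported, since published "heritability explained by the model" values do
not distinguish them.

Thresholds: Bonferroni α/m (reported as −log10) and Benjamini–Yekutieli
step-up with the harmonic correction c(m) = Σ1/i, both at α = 0.01 by
default. For rare, strongly structured traits the balanced-subset scan
runs the same model on every-case + n-control subsets (default 15 subsets
of 100 controls, seeded sampling without replacement, optional control
stratum) and reports per-marker counts of subsets passing Bonferroni and
the all-subsets consensus.

## Haplotypes

Phasing is haplotype-frequency EM (gene counting): each individual's
compatible ordered haplotype pairs (missing genotypes expand the set) are
weighted by current frequencies, and frequencies are re-estimated from
the posterior weights; the log-likelihood is non-decreasing per
iteration, with the best of 20 random restarts kept. Marker sets longer
than one window (default 6 markers, overlap 3, hard cap 12) are phased by
partition–ligation: adjacent windows are joined through haplotypes that
agree on the overlap, keeping the top 128 candidates by frequency and
always retaining a compatible pair for every sample. On ≤ 8-marker sets
the result matches full-enumeration EM to 1e-6 log-likelihood (tested).
This replaces cluster-HMM phasing entirely: at the 18–23-marker scale of
trait-associated sets the EM approach is exactly testable against an
enumeration oracle, which a HMM reimplementation would not be.

Haplotype "average heterozygosity" is the fraction of individuals whose
two reconstructed haplotypes differ; a per-marker variant is also
provided because published usage of the term is ambiguous. The
association test counts carriers (≥ 1 copy; a copies mode exists) of each
haplotype with frequency > 5% by phenotype class and applies a 1-df
goodness-of-fit chi-square against an equal split, no Yates correction.

## The synthetic panel generator

The generator is the package's study stand-in and defines its test
conditions:

* **Populations.** Three ancestral populations (60/40/25 individuals by
  default) diverged from Uniform(0.05, 0.95) ancestral frequencies by
  Balding–Nichols sampling with F_div = (0.15, 0.15, 0.18), plus 75
  admixed individuals with Dirichlet(0.3) ancestry — mirroring a panel
  whose largest group is modern breeding material, with roughly 40%
  admixed accessions rarely reaching q ≥ 0.8.
* **LD.** Each chromosome (8 chromosomes, lengths proportional to a
  compact 230 Mbp genome) is partitioned into marker blocks of geometric
  mean length 8; each population holds a pool of 8 haplotypes per block
  and individuals draw whole blocks from the pools of their (per-block)
  ancestry. Pool allele counts are rounded to the population frequency
  rather than Bernoulli-sampled: naive pools of size 8 add ~1/8 of drift
  on top of F_div, which would inflate realized Fst by ~0.1. A marker
  fixed across all pools would be monomorphic panel-wide; one pool column
  is redrawn in that case so ≥ 99% of clean markers stay polymorphic.
  This construction produces tunable block LD but is explicitly not a
  model of recombination history — decay-curve shapes are
  phenomenological, and tests treat them accordingly.
* **Inbreeding.** Partial selfing (0.3 / 0.6 / 0.3 per population; the
  landrace-like population highest) is realized by copying gamete blocks,
  producing the excess homozygosity such panels show. Published studies
  do not report per-population inbreeding; these are calibration choices.
* **Artifacts.** Marker classes are planted in array-realistic
  proportions (B 2.8%, C 9.5%, D 9.5%, E 25%, remainder A). Duplicated
  loci collapse the minor homozygote class into heterozygotes with 60% of
  major homozygotes following (emulating superimposed paralogous
  signals); null-allele markers no-call a 8–45% low-intensity stratum;
  failed markers get high no-call or sub-threshold clustering scores.
* **Clones and sports.** Clone groups copy samples with 0.5% random call
  noise (inside the 2% identity budget). Sports modify one clone-pair
  member in a 5.4 Mb window at the top of chromosome 6: 80% of
  heterozygous calls become a random homozygote and 40% of the remaining
  region calls go missing. The high conversion rate is a density
  calibration: at ~47 markers in the region it yields the ~10 localized
  differences that real sport pairs show on much denser arrays. Sport
  parents are drawn from samples with enough heterozygous calls in the
  region, since a fully homozygous parent leaves no signature to plant.
* **Traits.** Binary Mendelian traits with penetrance 1 and 2%
  misclassification (enough noise to keep chi-square tests honest without
  blurring the signal): recessive and dominant modes on causal markers
  with MAF 0.25–0.5, and an obligate-heterozygote mode on a low-MAF
  (0.08–0.2) marker with few minor homozygotes — a rare dominant,
  effectively homozygous-lethal allele, which is also the regime in which
  an additive scan has power for a heterozygote-only phenotype.

What passing tests on these panels show: that each algorithm recovers
what was planted under the stated statistical structure. What they do not
show: robustness to genotyping batch effects, pedigree structure beyond
clones, allele-frequency misspecification, or recombination-driven LD
decay shapes — none of which the generator attempts to model.

## Problem sizes and determinism

Defaults throughout are desk-scale: 2,000 markers × ~200 samples for the
full study simulation, 250–500 pruned markers and 400–2,000 Gibbs
iterations for structure runs, 5 balanced subsets of 60 controls for the
rare-trait scan. Every stochastic stage takes an explicit seed, the CLI
records it in a JSON manifest, and fixed-seed runs are bit-identical
(tested), including the Gibbs sampler.
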