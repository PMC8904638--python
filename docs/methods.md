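# Methods

`finepop` re-creates, on synthetic genomes with known truth, the staged
workflow used for fine-scale population-structure studies of admixed
cohorts: array QC and LD pruning; FST / RoH / PCA; Patterson
f-statistics with block-jackknife errors; all-vs-all haplotype painting;
TVD-based cluster refinement and heterogeneity; NNLS ancestry profiles;
and admixture dating from weighted-LD decay.  Real cohorts of this kind
are controlled-access, so the package's claims are parameter-recovery
claims: every stage is exercised on data whose generating truth is known,
and published quantities of the motivating study design (a 13-generation
pulse for the most recently admixed subgroup, ~19 generations for the two
older ones, NNLS weights of 66% and 54% for the most Arabian- and most
European-leaning clusters) are used as simulation truths.

## Synthetic data model

**Allele frequencies.** K source populations diverge from one ancestral
pool under the Balding–Nichols model: for ancestral frequency p and drift
F, source frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F), so E = p and
Var = F·p(1−p); two such sources have expected Weir–Cockerham FST close
to 2F/(1+F) in the large-sample limit (tests pin this with a Monte-Carlo
oracle rather than the asymptotic formula).  Ancestral frequencies are
Uniform(0.05, 0.95).  Haplotypes are independent Bernoulli(freq) draws per
site: the sources carry **no background LD**, which makes admixture the
only source of long-range association and gives the weighted-LD dating a
clean decay to fit.  Real arrays have background LD; the d_min cutoff
(below) is how the method copes there, and that interaction is *not*
probed by these simulations.

**Admixed genomes.** A single pulse g generations ago is simulated
directly in its stationary consequence: each haplotype is a mosaic whose
breakpoints form a Poisson process of rate g per Morgan, each segment's
source drawn i.i.d. from the mixing proportions and its alleles copied
from a random haplotype of that source's panel.  This yields ancestry
autocovariance α(1−α)e^(−g·d) at distance d Morgans — the textbook
admixture-LD decay — and realized per-individual ancestry fractions that
scatter around the proportions.  Continuous migration, multiple pulses,
selection and genotype error are out of scope.

**Genetic map.** Uniform 1 cM/Mb, evenly spaced SNPs, several independent
chromosomes (default 3 × 1 Morgan).  Map positions are carried as cM
floats; a piecewise map can be supplied through SNP metadata.

**Seeding.** One seed per scenario; stage generators derive from it by
fixed offsets (+1 frequencies, +2 panels, +3 mosaics, +4 copying
vectors), so any stage can be reproduced in isolation.

## Stage notes

**QC (genio).** Filter order is fixed: SNP missingness → individual
missingness → MAF → optional HWE (chi-square, disabled by default).
Defaults 0.05 / 0.05 / 0.01 are ordinary array-QC practice; the
relatedness cutoff PI_HAT > 0.25 (second degree) uses method-of-moments
IBD from IBS counts without small-sample allele-count corrections.  LD
pruning removes, within 200-SNP windows advancing by 25, the later SNP of
any pair with dosage-correlation r² > 0.4, permanently across windows;
missing dosages are mean-imputed for the correlation.  PLINK text carries
no allele-order declaration, so its reader takes the counted allele to be
the minor allele; EIGENSTRAT and VCF round-trip exactly.

**FST.** Weir–Cockerham (1984) components for r = 2, combined as a ratio
of sums Σa/Σ(a+b+c); SNPs monomorphic across both samples are excluded;
negative estimates are reported as computed (a clip flag exists for
display).  Duplicating the same individuals into both "populations" gives
a *negative* estimate — the among-population variance is exactly zero and
the unbiasing term overshoots — which is correct behaviour for this
estimator, not an error.

**RoH.** PLINK-style scan: 100-SNP windows (≤1 het, ≤5 missing), per-SNP
hit fraction ≥ 0.05, emitted runs ≥ 1000 kb and ≥ 100 SNPs.  The window,
length, het and missing values are the study design's; the hit fraction
and SNP floor are PLINK defaults, exposed as flags.

**f-statistics.** f3(C;A,B) uses per-SNP (c−a)(c−b) minus the unbiased
correction ĉ(1−ĉ)/(n_C−1); the correction and the heterozygosity
normalization are flags (raw estimator default).  f4 is (a−b)(c−d)
without correction; the f4-ratio jackknifes the ratio per block and flags
(rather than hides) denominators with |Z| < 3.  Standard errors use the
weighted delete-one-block jackknife of Busing et al. (1999) on contiguous
5-cM blocks (SNP-count blocks available without a map).  SNPs missing in
any required population are excluded listwise per statistic.

**Painting.** A simplified Li–Stephens copier: switch probability
1 − e^(−ρΔd) to a uniform donor (ρ = 50 per Morgan), emission error
μ = 0.001, and **Viterbi decoding** instead of ChromoPainter's
expected-count forward–backward — deterministic and checkable against
exhaustive path enumeration, at the cost of ignoring path uncertainty.
No EM re-estimation of ρ/μ.  Ties break toward the lowest donor index.
Chunk lengths are measured between interval midpoints, terminal chunks
extended to the map ends, so each recipient's lengths sum to twice the
map length exactly.

**Clustering and refinement.** Individuals are agglomerated (average
linkage) on pairwise TVD between copying vectors — a deterministic
stand-in for the fineSTRUCTURE MCMC; an external assignment can be
supplied instead.  Two refinement rules then apply: (i) the size rule
collapses, to a fixpoint, any dendrogram node with fewer than 5 leaf
clusters of which at least one has fewer than 5 members; (ii) TVD pooling
greedily merges pairs (up to triplets) of clusters by the TVD between
their mean chunk-count copying vectors against a 0.035 threshold.  The
source rule is stated as pooling when TVD is *above* the threshold, which
is opposite to the conventional merge-similar reading; the comparison
direction is therefore an explicit flag defaulting to merge-if-below, and
no claim is made about which the original analysis used.  Whether
"climbing" halts at the first failing node is equally unstated; the
fixpoint reading is implemented.  TVD magnitudes depend strongly on the
donor basis: on a per-individual basis all cluster distances are large,
so pooling should be run on cluster-aggregated copying vectors (the
analysis scripts do), and at demo cohort sizes the sensible threshold is
~0.1–0.2 rather than 0.035, which targets cohorts of thousands.

**NNLS ancestry.** min ‖y − βᵀS‖² with β ≥ 0; sum-to-one enforced by an
appended penalty row (default weight 100× the largest design entry)
followed by exact renormalization.  Pre-renormalization sums outside
[0.99, 1.01] raise a warning.  The target's own donor-cluster column is
removed from y and S (both renormalized) before solving; per-cluster
profiles decompose the cluster's mean vector by default (the mean of
member profiles is a flag — the original analysis does not say which it
used).  On painted data the recovered weights lean toward the majority
source because source profiles themselves contain chunk mass donated to
admixed individuals; exact-mixture recovery is the noise-free contract.

**Dating.** The two-reference weighted-LD statistic a(d) averages
ẑ_ij·w_i·w_j over same-chromosome SNP pairs binned by genetic distance
(ẑ = target genotype covariance, w = reference frequency contrast), then
fits a(d) = A·e^(−g·d) + c₀ (d in Morgans) by multi-start nonlinear least
squares (g starts 1, 1.5×, … up to 200).  Bins below d_min = 0.5 cM are
excluded (the conventional guard against background LD).  A flat curve —
amplitude not significant by F-test at 0.05 against the constant model —
is reported as non-converged with no date.  The O(m²) pair loop is run in
row blocks (no FFT acceleration; 20k-SNP problems take seconds).  Group
date distributions are compared with two-sided Wilcoxon rank-sum tests
(normal approximation, no tie correction — identical samples give p = 1
exactly) under Bonferroni correction over the number of pairs.  Year
conversions, where wanted, use 29 years/generation (configurable).

## Problem sizes

Recovery experiments run at: dating — 200 admixed diploids, two F = 0.05
sources of 100 diploids, 20,000 SNPs on 3 × 1-Morgan chromosomes, 10
replicates per date (medians within ±1 generation of truth at g = 13 and
19 in practice); f3 detection — 5,000 SNPs, 100 chromosomes sampled per
population, 50 replicates; f4 calibration — 500 replicates of a
no-gene-flow tree at 4,000 SNPs; oracle equivalence — 50 random small
instances per component.  The demonstration cohort in `analysis/` uses
3,000 SNPs and 25–30 individuals per group with continental-scale source
divergence (F = 0.15) so that painting separates donor groups cleanly at
that SNP count.

## Known limitations

* Viterbi chunk counts are harder (more confident) than ChromoPainter's
  expected counts; coancestry matrices are comparable in structure but
  not numerically interchangeable.
* The agglomerative clustering is not a posterior over partitions; with
  weakly diverged sources it fragments central populations (the TVD
  pooling step is what repairs this).
* No background LD in the generator means the d_min guard and the affine
  floor c₀ are exercised only against sampling noise.
* The RoH scanner's defaults for the two parameters the study design
  leaves unstated (hit fraction, SNP floor) follow PLINK and are not
  claimed to match the original run.
* f4-ratio assumes the classical five-population topology; no qpAdm-style
  model competition is offered.
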