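# Methods

## The compound binomial allele-frequency model

A diploid, non-imprinted locus heterozygous for alleles A and a expresses
both haplotypes at roughly equal rates, so among N sequenced fragments the
count k of A-reads is Binomial(N, n_A/(n_A + n_a)), where n_A and n_a are
the copy-weighted abundances of the two alleles in the sampled cell
population.  Library PCR amplifies the two allelic templates unequally; we
model the amplification factors as 2^α and 2^β and note that only the
difference δ = β − α affects the sampling odds:

    p(δ) = n_A / (n_A + n_a · 2^δ),
    P(k) = ∫ C(N,k) p(δ)^k (1 − p(δ))^(N−k) φ(δ; 0, σ) dδ.

δ is drawn once per locus (each locus has its own primers and local
sequence context), which makes the marginal distribution of k a
continuous mixture of binomials — overdispersed relative to a binomial
with the same mean, increasingly so with σ.  σ is expressed in log2
amplification units; σ = 0 means no PCR bias, σ = 1 a strong bias that
reproduces the broad allele-frequency histograms of real libraries.

Assumptions: loci are independent; N is the number of informative
fragments (those carrying A or a); sequencing errors at the SNP base are
rare enough to be bucketed as "other" and ignored by the model; the two
alleles are equally mappable.

### Numerical evaluation of the pmf

The mixing integral is evaluated by 64-node Gauss–Hermite quadrature and
renormalized to sum to 1 (the renormalization absorbs the O(1e-12)
truncation).  Gauss–Hermite is accurate while the binomial kernel (width
~√N in k) is wider than the node spacing; for N beyond ~4× the node count
the quadrature would resolve individual node-bumps, so the implementation
switches to a trapezoid rule on [−6σ, 6σ] with a grid of
max(801, 24·√N) points, which resolves the kernel at any N.  σ = 0 and
degenerate compositions (n_A = 0 or n_a = 0) return the closed-form
binomial.  Both routes preserve the allele-swap symmetry
P(k | n_A, n_a) = P(N−k | n_a, n_A) to 1e-10.

### Simulation

`sample_counts` draws per-site δ ~ Normal(0, σ) and then
k ~ Binomial(N, p(δ)) in one vectorized pass, so a single integer seed
fully determines the output regardless of iteration order.  Mixtures of
cell populations are simulated at count level: each component's allele
composition is normalized, weighted by its cell fraction, and the
compound binomial is sampled at the pooled composition.  (Read-level
resampling of per-population datasets is statistically equivalent at the
level of the marginal per-site counts, which is all the downstream
analysis consumes.)  Per-site depth is fixed at N = 50 by default — the
reference condition used throughout — with an optional negative-binomial
depth model for more realistic fixtures.

## Peak estimation

Reference-allele percentages are binned at 1-point width over [0, 100]
(the boundary value 100 falls in the last bin), smoothed with a centered
moving average, and the maximal smoothed bin inside a search window is
reported as the peak.  Exact ties break first toward the bin with the
larger raw count (a point mass keeps its own bin), then toward 50%.  The
default window [5, 95] excludes the homozygote spikes at 0/100%; analyses
that look for low-level contamination, whose peak sits next to 100%,
should raise the upper bound (the recovery tests use 99.5).

Two smoothing defaults are deliberate:

* display and model-level peaks use a 5-bin window;
* the per-chromosome screen and the genome-wide QC-report peak use a
  15-bin window.  With fixed N the fractions live on a lattice (2% apart
  at N = 50) and at σ ≈ 1 the distribution is nearly flat around its
  mode, so a 5-bin window (three lattice points) gives mode estimates
  that scatter over several points at a few thousand SNPs per chromosome
  — enough to push a diploid chromosome past a 10-point skew tolerance.
  The 15-bin window drives that false-positive rate to 0 in 2000
  simulated diploid chromosomes while leaving the diploid/trisomy
  separation (50% vs ~30%) untouched.

The mode estimate on a single draw remains quantized to the lattice and
carries ±2-point noise at 20 000 sites; tests that assert a peak position
therefore use the median over 20 replicate simulations.

A subtlety worth recording: at σ = 1 the mode of the mixture density for
an asymmetric composition is *not* the composition fraction.  For the 1:2
trisomic composition the density of p(δ) peaks at ≈ 0.29 (the maximizer
of φ(δ)/[p(1−p)] satisfies δ* = ln2·(1 − 2p*)), so the simulated trisomy
peak sits at ~29–31%, a few points below the 1/3 dose fraction; at σ = 0
it sits at 32–33%.  Trisomy detection is unaffected (both are far from
50%), but peak positions under strong PCR bias should be read as
systematically pulled toward the nearer tail.

## Genotype calls and the chromosome screen

A covered site (informative depth ≥ 20 by default; "informative" counts
only the two SNP alleles, since the model's N is defined over them) is
called homozygous for an allele reaching ≥ 95% of informative reads,
heterozygous otherwise.  The threshold is inclusive and configurable in
(0.5, 1].

Per chromosome, the screen histograms all covered sites, finds the
smoothed-mode peak in [5, 95]%, and flags the chromosome when
|peak − 50| exceeds 10 points — half the distance to the ~33/67% peaks of
a 2:1 dosage — unless the chromosome has fewer than 1000 SNPs, in which
case it only carries a low-SNP warning (such distributions are too noisy
to call).  The reported copy ratio peak/(100 − peak) estimates the
reference:alternative haplotype dosage: ≈ 1 diploid, ≈ 0.5 when the
alternative haplotype is duplicated, ≈ 2 for the mirror case.

## Contamination estimation

At loci where the majority population is homozygous-reference, a
contaminant heterozygous at those loci contributes half its reads to the
alternative allele, putting the expected peak at 100·(1 − c/2); hence
c = 2·(1 − peak/100), or c = 1 − peak/100 for a homozygous-alternative
contaminant, clipped to [0, 1].  The estimator deliberately ignores PCR
bias.  Its bias grows with c under σ ≈ 1 (the mixture-density mode shifts
as described above): at c = 0.1 the recovered value is within a couple of
points of truth, while at c = 0.5 it underestimates by ~0.1.  It is a
screening quantity, not a deconvolution.

## Gene-set and expression analyses

**Genotype-by-gene-set heterogeneity.**  Calls are cross-tabulated into a
3×3 table (expression class: set-A-specific / set-B-specific / other ×
genotype: hom-ref / hom-alt / het) and tested with a Monte-Carlo Fisher
exact test: tables with the observed margins are sampled by Patefield's
algorithm (via `scipy.stats.random_table`), and the p-value is
(b+1)/(m+1) where b counts sampled tables at most as probable (under the
multivariate hypergeometric null) as the observed one.  Including the
observed table keeps the estimate valid and never exactly zero;
probability ties are compared with a 1e-9 log-slack.  Independent
sampling targets the same null distribution as an MCMC walk over tables
and is directly verifiable against exhaustive enumeration, which the
tests do on small tables.

**Contaminant-specific SNPs.**  Sites where two parental strains are
homozygous for the same allele cannot show the other allele in a pure
sample of either strain or their F1; observing it (het or hom by the
usual threshold) implicates a third genotype.  When a candidate
contaminant's genotypes are supplied, hits are annotated with whether the
off-strain allele matches.

**Chromosome-wise expression.**  Genes must exceed 0.01 FPKM in every
sample of both groups; pseudogenes are excluded.  Per gene the log2 ratio
of group-mean FPKM is computed (arithmetic means before the log); per
chromosome the mean log-ratio, its fold 2^mean, and a one-sample t-test
of the chromosome's gene log-ratios against the all-genes mean log-ratio
are reported.  The `tail` parameter selects two-sided (default),
"greater" or "less".  For trisomy screening the one-sided "greater" test
is the appropriate form: the all-genes reference mean is itself pulled up
by an affected chromosome (by shift/#chromosomes), giving every diploid
chromosome a small negative offset that a two-sided test at a few
thousand genes will flag spuriously, while the gain direction is immune.
Marker matrices report log2((FPKM + ε)/(median across samples + ε)) with
ε = 1e-6 to keep silent genes finite.

## Synthetic data

The fixture generator emulates the real inputs end to end with known
truth: a VCF of biallelic SNPs carrying two inbred strains (one
homozygous-reference everywhere, one homozygous-alternative, so their F1
is heterozygous at every site), a GTF with one gene per 10 SNPs whose
exons cover all sites, SAM alignments whose pileup reproduces a requested
count table exactly (plus soft-clipped, spliced and deleted decoy reads
that must not be counted), count tables drawn from the compound binomial
under a mixture specification (populations × proportions × per-chromosome
haplotype copy numbers × σ), and two-group FPKM tables with planted
chromosome folds, log-normal noise, pseudogenes and sub-threshold genes.
Copy-weighted allele dose is the trisomy mechanism: a heterozygous
population with (1 ref, 2 alt) chromosome copies contributes doses
(1, 2), producing the ~1/3 peak.

What the fixtures do not emulate: sequencing error models and quality
strings, splice structure and intron-spanning reads beyond the decoy
cases, mappability differences between alleles, linkage between nearby
SNPs, and realistic depth heterogeneity (unless the negative-binomial
depth option is used).  Passing tests therefore demonstrate correctness
of the counting and inference logic under the model's assumptions, not
robustness to alignment artifacts in real libraries.

Problem sizes used by the test suite and the acceptance script — 20 000
sites per simulated sample, 2000 SNPs per screened chromosome, 20
chromosomes × 200 genes for expression tables, 20 seeds per operating-
characteristic battery — match the reference simulation conditions
(N = 50, σ ∈ {0, 1}) and give sub-minute runtimes.

## Known limitations

* Peak positions under strong PCR bias are biased toward the nearer tail;
  the contamination estimator inherits this (see above).
* σ is not fitted from data; it is a simulation parameter.  No mixture
  deconvolution beyond the peak-position estimate is attempted.
* The screen operates at whole-chromosome resolution; segmental CNVs are
  out of scope.
* Contamination by cells of an identical genetic background is invisible
  to allele frequencies by construction.
* Paired-end mates overlapping a site both count, and duplicates are not
  removed — fragment-level enumeration is the modeling unit, with PCR
  effects absorbed by σ rather than deduplication.
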