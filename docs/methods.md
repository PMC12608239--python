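# Methods

`recmap` implements the inference chain used to localize a fully penetrant
recessive mutation from pooled whole-genome sequencing of an intercross,
plus the downstream screens that narrow a mapped interval to a single
candidate gene.  This note records the models, the defaults and why they
were chosen, and what the bundled simulation does and does not emulate.

## Cross model

Both mapping hypotheses start from two heterozygous parents:

* **recessive causal** — a recessive allele *a* causes the phenotype;
  affected offspring are *aa*.  Expected mutant-allele frequencies are 1/2
  in each parent, 1 in the affected pool, and 1/3 in the unaffected pool
  (unaffected offspring are *AA:Aa* = 1:2).
* **dominant inhibitor** — the background is fixed for the causal mutation
  and a dominant inhibitor *B* suppresses it; affected offspring are the
  *bb* quarter.  Expected *B* frequencies: 1/2 (parents), 0 (affected
  pool), 2/3 (unaffected pool).

Either way the theoretical pool allele-frequency difference (dAF) is 2/3
and the affected:unaffected ratio is 1:3, tested with a plain Pearson
goodness-of-fit chi-square (1 df, no Yates correction — at the observed
counts the conclusion is insensitive to the correction, and uncorrected
Pearson is the standard default).

## Pooled F_ST scan

Per-site differentiation between pools uses the classical
heterozygosity-based estimator F_ST = (pi_T - pi_W)/pi_T with
H(p) = 2p(1-p).  No pool-size or finite-depth correction is applied by
default: the scan consumes only the *ordering* of windows, which any
consistent estimator preserves at the effect sizes a recessive intercross
produces (causal-site F_ST against a 1-vs-1/3 frequency contrast is 0.5).
Negative per-site values (estimator noise) are clamped to zero so window
means stay in [0, 1].

Windows are 50 kb sliding by 10 kb, anchored at position 1, full windows
only (a chromosome shorter than one window yields a single truncated
window).  The window statistic is the mean of per-site F_ST over sites
callable (depth >= 4) in both pools; windows with fewer than `min_snps`
(default 3) such sites carry no value.  Window values are Z-standardized
against the mean and sample (n-1) SD of all defined windows genome-wide.

The conventional candidate-region threshold ZF_ST > 11 presumes the window
count and null spread of a full multi-chromosome genome.  On the bundled
single 25 Mb chromosome (~2,500 windows) null windows stay below |Z| ~ 4
and the causal windows reach Z ~ 5–10, so the bundled pipeline
configuration uses a threshold of 5; both are plain parameters.
Above-threshold windows are merged (overlapping/abutting, optional gap)
into 1-based inclusive candidate regions.

## Genotype classes and the segregation filter

Hard read-fraction bands classify each (site, library): hom-ref at
f <= 0.05, het in [0.20, 0.80], hom-alt at f >= 0.95, otherwise (or below
4 reads; 2 for ~4x individuals) no-call.  A pool has no diploid genotype,
so "heterozygous" for a pool means an intermediate read fraction judged
with the same band.

The candidate-mutation filter retains variants with dAF > 0.5 that are het
in both parents and the unaffected pool and homozygous (either allele) in
the affected pool; both fixation directions encode the two hypotheses.  A
no-call in any required library rejects the variant — the manual
BAM-review rescue used on real data is deliberately not automated.  Note a
consequence quantified in the acceptance suite: at ~10x parent coverage a
true heterozygote lands inside the het band with probability ~0.93, so
across three parents and two pools the causal variant survives the filter
in *both* crosses in only ~55–65% of simulated replicates.  This is a
property of hard AF-band genotyping at these depths, not of the
implementation; real studies absorb it by manual review of the handful of
near-miss sites.

Structural variants are screened by the analogous seven-library pattern
(het in 3 parents + 2 unaffected pools, homozygous in both affected
pools); a no-call rejects with an `insufficient_evidence` flag.

## IBD screening and target mutations

For each candidate region, the genetic distance between two libraries is
the mean absolute difference of their allele frequencies over sites
callable in both — read fractions for pools, genotype dosage/2 for
individuals.  This is a pseudometric and needs no phasing, which is not
reliable at the ~4x coverage of the outside individuals.  An outside
individual is retained for a region only if its distance to *every*
affected pool is defined and <= 0.1.  `min_sites` (default 5) guards
against distances estimated from almost no sites; the default matches the
bundled density of ~10 SNPs per 50 kb region — raise it for dense real
callsets.

A candidate variant becomes a **target mutation** when the mutant allele
is fixed in every retained affected library.  A library contradicts
fixation only when it is classified hom-ref, or het with at least 2 reads
supporting the reference allele: at 4x coverage a single discordant read
is within sequencing-error expectation (the standard minimum-support rule
used by variant callers), and treating it as evidence would spuriously
veto a truly fixed allele in ~15% of replicates once 20+ low-coverage
individuals are screened.  No-calls are non-informative here.  Regions
with at least one surviving variant are target regions.

## Effect annotation

Coordinates are 1-based inclusive everywhere (BED exports convert to
0-based half-open).  Two deliberately separate helpers exist for interval
length (inclusive span) and point-to-point distance, because the two
conventions differ by one and are a classic source of silent bugs.  SNVs
in a CDS are translated before/after (strand-aware) and classified
synonymous / nonsynonymous / stopgain / stoploss; indels are frameshift
when the length change is not a multiple of 3; a stopgain at codon *k*
truncates the protein to *k* - 1 residues.  Splice sites and UTR subtypes
are out of scope.

## Differential expression and prioritization

Counts are normalized by median-of-ratios size factors.  The DE test is a
negative-binomial Wald test on the log2 fold change (pseudocount 0.5) with
a **common dispersion**: the median of per-gene method-of-moments
estimates.  With two or three samples per group the per-gene estimate is
far too noisy to use directly — power collapses well below what the
effect sizes warrant — and a common dispersion is the standard small-n
remedy; the cost is miscalibration for genes whose true dispersion departs
strongly from the bulk, which the null-calibration test bounds.  DEGs are
|log2FC| > 1 with Benjamini-Hochberg adjusted p < 0.05.  Over-
representation of user-supplied gene sets uses the one-sided
hypergeometric upper tail with BH across sets.

A target-region gene is a final candidate iff it is differentially
expressed, carries at least one coding candidate mutation, and no
independent true-breeding unaffected reference sample is het or
homozygous-mutant at any of those mutations (no-coverage genotypes are
non-informative); a homozygous-mutant reference disqualifies just as a het
does, since a true-breeding unaffected population cannot carry the causal
allele.  Candidates are ranked by mutation severity (stopgain/frameshift
first) and then |log2FC|.

## The synthetic dataset

The generator reproduces the study design at desk scale: one 25 Mb
chromosome with 5,000 SNPs (background founder frequencies Uniform(0.05,
0.95)); three heterozygous parents sharing one copy of a causal
haplotype; two crosses of 629 F2 each; affected pools of 59 and 64 fish
and unaffected pools of 80, sequenced at Poisson 30x (parents 10x) with
binomial allele sampling and a 0.002 per-read error; 5 farms x 10
affected outsiders at 4x; and a 3 vs 3 negative-binomial expression matrix
(dispersion 0.1).

Haplotype structure is the one deliberate abstraction.  The causal
haplotype is shared identically by all carriers over ±2 Mb around the
causal site (the parents are full sibs; sharing farms descend from the
same founder line) and carries otherwise-rare tag alleles over ±25 kb.
The tag flank sets the physical resolution of the scan: it matches the
window size so that the maximal-F_ST windows are exactly those containing
the causal site.  Real data decays smoothly with recombination instead of
having a sharp tag boundary, so passing the localization property here
says the machinery finds a compact ancestral tract, not that any real
cross would resolve to one window.  Two of five farms share the haplotype;
the others are fixed for an independent second causal allele 5 Mb away on
a Balding-Nichols-drifted background (divergence 0.3) — the heterogeneity
a multi-origin phenotype shows.  Recombination is Poisson(1) crossovers
per chromosome per meiosis, positions uniform.  Phenotype is binary and
fully penetrant; expressivity variation is not modelled.

Toy gene models make the annotation and prioritization stages testable:
the causal gene carries a stopgain (TGG→TGA at codon 150 of a 300-codon
CDS) at the causal SNP; three decoy genes near the locus carry linked
nonsynonymous tag variants whose mutant alleles also segregate (frequency
0.6) in the unrelated unaffected reference population, so the reference-
genotype rule eliminates them; background genes sit in SNP-free gaps and
contribute only expression.  The causal gene's true log2 fold change is
-2 (down in affected eyes) at mean 500; ~10% of background genes are DE
at |log2FC| 2.

Everything is deterministic given the seed: one root seed spawns a fixed,
named substream per stage, so adding data to one stage can never perturb
another.

## Problem sizes and runtime

The default simulation (5,000 sites x 60 libraries) runs in ~1 s; the
acceptance suite replays it for 20 seeds per property and completes in
well under a minute on one CPU.  The DE calibration uses 2,000-gene
matrices over 20 seeds.  These sizes were chosen so the full funnel is
exercised at the study's sample sizes while remaining instant to iterate
on.

## Known limitations

* Hard AF-band genotyping is a crude stand-in for likelihood-based
  calling; its low-depth behaviour dominates the filter's miss rate (see
  above).
* The F_ST estimator ignores pool size and finite depth; only window
  ordering is trusted, not absolute values.
* The common-dispersion DE test is a screening tool, not a DESeq
  replacement; with heterogeneous dispersions its per-gene p-values are
  approximate.
* The simulator's sharp IBD tract and tag flank idealize linkage decay;
  physical resolution claims do not transfer to real crosses.
* SV handling is genotype-pattern screening of biallelic pseudo-sites; no
  breakpoint or sequence-level SV modelling.
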