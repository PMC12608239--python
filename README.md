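# recmap

Recessive-locus mapping from pooled sequencing: the full inference chain a
bulked-segregant study uses to go from phenotype-defined DNA pools to a
single candidate gene, as a tested, reusable Python library with a
`recmap` command line.

The motivating system is ornamental-fish genetics — mapping the goldfish
*celestial eye* mutation, a fully penetrant recessive eye phenotype —
but every stage is generic over the design it encodes:

1. **Mendelian cross models** (`recmap.mendel`).  For an F2 from two
   heterozygous parents, the mutant allele *a* is expected at frequency
   1/2 in each parent, 1 in the affected pool and 1/3 in the unaffected
   pool (unaffected are *AA:Aa* = 1:2), so the theoretical pool
   allele-frequency difference (dAF) is 2/3; under the alternative
   dominant-inhibitor hypothesis the pools fix the opposite allele with
   the same dAF.  Segregation ratios are tested with a Pearson chi-square
   against 1:3.
2. **Pooled F_ST scan** (`recmap.pooled_scan`).  Per-site
   F_ST = (pi_T - pi_W)/pi_T between pools, averaged in 50 kb windows
   sliding by 10 kb, Z-standardized genome-wide (ZF_ST); above-threshold
   windows merge into candidate regions.
3. **Segregation-pattern filter** (`recmap.variant_filter`).  Candidate
   mutations have dAF > 0.5, are heterozygous in both parents and the
   unaffected pool, and homozygous in the affected pool; two crosses are
   intersected.  An analogous seven-library pattern screens SVs.
4. **IBD screen** (`recmap.ibd_screen`).  Affected individuals from other
   populations are kept per region only if their allele-frequency distance
   to every affected pool is <= 0.1; candidate variants fixed in all
   retained affected libraries become target mutations, their regions
   target regions.
5. **Effect annotation** (`recmap.variant_effects`).  Strand-aware coding
   consequences on explicit gene models (stopgain, stoploss,
   frameshift/non-frameshift indels, (non)synonymous), truncated-protein
   lengths, and careful 1-based inclusive coordinate arithmetic.
6. **Expression evidence** (`recmap.expression`).  Median-of-ratios
   normalization, a negative-binomial Wald DE test with common dispersion,
   BH correction (DEG: |log2FC| > 1, padj < 0.05), hypergeometric
   over-representation, and the final prioritization rule: a target-region
   gene survives iff it is differentially expressed, carries a coding
   candidate mutation, and no true-breeding unaffected reference sample
   carries that mutation.

A first-class synthetic-data generator (`recmap.synthetic_data`)
reproduces the whole study design — two het x het crosses segregating a
causal SNP, phenotype pools at 30x, parents at 10x, 50 low-coverage
outside individuals from 5 farms with and without the shared causal
haplotype, toy gene models harbouring a stopgain, and a 3 vs 3 expression
matrix — so the end-to-end pipeline (`recmap.pipeline`) is testable
without any external data.  See `docs/methods.md` for models, defaults
and limitations.

## Worked example

Segregation test on observed offspring counts (77 affected vs 232
unaffected):

```console
$ recmap mendel --affected 77 --unaffected 232
{
  "observed_affected": 77,
  "observed_unaffected": 232,
  "ratio": [1.0, 3.0],
  "expected_affected": 77.25,
  "expected_unaffected": 231.75,
  "chi2": 0.0010787486515641855,
  "p": 0.9737987435678683
}
```

p = 0.97: the counts are exactly what a single recessive locus predicts.

Full pipeline on the bundled simulation (one 25 Mb chromosome, 5,000
SNPs, 629 F2 per cross, pools of 59/64/80):

```python
from recmap import SimConfig, RunConfig, run_pipeline

summary = run_pipeline(RunConfig(sim=SimConfig(seed=1), out_dir="out"))
```

prints per-stage record counts and, for seed 1, funnels

```text
n_candidate_regions    = 6
n_candidate_mutations  = 11
n_target_mutations     = 6
target_region_span_mb  = 0.2
n_degs                 = 27
target_genes           = ['cerkl_l', 'frzb_l', 'itprid2_l', 'lrp2l']
candidate_genes        = ['lrp2l']
```

— six scan regions shrink to eleven shared candidate mutations, six
target mutations in 0.2 Mb of target regions, four differentially
expressed target genes, and finally the one simulated causal gene
(`lrp2l`, whose planted stopgain truncates a 300-codon protein to 149
residues); the three decoys are eliminated because unaffected reference
fish carry their mutant alleles.  The same run is available as
`recmap run --seed 1 --out out/`, and each stage separately as
`recmap simulate | scan | filter | ibd | effects | deg | prioritize`.

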