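"""Simulation of a recessive-locus mapping experiment.

The generator emulates the full study design the pipeline consumes:

* three heterozygous parents carrying one shared copy of a causal haplotype,
  crossed in two het x het matings segregating a fully penetrant recessive
  phenotype at a single causal SNP;
* phenotype-defined offspring DNA pools and the individually sequenced
  parents, read counts drawn per site as Poisson depth and binomial allele
  sampling with a small per-read error;
* affected individuals from several farms, some of which share the founder
  causal haplotype (identity by descent) and some of which carry an
  independent mutation at a second position on a drifted background;
* toy gene models around the causal locus - the causal gene harbours a
  stopgain at the causal SNP, decoy genes harbour linked nonsynonymous
  variants whose mutant alleles also segregate in the unrelated unaffected
  reference population;
* a genes x samples RNA-seq count matrix with differential expression
  concentrated near the causal locus.

Haplotype structure is deliberately simple: the causal haplotype is shared
identically by all carriers over ``share_flank_bp`` around the causal site,
and carries otherwise-rare "tag" alleles over the narrower
``tag_flank_bp``.  The tag flank sets the physical resolution of the F_ST
scan; its default matches the scan window so the signal concentrates in
windows containing the causal site, the way a compact ancestral tract does
after many generations of line breeding.  Everything is deterministic given
``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlleleCountTable, CrossLibraries, LibraryMeta, Role
from .variant_effects import GeneModel

PARENT_IDS = ("NEM", "NEF1", "NEF2")
DEFAULT_FARMS = ("Ah", "Bj", "Hb", "Js", "Sh")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _CODONS if c not in _STOP_CODONS]


@dataclass
class SimConfig:
    """All knobs of the simulated mapping experiment.

    Defaults reproduce the study scale: pools of 59/64 affected and 80
    unaffected F2 fish sequenced at ~30x, parents at ~10x, 50 outside
    individuals (5 farms x 10 fish) at ~4x, and a 3 vs 3 eyeball RNA-seq
    comparison.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length_bp: int = 25_000_000
    n_snps: int = 5_000
    causal_chrom: str = "chr1"
    causal_pos: int = 12_500_000
    hypothesis: str = "recessive_causal"
    n_offspring_per_cross: int = 629
    pool_sizes: dict = field(default_factory=lambda: {
        "affected_pool_1": 59,
        "affected_pool_2": 64,
        "unaffected_pool": 80,
    })
    depth: dict = field(default_factory=lambda: {
        "pool": 30.0, "parent": 10.0, "individual": 4.0, "reference": 20.0,
    })
    n_farms: int = 5
    n_per_farm: int = 10
    farms: tuple = DEFAULT_FARMS
    farms_sharing_ibd: tuple = ("Bj", "Sh")
    recomb_rate: float = 1.0
    background_divergence: float = 0.3
    tag_flank_bp: int = 25_000
    share_flank_bp: int = 2_000_000
    second_causal_offset_bp: int = 5_000_000
    seq_error: float = 0.002
    tag_rare_freq: float = 0.02
    # Expression model
    n_genes: int = 200
    expr_dispersion: float = 0.1
    expr_base_mean: float = 200.0
    focal_gene_mean: float = 500.0
    causal_lfc: float = -2.0
    decoy_lfc: float = 1.5
    frac_background_de: float = 0.10
    background_lfc: float = 2.0
    n_reference_unaffected: int = 3
    decoy_ref_alt_freq: float = 0.6

    def __post_init__(self) -> None:
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if self.n_farms != len(self.farms):
            self.farms = tuple(f"farm{i + 1}" for i in range(self.n_farms))
        if not set(self.farms_sharing_ibd) <= set(self.farms):
            raise ValueError("farms_sharing_ibd must be a subset of farms")
        if not (1 <= self.causal_pos <= self.chrom_length_bp):
            raise ValueError("causal_pos must lie within [1, chrom_length_bp]")
        if self.causal_chrom not in self.chrom_names:
            raise ValueError(
                f"causal_chrom {self.causal_chrom!r} not among "
                f"{self.chrom_names}"
            )
        if any(d <= 0 for d in self.depth.values()):
            raise ValueError("all depths must be > 0")
        if any(s < 1 for s in self.pool_sizes.values()):
            raise ValueError("pool sizes must be >= 1")
        if self.hypothesis not in ("recessive_causal", "dominant_inhibitor"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.expr_dispersion <= 0:
            raise ValueError("expression dispersion must be > 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One independent, reproducible RNG stream per simulation stage.

    Streams are spawned in a fixed order from a single root so that adding
    data for one stage can never perturb another.
    """
    names = ["founders", "genes", "cross1", "cross2", "pools", "farms",
             "expression", "reference"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# Founders


@dataclass
class Founders:
    """Site table, causal haplotype, and parental haplotypes."""

    config: SimConfig
    sites: pd.DataFrame            # chrom, pos, ref, alt, founder_af, is_tag
    positions: np.ndarray          # per-site position (int64)
    chrom_slices: list             # (chrom, lo, hi, length_bp)
    causal_hap: np.ndarray         # 0/1 per site
    parent_haps: dict              # parent -> (carrier_hap, other_hap)
    causal_index: int
    second_causal_index: int | None
    share_mask: np.ndarray         # sites within the shared IBD tract
    tag_mask: np.ndarray


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> Founders:
    """Draw the standing variation and the three heterozygous parents.

    Background allele frequencies are Uniform(0.05, 0.95); sites within the
    tag flank carry the alternate allele on the causal haplotype only, at
    background frequency ``tag_rare_freq`` elsewhere.  Every parent is
    heterozygous at the causal site, carrying one copy of the shared causal
    haplotype.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["founders"]
    per_chrom = np.full(config.n_chrom, config.n_snps // config.n_chrom)
    per_chrom[: config.n_snps % config.n_chrom] += 1
    if per_chrom[config.chrom_names.index(config.causal_chrom)] == 0:
        raise ValueError("no SNPs allocated to the causal chromosome")

    second_pos: int | None = None
    if config.n_snps >= 2:
        cand = config.causal_pos + config.second_causal_offset_bp
        if cand > config.chrom_length_bp:
            cand = config.causal_pos - config.second_causal_offset_bp
        if 1 <= cand <= config.chrom_length_bp and cand != config.causal_pos:
            second_pos = int(cand)

    chroms, positions = [], []
    chrom_slices = []
    lo = 0
    for name, n_here in zip(config.chrom_names, per_chrom):
        n_here = int(n_here)
        forced = []
        if name == config.causal_chrom:
            forced.append(config.causal_pos)
            if second_pos is not None and n_here >= 2:
                forced.append(second_pos)
        n_draw = max(n_here - len(forced), 0)
        pool = rng.choice(config.chrom_length_bp, size=min(
            n_draw + len(forced) + 10, config.chrom_length_bp),
            replace=False) + 1
        pool = [int(p) for p in pool if p not in forced][:n_draw]
        pos = np.array(sorted(set(pool) | set(forced)), dtype=np.int64)
        chroms.extend([name] * len(pos))
        positions.append(pos)
        chrom_slices.append((name, lo, lo + len(pos), config.chrom_length_bp))
        lo += len(pos)
    positions = np.concatenate(positions)
    n = len(positions)
    chrom_arr = np.array(chroms)

    af = rng.uniform(0.05, 0.95, n)
    tag_mask = (
        (chrom_arr == config.causal_chrom)
        & (np.abs(positions - config.causal_pos) <= config.tag_flank_bp)
    )
    share_mask = (
        (chrom_arr == config.causal_chrom)
        & (np.abs(positions - config.causal_pos) <= config.share_flank_bp)
    )
    af[tag_mask] = config.tag_rare_freq

    causal_index = int(np.flatnonzero(
        (chrom_arr == config.causal_chrom) & (positions == config.causal_pos)
    )[0])
    second_index = None
    if second_pos is not None:
        hits = np.flatnonzero(
            (chrom_arr == config.causal_chrom) & (positions == second_pos)
        )
        second_index = int(hits[0]) if hits.size else None

    causal_hap = (rng.random(n) < af).astype(np.uint8)
    causal_hap[tag_mask] = 1
    causal_hap[causal_index] = 1
    if second_index is not None:
        causal_hap[second_index] = 0

    parent_haps = {}
    for parent in PARENT_IDS:
        carrier = (rng.random(n) < af).astype(np.uint8)
        carrier[share_mask] = causal_hap[share_mask]
        carrier[causal_index] = 1
        other = (rng.random(n) < af).astype(np.uint8)
        other[causal_index] = 0
        if second_index is not None:
            other[second_index] = 0
            carrier[second_index] = 0
        parent_haps[parent] = (carrier, other)

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    shift = rng.integers(1, 4, n)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]

    sites = pd.DataFrame({
        "chrom": chrom_arr, "pos": positions, "ref": ref, "alt": alt,
        "founder_af": af, "is_tag": tag_mask,
    })
    return Founders(
        config=config, sites=sites, positions=positions,
        chrom_slices=chrom_slices, causal_hap=causal_hap,
        parent_haps=parent_haps, causal_index=causal_index,
        second_causal_index=second_index, share_mask=share_mask,
        tag_mask=tag_mask,
    )


# ---------------------------------------------------------------------------
# Meiosis and crosses


def _gametes(hap0: np.ndarray, hap1: np.ndarray, founders: Founders,
             rate: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` recombinant gametes from one parent.

    Crossover counts per chromosome are Poisson(``rate``), positions
    uniform; the starting haplotype of each chromosome is random.
    """
    out = np.empty((n, len(founders.positions)), dtype=np.uint8)
    for chrom, lo, hi, length in founders.chrom_slices:
        pos = founders.positions[lo:hi]
        h0, h1 = hap0[lo:hi], hap1[lo:hi]
        for i in range(n):
            k = int(rng.poisson(rate))
            start = int(rng.integers(0, 2))
            if k == 0:
                src = start
                out[i, lo:hi] = h0 if src == 0 else h1
            else:
                breaks = np.sort(rng.uniform(1, length + 1, k))
                seg = np.searchsorted(breaks, pos)
                src = (start + seg) % 2
                out[i, lo:hi] = np.where(src == 0, h0, h1)
    return out


@dataclass
class Offspring:
    """Genotypes (alt-allele dosage per site) and phenotypes of one cross."""

    parents: tuple[str, str]
    dosage: np.ndarray       # (n_offspring, n_sites) uint8 in {0,1,2}
    affected: np.ndarray     # boolean


def simulate_cross(founders: Founders, parents: tuple[str, str],
                   rng: np.random.Generator | None = None,
                   n_offspring: int | None = None) -> Offspring:
    """Mate two heterozygous parents and phenotype the offspring.

    Under ``recessive_causal`` an offspring is affected iff it is
    homozygous-alternate at the causal site; under ``dominant_inhibitor``
    iff it carries no copy of the (inhibitor) alternate allele.
    """
    config = founders.config
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_offspring if n_offspring is not None else config.n_offspring_per_cross
    ci = founders.causal_index
    for p in parents:
        h0, h1 = founders.parent_haps[p]
        if h0[ci] + h1[ci] != 1:
            raise ValueError(f"parent {p} is not heterozygous at the causal "
                             "site")
    gam_a = _gametes(*founders.parent_haps[parents[0]], founders,
                     config.recomb_rate, rng, n)
    gam_b = _gametes(*founders.parent_haps[parents[1]], founders,
                     config.recomb_rate, rng, n)
    dosage = gam_a + gam_b
    if config.hypothesis == "recessive_causal":
        affected = dosage[:, ci] == 2
        # Definitional under the recessive model: affected <=> homozygous.
        assert np.array_equal(affected, dosage[:, ci] == 2)
    else:
        affected = dosage[:, ci] == 0
    return Offspring(parents=tuple(parents), dosage=dosage, affected=affected)


# ---------------------------------------------------------------------------
# Sequencing


def _sequence_library(pool_freq: np.ndarray, mean_depth: float,
                      seq_error: float, rng: np.random.Generator) -> np.ndarray:
    """(ref, alt) read counts: Poisson depth, binomial allele sampling."""
    n = len(pool_freq)
    depth = rng.poisson(mean_depth, n)
    p_alt = pool_freq * (1 - seq_error) + (1 - pool_freq) * seq_error
    alt = rng.binomial(depth, p_alt)
    return np.column_stack([depth - alt, alt]).astype(np.int64)


def simulate_pools(founders: Founders, cross1: Offspring, cross2: Offspring,
                   rng: np.random.Generator | None = None
                   ) -> tuple[AlleleCountTable, dict[str, LibraryMeta]]:
    """Sequence the seven mapping-population libraries.

    The affected pool of each cross holds ``pool_sizes`` affected fish, the
    unaffected pool a uniform random sample (without replacement) of
    unaffected fish.  Parents are sequenced as two-chromosome "pools".  At
    each site the pool allele frequency is the mean genotype dosage / 2 over
    members, equimolar pooling being assumed.
    """
    config = founders.config
    rng = rng if rng is not None else _stage_rngs(config.seed)["pools"]
    counts: dict[str, np.ndarray] = {}
    meta: dict[str, LibraryMeta] = {}

    for parent in PARENT_IDS:
        h0, h1 = founders.parent_haps[parent]
        freq = (h0.astype(float) + h1) / 2
        counts[parent] = _sequence_library(
            freq, config.depth["parent"], config.seq_error, rng)
        meta[parent] = LibraryMeta(parent, Role.PARENT, cross=None)

    for idx, offspring in ((1, cross1), (2, cross2)):
        n_aff = int(config.pool_sizes[f"affected_pool_{idx}"])
        n_unaff = int(config.pool_sizes["unaffected_pool"])
        aff_idx = np.flatnonzero(offspring.affected)
        unaff_idx = np.flatnonzero(~offspring.affected)
        if len(aff_idx) < n_aff or len(unaff_idx) < n_unaff:
            raise ValueError(
                f"cross {idx}: not enough offspring to fill the pools "
                f"({len(aff_idx)} affected, {len(unaff_idx)} unaffected)"
            )
        aff_members = rng.choice(aff_idx, n_aff, replace=False)
        unaff_members = rng.choice(unaff_idx, n_unaff, replace=False)
        for tag, members, role in (
            (f"Pool_CE{idx}", aff_members, Role.AFFECTED_POOL),
            (f"Pool_NE{idx}", unaff_members, Role.UNAFFECTED_POOL),
        ):
            if len(members) == 0:
                raise ValueError(f"empty pool {tag}")
            freq = offspring.dosage[members].mean(axis=0) / 2
            counts[tag] = _sequence_library(
                freq, config.depth["pool"], config.seq_error, rng)
            meta[tag] = LibraryMeta(tag, role, cross=idx,
                                    pool_size=len(members))
    return AlleleCountTable(founders.sites, counts), meta


def pool_table_from_members(founders: Founders, dosage: np.ndarray,
                            mean_depth: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Sequence an arbitrary set of diploid members as one pool."""
    if dosage.ndim != 2 or dosage.shape[0] == 0:
        raise ValueError("empty pool")
    freq = dosage.mean(axis=0) / 2
    return _sequence_library(freq, mean_depth, founders.config.seq_error, rng)


# ---------------------------------------------------------------------------
# Outside individuals (farms)


@dataclass
class FarmSample:
    """Genotypes and metadata of the outside affected individuals."""

    lib_ids: list[str]
    farm_of: dict[str, str]
    sharing: dict[str, bool]
    dosage: np.ndarray  # (n_individuals, n_sites)


def _balding_nichols(af: np.ndarray, fst: float,
                     rng: np.random.Generator) -> np.ndarray:
    if fst <= 0:
        return af.copy()
    p = np.clip(af, 1e-6, 1 - 1e-6)
    shape = (1 - fst) / fst
    return rng.beta(p * shape, (1 - p) * shape)


def simulate_farms(founders: Founders,
                   rng: np.random.Generator | None = None) -> FarmSample:
    """Affected individuals from outside farms.

    Individuals from farms sharing the causal haplotype are homozygous for
    it across the shared tract; other farms are homozygous-alternate at an
    independent second causal position, with backgrounds drifted from the
    founder frequencies by a Balding-Nichols draw parameterized by
    ``background_divergence``.
    """
    config = founders.config
    rng = rng if rng is not None else _stage_rngs(config.seed)["farms"]
    n_sites = len(founders.positions)
    lib_ids, farm_of, sharing = [], {}, {}
    rows = []
    for farm in config.farms:
        farm_af = _balding_nichols(
            founders.sites["founder_af"].to_numpy(),
            config.background_divergence, rng)
        is_sharing = farm in config.farms_sharing_ibd
        for i in range(config.n_per_farm):
            lib = f"{farm}_{i + 1:02d}"
            h0 = (rng.random(n_sites) < farm_af).astype(np.uint8)
            h1 = (rng.random(n_sites) < farm_af).astype(np.uint8)
            if is_sharing:
                h0[founders.share_mask] = founders.causal_hap[founders.share_mask]
                h1[founders.share_mask] = founders.causal_hap[founders.share_mask]
                h0[founders.causal_index] = h1[founders.causal_index] = 1
            else:
                h0[founders.causal_index] = h1[founders.causal_index] = 0
                if founders.second_causal_index is not None:
                    si = founders.second_causal_index
                    h0[si] = h1[si] = 1
            rows.append(h0 + h1)
            lib_ids.append(lib)
            farm_of[lib] = farm
            sharing[lib] = is_sharing
    return FarmSample(lib_ids=lib_ids, farm_of=farm_of, sharing=sharing,
                      dosage=np.array(rows, dtype=np.uint8))


def sequence_individuals(founders: Founders, dosage: np.ndarray,
                         lib_ids: list[str], mean_depth: float,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Read counts for individually sequenced diploid fish."""
    out = {}
    for lib, row in zip(lib_ids, dosage):
        out[lib] = _sequence_library(
            row.astype(float) / 2, mean_depth, founders.config.seq_error, rng)
    return out


# ---------------------------------------------------------------------------
# Gene models and expression


@dataclass
class GeneTruth:
    """Ground truth linking gene models, variants and expression."""

    causal_gene: str
    causal_variant: tuple  # (chrom, pos, ref, alt)
    decoy_variants: pd.DataFrame  # gene_id, chrom, pos, ref, alt
    decoy_spans: list  # (chrom, start, end) per decoy gene
    de_truth: pd.DataFrame        # gene_id, true_log2fc, mean


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = [
        _SAFE_CODONS[int(i)]
        for i in rng.integers(0, len(_SAFE_CODONS), n_codons - 1)
    ]
    codons.append("TAA")
    return codons


def _find_gap(positions: np.ndarray, near: int, span_len: int,
              occupied: list[tuple[int, int]], chrom_len: int) -> int | None:
    """A start coordinate near ``near`` whose span avoids all SNP sites."""
    order = np.argsort(np.abs(positions - near))
    for j in order[:50]:
        left = int(positions[j])
        right = int(positions[j + 1]) if j + 1 < len(positions) else chrom_len
        if right - left - 1 < span_len + 2:
            continue
        start = left + 1 + (right - left - span_len - 1) // 2
        end = start + span_len - 1
        if start < 1 or end > chrom_len:
            continue
        if all(end < s or start > e for s, e in occupied):
            return start
    return None


def simulate_gene_models(
    founders: Founders, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], GeneTruth]:
    """Build toy gene models and align site alleles with their sequences.

    The causal gene is a single-exon 300-codon CDS whose 150th codon (TGG)
    is converted to a premature stop (TGA) by the causal SNP.  Three decoy
    genes near the causal site carry nonsynonymous variants at tag sites:
    linked, segregating with the phenotype in the mapping population, but
    with mutant alleles also present in unrelated unaffected populations.
    Remaining genes are placed in gaps between SNP sites so they carry no
    variants at all.  Site ``ref``/``alt`` bases inside gene spans are
    rewritten to match the gene sequence (this mutates ``founders.sites``;
    call before writing sync/VCF output).
    """
    config = founders.config
    rng = rng if rng is not None else _stage_rngs(config.seed)["genes"]
    sites = founders.sites
    chrom = config.causal_chrom
    chrom_len = config.chrom_length_bp
    models: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []

    def register(model: GeneModel) -> None:
        models.append(model)
        occupied.append((model.span_start, model.span_end))

    def rewrite_site_alleles(model: GeneModel, designed: dict[int, str]) -> None:
        mask = (
            (sites["chrom"] == model.chrom)
            & (sites["pos"] >= model.span_start)
            & (sites["pos"] <= model.span_end)
        )
        for idx in np.flatnonzero(mask.to_numpy()):
            pos = int(sites.at[idx, "pos"])
            ref_base = model.base_at(pos)
            sites.at[idx, "ref"] = ref_base
            if pos in designed:
                sites.at[idx, "alt"] = designed[pos]
            else:
                others = [b for b in "ACGT" if b != ref_base]
                sites.at[idx, "alt"] = others[int(rng.integers(0, 3))]

    # Causal gene: stopgain at codon 150 (TGG -> TGA via G>A at codon pos 3).
    n_codons = 300
    causal_cds_index = 150 * 3  # 1-based index of the causal base in the CDS
    start = config.causal_pos - causal_cds_index + 1
    codons = _random_cds(n_codons, rng)
    codons[149] = "TGG"
    seq = "".join(codons)
    causal_gene = GeneModel(
        gene_id="lrp2l", chrom=chrom, strand="+",
        exons=[(start, start + len(seq) - 1)],
        cds_start=start, cds_end=start + len(seq) - 1, seq=seq,
    )
    register(causal_gene)
    rewrite_site_alleles(causal_gene, {config.causal_pos: "A"})
    causal_variant = (chrom, config.causal_pos, "G", "A")

    # Decoy genes at tag sites: nonsynonymous GAT -> AAT (D -> N).
    tag_pos = sites.loc[
        founders.tag_mask & (sites["pos"] != config.causal_pos), "pos"
    ].to_numpy()
    tag_pos = tag_pos[np.argsort(np.abs(tag_pos - config.causal_pos))]
    decoy_rows = []
    decoy_spans: list[tuple] = []
    decoy_names = ["cerkl_l", "itprid2_l", "frzb_l"]
    for pos in tag_pos:
        if len(decoy_rows) == len(decoy_names):
            break
        pos = int(pos)
        n_cod = 100
        d_start = pos - 49 * 3  # variant at codon 50, position 1
        d_end = d_start + n_cod * 3 - 1
        if d_start < 1 or d_end > chrom_len:
            continue
        if any(d_end >= s - 1 and d_start <= e + 1 for s, e in occupied):
            continue
        codons = _random_cds(n_cod, rng)
        codons[49] = "GAT"
        seq = "".join(codons)
        name = decoy_names[len(decoy_rows)]
        model = GeneModel(
            gene_id=name, chrom=chrom, strand="+",
            exons=[(d_start, d_end)], cds_start=d_start, cds_end=d_end,
            seq=seq,
        )
        register(model)
        rewrite_site_alleles(model, {pos: "A"})
        decoy_rows.append((name, chrom, pos, "G", "A"))
        decoy_spans.append((chrom, d_start, d_end))
    decoy_variants = pd.DataFrame(
        decoy_rows, columns=["gene_id", "chrom", "pos", "ref", "alt"])

    # Background genes in SNP-free gaps: a few near the locus, the rest
    # spread along the chromosome; every 7th on the minus strand.
    chrom_positions = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
    n_background = max(config.n_genes - len(models), 0)
    near_offsets = [35_000, -35_000, 45_000, -45_000]
    targets = [config.causal_pos + off for off in near_offsets[:n_background]]
    if n_background > len(targets):
        extra = np.linspace(
            chrom_len * 0.02, chrom_len * 0.98, n_background - len(targets)
        ).astype(int)
        targets.extend(int(t) for t in extra)
    for g, near in enumerate(targets):
        span_len = 50 * 3
        start = _find_gap(chrom_positions, near, span_len, occupied, chrom_len)
        if start is None:
            continue
        seq = "".join(_random_cds(50, rng))
        strand = "-" if g % 7 == 6 else "+"
        model = GeneModel(
            gene_id=f"gene{g + 1:03d}", chrom=chrom, strand=strand,
            exons=[(start, start + span_len - 1)],
            cds_start=start, cds_end=start + span_len - 1,
            seq=seq if strand == "+" else _revcomp(seq),
        )
        register(model)

    # Expression truth: causal gene down in affected eyes, decoys DE too,
    # plus a sprinkling of background DEGs.
    truth_rows = [(causal_gene.gene_id, config.causal_lfc,
                   config.focal_gene_mean)]
    for i, (name, *_rest) in enumerate(decoy_rows):
        sign = 1 if i % 2 == 0 else -1
        truth_rows.append((name, sign * config.decoy_lfc,
                           config.focal_gene_mean))
    background = [m for m in models
                  if m.gene_id not in {r[0] for r in truth_rows}]
    n_de = int(round(config.frac_background_de * len(background)))
    de_idx = set(rng.choice(len(background), n_de, replace=False).tolist()) \
        if n_de else set()
    for i, m in enumerate(background):
        lfc = 0.0
        if i in de_idx:
            lfc = float(rng.choice([-1, 1])) * config.background_lfc
        mean = float(rng.lognormal(np.log(config.expr_base_mean), 1.0))
        truth_rows.append((m.gene_id, lfc, mean))
    de_truth = pd.DataFrame(truth_rows,
                            columns=["gene_id", "true_log2fc", "mean"])
    truth = GeneTruth(
        causal_gene=causal_gene.gene_id, causal_variant=causal_variant,
        decoy_variants=decoy_variants, decoy_spans=decoy_spans,
        de_truth=de_truth,
    )
    return models, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_expression(
    config: SimConfig, de_truth: pd.DataFrame,
    rng: np.random.Generator | None = None, n_per_group: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial RNA-seq counts for a two-group comparison.

    ``de_truth`` carries ``gene_id, true_log2fc, mean`` (unaffected-group
    mean); affected-group means are scaled by 2**true_log2fc.  Returns
    (counts, groups).
    """
    if config.expr_dispersion <= 0:
        raise ValueError("expression dispersion must be > 0")
    rng = rng if rng is not None else _stage_rngs(config.seed)["expression"]
    genes = de_truth["gene_id"].to_numpy()
    mu_unaff = de_truth["mean"].to_numpy(dtype=float)
    mu_aff = mu_unaff * np.power(2.0, de_truth["true_log2fc"].to_numpy())
    alpha = config.expr_dispersion
    n_nb = 1.0 / alpha

    cols = {}
    for i in range(n_per_group):
        cols[f"CE_{i + 1}"] = rng.negative_binomial(
            n_nb, n_nb / (n_nb + mu_aff))
    for i in range(n_per_group):
        cols[f"NE_{i + 1}"] = rng.negative_binomial(
            n_nb, n_nb / (n_nb + mu_unaff))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    groups = pd.Series(
        {c: ("affected" if c.startswith("CE") else "unaffected")
         for c in counts.columns}
    )
    return counts, groups


def simulate_reference_genotypes(
    founders: Founders, truth: GeneTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Read counts for unrelated true-breeding unaffected fish.

    The reference population carries no causal allele, background variation
    at founder frequencies, and — at every variant inside a decoy gene span —
    the mutant allele at ``decoy_ref_alt_freq``: neutral variants linked to
    the decoy genes that segregate in unrelated populations and betray the
    decoys.
    """
    config = founders.config
    rng = rng if rng is not None else _stage_rngs(config.seed)["reference"]
    af = founders.sites["founder_af"].to_numpy().copy()
    chroms = founders.sites["chrom"].to_numpy()
    for chrom, start, end in truth.decoy_spans:
        in_span = ((chroms == chrom) & (founders.positions >= start)
                   & (founders.positions <= end))
        af[in_span] = config.decoy_ref_alt_freq
    af[founders.causal_index] = 0.0
    out = {}
    for i in range(config.n_reference_unaffected):
        h0 = (rng.random(len(af)) < af).astype(np.uint8)
        h1 = (rng.random(len(af)) < af).astype(np.uint8)
        out[f"NEref_{i + 1}"] = _sequence_library(
            (h0 + h1) / 2, config.depth["reference"], config.seq_error, rng)
    return out


# ---------------------------------------------------------------------------
# Whole-dataset convenience


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus ground truth."""

    config: SimConfig
    founders: Founders
    gene_models: list[GeneModel]
    gene_truth: GeneTruth
    cross1: Offspring
    cross2: Offspring
    table: AlleleCountTable
    library_meta: dict[str, LibraryMeta]
    farm_sample: FarmSample
    expression_counts: pd.DataFrame
    expression_groups: pd.Series

    @property
    def cross1_libs(self) -> CrossLibraries:
        return CrossLibraries(("NEM", "NEF1"), "Pool_CE1", "Pool_NE1")

    @property
    def cross2_libs(self) -> CrossLibraries:
        return CrossLibraries(("NEM", "NEF2"), "Pool_CE2", "Pool_NE2")

    @property
    def kinds(self) -> dict[str, str]:
        return {
            lib: ("individual" if meta.role is Role.INDIVIDUAL else "pool")
            for lib, meta in self.library_meta.items()
        }


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run every simulation stage with stage-scoped RNG substreams."""
    rngs = _stage_rngs(config.seed)
    founders = simulate_founders(config, rngs["founders"])
    gene_models, gene_truth = simulate_gene_models(founders, rngs["genes"])
    cross1 = simulate_cross(founders, ("NEM", "NEF1"), rngs["cross1"])
    cross2 = simulate_cross(founders, ("NEM", "NEF2"), rngs["cross2"])
    table, meta = simulate_pools(founders, cross1, cross2, rngs["pools"])

    farms = simulate_farms(founders, rngs["farms"])
    farm_counts = sequence_individuals(
        founders, farms.dosage, farms.lib_ids,
        config.depth["individual"], rngs["farms"])
    counts = dict(table.counts)
    counts.update(farm_counts)
    for lib in farms.lib_ids:
        meta[lib] = LibraryMeta(lib, Role.INDIVIDUAL, farm=farms.farm_of[lib])

    ref_counts = simulate_reference_genotypes(
        founders, gene_truth, rngs["reference"])
    counts.update(ref_counts)
    for lib in ref_counts:
        meta[lib] = LibraryMeta(lib, Role.INDIVIDUAL, farm="reference")

    full_table = AlleleCountTable(founders.sites, counts)
    expr_counts, expr_groups = simulate_expression(
        config, gene_truth.de_truth, rngs["expression"])
    return SimulatedDataset(
        config=config, founders=founders, gene_models=gene_models,
        gene_truth=gene_truth, cross1=cross1, cross2=cross2,
        table=full_table, library_meta=meta, farm_sample=farms,
        expression_counts=expr_counts, expression_groups=expr_groups,
    )
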