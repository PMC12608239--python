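"""End-to-end orchestration: simulate -> scan -> filter -> IBD -> effects ->
DEG -> prioritize.

The pipeline reproduces the funnel structure of a pooled mapping study:
genome-wide candidate regions from the ZF_ST scan, segregation-pattern
candidate mutations shared by both crosses, IBD-screened target mutations
and regions, coding-effect annotation, and a final DEG-supported candidate
gene list.

Every stage logs its record counts; the JSON summary carries the whole
funnel so a run can be audited (and two runs with the same seed compared)
from one file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .core import Region, Role
from .expression import de_test, prioritize_candidates
from .ibd_screen import (
    distance_matrix,
    region_span_mb,
    retain_samples,
    screen_target_mutations,
)
from .pooled_scan import (
    call_candidate_regions,
    window_scan,
    zfst_transform,
)
from .synthetic_data import SimConfig, simulate_dataset
from .variant_effects import FUNCTIONAL_CATEGORIES, annotate_variants
from .variant_filter import candidate_mutation_filter, intersect_crosses

logger = logging.getLogger("recmap")


@dataclass
class RunConfig:
    """Stage parameters for one pipeline run.

    ``z_threshold`` defaults to 5: the conventional genome-wide cutoff of 11
    presumes the window count of a full multi-chromosome genome, while the
    bundled simulation scans a single chromosome (~2,500 windows), for which
    5 sits safely above the null window distribution.  It is a parameter,
    not a constant.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    window: int = 50_000
    step: int = 10_000
    z_threshold: float = 5.0
    min_snps: int = 3
    daf_min: float = 0.5
    d_max: float = 0.1
    min_sites: int = 5
    merge_gap: int = 0
    out_dir: str | None = None


def _merge_regions(regions: list[Region], merge_gap: int = 0) -> list[Region]:
    """Union of possibly overlapping 1-based regions."""
    out: list[Region] = []
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.start)
        cur = rs[0]
        for r in rs[1:]:
            if r.start <= cur.end + merge_gap + 1:
                cur = Region(chrom, cur.start, max(cur.end, r.end))
            else:
                out.append(cur)
                cur = r
        out.append(cur)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and optionally writes) the summary."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save(frame: pd.DataFrame, name: str) -> None:
        if out_dir is not None:
            rio.write_tsv(frame, out_dir / name)

    logger.info("=== stage: simulate ===")
    ds = simulate_dataset(config.sim)
    table = ds.table
    logger.info("simulated %d sites x %d libraries", table.n_sites,
                len(table.libraries))
    if out_dir is not None:
        rio.write_sync(table, out_dir / "all_libraries.sync")
        rio.write_gff3(ds.gene_models, out_dir / "genes.gff3")
        rio.write_gene_fasta(ds.gene_models, out_dir / "genes.fa")
        ds.expression_counts.to_csv(out_dir / "expression_counts.tsv",
                                    sep="\t")

    # --- scan ------------------------------------------------------------
    logger.info("=== stage: scan ===")
    region_objs: list[Region] = []
    for idx, cl in ((1, ds.cross1_libs), (2, ds.cross2_libs)):
        windows = window_scan(
            table, cl.affected_pool, cl.unaffected_pool,
            window=config.window, step=config.step, min_snps=config.min_snps)
        windows = zfst_transform(windows)
        regions = call_candidate_regions(
            windows, z_threshold=config.z_threshold,
            merge_gap=config.merge_gap)
        logger.info("cross %d: %d windows, %d candidate regions",
                    idx, len(windows), len(regions))
        save(windows, f"windows_cross{idx}.tsv")
        save(rio.windows_to_bed(windows), f"windows_cross{idx}.bed")
        save(regions, f"regions_cross{idx}.tsv")
        for _, r in regions.iterrows():
            region_objs.append(Region(r["chrom"], int(r["start"]),
                                      int(r["end"])))
    candidate_regions = _merge_regions(region_objs) if region_objs else []
    logger.info("union: %d candidate regions, total %.2f Mb",
                len(candidate_regions),
                sum(r.length for r in candidate_regions) / 1e6)

    summary: dict = {
        "seed": config.sim.seed,
        "n_sites": table.n_sites,
        "n_candidate_regions": len(candidate_regions),
        "candidate_regions": [
            dataclasses.asdict(r) for r in candidate_regions],
        "causal_gene_true": ds.gene_truth.causal_gene,
        "causal_variant_true": list(ds.gene_truth.causal_variant),
    }

    if not candidate_regions:
        summary.update({
            "n_candidate_mutations": 0, "n_target_mutations": 0,
            "target_regions": [], "target_region_span_mb": 0.0,
            "n_degs": 0, "candidate_genes": [],
        })
        if out_dir is not None:
            (out_dir / "summary.json").write_text(
                json.dumps(summary, indent=2))
        return summary

    # --- candidate mutation filter --------------------------------------
    logger.info("=== stage: filter ===")
    in_any_region = np.zeros(table.n_sites, dtype=bool)
    s = table.sites
    for r in candidate_regions:
        in_any_region |= ((s["chrom"] == r.chrom) & (s["pos"] >= r.start)
                          & (s["pos"] <= r.end)).to_numpy()
    region_table = table.subset_mask(in_any_region)
    rec1 = candidate_mutation_filter(region_table, ds.cross1_libs,
                                     daf_min=config.daf_min)
    rec2 = candidate_mutation_filter(region_table, ds.cross2_libs,
                                     daf_min=config.daf_min)
    shared = intersect_crosses(rec1, rec2)
    logger.info("candidate mutations: cross1 %d, cross2 %d, shared %d",
                int(rec1["retained"].sum()), int(rec2["retained"].sum()),
                len(shared))
    save(rec1, "candidates_cross1.tsv")
    save(rec2, "candidates_cross2.tsv")
    save(shared, "candidates_shared.tsv")
    summary["n_candidate_mutations"] = len(shared)

    # --- IBD screen ------------------------------------------------------
    logger.info("=== stage: ibd ===")
    affected_pools = ["Pool_CE1", "Pool_CE2"]
    individuals = [lib for lib, m in ds.library_meta.items()
                   if m.role is Role.INDIVIDUAL and m.farm != "reference"]
    kinds = ds.kinds
    retained_per_region: dict[int, list[str]] = {}
    for ridx, region in enumerate(candidate_regions):
        dmat = distance_matrix(
            table, affected_pools + individuals, region, kinds,
            min_sites=config.min_sites)
        retained = retain_samples(dmat, affected_pools, d_max=config.d_max)
        retained_per_region[ridx] = retained
        logger.info("region %d (%s:%d-%d): retained %d/%d outside samples",
                    ridx, region.chrom, region.start, region.end,
                    len(retained) - len(affected_pools), len(individuals))
        if out_dir is not None:
            dmat.d.to_csv(out_dir / f"distances_region{ridx}.tsv", sep="\t")
    target_mutations, target_regions = screen_target_mutations(
        shared, table, retained_per_region, candidate_regions,
        affected_pools, kinds)
    span_mb = float(sum(
        region_span_mb(int(r["start"]), int(r["end"]))
        for _, r in target_regions.iterrows()))
    logger.info("target mutations: %d in %d target regions (%.1f Mb)",
                len(target_mutations), len(target_regions), span_mb)
    save(target_mutations, "target_mutations.tsv")
    save(target_regions, "target_regions.tsv")
    summary["n_target_mutations"] = len(target_mutations)
    summary["target_regions"] = target_regions.to_dict("records")
    summary["target_region_span_mb"] = round(span_mb, 1)
    summary["retained_per_region"] = {
        str(k): v for k, v in retained_per_region.items()}

    # --- effects ---------------------------------------------------------
    logger.info("=== stage: effects ===")
    if len(target_mutations):
        effects = annotate_variants(
            target_mutations[["chrom", "pos", "ref", "alt"]], ds.gene_models)
    else:
        effects = pd.DataFrame(columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "category",
            "protein_change", "truncated_length", "distance"])
    functional = effects.loc[effects["category"].isin(FUNCTIONAL_CATEGORIES)]
    logger.info("functional mutations: %d (of %d annotated)",
                len(functional), len(effects))
    save(effects, "effects.tsv")

    # --- DEG -------------------------------------------------------------
    logger.info("=== stage: deg ===")
    deg = de_test(ds.expression_counts, ds.expression_groups)
    n_deg = int((deg["direction"] != "ns").sum())
    logger.info("DEGs: %d of %d genes", n_deg, len(deg))
    if out_dir is not None:
        deg.to_csv(out_dir / "deg.tsv", sep="\t")
    summary["n_degs"] = n_deg

    # --- prioritize ------------------------------------------------------
    logger.info("=== stage: prioritize ===")
    target_gene_ids = sorted({
        m.gene_id for m in ds.gene_models
        for _, tr in target_regions.iterrows()
        if m.chrom == tr["chrom"] and m.span_start <= int(tr["end"])
        and m.span_end >= int(tr["start"])
    })
    ref_libs = [lib for lib, m in ds.library_meta.items()
                if m.farm == "reference"]
    if len(functional) and ref_libs:
        from .variant_filter import classify_genotype, GenotypeThresholds

        rows = []
        thr = GenotypeThresholds(min_depth=4)
        for _, mut in functional.iterrows():
            si = table.site_index(mut["chrom"], int(mut["pos"]))
            row = {"chrom": mut["chrom"], "pos": int(mut["pos"])}
            for lib in ref_libs:
                row[lib] = int(classify_genotype(
                    int(table.ref_counts(lib)[si]),
                    int(table.alt_counts(lib)[si]), thr))
            rows.append(row)
        ref_genotypes = pd.DataFrame(rows).drop_duplicates(["chrom", "pos"])
    else:
        ref_genotypes = None
    ranked = prioritize_candidates(
        target_gene_ids, deg, functional, ref_genotypes)
    final = ranked.loc[ranked["retained"], "gene_id"].tolist()
    logger.info("target genes: %d; final candidates: %s",
                len(target_gene_ids), final or "none")
    save(ranked, "prioritization.tsv")
    summary["target_genes"] = target_gene_ids
    summary["candidate_genes"] = final
    summary["recovered_causal_gene"] = (
        final == [ds.gene_truth.causal_gene])

    if out_dir is not None:
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
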