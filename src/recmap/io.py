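"""Readers and writers for the formats the pipeline speaks.

Native tables are 1-based inclusive TSV; ``.bed`` exports are standard
0-based half-open.  The sync dialect is Popoolation2's: chrom, pos, ref
base, then one ``A:T:C:G:N:del`` count column per library.  A leading
``#`` header line naming the libraries is written and honoured on input;
files without it get ``lib1..libN``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlleleCountTable
from .variant_effects import GeneModel

_BASES = ("A", "T", "C", "G")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# sync


def write_sync(table: AlleleCountTable, path) -> None:
    """Write an AlleleCountTable as a Popoolation2-style sync file."""
    libs = table.libraries
    sites = table.sites
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tREF\t" + "\t".join(libs) + "\n")
        ref_idx = sites["ref"].map(_BASE_INDEX).to_numpy()
        alt_idx = sites["alt"].map(_BASE_INDEX).to_numpy()
        per_lib = [table.counts[lib] for lib in libs]
        for i in range(table.n_sites):
            fields = [
                str(sites.at[i, "chrom"]),
                str(int(sites.at[i, "pos"])),
                str(sites.at[i, "ref"]),
            ]
            for arr in per_lib:
                counts = [0, 0, 0, 0, 0, 0]
                counts[int(ref_idx[i])] = int(arr[i, 0])
                counts[int(alt_idx[i])] += int(arr[i, 1])
                fields.append(":".join(str(c) for c in counts))
            fh.write("\t".join(fields) + "\n")


def read_sync(path) -> AlleleCountTable:
    """Read a sync file, reducing each site to two alleles.

    The alternate allele is the non-reference base with the highest total
    count across libraries; ``N`` and deletion reads are ignored (no-call
    depth).  Malformed lines raise with their line number.
    """
    libs: list[str] | None = None
    chroms, positions, refs, alts = [], [], [], []
    rows: list[list[tuple[int, int]]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                if len(header) > 3:
                    libs = header[3:]
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{line_no}: expected at least 4 columns, got "
                    f"{len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            if ref not in _BASE_INDEX:
                raise ValueError(f"{path}:{line_no}: bad reference base {ref!r}")
            lib_counts = []
            totals = np.zeros(4, dtype=np.int64)
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}:{line_no}: expected 6 colon-separated "
                        f"counts, got {len(parts)} in {col!r}"
                    )
                try:
                    nums = [int(x) for x in parts]
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{line_no}: non-integer count in {col!r}"
                    ) from exc
                lib_counts.append(nums)
                totals += np.array(nums[:4])
            if libs is not None and len(lib_counts) != len(libs):
                raise ValueError(
                    f"{path}:{line_no}: {len(lib_counts)} libraries but "
                    f"header names {len(libs)}"
                )
            ref_i = _BASE_INDEX[ref]
            non_ref = [i for i in range(4) if i != ref_i]
            alt_i = max(non_ref, key=lambda i: totals[i])
            chroms.append(chrom)
            positions.append(int(pos_s))
            refs.append(ref)
            alts.append(_BASES[alt_i])
            rows.append([(nums[ref_i], nums[alt_i]) for nums in lib_counts])
    if not rows:
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        return AlleleCountTable(sites, {})
    n_libs = len(rows[0])
    libs = libs or [f"lib{i + 1}" for i in range(n_libs)]
    counts = {
        lib: np.array([row[i] for row in rows], dtype=np.int64)
        for i, lib in enumerate(libs)
    }
    sites = pd.DataFrame({
        "chrom": chroms, "pos": np.array(positions, dtype=np.int64),
        "ref": refs, "alt": alts,
    })
    return AlleleCountTable(sites, counts)


# ---------------------------------------------------------------------------
# VCF-lite (v4.2 subset, GT:AD)

_GT_STRING = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_GT_CODE = {v: k for k, v in _GT_STRING.items()}
_GT_CODE.update({"0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".": -1})


def write_vcf(
    table: AlleleCountTable, path, libraries: list[str] | None = None,
    genotypes: pd.DataFrame | None = None,
) -> None:
    """Write sites with per-library GT:AD.

    ``genotypes`` optionally carries genotype-class codes per library
    column; missing libraries get ``./.`` with their AD counts.
    """
    libs = libraries or table.libraries
    sites = table.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        for chrom in sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(libs) + "\n")
        for i in range(table.n_sites):
            fields = [
                str(sites.at[i, "chrom"]), str(int(sites.at[i, "pos"])),
                ".", str(sites.at[i, "ref"]), str(sites.at[i, "alt"]),
                ".", "PASS", ".", "GT:AD",
            ]
            for lib in libs:
                ref_n, alt_n = (int(x) for x in table.counts[lib][i])
                if genotypes is not None and lib in genotypes.columns:
                    gt = _GT_STRING[int(genotypes[lib].iloc[i])]
                else:
                    gt = "./."
                fields.append(f"{gt}:{ref_n},{alt_n}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[AlleleCountTable, pd.DataFrame]:
    """Read a GT:AD VCF back into counts and genotype-class codes."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    libs = list(vcf.samples)
    chroms, positions, refs, alts = [], [], [], []
    ad_rows, gt_rows = [], []
    for variant in vcf:
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0] if variant.ALT else ".")
        ad = variant.format("AD")
        ad_rows.append([(int(a[0]), int(a[1])) for a in ad])
        codes = []
        for gt in variant.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                codes.append(-1)
            else:
                codes.append(int(sum(alleles)))
        gt_rows.append(codes)
    vcf.close()
    sites = pd.DataFrame({
        "chrom": chroms, "pos": np.array(positions, dtype=np.int64),
        "ref": refs, "alt": alts,
    })
    counts = {
        lib: np.array([row[i] for row in ad_rows], dtype=np.int64)
        for i, lib in enumerate(libs)
    }
    genotypes = pd.DataFrame(
        {lib: [row[i] for row in gt_rows] for i, lib in enumerate(libs)}
    )
    return AlleleCountTable(sites, counts), genotypes


# ---------------------------------------------------------------------------
# Gene models: GFF3 + FASTA


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            fh.write("\t".join([
                m.chrom, "recmap", "gene", str(m.span_start),
                str(m.span_end), ".", m.strand, ".", attrs]) + "\n")
            mrna = f"{m.gene_id}.t1"
            fh.write("\t".join([
                m.chrom, "recmap", "mRNA", str(m.span_start),
                str(m.span_end), ".", m.strand, ".",
                f"ID={mrna};Parent={m.gene_id}"]) + "\n")
            for j, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join([
                    m.chrom, "recmap", "exon", str(s), str(e), ".",
                    m.strand, ".",
                    f"ID={mrna}.exon{j};Parent={mrna}"]) + "\n")
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs <= ce:
                    fh.write("\t".join([
                        m.chrom, "recmap", "CDS", str(cs), str(ce), ".",
                        m.strand, "0",
                        f"ID={mrna}.cds{j};Parent={mrna}"]) + "\n")


def write_gene_fasta(models: list[GeneModel], path) -> None:
    """Forward-strand gene-span sequences, one record per gene.

    Record headers carry the span so the sequences can be re-anchored:
    ``>gene_id chrom:start-end``.
    """
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.gene_id} {m.chrom}:{m.span_start}-{m.span_end}\n")
            for i in range(0, len(m.seq), 80):
                fh.write(m.seq[i:i + 80] + "\n")


def read_gene_models(gff_path, fasta_path) -> list[GeneModel]:
    """Rebuild gene models from GFF3 + FASTA.

    FASTA records may be whole chromosomes (ids matching the GFF3 seqid) or
    gene spans written by :func:`write_gene_fasta` (ids matching gene ids).
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True)
    fasta = Fasta(str(fasta_path), as_raw=True)
    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end)
                     for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end)
                   for f in db.children(mrna, featuretype="CDS")]
            break
        if not exons:
            exons = [(gene.start, gene.end)]
        exons = sorted(exons)
        span_start, span_end = exons[0][0], exons[-1][1]
        if gene_id in fasta:
            seq = str(fasta[gene_id][:])
            if len(seq) != span_end - span_start + 1:
                raise ValueError(
                    f"{gene_id}: FASTA record length {len(seq)} does not "
                    "match gene span")
        elif gene.seqid in fasta:
            seq = str(fasta[gene.seqid][span_start - 1:span_end])
        else:
            raise KeyError(
                f"no FASTA record for gene {gene_id} or contig {gene.seqid}")
        cds_start = min(s for s, _ in cds) if cds else span_start
        cds_end = max(e for _, e in cds) if cds else span_end
        models.append(GeneModel(
            gene_id=gene_id, chrom=gene.seqid, strand=gene.strand,
            exons=exons, cds_start=cds_start, cds_end=cds_end, seq=seq,
        ))
    return models


# ---------------------------------------------------------------------------
# Misc tables


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return pd.Series(df["group"].to_numpy(), index=df["sample"])


def windows_to_bed(windows: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive windows -> 0-based half-open BED frame."""
    out = windows.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    return out


def bed_to_windows(bed: pd.DataFrame) -> pd.DataFrame:
    out = bed.copy()
    out["start"] = out["start"].astype(np.int64) + 1
    return out


def write_tsv(frame: pd.DataFrame, path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", index=False, **kwargs)


# ---------------------------------------------------------------------------
# Config JSON


def config_to_json(config, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=list)


def sim_config_from_json(path):
    from .synthetic_data import SimConfig

    with open(path) as fh:
        raw = json.load(fh)
    for key in ("farms", "farms_sharing_ibd"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
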