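"""Genotype-class calling and segregation-pattern candidate filters.

A causal recessive variant segregating in an intercross of heterozygous
parents leaves a fingerprint across the mapping libraries: heterozygous in
both parents, intermediate frequency in the unaffected pool, fixed (for
either allele, depending on whether the mutation is causal or an inhibitor)
in the affected pool, and a large allele-frequency difference (dAF) between
the pools.  The filters here codify that fingerprint.

Pools have no diploid genotype; "heterozygous" for a pool means an
intermediate alternate-read fraction, judged with the same band used for
individual heterozygote calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlleleCountTable,
    CrossLibraries,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_LABELS,
    GT_NO_CALL,
)


@dataclass(frozen=True)
class GenotypeThresholds:
    """Read-fraction bands for hard genotype classification.

    With f the alternate read fraction: ``hom_ref`` if f <= t_low,
    ``hom_alt`` if f >= t_high, ``het`` if t_het_lo <= f <= t_het_hi,
    otherwise ``no_call``; sites below ``min_depth`` reads are ``no_call``.
    """

    t_low: float = 0.05
    t_het_lo: float = 0.20
    t_het_hi: float = 0.80
    t_high: float = 0.95
    min_depth: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.t_low < self.t_het_lo <= self.t_het_hi
                < self.t_high <= 1):
            raise ValueError(
                "inconsistent thresholds: require "
                "0 <= t_low < t_het_lo <= t_het_hi < t_high <= 1, got "
                f"{(self.t_low, self.t_het_lo, self.t_het_hi, self.t_high)}"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


#: Defaults for pools and parents (>= ~10x coverage).
POOL_THRESHOLDS = GenotypeThresholds(min_depth=4)
#: Defaults for low-coverage (~4x) individually sequenced fish.
INDIVIDUAL_THRESHOLDS = GenotypeThresholds(min_depth=2)


def classify_genotype(
    ref_count, alt_count, thresholds: GenotypeThresholds = POOL_THRESHOLDS
):
    """Classify sites into genotype classes from read counts.

    Vectorized; returns int codes (see :mod:`recmap.core`).  Scalars in,
    scalar out.
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    out = np.full(np.shape(depth), GT_NO_CALL, dtype=np.int8)
    ok = depth >= thresholds.min_depth
    out = np.where(ok & (f <= thresholds.t_low), GT_HOM_REF, out)
    out = np.where(ok & (f >= thresholds.t_high), GT_HOM_ALT, out)
    out = np.where(
        ok & (f >= thresholds.t_het_lo) & (f <= thresholds.t_het_hi),
        GT_HET, out,
    )
    if out.ndim == 0:
        return int(out)
    return out


def genotype_table(
    table: AlleleCountTable,
    thresholds_by_lib: dict[str, GenotypeThresholds] | None = None,
    default: GenotypeThresholds = POOL_THRESHOLDS,
) -> pd.DataFrame:
    """Genotype-class codes for every library in ``table``."""
    cols = {}
    for lib in table.libraries:
        thr = (thresholds_by_lib or {}).get(lib, default)
        cols[lib] = classify_genotype(
            table.ref_counts(lib), table.alt_counts(lib), thr
        )
    out = table.sites[["chrom", "pos", "ref", "alt"]].copy()
    for lib, codes in cols.items():
        out[lib] = codes
    return out


def candidate_mutation_filter(
    table: AlleleCountTable,
    cross: CrossLibraries,
    daf_min: float = 0.5,
    thresholds: GenotypeThresholds = POOL_THRESHOLDS,
    min_depth: int = 4,
) -> pd.DataFrame:
    """Variants matching the recessive segregation fingerprint of one cross.

    Retains variants with dAF > ``daf_min`` that are heterozygous in both
    parents and in the unaffected pool, and homozygous (either allele) in
    the affected pool.  Both fixation directions are kept because they
    encode the two cross hypotheses (causal recessive vs dominant
    inhibitor).  A ``no_call`` in any required library rejects the variant:
    the manual BAM-review rescue used on real data is deliberately not
    automated.

    Returns a DataFrame keyed by ``chrom, pos, ref, alt`` with per-library
    classes, the pool frequencies, ``daf`` and a boolean ``retained``.
    """
    needed = cross.all_libs()
    for lib in needed:
        if lib not in table.counts:
            raise KeyError(f"library {lib!r} missing from count table")

    out = table.sites[["chrom", "pos", "ref", "alt"]].copy()
    for lib in needed:
        out[f"class_{lib}"] = classify_genotype(
            table.ref_counts(lib), table.alt_counts(lib), thresholds
        )
    f_aff = table.alt_freq(cross.affected_pool, min_depth=min_depth)
    f_unaff = table.alt_freq(cross.unaffected_pool, min_depth=min_depth)
    out["af_affected"] = f_aff
    out["af_unaffected"] = f_unaff
    out["daf"] = np.abs(f_aff - f_unaff)

    parent_het = np.logical_and.reduce(
        [out[f"class_{p}"].to_numpy() == GT_HET for p in cross.parents]
    )
    unaff_het = out[f"class_{cross.unaffected_pool}"].to_numpy() == GT_HET
    aff_class = out[f"class_{cross.affected_pool}"].to_numpy()
    aff_fixed = (aff_class == GT_HOM_ALT) | (aff_class == GT_HOM_REF)
    daf_ok = np.nan_to_num(out["daf"].to_numpy(), nan=-1.0) > daf_min
    out["retained"] = parent_het & unaff_het & aff_fixed & daf_ok
    return out


def intersect_crosses(
    records_cross1: pd.DataFrame, records_cross2: pd.DataFrame
) -> pd.DataFrame:
    """Variants retained by the candidate filter in both crosses.

    Input frames are outputs of :func:`candidate_mutation_filter`; rows are
    matched on ``(chrom, pos, ref, alt)``.  The result carries the cross-1
    columns plus ``daf_cross2``.
    """
    key = ["chrom", "pos", "ref", "alt"]
    r1 = records_cross1.loc[records_cross1["retained"]]
    r2 = records_cross2.loc[records_cross2["retained"], key + ["daf"]]
    merged = r1.merge(r2, on=key, how="inner", suffixes=("", "_cross2"))
    return merged.reset_index(drop=True)


def region_overlap_report(
    regions_a: pd.DataFrame, regions_b: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise overlaps between two candidate-region sets (1-based)."""
    rows = []
    for _, a in regions_a.iterrows():
        for _, b in regions_b.iterrows():
            if a["chrom"] != b["chrom"]:
                continue
            lo = max(int(a["start"]), int(b["start"]))
            hi = min(int(a["end"]), int(b["end"]))
            if lo <= hi:
                rows.append((a["chrom"], int(a["start"]), int(a["end"]),
                             int(b["start"]), int(b["end"]), hi - lo + 1))
    return pd.DataFrame(
        rows, columns=["chrom", "start_a", "end_a", "start_b", "end_b",
                       "overlap_bp"]
    )


def sv_pattern_filter(
    sv_genotypes: pd.DataFrame,
    parents: tuple[str, str, str],
    unaffected_pools: tuple[str, str],
    affected_pools: tuple[str, str],
) -> pd.DataFrame:
    """Filter structural variants on the seven mapping-population libraries.

    Retains SVs heterozygous in all three parents and both unaffected pools
    and homozygous (either direction) in both affected pools.  A ``no_call``
    in any of the seven libraries rejects the SV and sets the
    ``insufficient_evidence`` flag rather than retaining it.

    ``sv_genotypes`` must carry one row per SV with genotype-class codes in
    columns named by library.
    """
    libs = [*parents, *unaffected_pools, *affected_pools]
    missing = [lib for lib in libs if lib not in sv_genotypes.columns]
    if missing:
        raise KeyError(f"SV genotype table lacks libraries: {missing}")
    out = sv_genotypes.copy()
    het_ok = np.logical_and.reduce(
        [out[lib].to_numpy() == GT_HET for lib in (*parents, *unaffected_pools)]
    )
    hom_ok = np.logical_and.reduce(
        [np.isin(out[lib].to_numpy(), (GT_HOM_REF, GT_HOM_ALT))
         for lib in affected_pools]
    )
    any_no_call = np.logical_or.reduce(
        [out[lib].to_numpy() == GT_NO_CALL for lib in libs]
    )
    out["insufficient_evidence"] = any_no_call
    out["retained"] = het_ok & hom_ok & ~any_no_call
    return out


def classes_to_labels(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Human-readable copy of a genotype-class frame (codes -> labels)."""
    out = frame.copy()
    for col in columns:
        out[col] = out[col].map(GT_LABELS)
    return out
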