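"""Cross-population identity-by-descent screening of candidate regions.

Affected individuals from outside the mapping population only inform the
screen if they inherit the same causal haplotype.  Operationally, a sample
shares the haplotype in a region when its genetic distance to every affected
mapping pool is small; samples farther than ``d_max`` (default 0.1) from any
affected pool are excluded for that region.  Candidate variants that remain
fixed for the mutant allele in all retained affected libraries are "target
mutations", and regions holding at least one are "target regions".

The distance between two libraries over a region is the mean absolute
difference of their allele frequencies across sites callable in both:
pool frequencies are read fractions, individual frequencies are genotype
dosages / 2.  This frequency-based distance is a pseudometric and requires
no phasing, which is unreliable at the ~4x coverage of the outside
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlleleCountTable,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_NO_CALL,
    Region,
)
from .variant_filter import (
    GenotypeThresholds,
    INDIVIDUAL_THRESHOLDS,
    classify_genotype,
)

DEFAULT_D_MAX = 0.1
DEFAULT_MIN_SITES = 5


def _library_freq(
    table: AlleleCountTable,
    lib: str,
    kind: str,
    pool_min_depth: int = 4,
    ind_thresholds: GenotypeThresholds = INDIVIDUAL_THRESHOLDS,
) -> np.ndarray:
    """Per-site allele frequency for a library; NaN where not callable."""
    if kind == "pool":
        return table.alt_freq(lib, min_depth=pool_min_depth)
    codes = classify_genotype(
        table.ref_counts(lib), table.alt_counts(lib), ind_thresholds
    )
    dosage = np.select(
        [codes == GT_HOM_REF, codes == GT_HET, codes == GT_HOM_ALT],
        [0.0, 0.5, 1.0],
        default=np.nan,
    )
    return dosage


def region_distance(
    table: AlleleCountTable,
    lib_i: str,
    lib_j: str,
    region: Region,
    kinds: dict[str, str],
    min_sites: int = DEFAULT_MIN_SITES,
) -> tuple[float, int]:
    """Mean |AF_i - AF_j| over region sites callable in both libraries.

    ``kinds`` maps library id to ``"pool"`` or ``"individual"``.  Returns
    ``(distance, n_sites_used)``; the distance is NaN when fewer than
    ``min_sites`` shared callable sites exist.
    """
    sub = table.subset_region(region.chrom, region.start, region.end)
    fi = _library_freq(sub, lib_i, kinds.get(lib_i, "pool"))
    fj = _library_freq(sub, lib_j, kinds.get(lib_j, "pool"))
    both = np.isfinite(fi) & np.isfinite(fj)
    n = int(both.sum())
    if n < max(min_sites, 1):
        return float("nan"), n
    return float(np.mean(np.abs(fi[both] - fj[both]))), n


@dataclass
class DistanceMatrix:
    """Pairwise distances between libraries over one region."""

    region: Region
    libraries: list[str]
    d: pd.DataFrame
    n_sites_used: pd.DataFrame


def distance_matrix(
    table: AlleleCountTable,
    libraries: list[str],
    region: Region,
    kinds: dict[str, str],
    min_sites: int = DEFAULT_MIN_SITES,
) -> DistanceMatrix:
    """All pairwise region distances among ``libraries``."""
    sub = table.subset_region(region.chrom, region.start, region.end)
    freqs = {
        lib: _library_freq(sub, lib, kinds.get(lib, "pool"))
        for lib in libraries
    }
    k = len(libraries)
    d = np.zeros((k, k))
    n = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            fi, fj = freqs[libraries[i]], freqs[libraries[j]]
            both = np.isfinite(fi) & np.isfinite(fj)
            m = int(both.sum())
            n[i, j] = n[j, i] = m
            if m < max(min_sites, 1):
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = float(np.mean(np.abs(fi[both] - fj[both])))
    return DistanceMatrix(
        region=region,
        libraries=list(libraries),
        d=pd.DataFrame(d, index=libraries, columns=libraries),
        n_sites_used=pd.DataFrame(n, index=libraries, columns=libraries),
    )


def retain_samples(
    dmat: DistanceMatrix,
    reference_pools: list[str],
    d_max: float = DEFAULT_D_MAX,
) -> list[str]:
    """Libraries retained for a region under the distance rule.

    An outside individual is retained only if its distance to *every*
    reference affected pool is defined and <= ``d_max``; a distance larger
    than ``d_max`` to any reference pool excludes it, and so does an
    undefined distance (insufficient shared sites).  Reference pools are
    always retained.
    """
    for pool in reference_pools:
        if pool not in dmat.libraries:
            raise KeyError(f"reference pool {pool!r} absent from matrix")
    retained = list(reference_pools)
    for lib in dmat.libraries:
        if lib in reference_pools:
            continue
        dists = [dmat.d.loc[lib, pool] for pool in reference_pools]
        if all(np.isfinite(x) and x <= d_max for x in dists):
            retained.append(lib)
    return retained


def screen_target_mutations(
    candidates: pd.DataFrame,
    table: AlleleCountTable,
    retained_per_region: dict[int, list[str]],
    regions: list[Region],
    affected_pools: list[str],
    kinds: dict[str, str],
    min_contra_reads: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep candidate variants fixed in every retained affected library.

    ``candidates`` is a frame keyed by ``chrom, pos, ref, alt`` (typically
    the output of the cross intersection).  For each region, candidate
    variants inside it are tested for fixation of the mutant allele in the
    retained libraries for that region (the affected pools plus retained
    outside individuals).

    Fixation evidence is judged per library: a library contradicts fixation
    when it is classified ``hom_ref``, or classified ``het`` with at least
    ``min_contra_reads`` reads supporting the reference allele.  A single
    discordant read at the ~4x coverage of outside individuals is within
    sequencing-error expectation and does not veto; ``no_call`` libraries
    are non-informative.

    Returns ``(target_mutations, target_regions)``; target regions are the
    input regions with at least one surviving variant, with the merged span
    of their surviving variants and a gene-count hook column.
    """
    key = ["chrom", "pos", "ref", "alt"]
    kept_rows = []
    region_rows = []
    for ridx, region in enumerate(regions):
        retained = retained_per_region.get(ridx)
        if retained is None:
            retained = list(affected_pools)
        in_region = candidates.loc[
            (candidates["chrom"] == region.chrom)
            & (candidates["pos"] >= region.start)
            & (candidates["pos"] <= region.end)
        ]
        if in_region.empty:
            continue
        survivors = []
        for _, row in in_region.iterrows():
            try:
                si = table.site_index(row["chrom"], int(row["pos"]))
            except KeyError:
                continue
            fixed = True
            for lib in retained:
                ref_n = int(table.ref_counts(lib)[si])
                alt_n = int(table.alt_counts(lib)[si])
                thr = (INDIVIDUAL_THRESHOLDS
                       if kinds.get(lib, "pool") == "individual"
                       else GenotypeThresholds())
                code = classify_genotype(ref_n, alt_n, thr)
                if code == GT_HOM_ALT or code == GT_NO_CALL:
                    continue
                if code == GT_HOM_REF:
                    fixed = False
                elif code == GT_HET and ref_n >= min_contra_reads:
                    fixed = False
                if not fixed:
                    break
            if fixed:
                survivors.append(row)
        if survivors:
            surv = pd.DataFrame(survivors)
            surv["region_index"] = ridx
            kept_rows.append(surv)
            region_rows.append(
                (ridx, region.chrom, region.start, region.end,
                 int(surv["pos"].min()), int(surv["pos"].max()),
                 len(surv))
            )
    if kept_rows:
        target_mutations = pd.concat(kept_rows, ignore_index=True)
    else:
        target_mutations = pd.DataFrame(columns=key + ["region_index"])
    target_regions = pd.DataFrame(
        region_rows,
        columns=["region_index", "chrom", "start", "end",
                 "span_start", "span_end", "n_target_mutations"],
    )
    return target_mutations, target_regions


def region_span_mb(start: int, end: int) -> float:
    """Span of a 1-based inclusive interval in megabases."""
    if start < 1 or end < 1:
        raise ValueError("coordinates are 1-based; must be >= 1")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return (end - start + 1) / 1_000_000
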