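"""Shared containers for pooled-mapping data.

All genomic coordinates in this package are 1-based inclusive.  BED export
(0-based half-open) is handled by :mod:`recmap.io` converters only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class Role(str, Enum):
    """What a sequencing library represents in the mapping design."""

    PARENT = "parent"
    AFFECTED_POOL = "affected_pool"
    UNAFFECTED_POOL = "unaffected_pool"
    INDIVIDUAL = "individual"


# Genotype classes are encoded as small ints so tables of calls stay compact.
GT_NO_CALL = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

GT_LABELS = {
    GT_NO_CALL: "no_call",
    GT_HOM_REF: "hom_ref",
    GT_HET: "het",
    GT_HOM_ALT: "hom_alt",
}


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one sequencing library.

    Parameters
    ----------
    lib_id:
        Library name as it appears in count tables (e.g. ``"Pool_CE1"``).
    role:
        Position of the library in the cross design.
    cross:
        1-based cross index for pools/parents belonging to a mapping cross,
        ``None`` for outside individuals.
    pool_size:
        Number of diploid individuals contributing DNA; 1 for individually
        sequenced fish and parents.
    farm:
        Source farm label for outside individuals.
    """

    lib_id: str
    role: Role
    cross: int | None = None
    pool_size: int = 1
    farm: str | None = None


class AlleleCountTable:
    """Per-site, per-library reference/alternate read counts.

    This is the in-memory equivalent of a Popoolation2 sync file reduced to
    two alleles per site.  ``sites`` is a DataFrame with columns
    ``chrom, pos, ref, alt`` (positions strictly increasing within each
    chromosome); ``counts`` maps a library id to an ``(n_sites, 2)`` integer
    array of ``[ref_count, alt_count]``.
    """

    def __init__(self, sites: pd.DataFrame, counts: dict[str, np.ndarray]):
        required = {"chrom", "pos", "ref", "alt"}
        missing = required - set(sites.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        sites = sites.reset_index(drop=True)
        for chrom, grp in sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )
        n = len(sites)
        clean: dict[str, np.ndarray] = {}
        for lib, arr in counts.items():
            arr = np.asarray(arr)
            if arr.shape != (n, 2):
                raise ValueError(
                    f"library {lib!r}: expected counts of shape ({n}, 2), "
                    f"got {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"library {lib!r}: negative read counts")
            clean[lib] = arr.astype(np.int64)
        self.sites = sites
        self.counts = clean

    # -- basic accessors ---------------------------------------------------

    @property
    def libraries(self) -> list[str]:
        return list(self.counts)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_sites

    def ref_counts(self, lib: str) -> np.ndarray:
        return self.counts[lib][:, 0]

    def alt_counts(self, lib: str) -> np.ndarray:
        return self.counts[lib][:, 1]

    def depth(self, lib: str) -> np.ndarray:
        return self.counts[lib].sum(axis=1)

    def alt_freq(self, lib: str, min_depth: int = 1) -> np.ndarray:
        """Alternate-allele read fraction; NaN where depth < ``min_depth``."""
        c = self.counts[lib]
        d = c.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = c[:, 1] / d
        f = np.where(d >= max(min_depth, 1), f, np.nan)
        return f

    # -- subsetting --------------------------------------------------------

    def subset_mask(self, mask: np.ndarray) -> "AlleleCountTable":
        mask = np.asarray(mask, dtype=bool)
        sites = self.sites.loc[mask].reset_index(drop=True)
        counts = {lib: arr[mask] for lib, arr in self.counts.items()}
        return AlleleCountTable(sites, counts)

    def subset_region(self, chrom: str, start: int, end: int) -> "AlleleCountTable":
        """Sites with ``pos`` in ``[start, end]`` on ``chrom`` (inclusive)."""
        s = self.sites
        mask = (s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] <= end)
        return self.subset_mask(mask.to_numpy())

    def site_index(self, chrom: str, pos: int) -> int:
        s = self.sites
        hit = np.flatnonzero((s["chrom"] == chrom) & (s["pos"] == pos))
        if hit.size != 1:
            raise KeyError(f"site {chrom}:{pos} not found")
        return int(hit[0])

    def equals(self, other: "AlleleCountTable") -> bool:
        if set(self.counts) != set(other.counts):
            return False
        if not self.sites.equals(other.sites):
            return False
        return all(
            np.array_equal(self.counts[lib], other.counts[lib])
            for lib in self.counts
        )


@dataclass
class CrossLibraries:
    """The four libraries defining one mapping cross."""

    parents: tuple[str, str]
    affected_pool: str
    unaffected_pool: str

    def all_libs(self) -> list[str]:
        return [*self.parents, self.affected_pool, self.unaffected_pool]


@dataclass
class Region:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("regions are 1-based; start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
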