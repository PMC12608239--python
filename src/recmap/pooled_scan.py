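"""Sliding-window F_ST scan between two offspring pools.

Per-site differentiation between the affected and unaffected pools is
measured with the classical heterozygosity-based fixation index

    F_ST = (pi_total - pi_within) / pi_total

with H(p) = 2p(1-p), pi_within = (H(p1) + H(p2))/2 and
pi_total = H((p1+p2)/2).  Window values (mean of per-site F_ST) are
Z-standardized over all windows with a defined value, and windows whose
ZF_ST exceeds a threshold are merged into candidate regions.

The estimator carries no pool-size or finite-depth correction by default:
the scan consumes only the ordering of windows and any consistent estimator
preserves it at the allele-frequency differences a recessive intercross
produces.  An optional depth/(depth-1) correction on the heterozygosities is
available via :func:`site_fst`'s callers for users who want it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AlleleCountTable, Region

DEFAULT_WINDOW = 50_000
DEFAULT_STEP = 10_000
DEFAULT_Z_THRESHOLD = 11.0


def pool_allele_freq(
    ref_count, alt_count, min_depth: int = 4
):
    """Alternate-allele read fraction, NaN when depth < ``min_depth``.

    Accepts scalars or arrays.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / depth
    f = np.where(depth >= max(min_depth, 1), f, np.nan)
    if f.ndim == 0:
        return float(f)
    return f


def site_fst(p1, p2, clamp: bool = True):
    """Per-site F_ST from two allele frequencies.

    Vectorized; NaN inputs propagate.  Sites monomorphic in the pooled sample
    (``pi_total == 0``) have F_ST 0.  Values are clamped to [0, 1]; the raw
    estimator can go slightly negative through rounding, never above 1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    finite1 = p1[np.isfinite(p1)]
    finite2 = p2[np.isfinite(p2)]
    if np.any((finite1 < 0) | (finite1 > 1)) or np.any((finite2 < 0) | (finite2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    h1 = 2 * p1 * (1 - p1)
    h2 = 2 * p2 * (1 - p2)
    pbar = (p1 + p2) / 2
    pi_total = 2 * pbar * (1 - pbar)
    pi_within = (h1 + h2) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (pi_total - pi_within) / pi_total
    fst = np.where(pi_total > 0, fst, 0.0)
    fst = np.where(np.isfinite(p1) & np.isfinite(p2), fst, np.nan)
    if clamp:
        fst = np.clip(fst, 0.0, 1.0)
    if fst.ndim == 0:
        return float(fst)
    return fst


def window_starts(chrom_length: int, window: int, step: int) -> np.ndarray:
    """1-based start positions of full windows anchored at position 1.

    Windows are [start, start + window - 1]; only windows fitting entirely
    on the chromosome are produced, so a 100 kb chromosome scanned with a
    50 kb window and 10 kb step yields starts 1, 10 001, ..., 50 001
    (six windows).  A chromosome shorter than one window yields a single
    truncated window spanning the whole chromosome.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    if step <= 0:
        raise ValueError("step size must be positive")
    if chrom_length < window:
        return np.array([1], dtype=np.int64)
    n = (chrom_length - window) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64)


def window_scan(
    table: AlleleCountTable,
    pool_a: str,
    pool_b: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_snps: int = 3,
    min_depth: int = 4,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean per-site F_ST in sliding windows along each chromosome.

    Returns a DataFrame with columns ``chrom, start, end, n_snps, fst``.
    ``n_snps`` counts sites with callable frequencies in both pools;
    windows with fewer than ``min_snps`` such sites have ``fst`` NaN.
    Chromosome lengths default to the last site position per chromosome.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    sites = table.sites
    if len(sites) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snps", "fst"]
        ).astype({"start": np.int64, "end": np.int64, "n_snps": np.int64,
                  "fst": float})

    fa = table.alt_freq(pool_a, min_depth=min_depth)
    fb = table.alt_freq(pool_b, min_depth=min_depth)
    fst = site_fst(fa, fb)
    callable_mask = np.isfinite(fst)

    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        chrom_fst = np.asarray(fst)[idx]
        chrom_call = callable_mask[idx]
        length = (chrom_lengths or {}).get(chrom, int(pos[-1]))
        for start in window_starts(length, window, step):
            end = min(start + window - 1, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            sel = slice(lo, hi)
            n_call = int(chrom_call[sel].sum())
            if n_call >= max(min_snps, 1):
                value = float(np.nanmean(chrom_fst[sel]))
            else:
                value = np.nan
            rows.append((chrom, int(start), int(end), n_call, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])


def zfst_transform(windows: pd.DataFrame) -> pd.DataFrame:
    """Add a genome-wide Z-score column ``zfst``.

    Standardization uses the mean and sample (n-1) standard deviation over
    every window with a defined ``fst``, across all chromosomes.  Windows
    without a defined ``fst`` keep NaN.
    """
    values = windows["fst"].to_numpy(dtype=float)
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError("Z-transformation needs at least two windows with "
                         "a defined F_ST")
    mean = values[defined].mean()
    sd = values[defined].std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate scan: all window F_ST values identical")
    out = windows.copy()
    out["zfst"] = (values - mean) / sd
    return out


def call_candidate_regions(
    windows: pd.DataFrame,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Merge above-threshold windows into candidate regions.

    A window qualifies when ``zfst > z_threshold``.  Qualifying windows on
    the same chromosome whose spans overlap, abut, or are separated by at
    most ``merge_gap`` bp are merged.  Returns a DataFrame with columns
    ``chrom, start, end, peak_zfst, n_windows``.
    """
    cols = ["chrom", "start", "end", "peak_zfst", "n_windows"]
    z = windows["zfst"].to_numpy(dtype=float)
    qual = windows.loc[np.isfinite(z) & (z > z_threshold)]
    if qual.empty:
        return pd.DataFrame(columns=cols).astype(
            {"start": np.int64, "end": np.int64, "n_windows": np.int64,
             "peak_zfst": float})
    rows = []
    for chrom, grp in qual.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_peak = -np.inf
        cur_n = 0
        for _, w in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = int(w["start"]), int(w["end"])
                cur_peak, cur_n = float(w["zfst"]), 1
            elif int(w["start"]) <= cur_end + merge_gap + 1:
                cur_end = max(cur_end, int(w["end"]))
                cur_peak = max(cur_peak, float(w["zfst"]))
                cur_n += 1
            else:
                rows.append((chrom, cur_start, cur_end, cur_peak, cur_n))
                cur_start, cur_end = int(w["start"]), int(w["end"])
                cur_peak, cur_n = float(w["zfst"]), 1
        rows.append((chrom, cur_start, cur_end, cur_peak, cur_n))
    return pd.DataFrame(rows, columns=cols)


def regions_from_frame(regions: pd.DataFrame) -> list[Region]:
    return [Region(r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in regions.iterrows()]
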