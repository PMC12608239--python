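"""Differential expression, over-representation, and candidate prioritization.

The DE test is a negative-binomial Wald test on median-of-ratios-normalized
counts with method-of-moments dispersion, in the spirit of the classical
count-based DE tools.  With three samples per group it is a screening test:
acceptance of the surrounding pipeline rests on simulation calibration
(type-I control and power), not on concordance with any specific published
gene list.

DEG thresholds follow the usual convention: |log2 fold change| > 1 and
Benjamini-Hochberg adjusted p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GT_HET, GT_HOM_ALT
from .variant_effects import FUNCTIONAL_CATEGORIES, SEVERITY_RANK

LFC_THRESHOLD = 1.0
PADJ_THRESHOLD = 0.05
_PSEUDOCOUNT = 0.5
_MIN_DISPERSION = 0.01


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    For each gene with nonzero counts in every sample, the ratio of each
    sample's count to the gene's geometric mean is formed; a sample's factor
    is the median of its ratios.  Raises when no gene is nonzero everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "normalization is undefined (filter samples or use another "
            "normalization)"
        )
    sub = mat[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_arrays(counts: pd.DataFrame, groups: pd.Series):
    labels = set(groups)
    if labels != {"affected", "unaffected"}:
        raise ValueError(
            f"groups must be 'affected'/'unaffected', got {sorted(labels)}"
        )
    aff = [c for c in counts.columns if groups[c] == "affected"]
    unaff = [c for c in counts.columns if groups[c] == "unaffected"]
    if len(aff) < 2 or len(unaff) < 2:
        raise ValueError("each group needs at least two samples")
    return aff, unaff


def de_test(counts: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-gene DE test, affected vs unaffected.

    Parameters
    ----------
    counts:
        Genes x samples non-negative integer counts.
    groups:
        Mapping or Series from sample name to ``"affected"``/``"unaffected"``.

    Returns a DataFrame indexed by gene with ``base_mean, log2fc, p, padj,
    direction``; ``direction`` is ``up``/``down`` (in the affected group)
    when the gene passes the DEG thresholds, else ``ns``.  Genes with zero
    counts in all samples are flagged ``ns`` with NaN statistics rather than
    dropped.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) \
        else groups
    aff, unaff = _group_arrays(counts, groups)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")

    sf = size_factors(counts)
    norm = counts / sf

    a = norm[aff].to_numpy(dtype=float)
    u = norm[unaff].to_numpy(dtype=float)
    na, nu = a.shape[1], u.shape[1]
    mean_a = a.mean(axis=1)
    mean_u = u.mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)

    log2fc = np.log2(mean_a + _PSEUDOCOUNT) - np.log2(mean_u + _PSEUDOCOUNT)

    # Method-of-moments dispersion pooled across the two groups
    # (Var = mu + alpha * mu^2  =>  alpha = (s^2 - mu) / mu^2), then shared
    # across genes as the median of the per-gene estimates: with two or
    # three samples per group the per-gene estimate is far too noisy to use
    # directly, and a common dispersion is the standard small-n remedy.
    var_a = a.var(axis=1, ddof=1)
    var_u = u.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_a = (var_a - mean_a) / np.maximum(mean_a, 1e-8) ** 2
        alpha_u = (var_u - mean_u) / np.maximum(mean_u, 1e-8) ** 2
    alpha_mom = (alpha_a + alpha_u) / 2
    informative = np.isfinite(alpha_mom) & (mean_a + mean_u > 0)
    if informative.any():
        alpha_common = float(np.median(alpha_mom[informative]))
    else:
        alpha_common = _MIN_DISPERSION
    alpha = max(alpha_common, _MIN_DISPERSION)

    # Wald statistic on the log2 fold change via the delta method.
    var_mean_a = (mean_a + alpha * mean_a**2) / na
    var_mean_u = (mean_u + alpha * mean_u**2) / nu
    ln2sq = np.log(2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(
            var_mean_a / np.maximum(mean_a + _PSEUDOCOUNT, 1e-8) ** 2
            + var_mean_u / np.maximum(mean_u + _PSEUDOCOUNT, 1e-8) ** 2
        ) / np.log(2)
        z = log2fc / se
    p = 2 * stats.norm.sf(np.abs(z))

    all_zero = counts.to_numpy().sum(axis=1) == 0
    p = np.where(all_zero, np.nan, p)
    log2fc = np.where(all_zero, np.nan, log2fc)

    padj = np.full_like(p, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])

    direction = np.where(
        np.isfinite(padj) & (padj < PADJ_THRESHOLD)
        & (np.abs(log2fc) > LFC_THRESHOLD),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "direction": direction,
        },
        index=counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def ora_hypergeom(
    deg_set: set, gene_sets: dict[str, set], universe: set
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation across gene sets.

    For each set, P(X >= k) where k is the overlap between the DEG set and
    the gene set, drawing |DEG| genes from a universe of size N containing
    |set| successes.  BH adjustment across the supplied sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_set) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(deg & members)
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(members), len(deg))
        )
        rows.append((name, k, len(members), len(deg), len(universe), p))
    out = pd.DataFrame(
        rows, columns=["gene_set", "k", "set_size", "n_deg", "n_universe", "p"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["padj"] = []
    return out


def prioritize_candidates(
    target_genes: list[str],
    deg_table: pd.DataFrame,
    functional_mutations: pd.DataFrame,
    reference_genotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank candidate genes by coding evidence and expression change.

    A gene from the target regions is retained iff

    a. it is differentially expressed (``direction`` != ``ns``),
    b. it carries at least one functional candidate mutation
       (stopgain/stoploss/frameshift/nonframeshift/nonsynonymous), and
    c. no independent true-breeding unaffected reference sample is
       heterozygous or homozygous-mutant at any of the gene's functional
       mutations; ``no_call`` reference genotypes are non-informative and do
       not exclude.

    Parameters
    ----------
    target_genes:
        Gene ids overlapping the target regions.
    deg_table:
        Output of :func:`de_test`, indexed by gene.
    functional_mutations:
        Frame with ``gene_id, chrom, pos, ref, alt, category`` for candidate
        mutations annotated on the target genes.
    reference_genotypes:
        Frame with ``chrom, pos`` plus one genotype-class column per
        reference sample; optional.

    Returns the retained genes ranked by mutation severity (most severe
    category per gene) and then |log2fc| descending, with an ``excluded_by``
    column in the companion audit columns explaining rejected genes.
    """
    rows = []
    fm = functional_mutations
    for gene in sorted(set(target_genes)):
        reasons = []
        if gene not in deg_table.index or deg_table.loc[gene, "direction"] == "ns":
            reasons.append("not_differentially_expressed")
        muts = fm.loc[
            (fm["gene_id"] == gene)
            & (fm["category"].isin(FUNCTIONAL_CATEGORIES))
        ]
        if muts.empty:
            reasons.append("no_functional_mutation")
        ref_hit = False
        if reference_genotypes is not None and not muts.empty:
            for _, m in muts.iterrows():
                match = reference_genotypes.loc[
                    (reference_genotypes["chrom"] == m["chrom"])
                    & (reference_genotypes["pos"] == m["pos"])
                ]
                if match.empty:
                    continue
                calls = match.drop(columns=["chrom", "pos"]).to_numpy().ravel()
                if np.any((calls == GT_HET) | (calls == GT_HOM_ALT)):
                    ref_hit = True
        if ref_hit:
            reasons.append("mutant_allele_in_unaffected_reference")

        if muts.empty:
            severity = max(SEVERITY_RANK.values())
            best_cat = None
        else:
            best_cat = min(muts["category"], key=lambda c: SEVERITY_RANK[c])
            severity = SEVERITY_RANK[best_cat]
        lfc = (
            float(deg_table.loc[gene, "log2fc"])
            if gene in deg_table.index else np.nan
        )
        rows.append(
            (gene, len(reasons) == 0, ";".join(reasons) or None, best_cat,
             severity, lfc, len(muts))
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "retained", "excluded_by", "top_category",
                 "severity_rank", "log2fc", "n_functional_mutations"],
    )
    out["abs_lfc"] = out["log2fc"].abs()
    out = out.sort_values(
        ["retained", "severity_rank", "abs_lfc", "gene_id"],
        ascending=[False, True, False, True],
    ).drop(columns="abs_lfc").reset_index(drop=True)
    return out
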