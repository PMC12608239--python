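import math

import numpy as np
import pandas as pd
import pytest

from recmap.core import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_NO_CALL
from recmap.expression import (
    bh_adjust,
    de_test,
    ora_hypergeom,
    prioritize_candidates,
    size_factors,
)


def test_size_factors_identical_columns():
    m = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
    assert size_factors(m).to_numpy() == pytest.approx([1.0, 1.0])


def test_size_factors_doubled_column():
    base = np.array([5, 10, 20, 40, 80])
    m = pd.DataFrame({"s1": base, "s2": 2 * base})
    sf = size_factors(m).to_numpy()
    assert sf[1] / sf[0] == pytest.approx(2.0)
    # median of ratios to the geometric mean: (1/sqrt(2), sqrt(2))
    assert sf == pytest.approx([2 ** -0.5, 2 ** 0.5])


def test_size_factors_single_gene():
    m = pd.DataFrame({"s1": [4], "s2": [9]})
    sf = size_factors(m).to_numpy()
    assert sf == pytest.approx([4 / 6, 9 / 6])


def test_size_factors_requires_all_nonzero_gene():
    m = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
    with pytest.raises(ValueError, match="nonzero"):
        size_factors(m)


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_reference_implementation(rng):
    """Agrees with statsmodels' BH to 1e-12 on 1,000 random vectors."""
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        n = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, n)
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)
        # rank-monotone: sorting by p sorts the adjusted values
        order = np.argsort(p)
        assert (np.diff(ours[order]) >= -1e-12).all()


def test_ora_exact_combinatorial_oracle():
    # N=10, K=5, n=4, k=4: P = C(5,4)*C(5,0)/C(10,4) = 5/210
    universe = {f"g{i}" for i in range(10)}
    gene_set = {f"g{i}" for i in range(5)}
    deg = {f"g{i}" for i in range(4)}
    out = ora_hypergeom(deg, {"s": gene_set}, universe)
    assert out.iloc[0]["p"] == pytest.approx(5 / 210)


def test_ora_matches_enumeration(rng):
    """Upper-tail p equals explicit pmf summation for N <= 30."""
    for _ in range(200):
        N = int(rng.integers(2, 31))
        universe = {f"g{i}" for i in range(N)}
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        gene_set = set(list(universe)[:K])
        deg = set(rng.choice(sorted(universe), n, replace=False))
        k = len(deg & gene_set)
        out = ora_hypergeom(deg, {"s": gene_set}, universe)
        p_expected = sum(
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            for x in range(k, min(K, n) + 1)
        )
        assert out.iloc[0]["p"] == pytest.approx(p_expected, abs=1e-12)


def test_ora_degenerate_cases():
    universe = {f"g{i}" for i in range(10)}
    out = ora_hypergeom(set(), {"s": set(list(universe)[:2])}, universe)
    assert out.iloc[0]["p"] == pytest.approx(1.0)
    out = ora_hypergeom(universe, {"s": universe}, universe)
    assert out.iloc[0]["p"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ora_hypergeom(set(), {}, set())


def _matrix(rng, n_genes, mu, lfc=None, alpha=0.1, n=3):
    mu = np.full(n_genes, mu, dtype=float)
    mu_aff = mu * (2.0 ** (lfc if lfc is not None else 0.0))
    r = 1 / alpha
    cols = {}
    for i in range(n):
        cols[f"A{i}"] = rng.negative_binomial(r, r / (r + mu_aff), n_genes)
    for i in range(n):
        cols[f"U{i}"] = rng.negative_binomial(r, r / (r + mu), n_genes)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    groups = pd.Series({c: "affected" if c.startswith("A") else "unaffected"
                        for c in counts.columns})
    return counts, groups


def test_de_test_flat_gene_is_ns(rng):
    # identical columns: size factors are 1 and normalized counts are equal
    # in both groups, so every gene has log2FC exactly 0
    col = rng.poisson(200, 50) + 1
    counts = pd.DataFrame({s: col for s in
                           ("A0", "A1", "A2", "U0", "U1", "U2")},
                          index=[f"g{i}" for i in range(50)])
    groups = pd.Series({c: "affected" if c.startswith("A") else "unaffected"
                        for c in counts.columns})
    res = de_test(counts, groups)
    assert res["log2fc"].to_numpy() == pytest.approx(0.0)
    assert (res["direction"] == "ns").all()


def test_de_test_strong_signal_flagged(rng):
    counts, groups = _matrix(rng, 300, mu=500)
    sig, _ = _matrix(rng, 40, mu=500, lfc=3.0)
    sig.index = [f"s{i}" for i in range(40)]
    res = de_test(pd.concat([counts, sig]), groups)
    flagged = res.loc[[f"s{i}" for i in range(40)], "direction"]
    assert (flagged == "up").mean() >= 0.9


def test_de_test_input_contracts(rng):
    counts, groups = _matrix(rng, 20, mu=100)
    with pytest.raises(ValueError, match="two samples"):
        de_test(counts[["A0", "A1", "U0"]],
                groups[["A0", "A1", "U0"]])
    bad = groups.copy()
    bad[:] = "case"
    with pytest.raises(ValueError):
        de_test(counts, bad)


def test_de_test_all_zero_gene_flagged_not_dropped(rng):
    counts, groups = _matrix(rng, 30, mu=100)
    counts.iloc[3] = 0
    res = de_test(counts, groups)
    assert len(res) == 30
    assert res.iloc[3]["direction"] == "ns"
    assert np.isnan(res.iloc[3]["p"])


DEG = pd.DataFrame(
    {"log2fc": [-2.5, 1.8, -1.4, 2.0, 0.1],
     "p": [1e-8, 1e-6, 1e-4, 1e-5, 0.8],
     "padj": [1e-6, 1e-5, 1e-3, 1e-4, 0.9],
     "direction": ["down", "up", "down", "up", "ns"]},
    index=["geneA", "geneB", "geneC", "geneD", "geneE"],
)

FUNCTIONAL = pd.DataFrame({
    "gene_id": ["geneA", "geneB", "geneC", "geneD"],
    "chrom": ["chr1"] * 4,
    "pos": [100, 200, 300, 400],
    "ref": ["G"] * 4, "alt": ["A"] * 4,
    "category": ["stopgain", "nonsynonymous", "nonsynonymous",
                 "nonsynonymous"],
})


def test_prioritize_reproduces_reference_exclusion_logic():
    """Of four DE genes with coding mutations, the three whose mutant
    alleles appear in true-breeding unaffected references are excluded."""
    refs = pd.DataFrame({
        "chrom": ["chr1"] * 4, "pos": [100, 200, 300, 400],
        "r1": [GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_NO_CALL],
        "r2": [GT_HOM_REF, GT_HOM_REF, GT_HET, GT_HET],
        "r3": [GT_NO_CALL, GT_HOM_REF, GT_HOM_ALT, GT_HOM_REF],
    })
    out = prioritize_candidates(
        ["geneA", "geneB", "geneC", "geneD", "geneE"], DEG, FUNCTIONAL, refs)
    retained = out.loc[out["retained"], "gene_id"].tolist()
    assert retained == ["geneA"]
    reasons = dict(zip(out["gene_id"], out["excluded_by"]))
    assert "mutant_allele_in_unaffected_reference" in reasons["geneB"]
    assert "no_functional_mutation" in reasons["geneE"]


def test_prioritize_no_coverage_is_non_informative():
    refs = pd.DataFrame({
        "chrom": ["chr1"], "pos": [100],
        "r1": [GT_NO_CALL], "r2": [GT_NO_CALL], "r3": [GT_NO_CALL],
    })
    out = prioritize_candidates(["geneA"], DEG, FUNCTIONAL, refs)
    assert out.loc[out["gene_id"] == "geneA", "retained"].item()


def test_prioritize_requires_de_and_mutation():
    no_de = DEG.copy()
    no_de.loc["geneA", "direction"] = "ns"
    out = prioritize_candidates(["geneA"], no_de, FUNCTIONAL, None)
    assert not out["retained"].any()
    out2 = prioritize_candidates(["geneE"], DEG, FUNCTIONAL, None)
    assert not out2["retained"].any()


def test_prioritize_order_independent():
    a = prioritize_candidates(["geneA", "geneB", "geneC"], DEG,
                              FUNCTIONAL, None)
    b = prioritize_candidates(["geneC", "geneA", "geneB"], DEG,
                              FUNCTIONAL, None)
    pd.testing.assert_frame_equal(a, b)


def test_prioritize_ranks_severity_then_lfc():
    out = prioritize_candidates(["geneA", "geneB", "geneC", "geneD"],
                                DEG, FUNCTIONAL, None)
    assert out["gene_id"].tolist()[0] == "geneA"  # stopgain first
    rest = out["gene_id"].tolist()[1:]
    assert rest == ["geneD", "geneB", "geneC"]  # |lfc| descending
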