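import numpy as np
import pandas as pd
import pytest

from recmap.core import AlleleCountTable, Region
from recmap.ibd_screen import (
    DistanceMatrix,
    distance_matrix,
    region_distance,
    region_span_mb,
    retain_samples,
    screen_target_mutations,
)


def _pool_counts(freqs, depth=40):
    freqs = np.asarray(freqs, dtype=float)
    alt = np.round(freqs * depth).astype(np.int64)
    return np.column_stack([depth - alt, alt])


def _table(freq_by_lib, positions=None):
    n = len(next(iter(freq_by_lib.values())))
    positions = positions if positions is not None \
        else np.arange(1, n + 1) * 100
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.asarray(positions, dtype=np.int64),
                          "ref": "A", "alt": "T"})
    return AlleleCountTable(
        sites, {lib: _pool_counts(f) for lib, f in freq_by_lib.items()})


REGION = Region("chr1", 1, 10_000)


def test_region_distance_hand_example():
    t = _table({"i": [0.0, 0.5, 1.0], "j": [0.0, 1.0, 1.0]})
    kinds = {"i": "pool", "j": "pool"}
    d, n = region_distance(t, "i", "j", REGION, kinds, min_sites=1)
    assert n == 3
    assert d == pytest.approx(0.5 / 3)


def test_region_distance_identical_and_opposite():
    same = _table({"i": [0.2, 0.8, 0.5], "j": [0.2, 0.8, 0.5]})
    kinds = {"i": "pool", "j": "pool"}
    d, _ = region_distance(same, "i", "j", REGION, kinds, min_sites=1)
    assert d == pytest.approx(0.0)
    opp = _table({"i": [0.0, 1.0], "j": [1.0, 0.0]})
    d, _ = region_distance(opp, "i", "j", REGION, kinds, min_sites=1)
    assert d == pytest.approx(1.0)


def test_region_distance_min_sites():
    t = _table({"i": [0.1, 0.2], "j": [0.1, 0.2]})
    d, n = region_distance(t, "i", "j", REGION,
                           {"i": "pool", "j": "pool"}, min_sites=5)
    assert np.isnan(d) and n == 2


def test_distance_matrix_is_pseudometric(rng):
    """Symmetry, zero diagonal, and (empirically) triangle inequality."""
    libs = [f"L{i}" for i in range(5)]
    freqs = {lib: rng.uniform(0, 1, 40) for lib in libs}
    t = _table(freqs)
    kinds = {lib: "pool" for lib in libs}
    dm = distance_matrix(t, libs, Region("chr1", 1, 10_000), kinds,
                         min_sites=1)
    d = dm.d.to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    for i in range(5):
        for j in range(5):
            for k in range(5):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_retain_samples_rules():
    libs = ["CE1", "CE2", "ind1", "ind2", "ind3"]
    d = pd.DataFrame(np.zeros((5, 5)), index=libs, columns=libs)
    d.loc["ind1", "CE1"] = d.loc["CE1", "ind1"] = 0.05
    d.loc["ind1", "CE2"] = d.loc["CE2", "ind1"] = 0.08
    d.loc["ind2", "CE1"] = d.loc["CE1", "ind2"] = 0.05
    d.loc["ind2", "CE2"] = d.loc["CE2", "ind2"] = 0.12
    d.loc["ind3", "CE1"] = d.loc["CE1", "ind3"] = np.nan
    dm = DistanceMatrix(Region("chr1", 1, 100), libs, d,
                        pd.DataFrame(10, index=libs, columns=libs))
    retained = retain_samples(dm, ["CE1", "CE2"], d_max=0.1)
    # ind2 excluded: distance to one pool exceeds 0.1; ind3: undefined
    assert retained == ["CE1", "CE2", "ind1"]
    with pytest.raises(KeyError):
        retain_samples(dm, ["CE9"])


def test_retain_samples_shrinks_with_dmax():
    libs = ["CE1"] + [f"i{k}" for k in range(6)]
    vals = [0.0, 0.02, 0.05, 0.09, 0.12, 0.2, 0.4]
    d = pd.DataFrame(
        [[abs(a - b) for b in vals] for a in vals], index=libs, columns=libs)
    dm = DistanceMatrix(Region("chr1", 1, 100), libs, d,
                        pd.DataFrame(10, index=libs, columns=libs))
    sizes = [len(retain_samples(dm, ["CE1"], d_max=x))
             for x in (0.3, 0.1, 0.05, 0.01)]
    assert sizes == sorted(sizes, reverse=True)


def test_screen_target_mutations_vetoes_and_no_calls():
    sites = pd.DataFrame({"chrom": "chr1", "pos": [100, 200],
                          "ref": "A", "alt": "T"})
    counts = {
        "CE1": np.array([[0, 30], [0, 30]]),
        "CE2": np.array([[0, 25], [0, 25]]),
        "ind_het": np.array([[3, 3], [0, 6]]),    # het at site 1 only
        "ind_nocall": np.array([[0, 1], [0, 1]]),  # below depth: ignored
    }
    table = AlleleCountTable(sites, counts)
    candidates = sites.copy()
    regions = [Region("chr1", 1, 1000)]
    retained = {0: ["CE1", "CE2", "ind_het", "ind_nocall"]}
    kinds = {"CE1": "pool", "CE2": "pool", "ind_het": "individual",
             "ind_nocall": "individual"}
    muts, target_regions = screen_target_mutations(
        candidates, table, retained, regions, ["CE1", "CE2"], kinds)
    # site 100 vetoed by the confident het; site 200 survives
    assert list(muts["pos"]) == [200]
    assert len(target_regions) == 1
    assert target_regions.iloc[0]["n_target_mutations"] == 1


def test_screen_single_error_read_does_not_veto():
    sites = pd.DataFrame({"chrom": "chr1", "pos": [100],
                          "ref": "A", "alt": "T"})
    table = AlleleCountTable(sites, {
        "CE1": np.array([[0, 30]]),
        "ind": np.array([[1, 3]]),  # one discordant read at 4x
    })
    muts, _ = screen_target_mutations(
        sites.copy(), table, {0: ["CE1", "ind"]},
        [Region("chr1", 1, 1000)], ["CE1"],
        {"CE1": "pool", "ind": "individual"})
    assert len(muts) == 1


def test_screen_reduces_to_pool_fixation_without_individuals():
    sites = pd.DataFrame({"chrom": "chr1", "pos": [100, 200],
                          "ref": "A", "alt": "T"})
    table = AlleleCountTable(sites, {
        "CE1": np.array([[0, 30], [15, 15]]),
    })
    muts, _ = screen_target_mutations(
        sites.copy(), table, {0: ["CE1"]}, [Region("chr1", 1, 1000)],
        ["CE1"], {"CE1": "pool"})
    assert list(muts["pos"]) == [100]


def test_region_span_mb():
    assert region_span_mb(25_346_752, 28_589_750) == pytest.approx(3.242999)
    assert round(region_span_mb(25_346_752, 28_589_750), 1) == 3.2
    assert region_span_mb(1, 1_000_000) == pytest.approx(1.0)
    assert region_span_mb(5, 5) == pytest.approx(1e-6)
    with pytest.raises(ValueError):
        region_span_mb(10, 5)


def test_farm_screen_on_simulated_data(small_dataset):
    """Sharing-farm fish are retained, non-sharing excluded, causal region."""
    ds = small_dataset
    cp = ds.config.causal_pos
    region = Region(ds.config.causal_chrom, cp - 30_000, cp + 30_000)
    libs = ["Pool_CE1", "Pool_CE2"] + ds.farm_sample.lib_ids
    dm = distance_matrix(ds.table, libs, region, ds.kinds, min_sites=3)
    retained = set(retain_samples(dm, ["Pool_CE1", "Pool_CE2"], d_max=0.1))
    sharing = {l for l in ds.farm_sample.lib_ids if ds.farm_sample.sharing[l]}
    non_sharing = set(ds.farm_sample.lib_ids) - sharing
    assert sharing <= retained
    assert not (non_sharing & retained)
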