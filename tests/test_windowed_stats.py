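"""Windows, Weir-Cockerham FST components, pi, d_XY and landscape correlations."""
import numpy as np
import pytest

from lakestream.genotype_data import PopulationMap
from lakestream.windowed_stats import (
    Window,
    build_windows,
    correlate_landscapes,
    site_fst_components,
    subsample_for_diversity,
    table_site_components,
    window_dxy,
    window_pi,
    window_sfs_1d,
    window_weighted_fst,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def _rad_table(n_loci=30, locus_len=200, spacing=10_000, n_samples=4):
    """Loci of `locus_len` contiguous sequenced sites (1 SNP + rest monomorphic)."""
    pos, mono = [], []
    for k in range(n_loci):
        start = 1 + k * spacing
        pos.append(start)  # one SNP at the locus start
        mono.extend(range(start + 1, start + locus_len))
    dosage = [[0, 1, 2, 1]] * n_loci
    return make_table(pos=pos, dosage=dosage, monomorphic={"chr1": mono})


def test_non_overlapping_windows_accumulate_whole_loci():
    t = _rad_table(n_loci=30)
    wins = build_windows(t, min_sites=2500)
    # 200-site loci: 13 loci = 2600 sites per full window
    assert [w.n_sequenced_sites for w in wins[:2]] == [2600, 2600]
    assert wins[-1].n_sequenced_sites == 4 * 200  # undersized remainder window
    # no locus split across windows
    for w in wins:
        for s, e in w.locus_spans:
            assert w.start <= s and e <= w.end
    spans = [tuple(sp) for w in wins for sp in w.locus_spans]
    assert len(spans) == len(set(spans)) == 30


def test_sliding_windows_fixed_coordinates():
    t = make_table(pos=[1, 2_000_000], dosage=[[0, 1, 0, 1]] * 2,
                   monomorphic={"chr1": [1_000_000]})
    wins = build_windows(t, mode="sliding", size_bp=1_000_000, step_bp=200_000)
    starts = [w.start for w in wins]
    assert starts[:6] == [1, 200_001, 400_001, 600_001, 800_001, 1_000_001]


# ---------------------------------------------------------------------------
# FST variance components
# ---------------------------------------------------------------------------

def _wc_oracle(dosages_by_pop):
    """Independent Weir-Cockerham oracle via ANOVA mean squares.

    Treats each diploid as two allele copies with an individual level:
    MSP (among populations), MSI (among individuals within populations),
    MSG (within individuals); then a, b, c from the classical MS identities.
    """
    r = len(dosages_by_pop)
    n_i = np.array([len(d) for d in dosages_by_pop], float)
    n_tot = n_i.sum()
    p_i = np.array([d.sum() / (2 * len(d)) for d in dosages_by_pop])
    p_bar = sum(d.sum() for d in dosages_by_pop) / (2 * n_tot)
    h_i = np.array([(d == 1).mean() for d in dosages_by_pop])
    n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    # sums of squares on allele indicators
    ssp = 2 * (n_i * (p_i - p_bar) ** 2).sum()
    ssi = sum(((d / 2 - pi) ** 2 * 2).sum() + (d == 1).sum() * 0.0
              for d, pi in zip(dosages_by_pop, p_i))
    # among individuals within pops: each individual's mean is d/2
    ssi = sum(2 * ((d / 2 - pi) ** 2).sum() for d, pi in zip(dosages_by_pop, p_i))
    ssg = sum((d == 1).sum() / 2.0 for d in dosages_by_pop)
    msp = ssp / (r - 1)
    msi = ssi / (n_tot - r)
    msg = ssg / n_tot
    a = (msp - msi) / (2 * n_c)
    b = (msi - msg) / 2
    c = msg
    return a, a + b + c


@pytest.mark.parametrize("seed", range(6))
def test_site_components_match_anova_oracle(seed):
    rng = np.random.default_rng(seed)
    d1 = rng.integers(0, 3, rng.integers(4, 12)).astype(float)
    d2 = rng.integers(0, 3, rng.integers(4, 12)).astype(float)
    if (d1.sum() + d2.sum()) in (0, 2 * (len(d1) + len(d2))):
        d1[0] = 1  # avoid the monomorphic corner case here
    a, tot = site_fst_components([d1, d2])
    ao, toto = _wc_oracle([d1, d2])
    assert a == pytest.approx(ao, abs=1e-10)
    assert tot == pytest.approx(toto, abs=1e-10)


def test_site_components_fixed_and_equal_frequency_limits():
    n = 20
    a, tot = site_fst_components([np.zeros(n), np.full(n, 2.0)])
    assert a / tot == pytest.approx(1.0, abs=0.03)  # fixation -> FST ~ 1
    d = np.array([0.0, 1, 1, 2] * 5)
    a2, _ = site_fst_components([d, d.copy()])
    assert abs(a2) < 0.05  # identical frequencies -> numerator ~ 0
    assert site_fst_components([np.zeros(5), np.zeros(5)]) == (0.0, 0.0)


def test_window_weighted_fst_is_ratio_of_sums():
    import pandas as pd
    comp = pd.DataFrame({
        "chrom": ["chr1"] * 2, "pos": [10, 20],
        "num": [0.5, 0.0], "den": [1.0, 1.0],
    })
    w = Window("chr1", 1, 100, 100)
    assert window_weighted_fst(w, comp) == pytest.approx(0.25)
    single = comp.iloc[:1]
    assert window_weighted_fst(w, single) == pytest.approx(0.5)
    empty = pd.DataFrame({"chrom": [], "pos": [], "num": [], "den": []})
    assert window_weighted_fst(w, empty) is None


def test_table_site_components_requires_two_genotypes():
    pm = PopulationMap({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
    t = make_table(pos=[1, 2], dosage=[[0, 2, 2, 0], [0, -1, 2, 0]])
    t.dosage[1, 1] = -1
    df = table_site_components(t, pm, ("A", "B"))
    assert df.pos.tolist() == [1]  # site 2 has a single genotyped A diploid


# ---------------------------------------------------------------------------
# pi and d_XY: SFS route == site-by-site route
# ---------------------------------------------------------------------------

def _pairwise_pi_oracle(dosage_block, L):
    """Average pairwise differences per site over allele copies (no phase needed)."""
    total = 0.0
    n = 2 * dosage_block.shape[1]
    for row in dosage_block:
        i = row.sum()
        total += i * (n - i)  # differing unordered pairs at this site
    return total / (n * (n - 1) / 2) / L


def _cross_pair_dxy_oracle(d1_block, d2_block, L):
    n1, n2 = 2 * d1_block.shape[1], 2 * d2_block.shape[1]
    total = 0.0
    for r1, r2 in zip(d1_block, d2_block):
        i, j = r1.sum(), r2.sum()
        total += i * (n2 - j) + j * (n1 - i)
    return total / (n1 * n2) / L


def test_window_pi_and_dxy_match_pairwise_oracles(two_pop_map):
    rng = np.random.default_rng(3)
    n_var = 40
    dosage = rng.integers(0, 3, (n_var, 4))
    t = make_table(pos=list(range(1, n_var + 1)), dosage=dosage,
                   monomorphic={"chr1": list(range(100, 160))})
    w = Window("chr1", 1, 200, 100)
    L = 100
    pi1 = window_pi(t, two_pop_map, w, "P1")
    assert pi1 == pytest.approx(_pairwise_pi_oracle(dosage[:, :2], L))
    dxy = window_dxy(t, two_pop_map, w, ("P1", "P2"))
    assert dxy == pytest.approx(_cross_pair_dxy_oracle(dosage[:, :2], dosage[:, 2:], L))
    assert pi1 >= 0 and dxy >= 0


def test_window_pi_simple_cases(two_pop_map):
    # one het-pattern site among 100 sites at n = 2 haplotypes: pi = 0.01
    t = make_table(pos=[1], dosage=[[1, 0, 0, 0]], monomorphic={"chr1": list(range(10, 109))})
    w = Window("chr1", 1, 200, 100)
    pm1 = PopulationMap({"s1": "P1", "s2": "X", "s3": "X", "s4": "X"})
    assert window_pi(t, pm1, w, "P1") == pytest.approx(0.01)
    # monomorphic window
    t2 = make_table(pos=[500], dosage=[[1, 0, 0, 0]], monomorphic={"chr1": list(range(10, 110))})
    assert window_pi(t2, pm1, w, "P1") == 0.0


def test_window_dxy_fixed_difference(two_pop_map):
    t = make_table(pos=[1], dosage=[[0, 0, 2, 2]], monomorphic={"chr1": list(range(10, 109))})
    w = Window("chr1", 1, 200, 100)
    assert window_dxy(t, two_pop_map, w, ("P1", "P2")) == pytest.approx(0.01)
    t2 = make_table(pos=[500], dosage=[[0, 0, 2, 2]], monomorphic={"chr1": list(range(10, 110))})
    assert window_dxy(t2, two_pop_map, w, ("P1", "P2")) == 0.0


def test_window_sfs_route_equals_direct_construction(two_pop_map):
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, (25, 4))
    t = make_table(pos=list(range(1, 26)), dosage=dosage, monomorphic={"chr1": [50, 51]})
    w = Window("chr1", 1, 60, 27)
    xi = window_sfs_1d(t, two_pop_map, w, "P1")
    direct = np.bincount(dosage[:, :2].sum(axis=1), minlength=5).astype(float)
    direct[0] += 2
    assert np.array_equal(xi, direct)


def test_subsample_for_diversity_complete_data():
    pm = PopulationMap({f"s{i}": "A" for i in range(8)})
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, (10, 8))
    dosage[dosage == 0] = 0
    t = make_table(pos=list(range(1, 11)), dosage=dosage,
                   samples=[f"s{i}" for i in range(8)])
    sub, spm = subsample_for_diversity(t, pm, ["A"], fraction=0.75, seed=2)
    assert len(sub.samples) == 6  # floor(0.75 x 8)
    assert (sub.dosage != -1).all()


# ---------------------------------------------------------------------------
# Landscape correlations
# ---------------------------------------------------------------------------

def test_correlate_landscapes_rules():
    a = np.arange(10, dtype=float)
    r, n = correlate_landscapes(a, 2 * a + 1)
    assert r == pytest.approx(1.0) and n == 10
    with pytest.raises(ValueError, match="shared"):
        correlate_landscapes(a, a, ("L1", "AGS1"), ("L1", "PLS1"), require_disjoint=True)
    with pytest.raises(ValueError, match="fewer than 3"):
        correlate_landscapes(np.array([1.0, np.nan]), np.array([1.0, 2.0]))


def test_independent_landscapes_are_uncorrelated():
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(40):
        a, b = rng.normal(size=(2, 1000))
        r, _ = correlate_landscapes(a, b)
        hits += abs(r) < 0.1
    assert hits >= 38  # >= 95% of replicates
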