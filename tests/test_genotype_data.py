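"""Filtering chain: depth fences, HWE screen, LD pruning, subsampling."""
import math

import numpy as np
import pytest

from lakestream.genotype_data import (
    MISSING,
    PopulationMap,
    filter_biallelic_autosomal,
    filter_depth_iqr,
    flag_allele_imbalance_individuals,
    haploidize,
    hwe_het_excess_filter,
    hwe_het_excess_pvalue,
    ld_prune,
    mask_and_drop_missing,
    read_vcf,
    rebalance_monomorphic,
    subsample_genotypes,
    write_vcf,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

VCF_SMALL = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:20\t1/1:15\t0/0:30
chr1\t150\t.\tC\t.\t.\tPASS\t.\tGT:DP\t0/0:20\t0/0:18\t0/0:22
chr1\t200\t.\tT\tC\t.\tPASS\t.\tGT:DP\t0/0:12\t./.:0\t0/1:25
chr1\t300\t.\tG\tA,T\t.\tPASS\t.\tGT:DP\t0/1:20\t0/2:15\t0/0:30
"""


def test_read_vcf_routes_invariant_records_and_keeps_multiallelics(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_SMALL)
    pop = tmp_path / "pop.txt"
    pop.write_text("a P1\nb P1\nc P2\n")
    table, popmap = read_vcf(str(vcf), str(pop))
    assert table.n_variants == 3  # 2 SNPs + 1 multiallelic retained at read time
    assert table.n_monomorphic == 1 and table.monomorphic["chr1"][0] == 150
    assert table.dosage[0].tolist() == [1, 2, 0]
    assert table.dosage[1].tolist() == [0, MISSING, 1]
    assert popmap.assignments["c"] == "P2"
    # multiallelic removed only by the dedicated filter
    bi = filter_biallelic_autosomal(table)
    assert bi.n_variants == 2


def test_read_vcf_unknown_popmap_sample_is_named(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_SMALL)
    pop = tmp_path / "pop.txt"
    pop.write_text("a P1\nb P1\nc P2\nghost P2\n")
    with pytest.raises(ValueError, match="ghost"):
        read_vcf(str(vcf), str(pop))


def test_vcf_round_trip(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_SMALL)
    table, _ = read_vcf(str(vcf), None)
    out = tmp_path / "o.vcf"
    write_vcf(filter_biallelic_autosomal(table), str(out))
    table2, _ = read_vcf(str(out), None)
    bi = filter_biallelic_autosomal(table)
    assert np.array_equal(table2.dosage, bi.dosage)
    assert np.array_equal(table2.depth, bi.depth)
    assert np.array_equal(table2.pos, bi.pos)
    assert table2.monomorphic.keys() == bi.monomorphic.keys()


# ---------------------------------------------------------------------------
# Depth / biallelic / missingness filters
# ---------------------------------------------------------------------------

def test_depth_iqr_fence():
    # site total depths {40, 40, 40, 40, 4000}: Q1 = Q3 = 40 (linear
    # interpolation), IQR 0 -> fence 40; only the high-depth site is removed
    t = make_table(
        pos=[10, 20, 30, 40, 50],
        dosage=[[0, 1]] * 5,
        depth=[[20, 20]] * 4 + [[2000, 2000]],
    )
    out = filter_depth_iqr(t, 1.5)
    assert out.n_variants == 4 and 50 not in out.pos
    # all-equal depths: IQR = 0 but boundary is kept (cutoff strict >)
    t2 = make_table(pos=[1, 2], dosage=[[0, 1], [1, 0]])
    assert filter_depth_iqr(t2, 1.5).n_variants == 2
    # enormous factor = identity once the IQR is positive
    t3 = make_table(pos=[1, 2, 3, 4, 5], dosage=[[0, 1]] * 5,
                    depth=[[5, 5], [10, 10], [15, 15], [20, 20], [2000, 2000]])
    assert filter_depth_iqr(t3, 1e12).n_variants == 5
    # idempotent
    assert filter_depth_iqr(out, 1.5).n_variants == out.n_variants


def test_biallelic_autosomal_filter():
    t = make_table(
        pos=[1, 2, 3, 4],
        chrom=["chr1", "chrXIX", "chr1", "chr1"],
        dosage=[[0, 1]] * 4,
        ref=["A", "A", "AT", "C"],
        alt=["G", "G", "A", "G,T"],
        monomorphic={"chrXIX": [99], "chr1": [50]},
    )
    out = filter_biallelic_autosomal(t)
    assert out.n_variants == 1 and out.pos[0] == 1
    assert "chrXIX" not in out.monomorphic and "chr1" in out.monomorphic


def test_mask_and_drop_missing():
    t = make_table(pos=[1], dosage=[[0, 1, 2, 0]], depth=[[12, 9, 30, 0]])
    out = mask_and_drop_missing(t, 10, 0.5)
    assert out.n_variants == 1
    assert (out.dosage[0] == MISSING).sum() == 2
    t2 = make_table(pos=[1], dosage=[[0, 1, 2, 0]], depth=[[9, 9, 9, 30]])
    assert mask_and_drop_missing(t2, 10, 0.5).n_variants == 0
    out3 = mask_and_drop_missing(t2, 0, 0.5)
    assert (out3.dosage == MISSING).sum() == 0


# ---------------------------------------------------------------------------
# HWE heterozygote-excess screen
# ---------------------------------------------------------------------------

def _hwe_enumeration_oracle(n_het, n_hom_ref, n_hom_alt):
    """Independent brute-force: P(het >= obs | allele counts) by direct
    multinomial enumeration over genotype configurations."""
    n = n_het + n_hom_ref + n_hom_alt
    na = n_het + 2 * n_hom_alt
    na = min(na, 2 * n - na)
    total, tail = 0.0, 0.0
    for h in range(na % 2, na + 1, 2):
        hom_a = (na - h) // 2
        hom_r = n - h - hom_a
        w = (
            math.factorial(n) / (math.factorial(h) * math.factorial(hom_a) * math.factorial(hom_r))
        ) * 2**h
        total += w
        if h >= n_het:
            tail += w
    return tail / total


@pytest.mark.parametrize(
    "het,hom_ref,hom_alt",
    [(10, 0, 0), (5, 3, 2), (2, 7, 1), (0, 9, 1), (4, 0, 4), (1, 1, 1)],
)
def test_hwe_pvalue_matches_enumeration(het, hom_ref, hom_alt):
    assert hwe_het_excess_pvalue(het, hom_ref, hom_alt) == pytest.approx(
        _hwe_enumeration_oracle(het, hom_ref, hom_alt), rel=1e-12
    )


def test_hwe_filter_flags_all_het_site_with_buffer():
    # 10 diploids all heterozygous: extreme het excess, exact P << 0.05
    pm = PopulationMap({f"s{i+1}": "P" for i in range(10)})
    t = make_table(
        pos=[450, 500, 5000],
        dosage=[[0, 2] * 5, [1] * 10, [0, 1] * 5],
        samples=[f"s{i+1}" for i in range(10)],
        monomorphic={"chr1": [480, 520, 700, 4990]},
    )
    out = hwe_het_excess_filter(t, pm, alpha=0.05, buffer_bp=100)
    # flagged site 500 and the variant at 450 (within 100 bp) are gone
    assert out.pos.tolist() == [5000]
    # buffered monomorphic sites removed too
    assert out.monomorphic["chr1"].tolist() == [700, 4990]


def test_hwe_all_homozygous_never_flagged():
    pm = PopulationMap({f"s{i+1}": "P" for i in range(6)})
    t = make_table(pos=[100], dosage=[[0, 0, 0, 2, 2, 2]], samples=[f"s{i+1}" for i in range(6)])
    assert hwe_het_excess_filter(t, pm).n_variants == 1


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_greedy_rules():
    # sites 1&2 perfectly correlated 50 bp apart -> second dropped
    d = [[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2], [2, 1, 0, 2, 1, 0]]
    t = make_table(pos=[100, 150, 5000], dosage=d, samples=[f"s{i}" for i in range(6)])
    out = ld_prune(t, 0.95, 200)
    assert out.pos.tolist() == [100, 5000]
    # same pair far apart: both kept
    t2 = make_table(pos=[100, 5100], dosage=d[:2], samples=[f"s{i}" for i in range(6)])
    assert ld_prune(t2, 0.95, 200).n_variants == 2


def test_ld_prune_three_site_chain():
    # r2(1,2) = 1, r2(1,3) ~ 0.25: middle removed, third kept vs site 1
    s1 = [0, 0, 1, 1, 2, 2, 0, 2]
    s3 = [0, 1, 1, 0, 2, 1, 0, 2]
    t = make_table(pos=[100, 150, 200], dosage=[s1, s1, s3], samples=[f"s{i}" for i in range(8)])
    out = ld_prune(t, 0.95, 200)
    assert out.pos.tolist() == [100, 200]
    # idempotent
    assert ld_prune(out, 0.95, 200).pos.tolist() == [100, 200]


# ---------------------------------------------------------------------------
# Subsampling / haploidization / monomorphic rebalancing
# ---------------------------------------------------------------------------

def test_subsample_genotypes_contract():
    pm = PopulationMap({f"s{i+1}": "P" for i in range(5)})
    t = make_table(
        pos=[1, 2],
        dosage=[[0, 1, 2, MISSING, 1], [MISSING, MISSING, 0, 1, 2]],
        samples=[f"s{i+1}" for i in range(5)],
    )
    out, npm = subsample_genotypes(t, {"P": 4}, pm, seed=1)
    assert out.n_variants == 1  # site 2 has only 3 callable genotypes
    assert (out.dosage == MISSING).sum() == 0
    assert out.samples == ["P_1", "P_2", "P_3", "P_4"]
    assert sorted(out.dosage[0].tolist()) == [0, 1, 1, 2]  # the forced choice
    out2, _ = subsample_genotypes(t, {"P": 4}, pm, seed=1)
    assert np.array_equal(out.dosage, out2.dosage)  # deterministic
    with pytest.raises(ValueError, match="exceeds population size"):
        subsample_genotypes(t, {"P": 6}, pm, seed=1)


def test_haploidize_preserves_frequency_in_expectation():
    rng = np.random.default_rng(0)
    n = 10_000
    t = make_table(pos=list(range(1, n + 1)), dosage=[[1, MISSING]] * n)
    out = haploidize(t, seed=42)
    assert (out.dosage[:, 1] == MISSING).all()
    n_two = int((out.dosage[:, 0] == 2).sum())
    # binomial(10000, 1/2) 99% bounds
    lo, hi = 5000 - 2.576 * np.sqrt(n * 0.25), 5000 + 2.576 * np.sqrt(n * 0.25)
    assert lo < n_two < hi
    assert set(np.unique(out.dosage[:, 0])) <= {0, 2}
    # all-homozygous input is untouched
    t2 = make_table(pos=[1, 2], dosage=[[0, 2], [2, 0]])
    assert np.array_equal(haploidize(t2, 1).dosage, t2.dosage)
    _ = rng


def test_rebalance_monomorphic_proportionality():
    t = make_table(
        pos=[1, 2], dosage=[[0, 1], [1, 0]],
        monomorphic={"chr1": list(range(100, 1100))},
    )
    # 1000 mono, 2 SNPs retained of 4 pre-pruning -> keep 500
    out = rebalance_monomorphic(t, n_snps_pre=4, seed=3)
    assert out.n_monomorphic == 500
    # retained == pre -> all kept
    assert rebalance_monomorphic(t, n_snps_pre=2, seed=3).n_monomorphic == 1000


def test_allele_imbalance_screen():
    t = make_table(
        pos=[1, 2],
        dosage=[[1, 1], [1, 1]],
        ad_ref=[[10, 19], [10, 19]],
        ad_alt=[[10, 1], [10, 1]],
    )
    assert flag_allele_imbalance_individuals(t, threshold=0.3) == ["s2"]
    t2 = make_table(pos=[1], dosage=[[1, 1]])
    with pytest.warns(UserWarning, match="allelic depths"):
        assert flag_allele_imbalance_individuals(t2) == []
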