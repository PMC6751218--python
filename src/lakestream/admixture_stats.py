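"""Admixture statistics: ABBA-BABA D, diagnostic SNP panels, hybrid indices.

D is the frequency-based (population-sample) estimator over a quartet
(P1, P2, P3, Outgroup): with derived-allele frequencies p̂_i after polarising
on the outgroup major allele,

    D = Σ_s [(1-p̂1) p̂2 p̂3 − p̂1 (1-p̂2) p̂3] / Σ_s [(1-p̂1) p̂2 p̂3 + p̂1 (1-p̂2) p̂3]

(the outgroup term (1-p̂4) is 1 by construction).  Standard errors come from
a delete-one block jackknife over genomic blocks; quartets with |Z| >= 3 are
flagged as significant excess allele sharing.

The hybrid index of an individual is the fraction of its alleles derived
from the West European lineage, scored over a panel of SNPs divergently
fixed between East (e.g. PLS1) and West (e.g. AGS1 + FRS4) reference
populations — the closed-form allele-count estimator, exact for divergently
fixed codominant markers, with exact binomial confidence bounds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .genotype_data import MISSING, GenotypeTable, PopulationMap


@dataclass
class QuartetResult:
    labels: tuple[str, str, str, str]
    d: float
    se: float
    z: float
    n_informative_blocks: int
    n_sites_used: int
    significant: bool  # |z| >= 3
    undefined: bool = False


@dataclass
class DiagnosticPanel:
    loci: list[tuple[str, int, str, str]]  # (chrom, pos, west_allele, east_allele)
    spacing_bp: int

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class HybridIndexResult:
    h: dict[str, float]  # individual -> fraction West alleles
    n_loci_scored: dict[str, int]
    ci95: dict[str, tuple[float, float]]

    def mean(self) -> float:
        return float(np.mean(list(self.h.values())))


def _pop_freqs(table: GenotypeTable, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and called-genotype count per site for one population."""
    d = table.dosage[:, cols].astype(float)
    called = d != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / (2.0 * n), np.nan)
    return freq, n


def d_statistic(
    table: GenotypeTable,
    popmap: PopulationMap,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    block_bp: int = 5_000_000,
) -> QuartetResult:
    """Frequency-based D with delete-one block-jackknife standard error.

    Sites where the outgroup is missing or polymorphic are dropped; the
    outgroup major allele defines the ancestral state.  Blocks are `block_bp`
    windows along each chromosome; only blocks with a non-zero denominator
    contribute to the jackknife.
    """
    idx = popmap.sample_indices(table.samples)
    for p in (p1, p2, p3, outgroup):
        if p not in idx:
            raise ValueError(f"population {p!r} has no samples")
    f1, n1 = _pop_freqs(table, idx[p1])
    f2, n2 = _pop_freqs(table, idx[p2])
    f3, n3 = _pop_freqs(table, idx[p3])
    fo, no = _pop_freqs(table, idx[outgroup])
    usable = (n1 > 0) & (n2 > 0) & (n3 > 0) & (no > 0) & ((fo == 0.0) | (fo == 1.0))
    # polarise: derived = allele absent from the (fixed) outgroup
    der1 = np.where(fo == 0.0, f1, 1.0 - f1)
    der2 = np.where(fo == 0.0, f2, 1.0 - f2)
    der3 = np.where(fo == 0.0, f3, 1.0 - f3)
    abba = (1.0 - der1) * der2 * der3
    baba = der1 * (1.0 - der2) * der3
    num = np.where(usable, abba - baba, 0.0)
    den = np.where(usable, abba + baba, 0.0)

    block_ids = np.empty(table.n_variants, dtype=object)
    for c in set(table.chrom.tolist()):
        cmask = table.chrom == c
        block_ids[cmask] = [f"{c}:{int(p) // block_bp}" for p in table.pos[cmask]]
    blocks = sorted(set(block_ids[usable].tolist()))
    bnum = np.array([num[block_ids == b].sum() for b in blocks])
    bden = np.array([den[block_ids == b].sum() for b in blocks])
    informative = bden > 0
    total_num, total_den = bnum.sum(), bden.sum()
    labels = (p1, p2, p3, outgroup)
    if total_den == 0:
        return QuartetResult(labels, np.nan, np.nan, np.nan, 0, int(usable.sum()), False, undefined=True)
    d = total_num / total_den
    bi_num, bi_den = bnum[informative], bden[informative]
    nb = int(informative.sum())
    if nb >= 2:
        d_jack = (total_num - bi_num) / (total_den - bi_den)
        se = float(np.sqrt((nb - 1) / nb * np.sum((d_jack - d_jack.mean()) ** 2)))
    else:
        se = np.nan
    z = d / se if se and np.isfinite(se) and se > 0 else np.nan
    return QuartetResult(labels, float(d), se, float(z), nb, int(usable.sum()),
                         bool(np.isfinite(z) and abs(z) >= 3))


def find_diagnostic_snps(
    table: GenotypeTable,
    popmap: PopulationMap,
    east_pops: list[str],
    west_pops: list[str],
    min_genotypes: int = 3,
    min_spacing_bp: int = 100_000,
) -> DiagnosticPanel:
    """SNPs divergently fixed between the East and West reference groups.

    A site qualifies iff at least `min_genotypes` diploids are scored in each
    group and all East alleles are one allele while all West alleles are the
    other; a greedy left-to-right scan enforces `min_spacing_bp` between
    consecutive panel loci.
    """
    idx = popmap.sample_indices(table.samples)
    east_cols = np.concatenate([idx[p] for p in east_pops])
    west_cols = np.concatenate([idx[p] for p in west_pops])
    loci: list[tuple[str, int, str, str]] = []
    last: dict[str, int] = {}
    order = np.lexsort((table.pos, table.chrom.astype(str)))
    for i in order:
        de = table.dosage[i, east_cols]
        dw = table.dosage[i, west_cols]
        de = de[de != MISSING]
        dw = dw[dw != MISSING]
        if len(de) < min_genotypes or len(dw) < min_genotypes:
            continue
        e_fixed_ref = np.all(de == 0)
        e_fixed_alt = np.all(de == 2)
        w_fixed_ref = np.all(dw == 0)
        w_fixed_alt = np.all(dw == 2)
        if not ((e_fixed_ref and w_fixed_alt) or (e_fixed_alt and w_fixed_ref)):
            continue
        c, p = str(table.chrom[i]), int(table.pos[i])
        if c in last and p - last[c] < min_spacing_bp:
            continue
        west_allele = str(table.alt[i]) if w_fixed_alt else str(table.ref[i])
        east_allele = str(table.ref[i]) if w_fixed_alt else str(table.alt[i])
        loci.append((c, p, west_allele, east_allele))
        last[c] = p
    if not loci:
        warnings.warn("find_diagnostic_snps: no divergently fixed SNPs found")
    return DiagnosticPanel(loci=loci, spacing_bp=min_spacing_bp)


def write_panel(panel: DiagnosticPanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\twest_allele\teast_allele\n")
        for c, p, w, e in panel.loci:
            fh.write(f"{c}\t{p}\t{w}\t{e}\n")


def hybrid_index(
    table: GenotypeTable,
    panel: DiagnosticPanel,
    individuals: list[str],
) -> HybridIndexResult:
    """Per-individual fraction of West-derived alleles over the panel loci.

    h = (#West alleles) / (2 x #loci scored); 0 = fixed East, 1 = fixed West.
    95% CIs are exact (Clopper-Pearson) binomial bounds on the allele count.
    Individuals scored at zero loci are excluded with a warning.
    """
    pos_index = {(str(c), int(p)): i for i, (c, p) in enumerate(zip(table.chrom, table.pos))}
    cols = {s: j for j, s in enumerate(table.samples)}
    h: dict[str, float] = {}
    n_scored: dict[str, int] = {}
    ci: dict[str, tuple[float, float]] = {}
    for ind in individuals:
        if ind not in cols:
            raise ValueError(f"individual {ind!r} not in table")
        j = cols[ind]
        west_alleles = 0
        loci_scored = 0
        for c, p, west_allele, _east in panel.loci:
            i = pos_index.get((c, p))
            if i is None:
                continue
            d = int(table.dosage[i, j])
            if d == MISSING:
                continue
            loci_scored += 1
            west_alleles += d if west_allele == str(table.alt[i]) else 2 - d
        if loci_scored == 0:
            warnings.warn(f"hybrid_index: individual {ind!r} scored at 0 panel loci; excluded")
            continue
        h[ind] = west_alleles / (2.0 * loci_scored)
        n_scored[ind] = loci_scored
        bt = binomtest(west_alleles, 2 * loci_scored)
        lohi = bt.proportion_ci(confidence_level=0.95, method="exact")
        ci[ind] = (float(lohi.low), float(lohi.high))
    return HybridIndexResult(h=h, n_loci_scored=n_scored, ci95=ci)
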