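"""Genomic windows and differentiation/diversity landscapes.

Windows either accumulate whole RAD loci until a minimum number of sequenced
sites is reached (non-overlapping mode) or tile the genome at fixed
size/step (sliding mode).  Per-SNP Weir-Cockerham variance components are
summed within windows and divided once — the weighted "ratio of averages"
FST.  Nucleotide diversity π and absolute divergence d_XY are computed from
each window's (joint) site-frequency spectrum over a complete-data
subsampled table, normalised per sequenced site:

    π    = (1/L) Σ_i  ξ_i · 2 i (n - i) / (n (n - 1))
    d_XY = (1/L) Σ_ij S_ij · [ (i/n1)(1 - j/n2) + (j/n2)(1 - i/n1) ]

which equal the average pairwise-difference counts over within- and
between-population haplotype pairs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .genotype_data import MISSING, GenotypeTable, PopulationMap


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_sequenced_sites: int
    locus_spans: list[tuple[int, int]] | None = None


@dataclass
class WindowStats:
    window: Window
    fst_weighted: float | None
    pi: dict[str, float]
    dxy: float | None
    mean_recomb: float | None = None


def infer_rad_loci(table: GenotypeTable, chrom: str, max_gap: int = 1) -> list[tuple[int, int, int]]:
    """Contiguous runs of sequenced positions = RAD loci: (start, end, n_sites).

    Positions more than `max_gap` apart start a new locus; RAD loci are short
    contiguous stretches separated by large unsequenced gaps, so the default
    (strict contiguity) recovers them exactly.
    """
    seq = table.sequenced_positions(chrom)
    if len(seq) == 0:
        return []
    breaks = np.where(np.diff(seq) > max_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(seq) - 1]])
    return [(int(seq[s]), int(seq[e]), int(e - s + 1)) for s, e in zip(starts, ends)]


def build_windows(
    table: GenotypeTable,
    min_sites: int = 2500,
    mode: str = "non_overlapping",
    size_bp: int = 1_000_000,
    step_bp: int = 200_000,
) -> list[Window]:
    """Non-overlapping windows of whole RAD loci totalling >= `min_sites`
    sequenced sites, or fixed-coordinate sliding windows."""
    if mode not in ("non_overlapping", "sliding"):
        raise ValueError("mode must be 'non_overlapping' or 'sliding'")
    windows: list[Window] = []
    for c in table.chromosomes():
        if mode == "sliding":
            seq = table.sequenced_positions(c)
            if len(seq) == 0:
                continue
            last = int(seq[-1])
            start = 1
            while start <= last:
                end = start + size_bp - 1
                n = int(((seq >= start) & (seq <= end)).sum())
                windows.append(Window(c, start, end, n))
                start += step_bp
            continue
        loci = infer_rad_loci(table, c)
        if not loci:
            continue
        acc: list[tuple[int, int, int]] = []
        acc_sites = 0
        for locus in loci:
            acc.append(locus)
            acc_sites += locus[2]
            if acc_sites >= min_sites:
                windows.append(Window(c, acc[0][0], acc[-1][1], acc_sites,
                                      [(s, e) for s, e, _ in acc]))
                acc, acc_sites = [], 0
        if acc:  # undersized remainder gets flagged as its own window
            windows.append(Window(c, acc[0][0], acc[-1][1], acc_sites,
                                  [(s, e) for s, e, _ in acc]))
    return windows


# ---------------------------------------------------------------------------
# FST (Weir-Cockerham variance components, ratio of averages)
# ---------------------------------------------------------------------------

def site_fst_components(
    dosages_by_pop: list[np.ndarray],
) -> tuple[float, float]:
    """Per-site Weir-Cockerham (1984) components for one biallelic SNP.

    `dosages_by_pop` holds the non-missing diploid dosages (0/1/2) of the two
    (or more) populations.  Returns ``(a, a + b + c)``: the among-population
    variance component and the total, whose window sums give the weighted
    ratio-of-averages FST.  A site monomorphic across the pooled sample
    contributes (0, 0).
    """
    r = len(dosages_by_pop)
    n_i = np.array([len(d) for d in dosages_by_pop], dtype=float)
    if np.any(n_i < 2):
        raise ValueError("need >= 2 genotyped diploids per population")
    p_i = np.array([d.sum() / (2 * len(d)) for d in dosages_by_pop])
    h_i = np.array([(d == 1).mean() for d in dosages_by_pop])
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    if p_bar in (0.0, 1.0):
        return 0.0, 0.0
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a), float(a + b + c)


def table_site_components(
    table: GenotypeTable,
    popmap: PopulationMap,
    pop_pair: tuple[str, str],
    min_genotypes: int = 2,
) -> pd.DataFrame:
    """Weir-Cockerham components for every eligible SNP of a population pair."""
    idx = popmap.sample_indices(table.samples)
    rows = []
    for i in range(table.n_variants):
        ds = []
        ok = True
        for p in pop_pair:
            d = table.dosage[i, idx[p]]
            d = d[d != MISSING].astype(float)
            if len(d) < min_genotypes:
                ok = False
                break
            ds.append(d)
        if not ok:
            continue
        a, tot = site_fst_components(ds)
        rows.append({"chrom": str(table.chrom[i]), "pos": int(table.pos[i]), "num": a, "den": tot})
    return pd.DataFrame(rows, columns=["chrom", "pos", "num", "den"])


def window_weighted_fst(window: Window, site_components: pd.DataFrame) -> float | None:
    """Ratio-of-averages FST: Σ numerators / Σ denominators over window sites."""
    sel = site_components[
        (site_components.chrom == window.chrom)
        & (site_components.pos >= window.start)
        & (site_components.pos <= window.end)
    ]
    den = sel.den.sum()
    if den == 0:
        return None
    return float(sel.num.sum() / den)


# ---------------------------------------------------------------------------
# pi and d_XY from windowed spectra
# ---------------------------------------------------------------------------

def _window_mask(table: GenotypeTable, window: Window) -> np.ndarray:
    return (table.chrom == window.chrom) & (table.pos >= window.start) & (table.pos <= window.end)


def _window_n_sites(table: GenotypeTable, window: Window) -> int:
    n_var = int(_window_mask(table, window).sum())
    mono = table.monomorphic.get(window.chrom, np.empty(0, dtype=np.int64))
    return n_var + int(((mono >= window.start) & (mono <= window.end)).sum())


def window_sfs_1d(table: GenotypeTable, popmap: PopulationMap, window: Window, pop: str) -> np.ndarray:
    """Unfolded 1D allele-count spectrum (ξ) of one population in one window.

    Requires complete data (use subsample_genotypes); index i counts sites
    with alt-allele count i among the n haplotypes.
    """
    cols = popmap.sample_indices(table.samples)[pop]
    mask = _window_mask(table, window)
    d = table.dosage[mask][:, cols]
    if (d == MISSING).any():
        raise ValueError("window_sfs_1d requires complete data; run subsample_genotypes")
    n = 2 * len(cols)
    xi = np.bincount(d.sum(axis=1), minlength=n + 1).astype(float)
    xi[0] += _window_n_sites(table, window) - int(mask.sum())
    return xi


def window_pi(table: GenotypeTable, popmap: PopulationMap, window: Window, pop: str) -> float | None:
    """Per-site nucleotide diversity of `pop` in `window` from its 1D-SFS."""
    L = _window_n_sites(table, window)
    if L == 0:
        return None
    xi = window_sfs_1d(table, popmap, window, pop)
    n = len(xi) - 1
    i = np.arange(n + 1)
    return float(np.sum(xi * 2.0 * i * (n - i) / (n * (n - 1))) / L)


def window_dxy(
    table: GenotypeTable, popmap: PopulationMap, window: Window, pop_pair: tuple[str, str]
) -> float | None:
    """Per-site absolute divergence between the pair from the joint 2D-SFS."""
    L = _window_n_sites(table, window)
    if L == 0:
        return None
    idx = popmap.sample_indices(table.samples)
    c1, c2 = idx[pop_pair[0]], idx[pop_pair[1]]
    mask = _window_mask(table, window)
    d1 = table.dosage[mask][:, c1]
    d2 = table.dosage[mask][:, c2]
    if (d1 == MISSING).any() or (d2 == MISSING).any():
        raise ValueError("window_dxy requires complete data; run subsample_genotypes")
    n1, n2 = 2 * len(c1), 2 * len(c2)
    S = np.zeros((n1 + 1, n2 + 1))
    np.add.at(S, (d1.sum(axis=1), d2.sum(axis=1)), 1.0)
    S[0, 0] += L - int(mask.sum())
    i = np.arange(n1 + 1)[:, None] / n1
    j = np.arange(n2 + 1)[None, :] / n2
    w = i * (1 - j) + j * (1 - i)
    return float((S * w).sum() / L)


def subsample_for_diversity(
    table: GenotypeTable, popmap: PopulationMap, pops: list[str], fraction: float = 0.75, seed: int = 0
):
    """Subsample to floor(fraction x population size) genotypes per population
    (complete-data panel for π / d_XY)."""
    from .genotype_data import subsample_genotypes

    k = {p: max(1, int(np.floor(fraction * len(popmap.members(p))))) for p in pops}
    return subsample_genotypes(table, k, popmap, seed)


def correlate_landscapes(
    stats_a: np.ndarray,
    stats_b: np.ndarray,
    pops_a: tuple[str, ...] | None = None,
    pops_b: tuple[str, ...] | None = None,
    require_disjoint: bool = False,
) -> tuple[float, int]:
    """Pearson r between two per-window landscapes over complete cases.

    For pairwise statistics (FST, d_XY) pass the population tuples and set
    `require_disjoint=True` to reject comparisons sharing a population
    (autocorrelation guard).
    """
    if require_disjoint:
        if pops_a is None or pops_b is None:
            raise ValueError("population labels required when require_disjoint=True")
        shared = set(pops_a) & set(pops_b)
        if shared:
            raise ValueError(f"population(s) shared between landscapes: {sorted(shared)}")
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete windows; correlation undefined")
    r, _ = pearsonr(a[ok], b[ok])
    return float(r), int(ok.sum())


def windows_table(stats: list[WindowStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {
            "chrom": s.window.chrom, "start": s.window.start, "end": s.window.end,
            "n_sites": s.window.n_sequenced_sites, "fst": s.fst_weighted, "dxy": s.dxy,
            "recomb": s.mean_recomb,
        }
        for p, v in s.pi.items():
            row[f"pi_{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
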