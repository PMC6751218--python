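"""Multidimensional site-frequency spectra: build, fold, marginalize, bootstrap.

An SFS is a k-dimensional count array indexed by per-population alternate
(or minor, when folded) allele counts; dimension p has length 2n_p + 1 for
n_p diploids.  The all-zero corner holds monomorphic sequenced sites, so
``total_sites`` — the quantity composite likelihoods are normalised over —
is simply the array total.

Folding uses the *global* minor allele: a cell whose total allele count
exceeds half the total sample size is added to its complementary cell;
cells exactly at half stay in place (tie convention that conserves totals).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_data import MISSING, GenotypeTable, PopulationMap


@dataclass
class SFS:
    counts: np.ndarray  # float64, shape prod(2*n_p + 1)
    pop_order: tuple[str, ...]
    sample_sizes: tuple[int, ...]  # haploid sizes 2*n_p
    folded: bool = False
    mask: np.ndarray | None = None  # True = excluded from likelihood sums

    def __post_init__(self):
        expected = tuple(n + 1 for n in self.sample_sizes)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected} from sample sizes")

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "SFS":
        return SFS(
            self.counts.copy(),
            self.pop_order,
            self.sample_sizes,
            self.folded,
            None if self.mask is None else self.mask.copy(),
        )


def _index_sums(shape: tuple[int, ...]) -> np.ndarray:
    """Array of index-vector sums (total allele count per cell)."""
    grids = np.indices(shape)
    return grids.sum(axis=0)


def sfs_from_genotypes(table: GenotypeTable, popmap: PopulationMap, pop_order: list[str]) -> SFS:
    """Tally the multidimensional SFS of a complete-data genotype table.

    Each variant increments the cell of its per-population alternate-allele
    counts; each monomorphic site increments the all-zero corner.
    """
    if table.n_variants and (table.dosage == MISSING).any():
        raise ValueError("table contains missing genotypes; run subsample_genotypes first")
    idx = popmap.sample_indices(table.samples)
    for p in pop_order:
        if p not in idx:
            raise ValueError(f"population {p!r} has no samples in the table")
    sizes = tuple(2 * len(idx[p]) for p in pop_order)
    counts = np.zeros(tuple(s + 1 for s in sizes))
    if table.n_variants:
        percell = np.stack([table.dosage[:, idx[p]].sum(axis=1) for p in pop_order], axis=1)
        np.add.at(counts, tuple(percell[:, d] for d in range(len(pop_order))), 1.0)
    counts[(0,) * len(pop_order)] += table.n_monomorphic
    return SFS(counts, tuple(pop_order), sizes, folded=False)


def fold_array(arr: np.ndarray, sample_sizes: tuple[int, ...]) -> np.ndarray:
    """Fold a k-dim spectrum array onto the global minor allele.

    Cells whose total allele count exceeds half the total sample size move to
    their complement (2n - v); cells exactly at half stay in place (tie rule
    that conserves the array total).
    """
    total = sum(sample_sizes)
    sums = _index_sums(arr.shape)
    major = sums > total / 2.0
    flip = tuple(slice(None, None, -1) for _ in sample_sizes)
    return np.where(major, 0.0, arr) + np.where(major, arr, 0.0)[flip]


def fold(sfs: SFS) -> SFS:
    """Fold onto the global minor allele; conserves total_sites; idempotent."""
    if sfs.folded:
        warnings.warn("fold: SFS already folded; returning a copy")
        return sfs.copy()
    folded = fold_array(sfs.counts, sfs.sample_sizes)
    new_mask = None
    if sfs.mask is not None:
        total = sum(sfs.sample_sizes)
        sums = _index_sums(sfs.counts.shape)
        major = sums > total / 2.0
        flip = tuple(slice(None, None, -1) for _ in sfs.sample_sizes)
        new_mask = (~major & sfs.mask) | (major & sfs.mask)[flip]
    return SFS(folded, sfs.pop_order, sfs.sample_sizes, folded=True, mask=new_mask)


def marginalize(sfs: SFS, keep_pops: list[str]) -> SFS:
    """Sum over the dimensions of dropped populations; conserves total_sites."""
    if not keep_pops:
        raise ValueError("keep_pops must be non-empty")
    for p in keep_pops:
        if p not in sfs.pop_order:
            raise ValueError(f"unknown population {p!r}")
    keep_axes = [sfs.pop_order.index(p) for p in keep_pops]
    drop_axes = tuple(i for i in range(len(sfs.pop_order)) if i not in keep_axes)
    counts = sfs.counts.sum(axis=drop_axes) if drop_axes else sfs.counts.copy()
    # surviving axes are in original order; permute to match keep_pops order
    remaining = [a for a in range(len(sfs.pop_order)) if a not in drop_axes]
    counts = np.transpose(counts, axes=[remaining.index(a) for a in keep_axes])
    sizes = tuple(sfs.sample_sizes[sfs.pop_order.index(p)] for p in keep_pops)
    return SFS(counts, tuple(keep_pops), sizes, folded=sfs.folded)


def mask_singletons(sfs: SFS) -> SFS:
    """Flag singleton cells (total allele count 1; also 2n-1 if unfolded) as masked."""
    out = sfs.copy()
    sums = _index_sums(out.counts.shape)
    m = sums == 1
    if not out.folded:
        m |= sums == sum(out.sample_sizes) - 1
    out.mask = m if out.mask is None else (out.mask | m)
    return out


def block_bootstrap(
    table: GenotypeTable,
    popmap: PopulationMap,
    pop_order: list[str],
    block_sites: int = 10_000,
    n_reps: int = 100,
    seed: int | None = None,
) -> list[SFS]:
    """Bootstrap the SFS over blocks of consecutive sequenced sites.

    Blocks are runs of `block_sites` sequenced sites (variant + monomorphic)
    within a chromosome; the final partial block on each chromosome is its own
    block.  Each replicate draws B blocks with replacement (B = observed block
    count) and sums their spectra.
    """
    idx = popmap.sample_indices(table.samples)
    sizes = tuple(2 * len(idx[p]) for p in pop_order)
    shape = tuple(s + 1 for s in sizes)
    block_counts: list[np.ndarray] = []
    for c in table.chromosomes():
        seq = table.sequenced_positions(c)
        if len(seq) == 0:
            continue
        var_mask = table.chrom == c
        var_pos = table.pos[var_mask]
        var_rows = np.where(var_mask)[0]
        mono = table.monomorphic.get(c, np.empty(0, dtype=np.int64))
        for start in range(0, len(seq), block_sites):
            block = seq[start : start + block_sites]
            lo, hi = block[0], block[-1]
            arr = np.zeros(shape)
            in_block = (var_pos >= lo) & (var_pos <= hi)
            for r in var_rows[in_block]:
                cell = tuple(int(table.dosage[r, idx[p]].sum()) for p in pop_order)
                arr[cell] += 1
            arr[(0,) * len(pop_order)] += int(((mono >= lo) & (mono <= hi)).sum())
            block_counts.append(arr)
    if len(block_counts) < 2:
        raise ValueError("fewer than 2 blocks; block bootstrap is meaningless")
    rng = np.random.default_rng(seed)
    B = len(block_counts)
    stacked = np.stack(block_counts)
    reps = []
    for _ in range(n_reps):
        draw = rng.integers(0, B, size=B)
        reps.append(SFS(stacked[draw].sum(axis=0), tuple(pop_order), sizes, folded=False))
    return reps


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_sfs(sfs: SFS, path: str) -> None:
    """Header: pops, haploid sizes, folded flag; body: row-major flat counts."""
    with open(path, "w") as fh:
        fh.write("# lakestream SFS v1\n")
        fh.write("pops\t" + "\t".join(sfs.pop_order) + "\n")
        fh.write("sizes\t" + "\t".join(str(s) for s in sfs.sample_sizes) + "\n")
        fh.write(f"folded\t{int(sfs.folded)}\n")
        fh.write(" ".join(repr(float(x)) for x in sfs.counts.ravel()) + "\n")
        if sfs.mask is not None:
            fh.write("mask " + " ".join(str(int(x)) for x in sfs.mask.ravel()) + "\n")


def read_sfs(path: str) -> SFS:
    pops: tuple[str, ...] = ()
    sizes: tuple[int, ...] = ()
    folded = False
    counts = None
    mask = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("pops\t"):
                pops = tuple(line.split("\t")[1:])
            elif line.startswith("sizes\t"):
                sizes = tuple(int(x) for x in line.split("\t")[1:])
            elif line.startswith("folded\t"):
                folded = bool(int(line.split("\t")[1]))
            elif line.startswith("mask "):
                mask = np.array([bool(int(x)) for x in line.split()[1:]])
            else:
                counts = np.array([float(x) for x in line.split()])
    if counts is None:
        raise ValueError(f"no counts found in {path}")
    shape = tuple(s + 1 for s in sizes)
    return SFS(
        counts.reshape(shape),
        pops,
        sizes,
        folded,
        None if mask is None else mask.reshape(shape),
    )
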