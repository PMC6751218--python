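"""Read, filter and transform multi-population RAD-seq genotype tables.

The container couples a variant table (chrom, pos, alleles, per-sample allele
dosages and read depths) with a registry of monomorphic sequenced sites.  The
registry matters: site-frequency spectra and windowed statistics are normalised
per *sequenced* site, not per SNP, so invariant positions must travel with the
SNPs through every filter.

Filters mirror the standard RAD-seq pre-SFS chain: total-depth outlier removal
(upper IQR fence), biallelic autosomal SNP selection, per-genotype depth
masking with a site-level missingness cap, a one-sided Hardy-Weinberg
heterozygote-excess screen (PCR/paralog artifacts) with a positional buffer,
LD pruning, genotype subsampling to a complete-data panel, haploidisation
(allelic-dropout mimicry) and proportional re-addition of monomorphic sites.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import rng_from_seed

MISSING = -1


@dataclass
class Variant:
    """A single biallelic (or to-be-filtered multiallelic) site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # comma-joined if multiallelic at read time
    dosages: np.ndarray  # per-sample alt count in {0,1,2}, MISSING if no call
    depths: np.ndarray  # per-sample read depth
    rad_locus_id: str | None = None


@dataclass
class PopulationMap:
    assignments: dict[str, str]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def members(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def sample_indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            out.setdefault(self.assignments[s], []).append(i)
        return {p: np.asarray(ix, dtype=int) for p, ix in out.items()}


@dataclass
class GenotypeTable:
    """Variants x samples dosage/depth matrices plus monomorphic-site registry.

    Arrays are row-aligned: ``dosage[i]``/``depth[i]`` belong to
    ``(chrom[i], pos[i])``.  ``dosage`` uses -1 for missing.  ``ad_ref`` /
    ``ad_alt`` (allelic depths) are optional and only used by the
    allele-imbalance screen.  ``monomorphic`` maps chromosome -> sorted
    1-based positions of invariant sequenced sites.
    """

    samples: list[str]
    chrom: np.ndarray  # object dtype
    pos: np.ndarray  # int64
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # (n_var, n_samples) int8
    depth: np.ndarray  # (n_var, n_samples) int32
    rad_locus: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    monomorphic: dict[str, np.ndarray] = field(default_factory=dict)

    # -- basic introspection -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_monomorphic(self) -> int:
        return int(sum(len(v) for v in self.monomorphic.values()))

    def variant(self, i: int) -> Variant:
        return Variant(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alt=str(self.alt[i]),
            dosages=self.dosage[i],
            depths=self.depth[i],
            rad_locus_id=None if self.rad_locus is None else str(self.rad_locus[i]),
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosage=self.dosage[mask],
            depth=self.depth[mask],
            rad_locus=None if self.rad_locus is None else self.rad_locus[mask],
            ad_ref=None if self.ad_ref is None else self.ad_ref[mask],
            ad_alt=None if self.ad_alt is None else self.ad_alt[mask],
            monomorphic={c: v.copy() for c, v in self.monomorphic.items()},
        )

    def copy(self) -> "GenotypeTable":
        return self.subset_variants(np.ones(self.n_variants, dtype=bool))

    def sequenced_positions(self, chrom: str) -> np.ndarray:
        """Sorted union of variant and monomorphic positions on one chromosome."""
        var = self.pos[self.chrom == chrom]
        mono = self.monomorphic.get(chrom, np.empty(0, dtype=np.int64))
        return np.sort(np.concatenate([var, mono]))

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in list(self.chrom) + list(self.monomorphic):
            if c not in seen:
                seen.append(str(c))
        return seen


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_popmap(path: str) -> PopulationMap:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"popmap line {ln}: expected 'sample population', got {line!r}")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)


def read_vcf(path: str, popmap_path: str | None = None):
    """Parse a VCF with GT/DP (optionally AD) FORMAT fields.

    Invariant records (no ALT allele) are routed to the monomorphic-site
    registry.  Multiallelic records are retained as-is and later removed by
    :func:`filter_biallelic_autosomal`.

    Returns ``(GenotypeTable, PopulationMap)`` or just the table when no
    popmap is given.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)

    chroms, poss, refs, alts = [], [], [], []
    dosages, depths, adr, ada = [], [], [], []
    mono: dict[str, list[int]] = {}
    any_ad = False

    for rec in vcf:
        if not rec.ALT:  # invariant sequenced site
            mono.setdefault(rec.CHROM, []).append(rec.POS)
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(",".join(rec.ALT))
        # gts012: 0/1/2 = alt dosage, 3 = missing
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        dosages.append(gt)
        try:
            dp = rec.format("DP")
            dp = np.zeros(len(samples), dtype=np.int32) if dp is None else dp[:, 0].astype(np.int32)
        except Exception:
            dp = np.zeros(len(samples), dtype=np.int32)
        dp[dp < 0] = 0
        depths.append(dp)
        try:
            ad = rec.format("AD")
        except KeyError:  # AD not declared in the header
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            any_ad = True
            a = ad.astype(np.int32)
            a[a < 0] = 0
            adr.append(a[:, 0])
            ada.append(a[:, 1])
        else:
            adr.append(np.full(len(samples), -1, dtype=np.int32))
            ada.append(np.full(len(samples), -1, dtype=np.int32))

    n = len(poss)
    table = GenotypeTable(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=np.array(dosages, dtype=np.int8) if n else np.empty((0, len(samples)), np.int8),
        depth=np.array(depths, dtype=np.int32) if n else np.empty((0, len(samples)), np.int32),
        ad_ref=np.array(adr, dtype=np.int32) if any_ad else None,
        ad_alt=np.array(ada, dtype=np.int32) if any_ad else None,
        monomorphic={c: np.array(sorted(v), dtype=np.int64) for c, v in mono.items()},
    )
    # mask dosages where no depth was recorded is *not* applied here: depth
    # thresholds are an explicit filter step (mask_and_drop_missing).
    if popmap_path is None:
        return table, None
    popmap = read_popmap(popmap_path)
    unknown = [s for s in popmap.assignments if s not in samples]
    if unknown:
        raise ValueError(f"popmap sample(s) not present in VCF: {', '.join(sorted(unknown))}")
    missing = [s for s in samples if s not in popmap.assignments]
    if missing:
        raise ValueError(f"VCF sample(s) missing from popmap: {', '.join(sorted(missing))}")
    return table, popmap


def write_vcf(table: GenotypeTable, path: str, include_monomorphic: bool = True) -> None:
    """Write the table as a minimal VCF v4.2 (GT:DP, plus AD when present)."""
    has_ad = table.ad_ref is not None
    records: list[tuple[str, int, str]] = []
    for i in range(table.n_variants):
        fields = []
        for j in range(table.n_samples):
            d = int(table.dosage[i, j])
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(d, "./.")
            s = f"{gt}:{int(table.depth[i, j])}"
            if has_ad:
                r, a = int(table.ad_ref[i, j]), int(table.ad_alt[i, j])
                s += f":{r},{a}" if r >= 0 else ":.,."
            fields.append(s)
        fmt = "GT:DP:AD" if has_ad else "GT:DP"
        line = (
            f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t{table.alt[i]}"
            f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(fields)
        )
        records.append((str(table.chrom[i]), int(table.pos[i]), line))
    if include_monomorphic:
        nocall = "\t".join(["0/0:30"] * table.n_samples)
        for c, positions in table.monomorphic.items():
            for p in positions:
                records.append((c, int(p), f"{c}\t{p}\t.\tN\t.\t.\tPASS\t.\tGT:DP\t{nocall}"))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n")
        for _, _, line in records:
            fh.write(line + "\n")


def write_monomorphic_registry(table: GenotypeTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\n")
        for c in sorted(table.monomorphic):
            for p in table.monomorphic[c]:
                fh.write(f"{c}\t{p}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_depth_iqr(table: GenotypeTable, factor: float = 1.5) -> GenotypeTable:
    """Drop sites whose total depth exceeds Q3 + factor x IQR (upper fence).

    Quartiles use linear interpolation on per-site total depths.  Sites at
    exactly the fence are kept (cutoff is strict `>`), so an all-equal depth
    distribution (IQR = 0) passes unchanged.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if table.n_variants == 0:
        warnings.warn("filter_depth_iqr: empty table")
        return table.copy()
    total = table.depth.sum(axis=1).astype(float)
    q1, q3 = np.percentile(total, [25, 75])
    fence = q3 + factor * (q3 - q1)
    return table.subset_variants(total <= fence)


def filter_biallelic_autosomal(table: GenotypeTable, sex_chrom: str = "chrXIX") -> GenotypeTable:
    """Keep biallelic SNPs on autosomes (drop indels, sex chromosome, multiallelics)."""
    keep = np.ones(table.n_variants, dtype=bool)
    for i in range(table.n_variants):
        ref, alt = str(table.ref[i]), str(table.alt[i])
        if table.chrom[i] == sex_chrom or "," in alt or len(ref) != 1 or len(alt) != 1:
            keep[i] = False
    out = table.subset_variants(keep)
    out.monomorphic.pop(sex_chrom, None)
    return out


def mask_and_drop_missing(table: GenotypeTable, min_depth: int = 10, max_missing: float = 0.5) -> GenotypeTable:
    """Mask genotypes below `min_depth` reads; drop sites > `max_missing` missing."""
    if min_depth < 0 or not (0 <= max_missing <= 1):
        raise ValueError("min_depth >= 0 and 0 <= max_missing <= 1 required")
    out = table.copy()
    if min_depth > 0:
        out.dosage = out.dosage.copy()
        out.dosage[out.depth < min_depth] = MISSING
    if out.n_variants == 0:
        return out
    frac = (out.dosage == MISSING).mean(axis=1)
    return out.subset_variants(frac <= max_missing)


def hwe_het_excess_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """One-sided exact P(het >= observed) under Hardy-Weinberg.

    Conditional on the observed allele counts, the number of heterozygotes is
    distributed over {n_alt mod 2, +2, ...}; probabilities follow the standard
    exact recurrence (Wigginton et al.'s formulation).
    """
    n = n_het + n_hom_ref + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_alt = min(n_alt, 2 * n - n_alt)  # rare allele count
    if n == 0 or n_alt == 0:
        return 1.0
    hets = list(range(n_alt % 2, n_alt + 1, 2))
    # unnormalised probabilities via recurrence
    probs = {hets[0]: 1.0}
    for h in hets[:-1]:
        hom_r = (n_alt - h) // 2  # rare homozygotes
        hom_c = n - h - hom_r
        nxt = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        probs[h + 2] = nxt
    z = sum(probs.values())
    return float(sum(v for h, v in probs.items() if h >= n_het) / z)


def hwe_het_excess_filter(
    table: GenotypeTable,
    popmap: PopulationMap,
    alpha: float = 0.05,
    buffer_bp: int = 100,
) -> GenotypeTable:
    """Remove heterozygote-excess sites (per-population exact test) plus a buffer.

    A site flagged in *any* population is removed together with every sequenced
    site (variant or monomorphic) within `buffer_bp` of it — the union over
    populations.  Populations with fewer than 2 genotyped diploids at a site
    are skipped for that site.
    """
    idx = popmap.sample_indices(table.samples)
    flagged: dict[str, list[int]] = {}
    for i in range(table.n_variants):
        for pop, cols in idx.items():
            d = table.dosage[i, cols]
            d = d[d != MISSING]
            if len(d) < 2:
                continue
            n_het = int((d == 1).sum())
            p = hwe_het_excess_pvalue(n_het, int((d == 0).sum()), int((d == 2).sum()))
            if p < alpha:
                flagged.setdefault(str(table.chrom[i]), []).append(int(table.pos[i]))
                break
    keep = np.ones(table.n_variants, dtype=bool)
    new_mono: dict[str, np.ndarray] = {}
    for c in table.chromosomes():
        bad = np.array(sorted(set(flagged.get(c, []))), dtype=np.int64)
        cmask = table.chrom == c
        if len(bad):
            positions = table.pos[cmask]
            near = np.array([np.any(np.abs(bad - p) <= buffer_bp) for p in positions])
            keep[np.where(cmask)[0][near]] = False
            mono = table.monomorphic.get(c, np.empty(0, dtype=np.int64))
            mkeep = np.array([not np.any(np.abs(bad - p) <= buffer_bp) for p in mono], dtype=bool)
            if len(mono):
                new_mono[c] = mono[mkeep]
        elif c in table.monomorphic:
            new_mono[c] = table.monomorphic[c].copy()
    out = table.subset_variants(keep)
    out.monomorphic = new_mono
    return out


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Genotypic r^2 over samples non-missing at both sites; 0 if undefined."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(table: GenotypeTable, r2_max: float = 0.95, window_bp: int = 200) -> GenotypeTable:
    """Greedy left-to-right LD pruning: drop the later member of violating pairs."""
    keep = np.ones(table.n_variants, dtype=bool)
    order = np.lexsort((table.pos, table.chrom.astype(str)))
    kept_by_chrom: dict[str, list[int]] = {}
    for i in order:
        c = str(table.chrom[i])
        p = int(table.pos[i])
        kept = kept_by_chrom.setdefault(c, [])
        drop = False
        for j in reversed(kept):
            if p - int(table.pos[j]) > window_bp:
                break
            if _r2(table.dosage[i], table.dosage[j]) > r2_max:
                drop = True
                break
        if drop:
            keep[i] = False
        else:
            kept.append(i)
    return table.subset_variants(keep)


def subsample_genotypes(table: GenotypeTable, k_per_pop: dict[str, int], popmap: PopulationMap, seed: int) -> tuple[GenotypeTable, PopulationMap]:
    """Subsample a fixed number of diploid genotypes per population at every site.

    Sites where any population has fewer than k non-missing genotypes are
    discarded; elsewhere exactly k genotypes per population are drawn without
    replacement.  Because the chosen individuals differ between sites, the
    output table carries k pseudo-samples per population (``pop_1..pop_k``)
    and is guaranteed free of missing data.
    """
    idx = popmap.sample_indices(table.samples)
    for pop, k in k_per_pop.items():
        if pop not in idx:
            raise ValueError(f"population {pop!r} not in popmap")
        if k > len(idx[pop]):
            raise ValueError(f"k={k} exceeds population size {len(idx[pop])} for {pop!r}")
    rng = rng_from_seed(seed)
    pops = list(k_per_pop)
    new_samples = [f"{p}_{i+1}" for p in pops for i in range(k_per_pop[p])]
    keep_rows, new_dos, new_dep = [], [], []
    for i in range(table.n_variants):
        row_d, row_p, ok = [], [], True
        for p in pops:
            cols = idx[p]
            good = cols[table.dosage[i, cols] != MISSING]
            if len(good) < k_per_pop[p]:
                ok = False
                break
            chosen = rng.choice(good, size=k_per_pop[p], replace=False)
            row_d.extend(table.dosage[i, chosen])
            row_p.extend(table.depth[i, chosen])
        if ok:
            keep_rows.append(i)
            new_dos.append(row_d)
            new_dep.append(row_p)
    keep_rows = np.array(keep_rows, dtype=int)
    out = table.subset_variants(np.isin(np.arange(table.n_variants), keep_rows))
    out.samples = new_samples
    out.dosage = np.array(new_dos, dtype=np.int8) if len(new_dos) else np.empty((0, len(new_samples)), np.int8)
    out.depth = np.array(new_dep, dtype=np.int32) if len(new_dep) else np.empty((0, len(new_samples)), np.int32)
    out.ad_ref = out.ad_alt = None
    new_map = PopulationMap({f"{p}_{i+1}": p for p in pops for i in range(k_per_pop[p])})
    return out, new_map


def haploidize(table: GenotypeTable, seed: int) -> GenotypeTable:
    """Resolve each heterozygote to a fake homozygote (0 or 2 with prob 1/2)."""
    rng = rng_from_seed(seed)
    out = table.copy()
    out.dosage = out.dosage.copy()
    het = out.dosage == 1
    out.dosage[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    return out


def rebalance_monomorphic(table: GenotypeTable, n_snps_pre: int, seed: int) -> GenotypeTable:
    """Downsample monomorphic sites proportionally to SNPs surviving LD pruning.

    N = round(M_pre x S_retained / S_pre) monomorphic sites are kept, drawn
    uniformly without replacement across the genome.
    """
    if n_snps_pre <= 0:
        raise ValueError("n_snps_pre must be positive")
    m_pre = table.n_monomorphic
    n_keep = int(round(m_pre * table.n_variants / n_snps_pre))
    if n_keep >= m_pre:
        if n_keep > m_pre:
            warnings.warn("rebalance_monomorphic: requested more monomorphic sites than available; keeping all")
        return table.copy()
    rng = rng_from_seed(seed)
    flat = [(c, int(p)) for c in sorted(table.monomorphic) for p in table.monomorphic[c]]
    chosen_idx = rng.choice(len(flat), size=n_keep, replace=False)
    chosen: dict[str, list[int]] = {}
    for i in chosen_idx:
        c, p = flat[i]
        chosen.setdefault(c, []).append(p)
    out = table.copy()
    out.monomorphic = {c: np.array(sorted(v), dtype=np.int64) for c, v in chosen.items()}
    return out


def flag_allele_imbalance_individuals(table: GenotypeTable, threshold: float = 0.3) -> list[str]:
    """Flag individuals whose heterozygous calls deviate strongly from 1:1 reads.

    Per individual: mean of minor/(minor+major) allelic depth over heterozygous
    genotypes; individuals with a mean below `threshold` are flagged.  Requires
    AD fields; returns an empty list (with a warning) when absent.
    """
    if table.ad_ref is None or table.ad_alt is None:
        warnings.warn("allele-imbalance screen skipped: no allelic depths (AD) in table")
        return []
    flagged = []
    for j, sample in enumerate(table.samples):
        het = table.dosage[:, j] == 1
        r = table.ad_ref[het, j].astype(float)
        a = table.ad_alt[het, j].astype(float)
        ok = (r >= 0) & (a >= 0) & (r + a > 0)
        if not ok.any():
            continue
        minor = np.minimum(r[ok], a[ok])
        frac = minor / (r[ok] + a[ok])
        if frac.mean() < threshold:
            flagged.append(sample)
    return flagged
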