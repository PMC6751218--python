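"""Synthetic RAD-seq fixtures: scenario VCFs, admixture cohorts, genetic maps.

These generators stand in for the study's raw sequence data so that every
pipeline stage is testable offline.  A scenario VCF emulates RAD-locus
structure (short contiguous loci around restriction sites; 200 bp = 100 bp
up- and downstream of a cut site by default), per-genotype negative-binomial
read depths with locus-dropout missingness, and multi-population genotype
frequencies drawn from a catalog coalescent model.  The admixture-cohort
generator exercises the diagnostic-SNP / hybrid-index machinery; the
genetic-map generator produces linear-plus-noise maps with designated
low-recombination segments for the recombination-rate filter.

Every generator is deterministic under a fixed seed and writes a truth
record so downstream tests compare generated against recovered values.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import msprime
import numpy as np

from ._util import spawn_seeds
from .demographic_models import DemographicModel, get_model
from .genotype_data import MISSING, GenotypeTable, PopulationMap
from .recomb_map import GeneticMap
from .admixture_stats import DiagnosticPanel

_BASES = ("A", "C", "G", "T")


@dataclass
class ScenarioSpec:
    model: str | DemographicModel = "3a"
    params: dict[str, float] | None = None
    sample_sizes: dict[str, int] | None = None  # diploids per population
    n_rad_loci: int = 2500
    locus_length: int = 200
    n_chromosomes: int = 4
    locus_spacing_bp: int = 20_000
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0  # negative-binomial shape; larger = tighter
    dropout_rate: float = 0.05  # per sample x locus
    seed: int = 0

    def __post_init__(self):
        if self.n_rad_loci < 1:
            raise ValueError("n_rad_loci must be >= 1")
        if not (0 <= self.dropout_rate <= 1):
            raise ValueError("dropout_rate must be in [0, 1]")

    def resolve_model(self) -> DemographicModel:
        return get_model(self.model) if isinstance(self.model, str) else self.model


def simulate_scenario_table(spec: ScenarioSpec) -> tuple[GenotypeTable, PopulationMap, dict]:
    """Simulate a genotype table under a catalog model (RAD-locus geometry).

    Each RAD locus is an independent non-recombining coalescent replicate of
    `locus_length` sites with infinite-sites binary mutations at the model's
    rate.  Depth and dropout are overlaid afterwards; genotypes at dropped-out
    sample x locus pairs are set missing with depth 0.
    """
    model = spec.resolve_model()
    params = model.params_with_defaults(spec.params)
    sizes = spec.sample_sizes or model.default_sample_sizes()
    if not sizes:
        raise ValueError("no sampled populations in the scenario")
    dem = model.to_demography(params)
    pops = list(sizes)
    samples = [f"{p}_{i+1}" for p in pops for i in range(sizes[p])]
    popmap = PopulationMap({f"{p}_{i+1}": p for p in pops for i in range(sizes[p])})
    anc_seed, mut_seed, depth_seed = spawn_seeds(spec.seed, 3)
    rng = np.random.default_rng(depth_seed)

    pop_ids = {p.name: i for i, p in enumerate(dem.populations)}
    reps = msprime.sim_ancestry(
        samples={p: n for p, n in sizes.items()},
        demography=dem,
        sequence_length=spec.locus_length,
        recombination_rate=0,
        num_replicates=spec.n_rad_loci,
        random_seed=anc_seed,
        ploidy=2,
    )
    mut_rng = np.random.default_rng(mut_seed)

    chroms, poss, refs, alts, dosages = [], [], [], [], []
    mono: dict[str, list[int]] = {}
    locus_of_chrom: list[tuple[str, int, int]] = []
    per_chrom = int(np.ceil(spec.n_rad_loci / spec.n_chromosomes))
    locus_sample_order: list[np.ndarray] = []

    for locus_i, ts in enumerate(reps):
        ts = msprime.sim_mutations(
            ts, rate=model.mu, random_seed=int(mut_rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(), discrete_genome=True,
        )
        chrom = f"chr{locus_i // per_chrom + 1}"
        locus_start = (locus_i % per_chrom) * spec.locus_spacing_bp + 1
        locus_of_chrom.append((chrom, locus_start, locus_start + spec.locus_length - 1))
        # order haplotype pairs by population to match `samples`
        cols = np.concatenate([
            ts.samples(population=pop_ids[p]) for p in pops
        ])
        locus_sample_order.append(cols)
        var_offsets = set()
        for var in ts.variants():
            g = np.array(var.genotypes)[cols]
            if len(set(var.alleles) - {None}) != 2:
                continue  # recurrent-hit site collapsed to >2 alleles: skip
            offset = int(var.site.position)
            if offset in var_offsets or offset >= spec.locus_length:
                continue
            dos = (g[0::2] + g[1::2]).astype(np.int8)
            if dos.min() == dos.max():
                continue  # monomorphic in sample
            var_offsets.add(offset)
            ref, alt = mut_rng.choice(len(_BASES), size=2, replace=False)
            chroms.append(chrom)
            poss.append(locus_start + offset)
            refs.append(_BASES[ref])
            alts.append(_BASES[alt])
            dosages.append(dos)
        for off in range(spec.locus_length):
            if off not in var_offsets:
                mono.setdefault(chrom, []).append(locus_start + off)

    n_var = len(poss)
    n_samp = len(samples)
    dosage = np.array(dosages, dtype=np.int8) if n_var else np.empty((0, n_samp), np.int8)
    # depth overlay: NB(mean, dispersion); dropout zeroes a sample x locus pair
    p_nb = spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean)
    depth = rng.negative_binomial(spec.depth_dispersion, p_nb, size=(n_var, n_samp)).astype(np.int32)
    if spec.dropout_rate > 0 and n_var:
        drop = rng.random((len(locus_of_chrom), n_samp)) < spec.dropout_rate
        pos_arr = np.array(poss)
        chrom_arr = np.array(chroms, dtype=object)
        for li, (c, s, e) in enumerate(locus_of_chrom):
            rows = np.where((chrom_arr == c) & (pos_arr >= s) & (pos_arr <= e))[0]
            for j in np.where(drop[li])[0]:
                depth[rows, j] = 0
    dosage = dosage.copy()
    dosage[depth == 0] = MISSING
    # allelic depths: binomial split at hets, all reads on the called allele otherwise
    ad_alt = np.where(dosage == 1, rng.binomial(np.maximum(depth, 0), 0.5),
                      np.where(dosage == 2, depth, 0)).astype(np.int32)
    ad_ref = (depth - ad_alt).astype(np.int32)
    ad_ref[dosage == MISSING] = -1
    ad_alt[dosage == MISSING] = -1

    order = np.lexsort((np.array(poss), np.array(chroms, dtype=str))) if n_var else np.array([], int)
    table = GenotypeTable(
        samples=samples,
        chrom=np.array(chroms, dtype=object)[order],
        pos=np.array(poss, dtype=np.int64)[order],
        ref=np.array(refs, dtype=object)[order],
        alt=np.array(alts, dtype=object)[order],
        dosage=dosage[order],
        depth=depth[order],
        ad_ref=ad_ref[order],
        ad_alt=ad_alt[order],
        monomorphic={c: np.array(sorted(v), dtype=np.int64) for c, v in mono.items()},
    )
    truth = {
        "model_id": model.model_id,
        "params": params,
        "sample_sizes": sizes,
        "n_rad_loci": spec.n_rad_loci,
        "locus_length": spec.locus_length,
        "n_snps": int(n_var),
        "seed": spec.seed,
    }
    return table, popmap, truth


def generate_scenario_vcf(spec: ScenarioSpec, out_prefix: str) -> tuple[str, str, str]:
    """Write `<prefix>.vcf`, `<prefix>.popmap`, `<prefix>.truth.json`."""
    from .genotype_data import write_vcf

    table, popmap, truth = simulate_scenario_table(spec)
    vcf_path = f"{out_prefix}.vcf"
    pop_path = f"{out_prefix}.popmap"
    truth_path = f"{out_prefix}.truth.json"
    write_vcf(table, vcf_path)
    with open(pop_path, "w") as fh:
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return vcf_path, pop_path, truth_path


# ---------------------------------------------------------------------------
# Diagnostic-panel admixture cohort
# ---------------------------------------------------------------------------

def generate_admixture_cohort(
    n_individuals: int = 8,
    n_loci: int = 299,
    west_prob: float = 0.44,
    seed: int = 0,
    n_parental: int = 4,
    spacing_bp: int = 100_000,
    depth: int = 30,
) -> tuple[GenotypeTable, PopulationMap, DiagnosticPanel]:
    """Cohort of admixed diploids genotyped at divergently fixed panel loci.

    Parental groups WEST/EAST are fixed for opposite alleles at every locus;
    each allele of an admixed individual is West-derived with probability
    `west_prob`.  Loci are spaced `spacing_bp` apart.
    """
    if not (0 <= west_prob <= 1):
        raise ValueError("west_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = (
        [f"WEST_{i+1}" for i in range(n_parental)]
        + [f"EAST_{i+1}" for i in range(n_parental)]
        + [f"ADM_{i+1}" for i in range(n_individuals)]
    )
    popmap = PopulationMap(
        {s: s.split("_")[0] for s in samples}
    )
    loci_per_chrom = int(np.ceil(n_loci / 4))
    chroms, poss = [], []
    for i in range(n_loci):
        chroms.append(f"chr{i // loci_per_chrom + 1}")
        poss.append((i % loci_per_chrom) * spacing_bp + 1)
    # West allele = alt everywhere (simple, and exercised by panel discovery)
    west = np.full((n_loci, n_parental), 2, dtype=np.int8)
    east = np.zeros((n_loci, n_parental), dtype=np.int8)
    adm = (
        (rng.random((n_loci, n_individuals)) < west_prob).astype(np.int8)
        + (rng.random((n_loci, n_individuals)) < west_prob).astype(np.int8)
    )
    dosage = np.concatenate([west, east, adm], axis=1)
    table = GenotypeTable(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["G"] * n_loci, dtype=object),
        dosage=dosage,
        depth=np.full((n_loci, len(samples)), depth, dtype=np.int32),
    )
    panel = DiagnosticPanel(
        loci=[(c, int(p), "G", "A") for c, p in zip(chroms, poss)],
        spacing_bp=spacing_bp,
    )
    return table, popmap, panel


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

def generate_genetic_map(
    chrom_lengths: dict[str, int],
    base_rate: float = 3.0,
    low_rate: float = 0.5,
    low_rate_fraction: float = 0.0,
    marker_spacing_bp: int = 100_000,
    cm_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GeneticMap, dict]:
    """Piecewise-linear genetic map with optional low-recombination middle segment.

    `base_rate` (cM/Mb) applies genome-wide except on a central segment of
    `low_rate_fraction` of each chromosome, which recombines at `low_rate`.
    Optional Gaussian noise (`cm_noise_sd`, cM) perturbs marker genetic
    positions (monotonicity enforced).  Returns the map and a truth record of
    segment boundaries and rates.
    """
    if low_rate_fraction and not (base_rate > 1.5 > low_rate):
        raise ValueError("expect base_rate > 1.5 cM/Mb > low_rate for the rate filter to be exercised")
    rng = np.random.default_rng(seed)
    gm = GeneticMap()
    truth: dict = {"base_rate": base_rate, "low_rate": low_rate, "segments": {}}
    for c, length in chrom_lengths.items():
        bp = np.arange(0, length + 1, marker_spacing_bp, dtype=float)
        if bp[-1] != length:
            bp = np.append(bp, float(length))
        if low_rate_fraction > 0:
            lo = length * (0.5 - low_rate_fraction / 2)
            hi = length * (0.5 + low_rate_fraction / 2)
        else:
            lo = hi = None
        if lo is not None:
            rate_at = np.where((bp >= lo) & (bp < hi), low_rate, base_rate)
        else:
            rate_at = np.full_like(bp, base_rate)
        seg_rates = rate_at[:-1] if len(rate_at) > 1 else rate_at
        cm = np.concatenate([[0.0], np.cumsum(np.diff(bp) * seg_rates / 1e6)])
        if cm_noise_sd > 0:
            cm = cm + rng.normal(0, cm_noise_sd, size=len(cm))
            cm = np.maximum.accumulate(cm)
            cm -= cm[0]
        gm.add_chromosome(c, bp, cm)
        truth["segments"][c] = {"low_start": lo, "low_end": hi}
    return gm, truth
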