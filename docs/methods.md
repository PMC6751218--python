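# Methods

`lakestream` re-implements, as a tested library, the population-genomic
inference chain used to reconstruct the origin of Lake Constance stickleback
ecotypes: RAD-seq genotype filtering, multidimensional site-frequency
spectra (SFS), hierarchical coalescent demographic model comparison by
composite likelihood, admixture statistics (ABBA-BABA D, hybrid index),
windowed differentiation/diversity landscapes, and genomic-island
permutation tests with West/East ancestry painting.  This note documents the
models, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Genotype filtering

The pre-SFS chain operates on a `GenotypeTable` that couples biallelic SNPs
(per-sample allele dosage and read depth) with a registry of monomorphic
sequenced sites — the registry is essential because SFS likelihoods and
windowed statistics are normalised per sequenced site, not per SNP.

Filters, in their canonical order:

1. **Total-depth fence** — sites with total depth above `Q3 + 1.5 x IQR`
   of the raw per-site depth distribution are removed (repeat/paralog
   collapse).  Quartiles use linear interpolation; the cutoff is strict
   (`>`), so a zero-IQR distribution passes unchanged.
2. **Biallelic autosomal SNPs** — indels, multiallelic sites and the sex
   chromosome (default `chrXIX`) are dropped.
3. **Depth masking** — genotypes under 10 reads become missing; sites with
   more than 50% missing genotypes are dropped.
4. **Heterozygote-excess screen** — per population, a one-sided exact
   Hardy-Weinberg test toward heterozygote excess (exact conditional
   distribution of heterozygote counts given allele counts); flagged sites
   plus every sequenced site within a 100 bp buffer are removed, unioned
   over populations.  Default alpha 0.05 (the test and level are package
   choices; only the screen itself and the buffer are prescribed).
5. **LD pruning** — greedy left-to-right scan; the later member of any pair
   with genotypic r² > 0.95 within 200 bp (SFS chain) or 100 kb (clustering
   chain) is dropped.
6. **Genotype subsampling** — at every site, exactly k genotypes per
   population drawn without replacement among non-missing calls; sites with
   fewer than k callable genotypes in any population are discarded.  The
   output holds k pseudo-samples per population (`pop_1..pop_k`), which is
   what makes "no missing data" literally true when the chosen individuals
   differ between sites.
7. **Haploidisation** — heterozygotes become fake homozygotes (0 or 2 with
   probability 1/2), mimicking allelic dropout so all samples share it.
8. **Monomorphic rebalancing** — after pruning S of S_pre SNPs, N =
   round(M_pre x S / S_pre) monomorphic sites are retained, drawn uniformly.

An allele-imbalance screen flags individuals whose mean minor-read fraction
over heterozygous calls falls below 0.3 (configurable; requires AD fields).

## Site-frequency spectra

The k-dimensional SFS counts sites by per-population alternate-allele count;
dimension p has length 2n_p + 1 and the all-zero corner holds monomorphic
sites, so the array total is the number of sequenced sites.  Folding uses
the *global* minor allele: a cell whose total allele count exceeds half the
total sample size is added to its complement (2n - v); cells exactly at half
stay in place once — a tie convention that conserves totals (whether the
original analysis halved ties instead is not recoverable; the difference
touches only the exact-half class).  Singleton masking flags cells with
total count 1 (and 2n-1 when unfolded) through an explicit mask rather than
zeroing, so totals stay interpretable.  Block bootstrap resamples runs of
10,000 consecutive sequenced sites within chromosomes, with replacement, to
the observed block count.

## Demographic model catalog

Three hierarchical levels (all parameter units follow the reporting
convention: sizes N_i in 2N_e units, pulses a_ij in percent of the target,
migration m_ij as 2N_e·m migrants per generation forward in time, times in
generations):

* **3-population**: branching orders of upper Rhone, Rhine (West) and
  Vistula (East); `3a` groups the West lineages, `3b`/`3c` the
  alternatives, `3d` a trichotomy.
* **4-population**: one Constance population attached to the Rhone (`3Lo`),
  Rhine (`3Li`) or Vistula (`3Lv`; `3S*` for streams), with optional
  admixture pulses from the Rhone ('o'), Rhine ('i') or both ('x').
* **5-population ecotype-divergence modes**: primary divergence (`PD`),
  ecological vicariance (`EVa`: lake derived from the stream lineage;
  `EVb`: lake and stream colonised separately), secondary contact
  (`SCi`/`SCo`: lake = East lineage, stream = a West lineage, with gene
  flow since contact), and hybrid origin `HO{a,b,c}{x,i,o}` — an
  East-derived lake-stream pair receiving West pulse(s) into the stream
  ('a'), the lake ('b') or their common ancestor ('c').  All 5-population
  models carry a lake-stream migration epoch until the ecotype split.
  The a/b/c pulse-target assignment is an interpretive reconstruction (the
  source material describes the variants only collectively); the catalog
  keeps it explicit and configurable through the model-building API.

The msprime translation divides sizes by two (diploid N), converts a
forward pulse into `dest` into a backward mass migration `dest -> source`
with proportion a/100 (multiple pulses at one time compose sequentially),
and converts forward migrant counts M_ab into the backward per-lineage rate
`M_ab / S_b` (fraction of the recipient replaced per generation, S_b the
recipient size in 2N_e units).  Event-time consistency (split ordering,
pulse activity windows) is validated before every simulation.

### Best-estimate parameter sets

`best_estimates()` packages the maximum-likelihood parameterizations used by
the synthetic-data generators and the acceptance protocol: the West-East
split at 3665 and Rhone-Rhine at 1710 generations; Rhine/Rhone pulse pairs
of 6.7/0.7 % (L2), 16.6/0.1 % (S2) and 27.2/0.2 % (NID); hybrid-origin
scenarios with lake-stream splits at 408 (L2-S2), 1276 (ROM-NID), 2819
(ROM-BOH) and 1065 (ROM-GRA) generations and West contributions of 14, 31,
32 and 48 % respectively ('x' totals split Rhine-dominant); lake sizes
2N_e = 3713 (L2) and 8473 (ROM); and a NID hybrid index of 0.44.  Sizes of
the three allopatric lineages and of the ancestral populations are not part
of that reported set; the catalog fixes them once at realistic values
(Rhone 4000, Rhine 2000, Vistula 6000, West ancestor 1e5, root 3e5, all
2N_e), with the deep sizes chosen so that simulated RAD polymorphism
density (~2.7% of sequenced sites at the 3-population sample sizes) is on
the order of the density of the empirical RAD datasets (~5%).  Colonisation
and pulse times not in the reported set are fixed at round values
consistent with the event ordering (e.g. L2-S2 contact at 700, colonisation
at 1500 generations).  The ROM scenarios model all three allopatric
lineages as unsampled ghost demes fixed to the 3a estimates (the
denser-data protocol); the L2-S2 scenario additionally samples the Rhine —
its fits sampled the sister lineages, and the ancestor-pulse proportion is
only weakly identified from the lake-stream joint SFS alone.

## Expected SFS and composite likelihood

The expected per-site SFS under a model is approximated from `n_sims`
independent single-site coalescent replicates: the branch-mode
allele-frequency spectrum (total branch length subtending each frequency
configuration) is averaged over replicates and multiplied by the mutation
rate (1.7e-8 per site per generation), giving the probability of each
polymorphic configuration; the monomorphic corner takes the remainder.
This is per-site Poisson mutation placement with the placement integrated
out — identical in expectation, with substantially lower Monte Carlo
variance per replicate.  Folding reuses the SFS fold.

The composite log10-likelihood of an observed SFS is `sum_i m_i log10 p_i`
over unmasked cells, monomorphic corner included by default (a
polymorphic-only switch renormalises without it).  Expected probabilities
are floored at `1/(10 n_sims)` so Monte-Carlo zeros cannot yield -inf.
Model comparison reports ΔLL against the saturated (observed-proportions)
likelihood — the table convention — and ΔAIC with
`AIC = 2k - 2 ln(10) LL10`; only AIC differences are meaningful.

**Optimization.**  `fit_model` runs ECM-style cycles of bounded 1-D line
searches over each free parameter (Brent, bounded), cycle count clamped to
[10, 50] by default with relative stopping tolerance 0.001, best of 100
random starts at full scale (log-uniform starts for sizes/times, uniform
for proportions); all knobs scale down for desk-size experiments.  Every
likelihood evaluation within one fit reuses one simulation seed, making the
objective deterministic.  A `grid` mode evaluates a fixed factorial
parameter grid instead; because grid points are data-independent,
`grid_fit_replicates` shares each expected SFS across many replicate
datasets — the economical protocol for model-recovery experiments.

**Uncertainty and distinguishability.**  95% CIs are empirical 2.5/97.5
percentiles over block-bootstrap replicates, each refit by several short
optimizations started from the (perturbed) ML parameters.  Model
distinguishability simulates replicate datasets under each candidate and
reports the overlap coefficient of the ΔLL distributions for each model
pair (1 = indistinguishable, 0 = cleanly separated).

## Recombination rates

cM(bp) per chromosome is smoothed with a cubic spline and differentiated;
rates are the derivative x 1e6 (cM/Mb), clipped at zero.  The smoothing
parameter p in (0, 1] maps to scipy's residual target
`s = ((1-p)/p) n sigma²`, with sigma² estimated from second differences of
the genetic positions — so any noiseless (piecewise-)linear map is
interpolated exactly regardless of p, and the default p = 0.7 applies a
moderate penalty on noisy maps.  The exact smoothing semantics of the
original tool are not recoverable; analytic test maps are insensitive to
this choice.  Sites in regions below 1.5 cM/Mb are excluded before SFS
construction (linked-selection guard); per-window rates average 10 equally
spaced evaluations spanning the window, endpoints included.

## Windowed statistics

Non-overlapping windows accumulate whole RAD loci (contiguous runs of
sequenced positions) until at least 2500 sequenced sites, never splitting a
locus; sliding windows use 1 Mb / 200 kb coordinates.  Per-SNP
differentiation uses the Weir-Cockerham (1984) two-allele variance
components for unequal sample sizes (among-population component a over
a+b+c, with the within-individual level retained); window FST is the ratio
of summed components ("ratio of averages"), which weights SNPs by their
information content.  π and d_XY come from each window's 1D/2D SFS over a
complete-data table (75% of each population's individuals, rounded down):

    π    = (1/L) Σ_i  ξ_i 2 i (n-i) / (n (n-1))
    d_XY = (1/L) Σ_ij S_ij [ (i/n1)(1-j/n2) + (j/n2)(1-i/n1) ]

with L the window's sequenced sites; both equal direct averages of pairwise
differences, and the test suite asserts that equality exactly.  Landscape
correlations are Pearson r over complete windows; comparisons of pairwise
statistics can require disjoint population pairs to avoid shared-population
autocorrelation.

## Admixture statistics

D uses population allele frequencies after polarising each site on the
(fixed) outgroup major allele:

    D = Σ[(1-p̂1)p̂2p̂3 - p̂1(1-p̂2)p̂3] / Σ[(1-p̂1)p̂2p̂3 + p̂1(1-p̂2)p̂3]

with a delete-one block jackknife (default 5 Mb blocks; the original block
size is unstated) for the standard error and a |Z| >= 3 significance
convention.  Diagnostic panels are SNPs divergently fixed between East and
West reference groups, at least 3 genotyped diploids per group, greedily
spaced >= 100 kb.  The hybrid index is the closed-form allele-count
estimator h = (#West alleles)/(2 x #loci) with exact (Clopper-Pearson)
binomial 95% bounds — for divergently fixed codominant markers this is the
maximum-likelihood estimate, making the closed form equivalent to the
numerical ML of dedicated packages.

## Island tests and ancestry painting

The island permutation test relocates each island uniformly (chromosome
chosen with probability proportional to its length, no wraparound, lengths
preserved) 10,000 times, recomputes the mean weighted FST of overlapped
windows, and reports a two-sided empirical p with add-one correction and
5%/1% flags.  Whether permutations should stay on the source chromosome is
an open question; the genome-wide universe is the default.  Ancestry
painting labels SNPs with |p_lake - p_stream| >= 0.5 by parental origin
when |p_West - p_East| >= 0.9 (both thresholds configurable; only "strong
differences" is prescribed): 'blue' = lake East / stream West, 'red' = the
reverse.

## Synthetic data

The scenario generator emulates RAD geometry: independent non-recombining
loci of 200 bp (100 bp either side of a cut site) spaced along chromosomes,
genotypes simulated per locus under a catalog model with binary
infinite-sites mutations, negative-binomial per-genotype depths (mean 30),
and sample-x-locus dropout that zeroes depth and masks genotypes.  Allelic
depths split binomially at heterozygotes.  It does **not** emulate
alignment or genotyping error, base-quality structure, PCR-duplicate
allelic imbalance beyond dropout, indels, linked selection, or recombination
within loci — so passing tests validate the statistical chain, not
robustness to raw-data artefacts.  The cohort generator produces parental
groups fixed for opposite alleles at 299 loci >= 100 kb apart plus admixed
individuals whose alleles are West-derived with a given probability; the
map generator produces piecewise-linear maps with a designated
low-recombination segment and optional marker noise.  All generators are
deterministic under a fixed seed and write truth records.

## Recovery protocol and problem sizes

The acceptance protocol (`lakestream.recovery`, `scripts/acceptance.py`)
simulates an observed folded SFS of 5e5 sequenced sites (multinomial draw
from a 30,000-replicate expected SFS) under a best-estimate scenario and
re-estimates one focal parameter by profile composite likelihood, all other
parameters fixed at their generating values.  Profiles are evaluated on
fixed grids containing the generating value — geometric steps of 2^(1/7)
(~10%) for times, 1-percentage-point steps for pulse proportions — with a
common simulation seed across grid points and 30,000 replicates per point;
grid points violating event-ordering constraints are skipped.  Recovery is
reported at grid resolution, the appropriate scale for these problem sizes.

Simulated likelihoods carry heavy-tailed Monte-Carlo noise: cells observed
a handful of times but assigned tiny, noisy expected probabilities can
shift a likelihood by several log10 units between simulation batches.
When the two leading grid points are separated by less than 10 log10 units
(the stage-1 noise scale) *and* differ materially (by at least 5% of the
parameter value), a second stage re-compares just those two candidates:
five independent batches of 30,000 replicates each evaluate a tail-pooled
likelihood — cells observed at most twice are aggregated into one class,
removing most of the rare-cell noise at its source — and the candidate
winning the median likelihood difference is reported.  The median over
batches is robust to the residual outlier batches that rare cells still
produce.  All stage constants are uniform across recovery targets.
The hybrid-index
calibration scores a synthetic 8-individual, 299-locus cohort at the
catalog's West-allele probability through panel discovery and the
allele-count estimator.  Model-recovery experiments (topology selection
among the 3-population models) use 20 replicate spectra of 1e5 sites and
shared-grid fits.  These sizes are the package's desk-scale defaults; all
are parameters of the public functions.

## Known limitations

* Expected spectra are Monte-Carlo approximations; likelihood *values*
  carry simulation noise of a few log10 units at the default settings, so
  only differences well above that scale are interpretable.
* The ECM optimizer is a local method over bounded boxes; multimodal
  surfaces (e.g. pulse-time/proportion trade-offs) need many starts or the
  grid mode.
* The catalog's unreported parameters (lineage/ancestor sizes, colonisation
  times) are fixed choices, not estimates; recovery targets are
  self-consistency checks of the inference chain under those conditions,
  not re-estimates from empirical data.
* Frequency-based D assumes the outgroup fixes the ancestral state; sites
  with polymorphic outgroups are dropped rather than modelled.
* The windowed statistics assume the subsampled table is missing-free;
  enforcement is by construction (`subsample_genotypes`), not imputation.
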