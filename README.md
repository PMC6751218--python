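# lakestream

Population-genomic inference for lake-stream stickleback ecotype divergence
in Lake Constance: did the two ecotypes arise in situ from one colonising
lineage, by ecological vicariance, by secondary contact of old East and
West European lineages — or are the stream populations of hybrid origin,
fuelled by admixture variation introgressed across a contact zone?

The package re-implements the full inference chain as a tested, reusable
library for RAD-seq data:

* **genotype_data** — VCF-based filtering: total-depth IQR fence, biallelic
  autosomal SNP selection, per-genotype depth masking, an exact
  heterozygote-excess Hardy-Weinberg screen with a 100 bp buffer, LD
  pruning, complete-data genotype subsampling, haploidisation, and
  proportional monomorphic-site rebalancing.
* **sfs_core** — multidimensional site-frequency spectra (monomorphic corner
  included), global-minor-allele folding, marginalisation, singleton
  masking, and a 10,000-site block bootstrap.
* **recomb_map** — recombination rates by cubic spline smoothing of a
  genetic map (first derivative in cM/Mb) and the < 1.5 cM/Mb site filter.
* **demographic_models** — a catalog of 30 coalescent models on three
  hierarchical levels (lineage trios; four-population admixture-pulse
  models; five-population ecotype-divergence modes: primary divergence,
  vicariance, secondary contact, hybrid origin), with expected SFS computed
  from msprime branch statistics.
* **sfs_inference** — multinomial composite likelihood
  `LL10 = Σ m_i log10 p_i`, ECM-style bounded optimization, AIC model
  comparison (`AIC = 2k − 2 ln 10 · LL10`), block-bootstrap confidence
  intervals, and model-distinguishability distributions.
* **admixture_stats** — frequency-based ABBA-BABA
  `D = Σ(ABBA − BABA) / Σ(ABBA + BABA)` with block-jackknife errors,
  divergently-fixed diagnostic SNP panels, and the allele-count hybrid
  index `h = #West alleles / (2 × #loci)` with exact binomial CIs.
* **windowed_stats** — RAD-locus-respecting windows (≥ 2500 sequenced
  sites), Weir-Cockerham variance components with ratio-of-averages
  weighted FST, π and d_XY from windowed spectra, landscape correlations.
* **island_tests** — positional permutation tests for genomic islands of
  differentiation and West/East ancestry painting of differentiated SNPs.
* **synthetic_data** — deterministic generators for RAD-like scenario VCFs
  (negative-binomial depths, locus dropout), diagnostic-panel admixture
  cohorts, and piecewise-linear genetic maps, each with truth records.

## Worked example

Simulate a RAD dataset under the hybrid-origin model for the L2-S2
lake-stream pair at the catalog's best estimates, build the folded joint
SFS, and compare divergence-mode likelihoods:

```python
import numpy as np
from lakestream.demographic_models import best_estimates, get_model, simulate_sfs_counts
from lakestream.sfs_inference import composite_loglik, saturated_loglik, profile_loglik
from lakestream.demographic_models import simulate_expected_sfs

entry = best_estimates()["L2-S2"]          # hybrid origin, ancestor pulse
model = get_model(entry["model_id"])       # "HOcx"
obs = simulate_sfs_counts(model, entry["params"], entry["sample_sizes"],
                          n_sites=500_000, n_sims=30_000, seed=11)

grid = np.array([8.5, 10.5, 12.5, 13.5, 14.5, 16.5, 18.5])  # Rhine pulse, %
prof = profile_loglik(obs, model, "A_RHINE", grid, params=entry["params"],
                      sample_sizes=entry["sample_sizes"], n_sims=30_000, seed=7)
print("profile LL10:", np.round(prof.loglik10 - prof.loglik10.max(), 1))
print("recovered Rhine pulse:", prof.best_value, "%")
print("West total:", prof.best_value + entry["params"]["A_RHONE"], "%")
```

Output:

```
profile LL10: [-32.  -18.1  -8.3   0.   -1.6 -10.3 -26.5]
recovered Rhine pulse: 13.5 %
West total: 14.0 %
```

The profile is maximised at the generating pulse proportion: the West
European contribution to the common ancestor of the L2-S2 ecotype pair is
recovered at 14% — the inference chain identifies the admixture signal the
hybrid-origin model encodes.  The same protocol recovers the deep
West-East lineage split (3665 generations), the Rhone-Rhine split (1710),
lake-stream divergence times (408-2819 generations by pair) and the
stream-ward West pulses (27-48%).

A thin CLI mirrors the library for shell use:

```bash
lakestream synth scenario --model 3a --n-loci 500 --seed 1 --out demo
lakestream filter demo.vcf demo.popmap --out filtered.vcf --min-depth 10 --seed 1
lakestream dstat demo.vcf demo.popmap --p1 RHONE --p2 RHINE --p3 VISTULA --outgroup VISTULA
```

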