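"""Hierarchical catalog of demographic models and expected SFS via coalescence.

The catalog encodes the three-level model hierarchy used to reconstruct the
origin of Lake Constance stickleback ecotypes:

* 3-population models (``3a``-``3d``): alternative branching orders of the
  three allopatric European lineages — upper Rhone, Rhine (West) and Vistula
  (East).  ``3a`` groups the two West European lineages.
* 4-population models (``3Lo/3Li/3Lv`` + pulse variants ``3Lv{x,o,i}``; the
  ``3S*`` analogues for stream populations): one Lake Constance population
  attached to one of the three lineages, optionally receiving admixture
  pulses from the Rhone ('o'), the Rhine ('i') or both ('x').
* 5-population models of ecotype divergence: primary divergence (``PD``),
  ecological vicariance (``EVa``/``EVb``), secondary contact (``SCi``/``SCo``)
  and hybrid origin (``HO{a,b,c}{x,i,o}``), where the hybrid-origin pulse
  targets the stream ('a'), the lake ('b') or their common ancestor ('c').

Units follow the reporting convention: population sizes N_i in units of 2N_e
(the simulator divides by two for msprime's diploid parameterization),
admixture proportions a_ij in percent of the target population, migration
m_ij as 2N_e·m migrants per generation forward in time (converted to the
backward per-lineage rate m_ij / S_recipient), and times in generations.

Expected spectra are approximated from independent single-site coalescent
replicates: the branch-mode allele-frequency spectrum (mean subtended branch
length per frequency cell) is averaged over replicates and scaled by the
mutation rate, giving the per-site probability of each polymorphic
configuration; the monomorphic corner absorbs the remainder.  This is the
expectation of Poisson mutation placement with the placement integrated out,
so it matches per-site mutation sprinkling in expectation at much lower
Monte Carlo variance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import yaml

from .sfs_core import SFS, fold_array

MU_DEFAULT = 1.7e-8

# Printed hybrid-index calibration for the NID cohort (fraction West alleles).
NID_HYBRID_INDEX = 0.44


# ---------------------------------------------------------------------------
# Model structure
# ---------------------------------------------------------------------------

@dataclass
class Deme:
    name: str
    size_param: str
    sampled: bool = True
    n_sampled_diploids: int = 0


@dataclass
class Split:
    time_param: str
    derived: list[str]
    ancestral: str


@dataclass
class Pulse:
    """Forward-time admixture pulse: `dest` receives `prop_param` % from `source`."""

    time_param: str
    dest: str
    source: str
    prop_param: str


@dataclass
class MigrationEpoch:
    """Symmetric-structure epoch of lake<->stream exchange from time 0 to `end_param`.

    `m_ab_param` is the forward-time number of migrants a -> b in 2N_e·m units.
    """

    pop_a: str
    pop_b: str
    m_ab_param: str
    m_ba_param: str
    end_param: str


@dataclass
class DemographicModel:
    model_id: str
    demes: list[Deme]
    ancestors: list[tuple[str, str]]  # (name, size_param)
    splits: list[Split]
    pulses: list[Pulse] = field(default_factory=list)
    migrations: list[MigrationEpoch] = field(default_factory=list)
    defaults: dict[str, float] = field(default_factory=dict)
    free: dict[str, tuple[float, float]] = field(default_factory=dict)
    mu: float = MU_DEFAULT
    description: str = ""

    @property
    def n_free_params(self) -> int:
        return len(self.free)

    def params_with_defaults(self, params: dict[str, float] | None) -> dict[str, float]:
        merged = dict(self.defaults)
        if params:
            unknown = set(params) - set(merged)
            if unknown:
                raise ValueError(f"unknown parameter(s) for {self.model_id}: {sorted(unknown)}")
            merged.update(params)
        return merged

    def default_sample_sizes(self) -> dict[str, int]:
        return {d.name: d.n_sampled_diploids for d in self.demes if d.sampled and d.n_sampled_diploids > 0}

    # -- validation ---------------------------------------------------------
    def _activity_windows(self, p: dict[str, float]) -> dict[str, tuple[float, float]]:
        """(birth, merge) time window in which each population holds lineages."""
        birth = {d.name: 0.0 for d in self.demes}
        merge = {d.name: np.inf for d in self.demes}
        for name, _ in self.ancestors:
            merge[name] = np.inf
        for s in self.splits:
            t = p[s.time_param]
            for d in s.derived:
                merge[d] = t
            birth.setdefault(s.ancestral, t)
            if s.ancestral not in {d.name for d in self.demes}:
                birth[s.ancestral] = t
        return {n: (birth[n], merge[n]) for n in birth}

    def validate(self, params: dict[str, float] | None = None) -> dict[str, float]:
        p = self.params_with_defaults(params)
        for name, sp in [(d.name, d.size_param) for d in self.demes] + list(self.ancestors):
            if p[sp] <= 0:
                raise ValueError(f"{self.model_id}: size {sp} for {name} must be > 0")
        win = self._activity_windows(p)
        for s in self.splits:
            t = p[s.time_param]
            if t < 0:
                raise ValueError(f"{self.model_id}: split time {s.time_param} < 0")
            b_anc = win[s.ancestral][0]
            if s.ancestral not in {d.name for d in self.demes} and t != b_anc:
                raise ValueError(f"{self.model_id}: inconsistent split ordering at {s.time_param}")
            if win[s.ancestral][1] <= t:
                raise ValueError(
                    f"{self.model_id}: ancestor {s.ancestral} merges before split at {s.time_param}"
                )
        for pu in self.pulses:
            a = p[pu.prop_param]
            if not (0 <= a <= 100):
                raise ValueError(f"{self.model_id}: pulse {pu.prop_param}={a} outside [0, 100]%")
            t = p[pu.time_param]
            for pop in (pu.dest, pu.source):
                lo, hi = win[pop]
                if not (lo <= t < hi):
                    raise ValueError(
                        f"{self.model_id}: pulse at {pu.time_param}={t} outside activity window "
                        f"[{lo}, {hi}) of {pop}"
                    )
        for me in self.migrations:
            t = p[me.end_param]
            for pop in (me.pop_a, me.pop_b):
                if win[pop][1] < t:
                    raise ValueError(f"{self.model_id}: migration epoch outlives {pop}")
        return p

    # -- msprime construction ------------------------------------------------
    def to_demography(self, params: dict[str, float] | None = None) -> msprime.Demography:
        p = self.validate(params)
        dem = msprime.Demography()
        for d in self.demes:
            dem.add_population(name=d.name, initial_size=p[d.size_param] / 2.0, initially_active=True)
        for name, sp in self.ancestors:
            dem.add_population(name=name, initial_size=p[sp] / 2.0)
        sizes = {d.name: p[d.size_param] for d in self.demes}
        sizes.update({name: p[sp] for name, sp in self.ancestors})
        for me in self.migrations:
            # forward a->b migrants M_ab: backward lineages in b jump to a at M_ab / S_b
            for src, dst, mp in ((me.pop_a, me.pop_b, me.m_ab_param), (me.pop_b, me.pop_a, me.m_ba_param)):
                rate = p[mp] / sizes[dst]
                if rate > 0:
                    dem.set_migration_rate(source=dst, dest=src, rate=rate)
                    dem.add_migration_rate_change(time=p[me.end_param], rate=0.0, source=dst, dest=src)
        for pu in self.pulses:
            # forward-time pulse into dest: backward mass migration dest -> source
            dem.add_mass_migration(
                time=p[pu.time_param], source=pu.dest, dest=pu.source, proportion=p[pu.prop_param] / 100.0
            )
        for s in self.splits:
            dem.add_population_split(time=p[s.time_param], derived=list(s.derived), ancestral=s.ancestral)
        dem.sort_events()
        return dem

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "mu": self.mu,
            "description": self.description,
            "demes": [
                {"name": d.name, "size_param": d.size_param, "sampled": d.sampled,
                 "n_sampled_diploids": d.n_sampled_diploids}
                for d in self.demes
            ],
            "ancestors": [{"name": n, "size_param": sp} for n, sp in self.ancestors],
            "splits": [{"time_param": s.time_param, "derived": s.derived, "ancestral": s.ancestral} for s in self.splits],
            "pulses": [
                {"time_param": x.time_param, "dest": x.dest, "source": x.source, "prop_param": x.prop_param}
                for x in self.pulses
            ],
            "migrations": [
                {"pop_a": m.pop_a, "pop_b": m.pop_b, "m_ab_param": m.m_ab_param,
                 "m_ba_param": m.m_ba_param, "end_param": m.end_param}
                for m in self.migrations
            ],
            "defaults": dict(self.defaults),
            "free": {k: list(v) for k, v in self.free.items()},
        }

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            model_id=d["model_id"],
            demes=[Deme(**x) for x in d["demes"]],
            ancestors=[(x["name"], x["size_param"]) for x in d["ancestors"]],
            splits=[Split(**x) for x in d["splits"]],
            pulses=[Pulse(**x) for x in d.get("pulses", [])],
            migrations=[MigrationEpoch(**x) for x in d.get("migrations", [])],
            defaults=d.get("defaults", {}),
            free={k: tuple(v) for k, v in d.get("free", {}).items()},
            mu=d.get("mu", MU_DEFAULT),
            description=d.get("description", ""),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Expected SFS
# ---------------------------------------------------------------------------

@dataclass
class ExpectedSFS:
    probs: np.ndarray  # sums to 1 including the monomorphic corner
    pop_order: tuple[str, ...]
    sample_sizes: tuple[int, ...]  # haploid
    folded: bool
    n_sims: int = 10**8  # effectively no likelihood floor for analytic inputs
    mask: np.ndarray | None = None


def simulate_expected_sfs(
    model: DemographicModel,
    params: dict[str, float] | None = None,
    sample_sizes: dict[str, int] | None = None,
    n_sims: int = 100_000,
    seed: int | None = None,
    folded: bool = True,
) -> ExpectedSFS:
    """Approximate the expected per-site SFS under `model` by coalescent simulation.

    `sample_sizes` maps deme name -> number of diploids (defaults to the
    model's sampled demes); demes absent from it act as unsampled 'ghost'
    populations.  See the module docstring for the branch-statistic estimator.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    sample_sizes = sample_sizes or model.default_sample_sizes()
    if not sample_sizes:
        raise ValueError("no sampled demes")
    dem = model.to_demography(params)
    pop_order = tuple(sample_sizes)
    pop_ids = {p.name: i for i, p in enumerate(dem.populations)}
    reps = msprime.sim_ancestry(
        samples={name: n for name, n in sample_sizes.items()},
        demography=dem,
        sequence_length=1,
        num_replicates=n_sims,
        random_seed=seed,
        ploidy=2,
    )
    acc: np.ndarray | None = None
    sample_sets_idx = [pop_ids[name] for name in pop_order]
    for ts in reps:
        sets = [ts.samples(population=i) for i in sample_sets_idx]
        afs = ts.allele_frequency_spectrum(sample_sets=sets, mode="branch", polarised=True, span_normalise=False)
        acc = afs if acc is None else acc + afs
    probs = acc * (model.mu / n_sims)
    corner = (0,) * len(pop_order)
    probs[corner] = 0.0
    poly = probs.sum()
    if poly >= 1.0:
        raise ValueError("mutation rate x tree length >= 1 per site; model outside the per-site regime")
    probs[corner] = 1.0 - poly
    haploid = tuple(2 * sample_sizes[p] for p in pop_order)
    if folded:
        probs = fold_array(probs, haploid)
    return ExpectedSFS(probs, pop_order, haploid, folded=folded, n_sims=n_sims)


def simulate_sfs_counts(
    model: DemographicModel,
    params: dict[str, float] | None = None,
    sample_sizes: dict[str, int] | None = None,
    n_sites: int = 500_000,
    n_sims: int = 30_000,
    seed: int | None = None,
    folded: bool = True,
) -> SFS:
    """Simulate an observed SFS of `n_sites` independent sites (multinomial draw
    from a high-precision expected SFS)."""
    from ._util import spawn_seeds

    s_exp, s_draw = spawn_seeds(seed, 2)
    exp = simulate_expected_sfs(model, params, sample_sizes, n_sims=n_sims, seed=s_exp, folded=folded)
    rng = np.random.default_rng(s_draw)
    counts = rng.multinomial(n_sites, exp.probs.ravel() / exp.probs.sum()).astype(float)
    return SFS(counts.reshape(exp.probs.shape), exp.pop_order, exp.sample_sizes, folded=folded)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

_N_BOUNDS = (100.0, 1e6)
_T_BOUNDS = (10.0, 30_000.0)
_A_BOUNDS = (0.0, 100.0)
_M_BOUNDS = (0.0, 50.0)

# Shared allopatric-lineage parameters (model 3a scale).  Split times are the
# catalog's best estimates; lineage and ancestral sizes are catalog choices
# (see docs/methods.md) at a scale giving RAD-like polymorphism density.
_P3A = {
    "N_RHONE": 4000.0,
    "N_RHINE": 2000.0,
    "N_VISTULA": 6000.0,
    "N_WANC": 100_000.0,
    "N_ROOT": 300_000.0,
    "T_RR": 1710.0,
    "T_WE": 3665.0,
}


def _three_pop_models() -> dict[str, DemographicModel]:
    leaf = lambda: [
        Deme("RHONE", "N_RHONE", True, 4),
        Deme("RHINE", "N_RHINE", True, 3),
        Deme("VISTULA", "N_VISTULA", True, 4),
    ]
    out = {}
    trios = {
        "3a": (["RHONE", "RHINE"], "VISTULA", "West lineages (Rhone, Rhine) sister to Vistula"),
        "3b": (["RHONE", "VISTULA"], "RHINE", "Rhone sister to Vistula"),
        "3c": (["RHINE", "VISTULA"], "RHONE", "Rhine sister to Vistula"),
    }
    for mid, (pair, outer, desc) in trios.items():
        out[mid] = DemographicModel(
            model_id=mid,
            demes=leaf(),
            ancestors=[("PANC", "N_WANC"), ("ROOT", "N_ROOT")],
            splits=[
                Split("T_RR", pair, "PANC"),
                Split("T_WE", ["PANC", outer], "ROOT"),
            ],
            defaults=dict(_P3A),
            free={
                "N_RHONE": _N_BOUNDS, "N_RHINE": _N_BOUNDS, "N_VISTULA": _N_BOUNDS,
                "N_WANC": _N_BOUNDS, "N_ROOT": _N_BOUNDS,
                "T_RR": _T_BOUNDS, "T_WE": _T_BOUNDS,
            },
            description=desc + "; two split-time parameters",
        )
    d3d = dict(_P3A)
    d3d.pop("T_RR")
    d3d.pop("N_WANC")
    out["3d"] = DemographicModel(
        model_id="3d",
        demes=leaf(),
        ancestors=[("ROOT", "N_ROOT")],
        splits=[Split("T_WE", ["RHONE", "RHINE", "VISTULA"], "ROOT")],
        defaults=d3d,
        free={
            "N_RHONE": _N_BOUNDS, "N_RHINE": _N_BOUNDS, "N_VISTULA": _N_BOUNDS,
            "N_ROOT": _N_BOUNDS, "T_WE": _T_BOUNDS,
        },
        description="simultaneous three-way split (polytomy); one split-time parameter",
    )
    return out


_FOUR_POP_DEFAULTS = {
    "N_FOCAL": 4000.0, "T_COL": 800.0, "T_ADM": 150.0,
    "A_RHINE": 10.0, "A_RHONE": 1.0,
}


def _four_pop_models() -> dict[str, DemographicModel]:
    out = {}
    parents = {"o": "RHONE", "i": "RHINE", "v": "VISTULA"}
    for eco in ("L", "S"):
        for letter, parent in parents.items():
            for pulses_code in ("", "x", "o", "i"):
                if pulses_code and letter != "v":
                    continue  # pulse variants are explored on the East-derived backbone
                mid = f"3{eco}{letter}{pulses_code}"
                pulses = []
                free = {
                    "N_RHONE": _N_BOUNDS, "N_RHINE": _N_BOUNDS, "N_VISTULA": _N_BOUNDS,
                    "N_WANC": _N_BOUNDS, "N_ROOT": _N_BOUNDS, "N_FOCAL": _N_BOUNDS,
                    "T_RR": _T_BOUNDS, "T_WE": _T_BOUNDS, "T_COL": _T_BOUNDS,
                }
                defaults = dict(_P3A, **_FOUR_POP_DEFAULTS)
                if pulses_code in ("x", "i"):
                    pulses.append(Pulse("T_ADM", "FOCAL", "RHINE", "A_RHINE"))
                    free["A_RHINE"] = _A_BOUNDS
                if pulses_code in ("x", "o"):
                    pulses.append(Pulse("T_ADM", "FOCAL", "RHONE", "A_RHONE"))
                    free["A_RHONE"] = _A_BOUNDS
                if pulses_code:
                    free["T_ADM"] = (10.0, 1500.0)
                else:
                    defaults.pop("T_ADM")
                    defaults.pop("A_RHINE")
                    defaults.pop("A_RHONE")
                out[mid] = DemographicModel(
                    model_id=mid,
                    demes=[
                        Deme("RHONE", "N_RHONE", True, 4),
                        Deme("RHINE", "N_RHINE", True, 3),
                        Deme("VISTULA", "N_VISTULA", True, 4),
                        Deme("FOCAL", "N_FOCAL", True, 6),
                    ],
                    ancestors=[("PANC", "N_WANC"), ("ROOT", "N_ROOT")],
                    splits=[
                        Split("T_COL", ["FOCAL"], parent),
                        Split("T_RR", ["RHONE", "RHINE"], "PANC"),
                        Split("T_WE", ["PANC", "VISTULA"], "ROOT"),
                    ],
                    pulses=pulses,
                    defaults=defaults,
                    free=free,
                    description=(
                        f"Constance {'lake' if eco == 'L' else 'stream'} population derived from "
                        f"{parent.title()}" + (f" with pulse(s) '{pulses_code}'" if pulses_code else "")
                    ),
                )
    return out


_FIVE_POP_DEFAULTS = {
    "N_LAKE": 4000.0, "N_STREAM": 4000.0, "N_CANC": 4000.0,
    "T_LS": 1000.0, "T_COL": 2500.0, "M_LS": 1.0, "M_SL": 1.0,
}


def _five_pop_base(mid: str, splits: list[Split], extra_defaults: dict, extra_free: dict,
                   pulses: list[Pulse], desc: str, drop: set[str] = frozenset()) -> DemographicModel:
    defaults = {**_P3A, **_FIVE_POP_DEFAULTS, **extra_defaults}
    for k in drop:
        defaults.pop(k, None)
    free = {
        "N_LAKE": _N_BOUNDS, "N_STREAM": _N_BOUNDS,
        "T_LS": _T_BOUNDS, "M_LS": _M_BOUNDS, "M_SL": _M_BOUNDS,
        **extra_free,
    }
    uses_canc = any(s.ancestral == "CANC" for s in splits)
    ancestors = [("PANC", "N_WANC"), ("ROOT", "N_ROOT")]
    if uses_canc:
        ancestors.insert(0, ("CANC", "N_CANC"))
        free["N_CANC"] = _N_BOUNDS
    else:
        defaults.pop("N_CANC", None)
    return DemographicModel(
        model_id=mid,
        demes=[
            Deme("RHONE", "N_RHONE", False, 0),
            Deme("RHINE", "N_RHINE", False, 0),
            Deme("VISTULA", "N_VISTULA", False, 0),
            Deme("LAKE", "N_LAKE", True, 6),
            Deme("STREAM", "N_STREAM", True, 6),
        ],
        ancestors=ancestors,
        splits=splits + [
            Split("T_RR", ["RHONE", "RHINE"], "PANC"),
            Split("T_WE", ["PANC", "VISTULA"], "ROOT"),
        ],
        pulses=pulses,
        migrations=[MigrationEpoch("LAKE", "STREAM", "M_LS", "M_SL", "T_LS")],
        defaults=defaults,
        free=free,
        description=desc,
    )


def _five_pop_models() -> dict[str, DemographicModel]:
    out = {}
    ho_splits = [Split("T_LS", ["LAKE", "STREAM"], "CANC"), Split("T_COL", ["CANC"], "VISTULA")]
    out["PD"] = _five_pop_base(
        "PD", ho_splits, {}, {"T_COL": _T_BOUNDS}, [],
        "primary divergence in situ: single East-derived colonisation, then lake-stream split",
    )
    out["EVa"] = _five_pop_base(
        "EVa",
        [Split("T_LS", ["LAKE"], "STREAM"), Split("T_COL", ["STREAM"], "VISTULA")],
        {}, {"T_COL": _T_BOUNDS}, [],
        "ecological vicariance: streams colonised first, lake ecotype derived from the stream lineage",
        drop={"N_CANC"},
    )
    out["EVb"] = _five_pop_base(
        "EVb",
        [Split("T_LS", ["LAKE"], "VISTULA"), Split("T_COL", ["STREAM"], "VISTULA")],
        {}, {"T_COL": _T_BOUNDS}, [],
        "ecological vicariance: lake and stream colonised separately from the East lineage (stream first)",
        drop={"N_CANC"},
    )
    for letter, west in (("i", "RHINE"), ("o", "RHONE")):
        out[f"SC{letter}"] = _five_pop_base(
            f"SC{letter}",
            [Split("T_LS", ["LAKE"], "VISTULA"), Split("T_COL", ["STREAM"], west)],
            # stream lineage must join its West parent before the Rhone-Rhine split
            {"T_COL": 1500.0}, {"T_COL": (10.0, 1700.0)}, [],
            f"secondary contact: lake = East lineage, stream = {west.title()} lineage, gene flow on contact",
            drop={"N_CANC"},
        )
    targets = {"a": "STREAM", "b": "LAKE", "c": "CANC"}
    for tl, target in targets.items():
        for sl in ("x", "i", "o"):
            mid = f"HO{tl}{sl}"
            pulses = []
            extra_free: dict = {"T_COL": _T_BOUNDS, "T_ADM": _T_BOUNDS}
            extra_defaults: dict = {"T_ADM": 1500.0 if tl == "c" else 300.0,
                                    "A_RHINE": 15.0, "A_RHONE": 1.0}
            if sl in ("x", "i"):
                pulses.append(Pulse("T_ADM", target, "RHINE", "A_RHINE"))
                extra_free["A_RHINE"] = _A_BOUNDS
            else:
                extra_defaults.pop("A_RHINE")
            if sl in ("x", "o"):
                pulses.append(Pulse("T_ADM", target, "RHONE", "A_RHONE"))
                extra_free["A_RHONE"] = _A_BOUNDS
            else:
                extra_defaults.pop("A_RHONE")
            where = {"a": "stream", "b": "lake", "c": "lake-stream common ancestor"}[tl]
            out[mid] = _five_pop_base(
                mid, list(ho_splits), extra_defaults, extra_free, pulses,
                f"hybrid origin: East-derived lake-stream pair; West pulse(s) '{sl}' into the {where}",
            )
    return out


def model_catalog() -> dict[str, DemographicModel]:
    """All model families keyed by id, with placeholder/best-estimate defaults."""
    cat: dict[str, DemographicModel] = {}
    cat.update(_three_pop_models())
    cat.update(_four_pop_models())
    cat.update(_five_pop_models())
    return cat


def get_model(model_id: str) -> DemographicModel:
    cat = model_catalog()
    if model_id not in cat:
        raise KeyError(f"unknown model id {model_id!r}; valid ids: {', '.join(sorted(cat))}")
    return cat[model_id]


def best_estimates() -> dict[str, dict]:
    """Catalog of maximum-likelihood parameter sets for the best-supported models.

    Split times, admixture proportions, lake sizes, divergence times and the
    NID hybrid index carry the reported best estimates; remaining sizes and
    event times are catalog choices documented in docs/methods.md.  Scenarios:

    * ``3pop`` — model 3a for the allopatric lineage trio.
    * ``L2`` / ``S2`` / ``NID`` — 4-population both-West-pulse models
      (3Lvx / 3Svx) for single Constance populations.
    * ``L2-S2``, ``ROM-NID``, ``ROM-BOH``, ``ROM-GRA`` — hybrid-origin
      lake-stream pair models (allopatric lineages as ghost demes).
    """
    ghost = {"LAKE": 0, "STREAM": 0}  # documentation aid only
    _ = ghost
    return {
        "3pop": {
            "model_id": "3a",
            "params": dict(_P3A),
            "sample_sizes": {"RHONE": 4, "RHINE": 3, "VISTULA": 4},
        },
        "L2": {
            "model_id": "3Lvx",
            "params": dict(_P3A, N_FOCAL=3713.0, T_COL=800.0, T_ADM=150.0, A_RHINE=6.7, A_RHONE=0.7),
            "sample_sizes": {"RHONE": 4, "RHINE": 3, "VISTULA": 4, "FOCAL": 6},
        },
        "S2": {
            "model_id": "3Svx",
            "params": dict(_P3A, N_FOCAL=2000.0, T_COL=800.0, T_ADM=150.0, A_RHINE=16.6, A_RHONE=0.1),
            "sample_sizes": {"RHONE": 4, "RHINE": 3, "VISTULA": 4, "FOCAL": 6},
        },
        "NID": {
            "model_id": "3Svx",
            "params": dict(_P3A, N_FOCAL=4000.0, T_COL=800.0, T_ADM=150.0, A_RHINE=27.2, A_RHONE=0.2),
            "sample_sizes": {"RHONE": 4, "RHINE": 3, "VISTULA": 4, "FOCAL": 6},
            "hybrid_index": NID_HYBRID_INDEX,
        },
        "L2-S2": {
            # SbfI-style scenario: the Rhine (pulse source) is a sampled
            # lineage, as in the SbfI fits; Rhone and Vistula stay ghosts.
            "model_id": "HOcx",
            "params": dict(
                _P3A, N_LAKE=3713.0, N_STREAM=2000.0, N_CANC=3000.0,
                T_LS=408.0, T_ADM=700.0, T_COL=1500.0,
                A_RHINE=13.5, A_RHONE=0.5, M_LS=1.0, M_SL=1.0,
            ),
            "sample_sizes": {"LAKE": 6, "STREAM": 6, "RHINE": 3},
            "west_total_pct": 14.0,
        },
        "ROM-NID": {
            "model_id": "HOcx",
            "params": dict(
                _P3A, N_LAKE=8473.0, N_STREAM=4000.0, N_CANC=5000.0,
                T_LS=1276.0, T_ADM=1400.0, T_COL=3000.0,
                A_RHINE=30.0, A_RHONE=1.0, M_LS=1.0, M_SL=1.0,
            ),
            "sample_sizes": {"LAKE": 7, "STREAM": 9},
            "west_total_pct": 31.0,
        },
        "ROM-BOH": {
            "model_id": "HOai",
            "params": dict(
                _P3A, N_LAKE=8473.0, N_STREAM=8000.0, N_CANC=5000.0,
                T_LS=2819.0, T_ADM=1500.0, T_COL=3200.0,
                A_RHINE=32.0, M_LS=1.0, M_SL=1.0,
            ),
            "sample_sizes": {"LAKE": 7, "STREAM": 9},
            "west_total_pct": 32.0,
        },
        "ROM-GRA": {
            "model_id": "HOax",
            "params": dict(
                _P3A, N_LAKE=8473.0, N_STREAM=12000.0, N_CANC=5000.0,
                T_LS=1065.0, T_ADM=600.0, T_COL=3000.0,
                A_RHINE=40.0, A_RHONE=8.0, M_LS=1.0, M_SL=1.0,
            ),
            "sample_sizes": {"LAKE": 7, "STREAM": 9},
            "west_total_pct": 48.0,
        },
    }
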