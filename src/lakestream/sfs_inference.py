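"""Composite-likelihood fitting of demographic models to observed SFS.

The observed multidimensional SFS (counts over sequenced sites, monomorphic
corner included) is treated as a multinomial sample from the model's expected
per-site cell probabilities; the composite log10-likelihood is
``sum_i m_i * log10(p_i)`` over unmasked cells.  Models are compared by AIC
(``AIC = 2k - 2 ln(10) * LL10``); uncertainty comes from block-bootstrap
replicates of the observed spectrum, distinguishability from likelihood
distributions simulated under each candidate model.

Optimization is ECM-style: cyclic bounded one-dimensional maximizations over
the free parameters, repeated until the relative log-likelihood change drops
below a tolerance, best of several random starts.  Expected spectra are
Monte-Carlo approximations, so every evaluation within one fit reuses the
same simulation seed (common random numbers) to keep the objective
deterministic; a fixed-grid mode offers cacheable, data-independent
evaluation points for repeated fits to replicate datasets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._util import rng_from_seed, spawn_seeds
from .demographic_models import DemographicModel, ExpectedSFS, simulate_expected_sfs
from .sfs_core import SFS

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def composite_loglik(obs: SFS, expected: ExpectedSFS, use_monomorphic: bool = True) -> float:
    """Multinomial composite log10-likelihood of an observed SFS.

    Expected cell probabilities are floored at 1/(10 * n_sims) before the log
    so Monte-Carlo zeros cannot produce -inf.  Masked cells (in either the
    observed or expected object) are excluded.  With ``use_monomorphic=False``
    the monomorphic corner is dropped and probabilities renormalised over the
    polymorphic cells.
    """
    if obs.counts.shape != expected.probs.shape:
        raise ValueError(f"shape mismatch: obs {obs.counts.shape} vs expected {expected.probs.shape}")
    if obs.folded != expected.folded:
        raise ValueError("folded flags differ between observed and expected SFS")
    include = np.ones(obs.counts.shape, dtype=bool)
    if obs.mask is not None:
        include &= ~obs.mask
    if expected.mask is not None:
        include &= ~expected.mask
    p = expected.probs.copy()
    if not use_monomorphic:
        corner = (0,) * len(obs.sample_sizes)
        include[corner] = False
        p_sum = p[include].sum()
        if p_sum <= 0:
            raise ValueError("no probability mass on included cells")
        p = p / p_sum
    floor = 1.0 / (10.0 * expected.n_sims)
    p = np.maximum(p, floor)
    m = obs.counts
    return float(np.sum(m[include] * np.log10(p[include])))


def saturated_loglik(obs: SFS, use_monomorphic: bool = True) -> float:
    """Log10-likelihood of the observed proportions themselves (the multinomial
    maximum over all probability vectors) — the ideal against which model
    deficits (ΔLL) are measured."""
    include = np.ones(obs.counts.shape, dtype=bool)
    if obs.mask is not None:
        include &= ~obs.mask
    if not use_monomorphic:
        include[(0,) * len(obs.sample_sizes)] = False
    m = obs.counts[include]
    tot = m.sum()
    nz = m > 0
    return float(np.sum(m[nz] * np.log10(m[nz] / tot)))


def aic_from_loglik10(loglik10: float, n_free_params: int) -> float:
    """AIC = 2k - 2 ln(10) * LL10 (natural-log conversion of the log10 likelihood)."""
    return 2.0 * n_free_params - 2.0 * LN10 * loglik10


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model_id: str
    ml_params: dict[str, float]
    loglik10: float
    aic: float
    n_free_params: int
    n_starts_used: int
    converged: bool
    obs_key: tuple = ()


@dataclass
class BootstrapCI:
    intervals: dict[str, tuple[float, float]]
    n_replicates: int
    estimates: pd.DataFrame | None = None


def _obs_key(obs: SFS) -> tuple:
    return (obs.counts.shape, round(obs.total_sites, 6), obs.folded)


class _CachedObjective:
    """Deterministic (CRN) composite-loglik objective with memoisation."""

    def __init__(self, obs, model, fixed, sample_sizes, n_sims, sim_seed, use_monomorphic, round_digits=10):
        self.obs = obs
        self.model = model
        self.fixed = fixed
        self.sample_sizes = sample_sizes
        self.n_sims = n_sims
        self.sim_seed = sim_seed
        self.use_monomorphic = use_monomorphic
        self.round_digits = round_digits
        self.cache: dict[tuple, float] = {}
        self.n_evals = 0

    def __call__(self, free_values: dict[str, float]) -> float:
        key = tuple(sorted((k, round(v, self.round_digits)) for k, v in free_values.items()))
        if key in self.cache:
            return self.cache[key]
        params = {**self.fixed, **free_values}
        try:
            exp = simulate_expected_sfs(
                self.model, params, self.sample_sizes,
                n_sims=self.n_sims, seed=self.sim_seed, folded=self.obs.folded,
            )
            if self.obs.mask is not None:
                exp.mask = self.obs.mask
            ll = composite_loglik(self.obs, exp, use_monomorphic=self.use_monomorphic)
        except ValueError:
            ll = -np.inf
        self.n_evals += 1
        self.cache[key] = ll
        return ll


def _random_start(rng, free: dict[str, tuple[float, float]]) -> dict[str, float]:
    start = {}
    for name, (lo, hi) in free.items():
        if name.startswith("A_") or name.startswith("M_"):
            start[name] = rng.uniform(lo, hi)
        else:
            lo_ = max(lo, 1e-6)
            start[name] = float(np.exp(rng.uniform(np.log(lo_), np.log(hi))))
    return start


def fit_model(
    obs: SFS,
    model: DemographicModel,
    free: dict[str, tuple[float, float]] | None = None,
    fixed: dict[str, float] | None = None,
    sample_sizes: dict[str, int] | None = None,
    n_starts: int = 10,
    min_cycles: int = 10,
    max_cycles: int = 50,
    tol: float = 1e-3,
    n_sims: int = 5000,
    seed: int | None = None,
    use_monomorphic: bool = True,
    method: str = "ecm",
    grid_points: int = 9,
    line_search_iters: int = 12,
    start: dict[str, float] | None = None,
) -> FitResult:
    """Maximise the composite likelihood over the model's free parameters.

    ``method='ecm'``: per start, cyclic bounded 1-D line searches over each
    free parameter until the relative LL10 change is below `tol` (cycle count
    clamped to [min_cycles, max_cycles]).  ``method='grid'``: evaluate a fixed
    per-parameter geometric/linear grid factorially (for small free sets);
    evaluation points are data-independent, so the expected-SFS work can be
    shared across fits via `objective_cache`.
    """
    free = dict(model.free if free is None else free)
    fixed_params = model.params_with_defaults(fixed)
    if not free:
        raise ValueError("no free parameters to fit")
    sim_seed, start_seed = spawn_seeds(seed, 2)
    objective = _CachedObjective(
        obs, model, fixed_params, sample_sizes, n_sims, sim_seed, use_monomorphic
    )
    rng = rng_from_seed(start_seed)

    best_ll, best_params, converged_any = -np.inf, None, False
    if method == "grid":
        grids = {}
        for name, (lo, hi) in free.items():
            if name.startswith("A_") or name.startswith("M_"):
                grids[name] = np.linspace(lo, hi, grid_points)
            else:
                grids[name] = np.geomspace(max(lo, 1e-6), hi, grid_points)
        mesh = np.meshgrid(*[grids[n] for n in free], indexing="ij")
        combos = np.stack([m.ravel() for m in mesh], axis=1)
        for row in combos:
            vals = dict(zip(free, (float(x) for x in row)))
            ll = objective(vals)
            if ll > best_ll:
                best_ll, best_params = ll, vals
        converged_any = True
        n_starts_used = 1
    else:
        n_starts_used = n_starts
        for s in range(n_starts):
            if s == 0 and start is not None:
                current = dict(start)
            elif s == 0:
                rs = _random_start(rng, free)
                current = {k: fixed_params.get(k, rs[k]) for k in free}
            else:
                current = _random_start(rng, free)
            current = {k: float(np.clip(current[k], *free[k])) for k in free}
            ll_prev = objective(current)
            converged = False
            for cycle in range(max_cycles):
                for name in free:
                    lo, hi = free[name]

                    def neg(v, _name=name):
                        return -objective({**current, _name: float(v)})

                    res = minimize_scalar(
                        neg, bounds=(lo, hi), method="bounded",
                        options={"maxiter": line_search_iters, "xatol": (hi - lo) * 1e-3},
                    )
                    if -res.fun > objective(current):
                        current[name] = float(res.x)
                ll_now = objective(current)
                if cycle + 1 >= min_cycles and abs(ll_now - ll_prev) <= tol * max(1.0, abs(ll_now)):
                    converged = True
                    ll_prev = ll_now
                    break
                ll_prev = ll_now
            if ll_prev > best_ll:
                best_ll, best_params, converged_any = ll_prev, dict(current), converged
    if best_params is None or not np.isfinite(best_ll):
        raise RuntimeError(
            f"fit_model({model.model_id}): all starts gave non-finite likelihood "
            f"({objective.n_evals} evaluations)"
        )
    return FitResult(
        model_id=model.model_id,
        ml_params={**fixed_params, **best_params},
        loglik10=best_ll,
        aic=aic_from_loglik10(best_ll, len(free)),
        n_free_params=len(free),
        n_starts_used=n_starts_used,
        converged=converged_any,
        obs_key=_obs_key(obs),
    )


def compare_models(fits: list[FitResult], obs: SFS, use_monomorphic: bool = True) -> pd.DataFrame:
    """Model-comparison table: ΔLL vs the observed-proportions ideal, ΔAIC vs best.

    ΔLL = saturated LL10 - model LL10 (log10 units, >= 0 up to Monte-Carlo
    noise); ΔAIC = AIC - min AIC.  Sorted by increasing ΔAIC.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    keys = {f.obs_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different observed SFS")
    ideal = saturated_loglik(obs, use_monomorphic=use_monomorphic)
    rows = [
        {
            "model": f.model_id,
            "loglik10": f.loglik10,
            "delta_ll": ideal - f.loglik10,
            "k": f.n_free_params,
            "aic": f.aic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.sort_values("delta_aic", ignore_index=True)


def bootstrap_ci(
    model: DemographicModel,
    best_params: dict[str, float],
    free: dict[str, tuple[float, float]],
    bootstrap_sfs_list: list[SFS],
    n_opts_per_rep: int = 10,
    sample_sizes: dict[str, int] | None = None,
    n_sims: int = 3000,
    seed: int | None = None,
    perturb_frac: float = 0.2,
    min_cycles: int = 1,
    max_cycles: int = 5,
    use_monomorphic: bool = True,
) -> BootstrapCI:
    """95% empirical-percentile CIs from block-bootstrap SFS replicates.

    Per replicate: `n_opts_per_rep` short local optimizations started from
    the (multiplicatively perturbed) ML parameters; the best-likelihood
    parameter vector per replicate enters the percentile computation.
    """
    if len(bootstrap_sfs_list) < 20:
        warnings.warn("bootstrap_ci: fewer than 20 replicates; percentile CIs are unstable")
    rng = rng_from_seed(seed)
    rows = []
    for rep_i, rep in enumerate(bootstrap_sfs_list):
        best_ll, best_vec = -np.inf, None
        for _ in range(n_opts_per_rep):
            start = {
                k: float(np.clip(best_params[k] * rng.uniform(1 - perturb_frac, 1 + perturb_frac), *free[k]))
                for k in free
            }
            fit = fit_model(
                rep, model, free=free, fixed={k: v for k, v in best_params.items() if k not in free},
                sample_sizes=sample_sizes, n_starts=1, min_cycles=min_cycles, max_cycles=max_cycles,
                n_sims=n_sims, seed=int(rng.integers(1, 2**31 - 1)), use_monomorphic=use_monomorphic,
                start=start,
            )
            if fit.loglik10 > best_ll:
                best_ll, best_vec = fit.loglik10, {k: fit.ml_params[k] for k in free}
        rows.append({"replicate": rep_i, **best_vec})
    df = pd.DataFrame(rows)
    intervals = {
        k: (float(np.percentile(df[k], 2.5)), float(np.percentile(df[k], 97.5))) for k in free
    }
    return BootstrapCI(intervals=intervals, n_replicates=len(bootstrap_sfs_list), estimates=df)


# ---------------------------------------------------------------------------
# Profile likelihood & distinguishability
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    param: str
    best_value: float
    grid: np.ndarray
    loglik10: np.ndarray


def profile_loglik(
    obs: SFS,
    model: DemographicModel,
    param: str,
    grid: np.ndarray,
    params: dict[str, float] | None = None,
    sample_sizes: dict[str, int] | None = None,
    n_sims: int = 4000,
    seed: int | None = None,
    use_monomorphic: bool = True,
) -> ProfileResult:
    """Composite LL10 along a grid of one parameter, all others fixed.

    The same simulation seed is reused at every grid point (common random
    numbers), so Monte-Carlo noise largely cancels in likelihood differences
    along the profile.
    """
    fixed = model.params_with_defaults(params)
    lls = []
    for v in grid:
        p = {**fixed, param: float(v)}
        exp = simulate_expected_sfs(model, p, sample_sizes, n_sims=n_sims, seed=seed, folded=obs.folded)
        if obs.mask is not None:
            exp.mask = obs.mask
        lls.append(composite_loglik(obs, exp, use_monomorphic=use_monomorphic))
    lls = np.array(lls)
    return ProfileResult(param, float(np.asarray(grid)[np.argmax(lls)]), np.asarray(grid, dtype=float), lls)


def grid_fit_replicates(
    models: dict[str, tuple[DemographicModel, dict[str, float], dict[str, np.ndarray]]],
    obs_list: list[SFS],
    sample_sizes: dict[str, int] | None = None,
    n_sims: int = 8000,
    seed: int | None = None,
    use_monomorphic: bool = True,
) -> pd.DataFrame:
    """Fit several models to many replicate spectra on fixed parameter grids.

    ``models`` maps model name -> (model, fixed_params, {param: grid values}).
    Because the evaluation grids are data-independent, each expected SFS is
    simulated once and reused across all replicates — the economical protocol
    for model-recovery experiments.  Grid combinations violating a model's
    event-ordering constraints are skipped.  Returns a long-format table
    (replicate, model, loglik10, aic, k) where per-replicate values are the
    grid maxima.
    """
    from itertools import product

    seeds = spawn_seeds(seed, len(models))
    rows = []
    for (name, (model, fixed, grids)), sd in zip(models.items(), seeds):
        free_names = list(grids)
        k = len(free_names)
        expected: list[ExpectedSFS] = []
        for combo in product(*[grids[p] for p in free_names]):
            params = {**model.params_with_defaults(fixed), **dict(zip(free_names, map(float, combo)))}
            try:
                model.validate(params)
            except ValueError:
                continue
            expected.append(
                simulate_expected_sfs(model, params, sample_sizes, n_sims=n_sims,
                                      seed=sd, folded=obs_list[0].folded)
            )
        if not expected:
            raise ValueError(f"model {name}: no valid grid combination")
        for rep_i, obs in enumerate(obs_list):
            lls = [composite_loglik(obs, e, use_monomorphic=use_monomorphic) for e in expected]
            best = float(np.max(lls))
            rows.append({"replicate": rep_i, "model": name, "loglik10": best,
                         "aic": aic_from_loglik10(best, k), "k": k})
    return pd.DataFrame(rows)


def _overlap_coefficient(x: np.ndarray, y: np.ndarray, n_bins: int = 20) -> float:
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi <= lo:
        return 1.0
    bins = np.linspace(lo, hi, n_bins + 1)
    fx, _ = np.histogram(x, bins=bins)
    fy, _ = np.histogram(y, bins=bins)
    return float(np.minimum(fx / len(x), fy / len(y)).sum())


def model_distinguishability(
    models: dict[str, tuple[DemographicModel, dict[str, float]]],
    sample_sizes_map: dict[str, dict[str, int]] | dict[str, int],
    n_sites: int = 100_000,
    n_rep_sfs: int = 100,
    n_sims: int = 5000,
    seed: int | None = None,
    folded: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Likelihood distributions of data simulated under each model, evaluated
    under every model, plus pairwise distribution-overlap coefficients.

    Overlap near 1 means the models explain each other's data equally well
    (indistinguishable); near 0 means replicates are cleanly separated.
    Returns ``(loglik_table, overlap_matrix)``.
    """
    names = list(models)
    per_model_sizes = (
        sample_sizes_map if names and isinstance(next(iter(sample_sizes_map.values()), None), dict)
        else {n: sample_sizes_map for n in names}
    )
    seeds = spawn_seeds(seed, 2 * len(names))
    expected = {
        n: simulate_expected_sfs(models[n][0], models[n][1], per_model_sizes[n],
                                 n_sims=n_sims, seed=seeds[i], folded=folded)
        for i, n in enumerate(names)
    }
    rows = []
    for i, gen in enumerate(names):
        rng = rng_from_seed(seeds[len(names) + i])
        probs = expected[gen].probs.ravel()
        probs = probs / probs.sum()
        for rep in range(n_rep_sfs):
            counts = rng.multinomial(n_sites, probs).astype(float).reshape(expected[gen].probs.shape)
            obs = SFS(counts, expected[gen].pop_order, expected[gen].sample_sizes, folded=folded)
            row = {"generating": gen, "replicate": rep}
            for ev in names:
                if expected[ev].probs.shape != obs.counts.shape:
                    row[ev] = np.nan
                else:
                    row[ev] = composite_loglik(obs, expected[ev])
            rows.append(row)
    table = pd.DataFrame(rows)
    overlap = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            da = table.loc[table.generating == a, a].to_numpy() - table.loc[table.generating == a, b].to_numpy()
            db = table.loc[table.generating == b, a].to_numpy() - table.loc[table.generating == b, b].to_numpy()
            if np.isnan(da).any() or np.isnan(db).any():
                ov = np.nan
            else:
                ov = _overlap_coefficient(da, db)
            overlap.loc[a, b] = overlap.loc[b, a] = ov
    return table, overlap
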