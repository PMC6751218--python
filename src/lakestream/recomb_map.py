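"""Local recombination rates from a genetic map by cubic smoothing splines.

The genetic position cM(bp) of each chromosome is smoothed with a cubic
spline and differentiated; the first derivative (x 1e6) is the local rate in
cM/Mb, clipped at zero.  The smoothing strength is a normalized parameter
p in (0, 1]: p = 1 interpolates the markers exactly, smaller p increases the
penalty.  Internally p maps to scipy's UnivariateSpline residual target
``s = ((1 - p) / p) * n * sigma2``, where sigma2 is a marker-noise estimate
from second differences of the genetic positions (so a noiseless map is
always interpolated exactly, whatever p).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .genotype_data import GenotypeTable


@dataclass
class GeneticMap:
    """Per-chromosome marker physical (bp) and genetic (cM) positions."""

    markers: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, bp: np.ndarray, cm: np.ndarray) -> None:
        bp = np.asarray(bp, dtype=float)
        cm = np.asarray(cm, dtype=float)
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"{chrom}: physical positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"{chrom}: genetic positions must be non-decreasing")
        self.markers[chrom] = (bp, cm)


def read_genetic_map(path: str) -> GeneticMap:
    """Tab-separated (chrom, bp, cM), '#' comments allowed."""
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, bp, cm = line.split("\t")[:3]
            rows.setdefault(c, []).append((float(bp), float(cm)))
    gm = GeneticMap()
    for c, pts in rows.items():
        pts.sort()
        gm.add_chromosome(c, np.array([p[0] for p in pts]), np.array([p[1] for p in pts]))
    return gm


def write_genetic_map(gm: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tbp\tcM\n")
        for c, (bp, cm) in gm.markers.items():
            for b, m in zip(bp, cm):
                fh.write(f"{c}\t{int(b)}\t{m:.6f}\n")


class RateFunction:
    """Callable rate(chrom, bp) -> cM/Mb from per-chromosome fitted splines."""

    def __init__(self, splines: dict[str, UnivariateSpline]):
        self._splines = splines

    def chromosomes(self) -> list[str]:
        return list(self._splines)

    def __call__(self, chrom: str, bp) -> np.ndarray | float:
        if chrom not in self._splines:
            raise KeyError(f"chromosome {chrom!r} not in the fitted map")
        deriv = self._splines[chrom].derivative()(np.asarray(bp, dtype=float))
        rate = np.clip(deriv * 1e6, 0.0, None)  # cM/bp -> cM/Mb, no negative rates
        return float(rate) if np.isscalar(bp) or np.ndim(bp) == 0 else rate

    def to_bedgraph(self, path: str, step_bp: int = 100_000, chrom_lengths: dict[str, int] | None = None) -> None:
        with open(path, "w") as fh:
            for c, spl in self._splines.items():
                xmax = chrom_lengths[c] if chrom_lengths else float(spl.get_knots()[-1])
                edges = np.arange(0, xmax + step_bp, step_bp)
                for lo, hi in zip(edges[:-1], edges[1:]):
                    fh.write(f"{c}\t{int(lo)}\t{int(min(hi, xmax))}\t{self(c, (lo + hi) / 2):.4f}\n")


def fit_rate_spline(gm: GeneticMap, smoothing: float = 0.7) -> RateFunction:
    """Fit a cubic smoothing spline cM(bp) per chromosome; see module docs."""
    if not (0 < smoothing <= 1):
        raise ValueError("smoothing must be in (0, 1]")
    splines: dict[str, UnivariateSpline] = {}
    for c, (bp, cm) in gm.markers.items():
        n = len(bp)
        if n < 4:
            raise ValueError(f"chromosome {c!r} has {n} markers; >= 4 required for a cubic spline")
        if smoothing == 1.0:
            s = 0.0
        else:
            d2 = np.diff(cm, 2)
            sigma2 = float(np.mean(d2**2) / 6.0) if len(d2) else 0.0
            s = (1.0 - smoothing) / smoothing * n * sigma2
            if s < 1e-8 * max(float(np.var(cm)), 1.0):
                s = 0.0  # noiseless map: interpolate exactly
        with warnings.catch_warnings():
            # fitpack warns when the residual target is unattainable; the
            # returned approximation is what we want in that regime
            warnings.simplefilter("ignore", UserWarning)
            splines[c] = UnivariateSpline(bp, cm, k=3, s=s)
    return RateFunction(splines)


def filter_low_recombination(table: GenotypeTable, rate_fn: RateFunction, min_rate: float = 1.5) -> GenotypeTable:
    """Drop variant and monomorphic sites where the local rate < min_rate cM/Mb."""
    known = set(rate_fn.chromosomes())
    keep = np.ones(table.n_variants, dtype=bool)
    n_unmapped = 0
    for c in table.chromosomes():
        cmask = table.chrom == c
        if c not in known:
            n_unmapped += int(cmask.sum()) + len(table.monomorphic.get(c, ()))
            keep[cmask] = False
            continue
        if cmask.any():
            rates = rate_fn(c, table.pos[cmask].astype(float))
            keep[np.where(cmask)[0]] = rates >= min_rate
    out = table.subset_variants(keep)
    new_mono: dict[str, np.ndarray] = {}
    for c, positions in table.monomorphic.items():
        if c not in known:
            continue
        if len(positions):
            rates = rate_fn(c, positions.astype(float))
            kept = positions[rates >= min_rate]
            if len(kept):
                new_mono[c] = kept
    out.monomorphic = new_mono
    if n_unmapped:
        warnings.warn(f"filter_low_recombination: removed {n_unmapped} sites on chromosomes absent from the map")
    return out


def window_mean_rate(window, rate_fn: RateFunction, n_points: int = 10) -> float:
    """Mean rate over n_points equally spaced positions spanning [start, end]."""
    xs = np.linspace(window.start, window.end, n_points)
    return float(np.mean(rate_fn(window.chrom, xs)))
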