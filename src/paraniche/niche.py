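"""Cover-weighted kernel-density niche ranges and optima per species.

For every parasitic species with enough occurrences (default 50 plots), its
realised niche along an environmental or community-indicator gradient is
summarised by three numbers: a cover-weighted optimum (weighted arithmetic
mean) and a 95% range read from a Gaussian kernel density estimate weighted
by square-rooted relative cover,

    w_i = sqrt(c_i) / sum_j sqrt(c_j),

evaluated on a 512-point grid.  The grid densities are normalised to sum to
one and the 0.025 / 0.975 quantiles of the discrete distribution give the
range bounds.  The bandwidth defaults to Silverman's rule of thumb on the
weighted sample with effective sample size 1 / sum(w_i^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, EIVE_INDICATORS, PARASITE_TYPES, TraitRecord
from .cover import AggregatedPlot
from .eive import plot_mean_eive


@dataclass
class NicheEstimate:
    taxon_id: str
    variable: str
    lower: float
    optimum: float
    upper: float
    n_occurrences: int
    observed_min: float | None = None
    observed_max: float | None = None


def species_weights(covers: Sequence[float]) -> np.ndarray:
    """Square-rooted relative covers normalised to sum to one."""
    covers = np.asarray(covers, dtype=float)
    if covers.size == 0:
        raise ValueError("species_weights: no occurrences")
    if np.any(covers <= 0):
        raise ValueError("species_weights: covers must be positive")
    w = np.sqrt(covers)
    return w / w.sum()


def silverman_bandwidth(values: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule of thumb on the weighted sample.

    Uses the weighted standard deviation (and weighted IQR where narrower)
    with the effective sample size n_eff = 1 / sum(w_i^2).
    """
    mean = float(np.sum(weights * values))
    var = float(np.sum(weights * (values - mean) ** 2))
    sd = np.sqrt(var)
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    q25, q75 = np.interp([0.25, 0.75], cum, values[order])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread == 0.0:
        spread = max(abs(mean), 1.0) * 1e-3  # point-mass-like sample
    n_eff = 1.0 / float(np.sum(weights ** 2))
    return 0.9 * spread * n_eff ** (-1.0 / 5.0)


def weighted_kde(
    values: Sequence[float],
    weights: Sequence[float],
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel mixture density on a regular grid.

    The grid spans [min - 3h, max + 3h].  Returns (grid, density); the
    density integrates to one (trapezoid) up to kernel tail truncation.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(values) != len(weights):
        raise ValueError("values and weights must have equal length")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(values, weights)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo, hi = values.min() - 3.0 * bandwidth, values.max() + 3.0 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    u = (grid[:, None] - values[None, :]) / bandwidth
    density = (weights[None, :] * np.exp(-0.5 * u ** 2)).sum(axis=1)
    density /= bandwidth * np.sqrt(2.0 * np.pi)
    return grid, density


def niche_interval(grid: np.ndarray, density: np.ndarray,
                   lower_q: float = 0.025, upper_q: float = 0.975) -> tuple[float, float]:
    """Quantiles of the discrete distribution given by normalised grid densities."""
    rel = np.asarray(density, dtype=float)
    rel = rel / rel.sum()
    cum = np.cumsum(rel)
    lower = float(grid[np.searchsorted(cum, lower_q, side="left")])
    upper = float(grid[np.searchsorted(cum, upper_q, side="left")])
    return lower, upper


def niche_optimum(values: Sequence[float], weights: Sequence[float]) -> float:
    """Cover-weighted arithmetic mean."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * values))


def species_niche(values: Sequence[float], covers: Sequence[float],
                  taxon_id: str = "", variable: str = "",
                  bandwidth: float | None = None) -> NicheEstimate:
    """Niche summary for one species along one gradient."""
    values = np.asarray(values, dtype=float)
    w = species_weights(covers)
    if len(np.unique(values)) < 2:
        v = float(values[0])
        return NicheEstimate(taxon_id, variable, v, v, v, len(values), v, v)
    grid, density = weighted_kde(values, w, bandwidth)
    lower, upper = niche_interval(grid, density)
    return NicheEstimate(taxon_id, variable, lower, niche_optimum(values, w), upper,
                         len(values), float(values.min()), float(values.max()))


def niche_table(
    dataset: Dataset,
    agg: Mapping[str, AggregatedPlot],
    variables: Sequence[str],
    min_occurrences: int = 50,
    functional_types: Sequence[str] = PARASITE_TYPES,
) -> list[NicheEstimate]:
    """Niche estimates per qualifying species and variable.

    ``variables`` may be environmental predictor names (read from plot
    headers) or ``"eive_<indicator>"`` community means, in which case the
    focal species itself is excluded from each plot's mean.
    """
    traits = dataset.trait_map()
    headers = {h.plot_id: h for h in dataset.headers}
    occurrences: dict[str, list[tuple[str, float]]] = {}
    for pid, plot in agg.items():
        for taxon, rel in plot.species_relative.items():
            if traits[taxon].functional_type in functional_types:
                occurrences.setdefault(taxon, []).append((pid, rel))

    out: list[NicheEstimate] = []
    for taxon in sorted(occurrences):
        occ = occurrences[taxon]
        if len(occ) < min_occurrences:
            continue
        for variable in variables:
            if variable.startswith("eive_"):
                indicator = variable.removeprefix("eive_").upper()
                if indicator not in EIVE_INDICATORS:
                    raise ValueError(f"unknown indicator variable {variable!r}")
                pairs = []
                for pid, rel in occ:
                    m = plot_mean_eive(agg[pid], traits, indicator,
                                       exclude_taxa=[taxon])
                    if m is not None:
                        pairs.append((m, rel))
            else:
                pairs = []
                for pid, rel in occ:
                    env = headers[pid].env
                    if variable not in env:
                        raise ValueError(f"unknown variable {variable!r}")
                    pairs.append((env[variable], rel))
            if len(pairs) < min_occurrences:
                continue
            values = [v for v, _ in pairs]
            covers = [c for _, c in pairs]
            out.append(species_niche(values, covers, taxon, variable))
    return out


def niche_frame(estimates: Sequence[NicheEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "taxon_id": e.taxon_id, "variable": e.variable, "lower": e.lower,
        "optimum": e.optimum, "upper": e.upper, "n_occurrences": e.n_occurrences,
        "observed_min": e.observed_min, "observed_max": e.observed_max,
    } for e in estimates])
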