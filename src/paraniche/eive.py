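"""Community-mean ecological indicator values and the modified permutation test.

Each species carries European ecological indicator values (EIVE) for soil
nitrogen (N), soil moisture (M), soil reaction (R), temperature (T) and
light (L) on a 0-10 scale.  A plot's community mean for an indicator is the
unweighted mean over the species present that have a value, excluding the
species of the focal parasitic functional type (so the mean describes the
host community, not the parasites themselves).

Whether plots occupied by a functional type sit at different community
indicator values than unoccupied plots is tested with a species-level
permutation null: species' indicator values are shuffled among species
(plot composition fixed), the plot means and the occupied-minus-unoccupied
difference recomputed each time.  The standardised effect size is

    SES = (Diff_real - mean(Diff_rand)) / SD(Diff_rand)

and the reported p-value is the fraction of permutations whose difference
exceeds the observed one in the direction of the SES.  Because that p is
one-sided in a data-driven direction, decision rules at level alpha should
compare it to alpha/2 (``p_two_sided`` is provided for this).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import Dataset, EIVE_INDICATORS, TraitRecord
from .cover import AggregatedPlot

logger = logging.getLogger(__name__)


@dataclass
class PermTestResult:
    indicator: str
    functional_type: str
    diff_real: float
    null_diffs: list[float]
    ses: float | None
    p: float
    n_perm: int
    seed: int | None

    @property
    def p_two_sided(self) -> float:
        return min(1.0, 2.0 * self.p)


def aggregate_eive(member_traits: Sequence[TraitRecord]) -> dict[str, float | None]:
    """Per-indicator arithmetic mean over members with data; None if no data."""
    out: dict[str, float | None] = {}
    for ind in EIVE_INDICATORS:
        values = [t.eive(ind) for t in member_traits if t.eive(ind) is not None]
        out[ind] = float(np.mean(values)) if values else None
    return out


def fill_aggregate_eive(traits: Iterable[TraitRecord]) -> list[TraitRecord]:
    """Fill missing indicator values of aggregate taxa from their members."""
    traits = list(traits)
    by_id = {t.taxon_id: t for t in traits}
    for t in traits:
        if not t.is_aggregate:
            continue
        members = [by_id[m] for m in t.member_taxa if m in by_id]
        means = aggregate_eive(members)
        for ind, col in (("N", "eive_n"), ("M", "eive_m"), ("R", "eive_r"),
                         ("T", "eive_t"), ("L", "eive_l")):
            if getattr(t, col) is None and means[ind] is not None:
                setattr(t, col, means[ind])
    return traits


def plot_mean_eive(
    plot: AggregatedPlot,
    traits: Mapping[str, TraitRecord],
    indicator: str,
    exclude_type: str | None = None,
    exclude_taxa: Iterable[str] = (),
) -> float | None:
    """Unweighted mean indicator value over species with data, excluding the
    focal functional type (and/or explicit taxa); None if no species qualify."""
    excluded = set(exclude_taxa)
    values = []
    for taxon in plot.species_cover:
        if taxon in excluded:
            continue
        trait = traits[taxon]
        if exclude_type is not None and trait.functional_type == exclude_type:
            continue
        v = trait.eive(indicator)
        if v is not None:
            values.append(v)
    return float(np.mean(values)) if values else None


def observed_difference(occupied_means: Sequence[float],
                        unoccupied_means: Sequence[float]) -> float:
    """Mean community indicator value in occupied minus unoccupied plots."""
    if len(occupied_means) == 0 or len(unoccupied_means) == 0:
        raise ValueError("both occupied and unoccupied plots are required")
    return float(np.mean(occupied_means) - np.mean(unoccupied_means))


def _membership(
    agg: Mapping[str, AggregatedPlot],
    traits: Mapping[str, TraitRecord],
    indicator: str,
    functional_type: str,
):
    """Presence matrix over the permutation universe (all species with a
    value for the indicator), with focal-type columns zeroed so plot means
    always exclude the focal type, plus the occupancy vector."""
    species = sorted(t.taxon_id for t in traits.values() if t.eive(indicator) is not None)
    if len(species) < 2:
        raise ValueError("need at least 2 species with values for the indicator")
    col = {s: j for j, s in enumerate(species)}
    values = np.array([traits[s].eive(indicator) for s in species], dtype=float)
    usable = ~np.array([traits[s].functional_type == functional_type for s in species])
    plot_ids = sorted(agg)
    M = np.zeros((len(plot_ids), len(species)))
    occupied = np.zeros(len(plot_ids), dtype=bool)
    for i, pid in enumerate(plot_ids):
        plot = agg[pid]
        occupied[i] = bool(plot.type_presence.get(functional_type, 0))
        for taxon in plot.species_cover:
            j = col.get(taxon)
            if j is not None and usable[j]:
                M[i, j] = 1.0
    counts = M.sum(axis=1)
    keep = counts > 0  # plots whose mean is missing after exclusion drop out
    return M[keep], counts[keep], occupied[keep], values


def _diffs_from_values(M, counts, occupied, value_matrix) -> np.ndarray:
    """Occupied-minus-unoccupied difference of plot means, one per column of
    value_matrix (n_species x n_draws)."""
    means = (M @ value_matrix) / counts[:, None]
    return means[occupied].mean(axis=0) - means[~occupied].mean(axis=0)


def modified_permutation_test(
    agg: Mapping[str, AggregatedPlot],
    traits: Mapping[str, TraitRecord],
    functional_type: str,
    indicator: str,
    n_perm: int = 1000,
    seed: int | None = 0,
    exact: bool = False,
) -> PermTestResult:
    """Species-level permutation test of the occupied/unoccupied difference
    in community-mean indicator values.

    With ``exact=True`` all permutations of the species' values are
    enumerated instead of sampled (only feasible for small species pools).
    """
    M, counts, occupied, values = _membership(agg, traits, indicator, functional_type)
    if not occupied.any() or occupied.all():
        raise ValueError("both occupied and unoccupied plots are required")
    diff_real = float(_diffs_from_values(M, counts, occupied, values[:, None])[0])

    if exact:
        perms = np.array(list(itertools.permutations(values)))
        value_matrix = perms.T
        n_used = value_matrix.shape[1]
    else:
        rng = np.random.default_rng(seed)
        value_matrix = np.empty((len(values), n_perm))
        for b in range(n_perm):
            value_matrix[:, b] = rng.permutation(values)
        n_used = n_perm
    # the permutation only reorders the species values
    assert np.allclose(np.sort(value_matrix, axis=0), np.sort(values)[:, None])
    null = _diffs_from_values(M, counts, occupied, value_matrix)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        logger.warning("degenerate permutation null (SD = 0); SES undefined")
        return PermTestResult(indicator, functional_type, diff_real, null.tolist(),
                              None, 1.0, n_used, seed)
    ses = (diff_real - null_mean) / null_sd
    if ses > 0:
        p = float(np.sum(null >= diff_real)) / n_used
    elif ses < 0:
        p = float(np.sum(null <= diff_real)) / n_used
    else:
        p = 1.0
    return PermTestResult(indicator, functional_type, diff_real, null.tolist(),
                          float(ses), p, n_used, seed)


def permutation_tests_all(
    agg: Mapping[str, AggregatedPlot],
    traits: Mapping[str, TraitRecord],
    functional_type: str,
    indicators: Sequence[str] = EIVE_INDICATORS,
    n_perm: int = 1000,
    seed: int | None = 0,
    joint: bool = False,
) -> dict[str, PermTestResult]:
    """Run the permutation test for several indicators.

    ``joint=True`` applies the same species permutation to every indicator
    (values shuffled as 5-tuples); its universe is restricted to species with
    complete values for the requested indicators.  The default permutes each
    indicator independently, matching per-indicator testing.
    """
    if not joint:
        return {ind: modified_permutation_test(agg, traits, functional_type, ind,
                                               n_perm, seed)
                for ind in indicators}
    rng = np.random.default_rng(seed)
    species = sorted(t.taxon_id for t in traits.values()
                     if all(t.eive(ind) is not None for ind in indicators))
    if len(species) < 2:
        raise ValueError("need at least 2 species with complete values for joint mode")
    col = {s: j for j, s in enumerate(species)}
    usable = ~np.array([traits[s].functional_type == functional_type for s in species])
    plot_ids = sorted(agg)
    M = np.zeros((len(plot_ids), len(species)))
    occupied = np.zeros(len(plot_ids), dtype=bool)
    for i, pid in enumerate(plot_ids):
        plot = agg[pid]
        occupied[i] = bool(plot.type_presence.get(functional_type, 0))
        for taxon in plot.species_cover:
            j = col.get(taxon)
            if j is not None and usable[j]:
                M[i, j] = 1.0
    counts = M.sum(axis=1)
    keep = counts > 0
    M, counts, occupied = M[keep], counts[keep], occupied[keep]
    if not occupied.any() or occupied.all():
        raise ValueError("both occupied and unoccupied plots are required")
    perm_idx = np.stack([rng.permutation(len(species)) for _ in range(n_perm)], axis=1)

    out: dict[str, PermTestResult] = {}
    for ind in indicators:
        values = np.array([traits[s].eive(ind) for s in species], dtype=float)
        diff_real = float(_diffs_from_values(M, counts, occupied, values[:, None])[0])
        null = _diffs_from_values(M, counts, occupied, values[perm_idx])
        null_mean, null_sd = float(null.mean()), float(null.std(ddof=1))
        if null_sd == 0.0:
            logger.warning("degenerate permutation null (SD = 0); SES undefined")
            out[ind] = PermTestResult(ind, functional_type, diff_real, null.tolist(),
                                      None, 1.0, n_perm, seed)
            continue
        ses = (diff_real - null_mean) / null_sd
        p = (float(np.sum(null >= diff_real)) / n_perm if ses > 0
             else float(np.sum(null <= diff_real)) / n_perm if ses < 0 else 1.0)
        out[ind] = PermTestResult(ind, functional_type, diff_real, null.tolist(),
                                  float(ses), p, n_perm, seed)
    return out
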