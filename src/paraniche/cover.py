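"""Layer aggregation and relative cover of parasitic functional types.

Vegetation-plot databases record the same species in several vertical
layers (tree / shrub / herb).  Layer records of one species are combined
into a single plot-level cover with the Jennings–Fischer formula, which
treats layers as independently overlapping:

    combined = 100 * (1 - prod_i (1 - c_i / 100))

Relative cover then divides each species' combined cover by the summed
species covers of the plot, and the relative cover of a parasitic
functional type is the sum of the relative covers of its member species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, FUNCTIONAL_TYPES, PARASITE_TYPES, TraitRecord


@dataclass
class AggregatedPlot:
    plot_id: str
    species_cover: dict[str, float] = field(default_factory=dict)
    species_relative: dict[str, float] = field(default_factory=dict)
    type_relative: dict[str, float] = field(default_factory=dict)
    type_presence: dict[str, int] = field(default_factory=dict)


def combine_layers(covers: Sequence[float]) -> float:
    """Combine per-layer covers (%) of one species into a total cover.

    Assumes independent overlap between layers, so the combined cover is the
    union probability of the per-layer covers scaled to percent.  The result
    lies in [max(covers), min(100, sum(covers))].
    """
    if len(covers) == 0:
        raise ValueError("combine_layers: empty cover list")
    for c in covers:
        if not (0.0 < c <= 100.0):
            raise ValueError(f"combine_layers: cover {c} outside (0, 100]")
    prod = 1.0
    for c in covers:
        prod *= 1.0 - c / 100.0
    return 100.0 * (1.0 - prod)


def relative_cover(species_cover: Mapping[str, float]) -> dict[str, float]:
    """Each species' combined cover divided by the plot's summed covers."""
    if not species_cover:
        raise ValueError("relative_cover: empty plot")
    total = float(sum(species_cover.values()))
    return {k: v / total for k, v in species_cover.items()}


def functional_type_cover(
    species_relative: Mapping[str, float],
    traits: Mapping[str, TraitRecord],
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-type sums of member species' relative cover, plus presence flags."""
    type_relative = {t: 0.0 for t in FUNCTIONAL_TYPES}
    type_presence = {t: 0 for t in FUNCTIONAL_TYPES}
    for taxon, rel in species_relative.items():
        trait = traits.get(taxon)
        if trait is None:
            raise ValueError(f"functional_type_cover: no trait record for taxon {taxon!r}")
        type_relative[trait.functional_type] += rel
        type_presence[trait.functional_type] = 1
    return type_relative, type_presence


def aggregate_dataset(dataset: Dataset) -> dict[str, AggregatedPlot]:
    """Aggregate all plots: combine layers per species, compute relative and
    functional-type covers.  Plots without observations get empty maps."""
    obs = dataset.observations_frame()
    traits = dataset.trait_map()
    out = {h.plot_id: AggregatedPlot(plot_id=h.plot_id) for h in dataset.headers}
    if len(obs):
        # Jennings-Fischer via product of (1 - c/100) within (plot, taxon)
        obs = obs.assign(miss=1.0 - obs["cover_pct"] / 100.0)
        prod = obs.groupby(["plot_id", "taxon_id"], sort=True)["miss"].prod()
        combined = 100.0 * (1.0 - prod)
        for (plot_id, taxon_id), cov in combined.items():
            out[plot_id].species_cover[taxon_id] = float(cov)
    for plot in out.values():
        if plot.species_cover:
            plot.species_relative = relative_cover(plot.species_cover)
        plot.type_relative, plot.type_presence = functional_type_cover(
            plot.species_relative, traits)
    return out


def type_cover_frame(agg: Mapping[str, AggregatedPlot],
                     types: Iterable[str] = PARASITE_TYPES) -> pd.DataFrame:
    """Plot × functional-type table of relative cover and presence flags."""
    types = list(types)
    rows = []
    for plot_id, plot in agg.items():
        row: dict[str, object] = {"plot_id": plot_id}
        for t in types:
            row[f"cover_{t}"] = plot.type_relative.get(t, 0.0)
            row[f"presence_{t}"] = plot.type_presence.get(t, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id").sort_index()


def aggregated_frame(agg: Mapping[str, AggregatedPlot]) -> pd.DataFrame:
    """Long plot × species table of combined and relative covers."""
    rows = []
    for plot_id in sorted(agg):
        plot = agg[plot_id]
        for taxon, cov in sorted(plot.species_cover.items()):
            rows.append((plot_id, taxon, cov, plot.species_relative[taxon]))
    return pd.DataFrame(rows, columns=["plot_id", "taxon_id", "cover_pct", "relative_cover"])
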