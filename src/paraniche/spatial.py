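"""Spatial thinning of near-duplicate plots and hexagonal-grid cover maps.

Vegetation-plot archives contain resampled and duplicated plots.  To limit
spatial pseudoreplication, any pair of plots lying within 1 km of each
other and compositionally near-identical (cover-weighted Bray-Curtis)
is reduced to a single randomly selected plot.

For mapping, plot-level relative covers of each parasitic functional type
are averaged over a hexagonal grid (default 50 km flat-to-flat in the
north-south direction, i.e. cell area (sqrt(3)/2) * 50^2 ~ 2165 km^2) and
classified into quantile colour classes, excluding empty cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, mapping

from .data import Dataset, PARASITE_TYPES, PlotHeader
from .cover import AggregatedPlot

EARTH_RADIUS_KM = 6371.0


def plot_distance(a: PlotHeader, b: PlotHeader, crs_mode: str = "planar_km") -> float:
    """Distance in km: Euclidean in planar mode, haversine in degrees mode."""
    if crs_mode == "planar_km":
        return math.hypot(a.x - b.x, a.y - b.y)
    if crs_mode == "degrees":
        lon1, lat1, lon2, lat2 = map(math.radians, (a.x, a.y, b.x, b.y))
        h = (math.sin((lat2 - lat1) / 2) ** 2
             + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2)
        return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))
    raise ValueError(f"unknown crs_mode {crs_mode!r}")


def bray_curtis(a: Mapping[str, float] | Sequence[float],
                b: Mapping[str, float] | Sequence[float]) -> float:
    """Cover-weighted Bray-Curtis dissimilarity: sum|a-b| / sum(a+b)."""
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        keys = sorted(set(a) | set(b))
        av = np.array([a.get(k, 0.0) for k in keys], dtype=float)
        bv = np.array([b.get(k, 0.0) for k in keys], dtype=float)
    else:
        av = np.asarray(a, dtype=float)
        bv = np.asarray(b, dtype=float)
        if av.shape != bv.shape:
            raise ValueError("bray_curtis: vectors must have equal length")
    denom = float(np.sum(av + bv))
    if denom == 0.0:
        raise ValueError("bray_curtis: both compositions empty")
    return float(np.sum(np.abs(av - bv)) / denom)


# ---------------------------------------------------------------------------
# near-duplicate thinning
# ---------------------------------------------------------------------------

@dataclass
class ThinResult:
    retained: set[str]
    dropped: list[tuple[str, str]]  # (dropped plot, conflicting partner retained at the time)


def _candidate_pairs(xy: np.ndarray, dist_km: float) -> np.ndarray:
    """Index pairs with Euclidean distance < dist_km (KD-tree, planar)."""
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=dist_km, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    d = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
    return pairs[d < dist_km]


def conflicting_pairs(
    dataset: Dataset,
    agg: Mapping[str, AggregatedPlot],
    dist_km: float = 1.0,
    sim_threshold: float = 0.8,
    mode: str = "similarity",
) -> list[tuple[str, str]]:
    """All plot pairs violating the distance + compositional-similarity rule.

    ``mode="similarity"`` flags pairs with (1 - Bray-Curtis) > sim_threshold;
    ``mode="dissimilarity"`` applies the threshold to the dissimilarity itself.
    """
    if mode not in ("similarity", "dissimilarity"):
        raise ValueError(f"unknown mode {mode!r}")
    headers = dataset.headers
    ids = [h.plot_id for h in headers]
    if dataset.crs_mode == "planar_km":
        xy = np.array([[h.x, h.y] for h in headers])
        pairs = _candidate_pairs(xy, dist_km)
    else:
        # small-angle prefilter in degrees, exact haversine check after
        deg = dist_km / 111.0 * 1.5
        xy = np.array([[h.x, h.y] for h in headers])
        cand = _candidate_pairs(xy, deg)
        keep = [(i, j) for i, j in cand
                if plot_distance(headers[i], headers[j], "degrees") < dist_km]
        pairs = np.array(keep, dtype=int).reshape(-1, 2)
    out = []
    for i, j in pairs:
        a, b = agg[ids[i]].species_cover, agg[ids[j]].species_cover
        if not a and not b:
            continue
        bc = bray_curtis(a, b)
        hit = (1.0 - bc) > sim_threshold if mode == "similarity" else bc > sim_threshold
        if hit:
            out.append((ids[i], ids[j]))
    return out


def thin_plots(
    dataset: Dataset,
    agg: Mapping[str, AggregatedPlot],
    dist_km: float = 1.0,
    sim_threshold: float = 0.8,
    mode: str = "similarity",
    seed: int = 0,
) -> ThinResult:
    """Drop plots until no retained pair is both close and near-identical.

    Conflict edges are visited in seed-shuffled order; for each edge whose
    endpoints are both still retained, a uniformly random endpoint is dropped.
    The result satisfies the pair rule and is reproducible given the seed.
    """
    edges = conflicting_pairs(dataset, agg, dist_km, sim_threshold, mode)
    rng = np.random.default_rng(seed)
    retained = {h.plot_id for h in dataset.headers}
    dropped: list[tuple[str, str]] = []
    order = rng.permutation(len(edges))
    for k in order:
        a, b = edges[k]
        if a in retained and b in retained:
            victim, partner = (a, b) if rng.random() < 0.5 else (b, a)
            retained.discard(victim)
            dropped.append((victim, partner))
    return ThinResult(retained=retained, dropped=dropped)


# ---------------------------------------------------------------------------
# hexagonal grid
# ---------------------------------------------------------------------------

@dataclass
class HexGrid:
    """Flat-top hexagons whose flat-to-flat width (north-south) is cell_width_km.

    Cell area is (sqrt(3)/2) * width^2; a 50-km grid gives 2165.06 km^2.
    """

    cell_width_km: float
    centers: np.ndarray  # (n_cells, 2)
    polygons: list[Polygon]
    n_plots: np.ndarray | None = None
    mean_cover: dict[str, np.ndarray] = field(default_factory=dict)
    classes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cell_area_km2(self) -> float:
        return (math.sqrt(3.0) / 2.0) * self.cell_width_km ** 2

    def assign(self, xy: np.ndarray) -> np.ndarray:
        """Cell index for each point: nearest hexagon centre (the hexagonal
        tiling is the Voronoi partition of its centres, so every point maps
        to exactly one cell)."""
        tree = cKDTree(self.centers)
        _, idx = tree.query(np.atleast_2d(xy))
        return idx

    def to_geojson(self) -> dict:
        features = []
        for i, poly in enumerate(self.polygons):
            props: dict[str, object] = {"cell_id": i}
            if self.n_plots is not None:
                props["n_plots"] = int(self.n_plots[i])
            for t, means in self.mean_cover.items():
                v = means[i]
                props[f"mean_cover_{t}"] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            for t, cls in self.classes.items():
                c = cls[i]
                props[f"class_{t}"] = None if c is None or c < 0 else int(c)
            features.append({
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": props,
            })
        return {"type": "FeatureCollection", "features": features}


def hexagon(cx: float, cy: float, width_km: float) -> Polygon:
    s = width_km / math.sqrt(3.0)  # side length
    w2 = width_km / 2.0
    return Polygon([
        (cx + s, cy), (cx + s / 2.0, cy + w2), (cx - s / 2.0, cy + w2),
        (cx - s, cy), (cx - s / 2.0, cy - w2), (cx + s / 2.0, cy - w2),
    ])


def build_hex_grid(bbox: tuple[float, float, float, float],
                   width_km: float = 50.0) -> HexGrid:
    """Tile a planar bounding box (xmin, ymin, xmax, ymax) with hexagons."""
    if width_km <= 0:
        raise ValueError("width_km must be positive")
    xmin, ymin, xmax, ymax = bbox
    if xmax < xmin or ymax < ymin:
        raise ValueError("degenerate bbox: max < min")
    s = width_km / math.sqrt(3.0)
    dx = 1.5 * s
    centers = []
    col_lo = math.floor((xmin - s) / dx)
    col_hi = math.ceil((xmax + s) / dx)
    for col in range(col_lo, col_hi + 1):
        cx = col * dx
        y_off = (width_km / 2.0) if (col % 2) else 0.0
        row_lo = math.floor((ymin - width_km - y_off) / width_km)
        row_hi = math.ceil((ymax + width_km - y_off) / width_km)
        for row in range(row_lo, row_hi + 1):
            cy = row * width_km + y_off
            centers.append((cx, cy))
    centers_arr = np.array(centers)
    polys = [hexagon(cx, cy, width_km) for cx, cy in centers]
    return HexGrid(cell_width_km=width_km, centers=centers_arr, polygons=polys)


def grid_summarise(
    grid: HexGrid,
    xy: np.ndarray,
    type_relative: Mapping[str, np.ndarray],
    min_plots: int = 5,
) -> HexGrid:
    """Per-cell plot counts and mean relative cover per functional type.

    Cells with fewer than ``min_plots`` plots get NaN means (shown as null in
    GeoJSON), mirroring the map rule of only summarising well-sampled cells.
    """
    idx = grid.assign(np.asarray(xy, dtype=float))
    n_cells = len(grid.polygons)
    counts = np.bincount(idx, minlength=n_cells)
    grid.n_plots = counts
    for t, values in type_relative.items():
        sums = np.bincount(idx, weights=np.asarray(values, dtype=float), minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        means[counts < min_plots] = np.nan
        grid.mean_cover[t] = means
    return grid


def quantile_classes(values: np.ndarray, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Quantile colour classes, computed over non-zero values only.

    Zero (and NaN) cells are assigned class 0 (-1 for NaN); non-zero cells are
    split into k classes 1..k with linear-interpolation quantile breaks.
    Returns (breaks, classes); with fewer than k distinct non-zero values the
    number of classes shrinks and a warning is issued.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = np.asarray(values, dtype=float)
    classes = np.zeros(len(values), dtype=int)
    classes[np.isnan(values)] = -1
    nonzero = values[np.nan_to_num(values) > 0]
    if len(nonzero) == 0:
        return np.array([]), classes
    breaks = np.quantile(nonzero, np.linspace(0, 1, k + 1)[1:-1], method="linear")
    breaks = np.unique(breaks)
    if len(breaks) < k - 1:
        warnings.warn(f"only {len(breaks) + 1} distinct quantile classes possible "
                      f"(requested {k})", stacklevel=2)
    mask = np.nan_to_num(values) > 0
    classes[mask] = np.searchsorted(breaks, values[mask], side="left") + 1
    return breaks, classes
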