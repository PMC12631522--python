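"""Domain types and tabular IO for vegetation-plot datasets.

The package works on three long-format tables:

* ``plots.csv`` — one row per vegetation plot: coordinates, plot size,
  habitat code, binary habitat descriptors (open / wet / saline) and
  environmental covariates (CHELSA-style bioclim variables, potential
  evapotranspiration, terrain ruggedness).
* ``observations.csv`` — one row per (plot, species, vegetation layer)
  with a percentage cover in (0, 100].
* ``traits.csv`` — one row per taxon: parasitic functional type and the
  five European ecological indicator values (EIVE: nitrogen, moisture,
  reaction, temperature, light), each on a 0–10 scale or missing.

Coordinates are either decimal degrees (distances via haversine) or a
planar km frame (Euclidean distances); the dataset carries a CRS-mode
flag so downstream spatial code never has to guess.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FUNCTIONAL_TYPES = ("euphytoid", "obligate_root", "vine", "mistletoe", "autotroph")
#: the three functional types analysed quantitatively (mistletoes are too
#: sparse and geographically biased for inference and are kept only as labels)
PARASITE_TYPES = ("euphytoid", "obligate_root", "vine")
EIVE_INDICATORS = ("N", "M", "R", "T", "L")
EIVE_COLUMNS = {"N": "eive_n", "M": "eive_m", "R": "eive_r", "T": "eive_t", "L": "eive_l"}

ENV_PREDICTORS = ("bio2", "bio4", "bio10", "bio12", "bio15", "bio18", "pet_penman", "tri")

PLOT_COLUMNS = [
    "plot_id", "x", "y", "plot_size_m2", "habitat_code", "open", "wet", "saline",
    *ENV_PREDICTORS,
]
OBS_COLUMNS = ["plot_id", "taxon_id", "layer_id", "cover_pct"]
TRAIT_COLUMNS = [
    "taxon_id", "functional_type", "eive_n", "eive_m", "eive_r", "eive_t", "eive_l",
    "member_taxa",
]


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong dialect."""


@dataclass
class TraitRecord:
    taxon_id: str
    functional_type: str
    eive_n: float | None = None
    eive_m: float | None = None
    eive_r: float | None = None
    eive_t: float | None = None
    eive_l: float | None = None
    is_aggregate: bool = False
    member_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.functional_type not in FUNCTIONAL_TYPES:
            raise ValueError(
                f"unknown functional type {self.functional_type!r} for taxon {self.taxon_id}"
            )
        for name in ("eive_n", "eive_m", "eive_r", "eive_t", "eive_l"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 10.0):
                raise ValueError(f"{name}={v} outside [0, 10] for taxon {self.taxon_id}")
        if self.is_aggregate and not self.member_taxa:
            raise ValueError(f"aggregate {self.taxon_id} has no member taxa")

    def eive(self, indicator: str) -> float | None:
        return getattr(self, EIVE_COLUMNS[indicator])


@dataclass
class PlotHeader:
    plot_id: str
    x: float
    y: float
    plot_size_m2: float | None = None
    habitat_code: str = ""
    open: int = 0
    wet: int = 0
    saline: int = 0
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("open", "wet", "saline"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name}={getattr(self, name)} not binary in plot {self.plot_id}")
        if self.plot_size_m2 is not None and not self.plot_size_m2 > 0:
            raise ValueError(f"plot_size_m2={self.plot_size_m2} not positive in plot {self.plot_id}")


@dataclass
class LayerObservation:
    plot_id: str
    taxon_id: str
    layer_id: int
    cover_pct: float

    def __post_init__(self) -> None:
        if not (0.0 < self.cover_pct <= 100.0):
            raise ValueError(
                f"cover_pct={self.cover_pct} outside (0, 100] for "
                f"({self.plot_id}, {self.taxon_id}, layer {self.layer_id})"
            )


@dataclass
class Dataset:
    """A validated triple of plot headers, layer observations and traits."""

    headers: list[PlotHeader]
    observations: list[LayerObservation]
    traits: list[TraitRecord]
    crs_mode: str = "planar_km"  # "planar_km" | "degrees"

    def __post_init__(self) -> None:
        if self.crs_mode not in ("planar_km", "degrees"):
            raise ValueError(f"unknown crs_mode {self.crs_mode!r}")
        self.validate()

    def validate(self) -> None:
        plot_ids = {h.plot_id for h in self.headers}
        if len(plot_ids) != len(self.headers):
            raise ValueError("duplicate plot_id in headers")
        taxon_ids = {t.taxon_id for t in self.traits}
        if len(taxon_ids) != len(self.traits):
            raise ValueError("duplicate taxon_id in traits")
        seen: set[tuple[str, str, int]] = set()
        for i, obs in enumerate(self.observations):
            if obs.plot_id not in plot_ids:
                raise ValueError(f"observation row {i}: unknown plot_id {obs.plot_id!r}")
            if obs.taxon_id not in taxon_ids:
                raise ValueError(f"observation row {i}: unknown taxon_id {obs.taxon_id!r}")
            key = (obs.plot_id, obs.taxon_id, obs.layer_id)
            if key in seen:
                raise ValueError(f"observation row {i}: duplicate (plot, taxon, layer) {key}")
            seen.add(key)

    # -- frame views -------------------------------------------------------
    def headers_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.headers:
            row: dict[str, Any] = {
                "plot_id": h.plot_id, "x": h.x, "y": h.y,
                "plot_size_m2": np.nan if h.plot_size_m2 is None else h.plot_size_m2,
                "habitat_code": h.habitat_code,
                "open": h.open, "wet": h.wet, "saline": h.saline,
            }
            for k in ENV_PREDICTORS:
                row[k] = h.env.get(k, np.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=PLOT_COLUMNS)

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(o.plot_id, o.taxon_id, o.layer_id, o.cover_pct) for o in self.observations],
            columns=OBS_COLUMNS,
        )

    def traits_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.traits:
            rows.append({
                "taxon_id": t.taxon_id, "functional_type": t.functional_type,
                "eive_n": np.nan if t.eive_n is None else t.eive_n,
                "eive_m": np.nan if t.eive_m is None else t.eive_m,
                "eive_r": np.nan if t.eive_r is None else t.eive_r,
                "eive_t": np.nan if t.eive_t is None else t.eive_t,
                "eive_l": np.nan if t.eive_l is None else t.eive_l,
                "member_taxa": ";".join(t.member_taxa),
            })
        return pd.DataFrame(rows, columns=TRAIT_COLUMNS)

    def trait_map(self) -> dict[str, TraitRecord]:
        return {t.taxon_id: t for t in self.traits}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _opt_float(v: Any) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def read_dataset(
    plot_path: str | Path,
    obs_path: str | Path,
    trait_path: str | Path,
    crs_mode: str = "planar_km",
) -> Dataset:
    """Read and validate the three CSV tables into a :class:`Dataset`.

    Comma-separated, UTF-8, header row required; missing values are empty
    fields.  Missing EIVE values are legal; missing covers are not.
    """
    plots = pd.read_csv(plot_path, dtype={"plot_id": str, "habitat_code": str})
    obs = pd.read_csv(obs_path, dtype={"plot_id": str, "taxon_id": str})
    traits = pd.read_csv(trait_path, dtype={"taxon_id": str, "member_taxa": str})
    _require_columns(plots, PLOT_COLUMNS, "plots")
    _require_columns(obs, OBS_COLUMNS, "observations")
    _require_columns(traits, TRAIT_COLUMNS, "traits")

    headers = []
    for i, r in plots.iterrows():
        try:
            headers.append(PlotHeader(
                plot_id=r["plot_id"], x=float(r["x"]), y=float(r["y"]),
                plot_size_m2=_opt_float(r["plot_size_m2"]),
                habitat_code="" if pd.isna(r["habitat_code"]) else str(r["habitat_code"]),
                open=int(r["open"]), wet=int(r["wet"]), saline=int(r["saline"]),
                env={k: float(r[k]) for k in ENV_PREDICTORS if not pd.isna(r[k])},
            ))
        except ValueError as exc:
            raise ValueError(f"plots row {i}: {exc}") from exc

    observations = []
    for i, r in obs.iterrows():
        if pd.isna(r["cover_pct"]):
            raise ValueError(f"observations row {i}: missing cover_pct")
        try:
            observations.append(LayerObservation(
                plot_id=r["plot_id"], taxon_id=r["taxon_id"],
                layer_id=int(r["layer_id"]), cover_pct=float(r["cover_pct"]),
            ))
        except ValueError as exc:
            raise ValueError(f"observations row {i}: {exc}") from exc

    trait_records = []
    for i, r in traits.iterrows():
        members_raw = r["member_taxa"]
        members = [] if pd.isna(members_raw) or members_raw == "" else str(members_raw).split(";")
        try:
            trait_records.append(TraitRecord(
                taxon_id=r["taxon_id"], functional_type=str(r["functional_type"]),
                eive_n=_opt_float(r["eive_n"]), eive_m=_opt_float(r["eive_m"]),
                eive_r=_opt_float(r["eive_r"]), eive_t=_opt_float(r["eive_t"]),
                eive_l=_opt_float(r["eive_l"]),
                is_aggregate=bool(members), member_taxa=members,
            ))
        except ValueError as exc:
            raise ValueError(f"traits row {i}: {exc}") from exc

    return Dataset(headers=headers, observations=observations, traits=trait_records,
                   crs_mode=crs_mode)


def write_dataset(dataset: Dataset, plot_path: str | Path, obs_path: str | Path,
                  trait_path: str | Path) -> None:
    dataset.headers_frame().to_csv(plot_path, index=False)
    dataset.observations_frame().to_csv(obs_path, index=False)
    dataset.traits_frame().to_csv(trait_path, index=False)


# ---------------------------------------------------------------------------
# result serialisation
# ---------------------------------------------------------------------------

def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is None or isinstance(obj, (str, int, float, bool)):
        if isinstance(obj, float) and math.isnan(obj):
            return None
        return obj
    raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def write_results(obj: Any, path: str | Path) -> Path:
    """Serialise a result object to JSON (or GeoJSON for hex grids).

    Accepts dataclass result types, lists of them, or plain dicts.  Objects
    exposing ``__geo_interface__``-style output via a ``to_geojson`` method
    (the hexagonal grid) are written as a GeoJSON FeatureCollection.
    """
    path = Path(path)
    if hasattr(obj, "to_geojson"):
        payload = obj.to_geojson()
    else:
        payload = _to_jsonable(obj)
    path.write_text(json.dumps(payload, indent=1, allow_nan=False), encoding="utf-8")
    return path


def read_results(path: str | Path) -> Any:
    return json.loads(Path(path).read_text(encoding="utf-8"))
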