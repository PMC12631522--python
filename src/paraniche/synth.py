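"""Synthetic vegetation-plot datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* plots scattered on a planar km frame with environmental covariates drawn
  on smooth spatial fields (sums of planar sinusoids plus white noise; an
  ``spatially_iid`` switch disables the spatial structure),
* a species pool mixing autotrophs with parasitic functional types in
  configurable proportions,
* plot-level occupancy of each parasitic type following a logistic model on
  standardised environmental predictors (``effect_spec``), with the
  intercept calibrated by root finding so the realised prevalence matches
  the configured one,
* species indicator values (EIVE) built as habitat optimum + noise, and
  community composition of occupied plots exponentially tilted so that the
  community-mean indicator value differs between occupied and unoccupied
  plots by a configured shift (the tilt coefficient is solved numerically
  against the autotroph pool),
* right-skewed (truncated log-normal) covers split across vegetation
  layers, and
* a configurable fraction of plots cloned as near-duplicates within 1 km
  and Bray-Curtis dissimilarity well below 0.2.

Everything is a pure function of the seed: the same configuration produces
byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import (Dataset, ENV_PREDICTORS, EIVE_COLUMNS, EIVE_INDICATORS,
                   LayerObservation, PARASITE_TYPES, PlotHeader, TraitRecord)


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


#: indicators whose community means are shifted between occupied and
#: unoccupied plots (soil reaction is left unshifted)
SHIFTED_INDICATORS = ("N", "M", "T", "L")

# (mean, sd, lower clip) of each environmental covariate, on the units the
# headers use: bio2 degC, bio4 degC/100, bio10 degC, bio12/bio15/bio18 mm,
# PET mm, TRI m
ENV_MARGINALS: dict[str, tuple[float, float, float | None]] = {
    "bio2": (9.0, 2.0, 0.5),
    "bio4": (650.0, 150.0, 50.0),
    "bio10": (16.0, 4.0, None),
    "bio12": (700.0, 250.0, 50.0),
    "bio15": (30.0, 10.0, 2.0),
    "bio18": (220.0, 80.0, 5.0),
    "pet_penman": (80.0, 20.0, 10.0),
    "tri": (150.0, 120.0, 0.0),
}

DEFAULT_TYPE_PROPORTIONS = {"euphytoid": 0.088, "obligate_root": 0.026, "vine": 0.006}
DEFAULT_TYPE_PREVALENCE = {"euphytoid": 0.25, "obligate_root": 0.10, "vine": 0.05}
DEFAULT_EFFECT_SPEC: dict[str, list[tuple[str, float]]] = {
    "euphytoid": [("bio10", -1.0), ("bio18", 0.8), ("bio15", -0.5), ("tri", 0.5)],
    "obligate_root": [("bio10", 1.0), ("bio15", 0.6), ("tri", 0.5)],
    "vine": [("bio10", 0.8), ("bio12", -0.5), ("bio15", 0.5)],
}
DEFAULT_EIVE_SHIFT = {"euphytoid": -0.5, "obligate_root": -0.4, "vine": -0.3}


@dataclass
class SynthConfig:
    n_plots: int = 2000
    n_species: int = 300
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS))
    type_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PREVALENCE))
    effect_spec: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {t: list(v) for t, v in DEFAULT_EFFECT_SPEC.items()})
    eive_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EIVE_SHIFT))
    dup_pair_fraction: float = 0.05
    n_layers_max: int = 3
    mean_richness: float = 15.0
    eive_missing_rate: float = 0.1
    domain_km: float = 1000.0
    spatially_iid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots <= 0 or self.n_species <= 0:
            raise ConfigError("n_plots and n_species must be positive")
        total = sum(self.type_proportions.values())
        if total > 1.0 + 1e-12:
            raise ConfigError("type proportions sum to more than 1")
        for t in self.type_proportions:
            if t not in PARASITE_TYPES + ("mistletoe",):
                raise ConfigError(f"unknown functional type {t!r}")
        if not (0.0 <= self.dup_pair_fraction < 1.0):
            raise ConfigError("dup_pair_fraction must be in [0, 1)")
        if self.n_layers_max < 1:
            raise ConfigError("n_layers_max must be >= 1")


@dataclass
class GroundTruth:
    effect_spec: dict[str, list[tuple[str, float]]]
    eive_shift: dict[str, float]
    type_prevalence: dict[str, float]
    intercepts: dict[str, float]
    tilt_coefficients: dict[str, dict[str, float]]
    species_by_type: dict[str, list[str]]
    duplicate_pairs: list[tuple[str, str]]
    occupancy: dict[str, list[str]]


def _spatial_field(xy: np.ndarray, rng: np.random.Generator,
                   domain_km: float) -> np.ndarray:
    """Sum of 3 planar sinusoids, standardised to unit variance."""
    f = np.zeros(len(xy))
    for _ in range(3):
        wavelength = rng.uniform(0.2, 0.8) * domain_km
        theta = rng.uniform(0.0, 2.0 * np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        proj = (xy[:, 0] * np.cos(theta) + xy[:, 1] * np.sin(theta))
        f += rng.uniform(0.5, 1.0) * np.sin(2.0 * np.pi * proj / wavelength + phase)
    sd = f.std()
    return f / sd if sd > 0 else f


def _calibrate_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept b with mean(expit(b + lp)) == prevalence."""
    def gap(b: float) -> float:
        return float(np.mean(expit(b + lp))) - prevalence
    return brentq(gap, -30.0, 30.0, xtol=1e-10)


def _solve_tilt(values: np.ndarray, weights: np.ndarray, shift: float) -> float:
    """Tilt coefficient l with tilted pool mean = base mean + shift.

    The tilted pool draws species j with weight w_j * exp(l * e_j)."""
    base = float(np.sum(weights * values) / np.sum(weights))
    if shift == 0.0:
        return 0.0
    lo, hi = values.min(), values.max()
    if not (lo < base + shift < hi):
        raise ConfigError(f"eive shift {shift} puts the target mean outside the pool range")
    def gap(l: float) -> float:
        w = weights * np.exp(l * (values - base))  # centred for stability
        return float(np.sum(w * values) / np.sum(w)) - base - shift
    return brentq(gap, -8.0, 8.0, xtol=1e-12)


def _species_pool(cfg: SynthConfig, rng: np.random.Generator):
    counts = {t: int(round(p * cfg.n_species)) for t, p in cfg.type_proportions.items()}
    n_parasites = sum(counts.values())
    if n_parasites >= cfg.n_species:
        raise ConfigError("no autotroph species left in the pool")
    for t, shift in cfg.eive_shift.items():
        if shift != 0.0 and counts.get(t, 0) == 0:
            raise ConfigError(f"eive_shift configured for {t} but the pool has no such species")
    for t, prev in cfg.type_prevalence.items():
        if prev > 0.0 and counts.get(t, 0) == 0:
            raise ConfigError(f"prevalence configured for {t} but the pool has no such species")
    species_by_type: dict[str, list[str]] = {}
    traits: list[TraitRecord] = []
    abundance: dict[str, float] = {}
    for t in sorted(counts) + ["autotroph"]:
        n = counts[t] if t != "autotroph" else cfg.n_species - n_parasites
        ids = [f"sp_{t}_{i:04d}" for i in range(n)]
        species_by_type[t] = ids
        for sid in ids:
            eive: dict[str, float | None] = {}
            for ind in EIVE_INDICATORS:
                if rng.random() < cfg.eive_missing_rate:
                    eive[ind] = None
                else:
                    optimum = rng.uniform(2.0, 8.0)
                    eive[ind] = float(np.clip(optimum + rng.normal(0.0, 1.0), 0.0, 10.0))
            traits.append(TraitRecord(
                taxon_id=sid, functional_type=t,
                eive_n=eive["N"], eive_m=eive["M"], eive_r=eive["R"],
                eive_t=eive["T"], eive_l=eive["L"]))
            abundance[sid] = float(rng.lognormal(0.0, 1.0))
    return species_by_type, traits, abundance


def _truncated_lognormal_cover(rng: np.random.Generator, mu: float, sigma: float) -> float:
    c = float(rng.lognormal(mu, sigma))
    return float(np.clip(c, 0.1, 100.0))


def generate_dataset(cfg: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset plus the ground truth used to build it."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_plots
    xy = rng.uniform(0.0, cfg.domain_km, size=(n, 2))

    env = {}
    for name in ENV_PREDICTORS:
        mean, sd, lo = ENV_MARGINALS[name]
        if cfg.spatially_iid:
            raw = rng.normal(0.0, 1.0, n)
        else:
            raw = 0.75 * _spatial_field(xy, rng, cfg.domain_km) + 0.66 * rng.normal(0.0, 1.0, n)
        values = mean + sd * raw
        if lo is not None:
            values = np.clip(values, lo, None)
        env[name] = values

    species_by_type, traits, abundance = _species_pool(cfg, rng)
    trait_by_id = {t.taxon_id: t for t in traits}

    # occupancy of each parasitic type: logistic on standardised predictors
    occupancy: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    for t, prevalence in cfg.type_prevalence.items():
        if not species_by_type.get(t):
            continue
        lp = np.zeros(n)
        for name, coef in cfg.effect_spec.get(t, []):
            z = (env[name] - env[name].mean()) / env[name].std()
            lp += coef * z
        b = _calibrate_intercept(lp, prevalence)
        intercepts[t] = b
        occupancy[t] = rng.random(n) < expit(b + lp)

    # tilt coefficients: shift of the autotroph community mean per indicator
    autotrophs = species_by_type["autotroph"]
    auto_abund = np.array([abundance[s] for s in autotrophs])
    tilts: dict[str, dict[str, float]] = {}
    for t, shift in cfg.eive_shift.items():
        if t not in occupancy:
            continue
        tilts[t] = {}
        for ind in SHIFTED_INDICATORS:
            have = np.array([trait_by_id[s].eive(ind) is not None for s in autotrophs])
            vals = np.array([trait_by_id[s].eive(ind) or 0.0 for s in autotrophs])
            tilts[t][ind] = _solve_tilt(vals[have], auto_abund[have], shift)

    # per-plot composition
    headers: list[PlotHeader] = []
    observations: list[LayerObservation] = []
    eive_matrix = {ind: np.array([
        trait_by_id[s].eive(ind) if trait_by_id[s].eive(ind) is not None else np.nan
        for s in autotrophs]) for ind in SHIFTED_INDICATORS}
    # species with a missing value are tilt-neutral (weight factor 1)
    centred = {ind: np.nan_to_num(
        eive_matrix[ind] - np.nanmean(eive_matrix[ind]), nan=0.0)
        for ind in SHIFTED_INDICATORS}
    plot_sizes = np.array([1.0, 4.0, 16.0, 25.0, 100.0])

    for i in range(n):
        pid = f"P{i:05d}"
        logw = np.log(auto_abund)
        for t, occ in occupancy.items():
            if occ[i]:
                for ind in SHIFTED_INDICATORS:
                    logw = logw + tilts[t][ind] * centred[ind]
        w = np.exp(logw - logw.max())
        w /= w.sum()
        richness = min(1 + rng.poisson(cfg.mean_richness - 1.0), len(autotrophs))
        chosen = list(rng.choice(len(autotrophs), size=richness, replace=False, p=w))
        plot_species = [autotrophs[j] for j in chosen]
        for t, occ in occupancy.items():
            if occ[i]:
                pool = species_by_type[t]
                k = min(1 + int(rng.random() < 0.3), len(pool))
                plot_species += [pool[j] for j in
                                 rng.choice(len(pool), size=k, replace=False)]
        for sid in plot_species:
            parasite = trait_by_id[sid].functional_type != "autotroph"
            total = _truncated_lognormal_cover(
                rng, np.log(3.0) if parasite else np.log(10.0), 0.8 if parasite else 1.0)
            n_layers = int(rng.integers(1, cfg.n_layers_max + 1))
            shares = rng.dirichlet(np.ones(n_layers))
            for layer in range(n_layers):
                c = max(total * shares[layer], 1e-3)
                observations.append(LayerObservation(pid, sid, layer + 1, float(min(c, 100.0))))
        size = float(rng.choice(plot_sizes))
        headers.append(PlotHeader(
            plot_id=pid, x=float(xy[i, 0]), y=float(xy[i, 1]),
            plot_size_m2=None if rng.random() < 0.15 else size,
            habitat_code=f"H{int(rng.integers(1, 9))}",
            open=int(rng.random() < 0.6), wet=int(rng.random() < 0.15),
            saline=int(rng.random() < 0.05),
            env={k: float(env[k][i]) for k in ENV_PREDICTORS}))

    # near-duplicate clones
    n_dup = int(round(cfg.dup_pair_fraction * n))
    duplicate_pairs: list[tuple[str, str]] = []
    if n_dup > 0:
        originals = rng.choice(n, size=n_dup, replace=False)
        obs_by_plot: dict[str, list[LayerObservation]] = {}
        for o in observations:
            obs_by_plot.setdefault(o.plot_id, []).append(o)
        for i in sorted(originals):
            src = headers[i]
            clone_id = f"{src.plot_id}d"
            angle = rng.uniform(0.0, 2.0 * np.pi)
            radius = rng.uniform(0.1, 0.5)
            headers.append(PlotHeader(
                plot_id=clone_id,
                x=src.x + radius * np.cos(angle), y=src.y + radius * np.sin(angle),
                plot_size_m2=src.plot_size_m2, habitat_code=src.habitat_code,
                open=src.open, wet=src.wet, saline=src.saline, env=dict(src.env)))
            for o in obs_by_plot.get(src.plot_id, []):
                factor = rng.uniform(0.92, 1.08)
                observations.append(LayerObservation(
                    clone_id, o.taxon_id, o.layer_id,
                    float(np.clip(o.cover_pct * factor, 1e-3, 100.0))))
            duplicate_pairs.append((src.plot_id, clone_id))

    dataset = Dataset(headers=headers, observations=observations, traits=traits,
                      crs_mode="planar_km")
    truth = GroundTruth(
        effect_spec={t: list(v) for t, v in cfg.effect_spec.items()},
        eive_shift=dict(cfg.eive_shift),
        type_prevalence=dict(cfg.type_prevalence),
        intercepts=intercepts,
        tilt_coefficients=tilts,
        species_by_type=species_by_type,
        duplicate_pairs=duplicate_pairs,
        occupancy={t: [f"P{i:05d}" for i in np.flatnonzero(occ)]
                   for t, occ in occupancy.items()},
    )
    return dataset, truth


def null_dataset(cfg: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """As :func:`generate_dataset` with no environmental effects and no
    indicator shifts: occupancy independent of environment and of EIVE."""
    null_cfg = dataclasses.replace(
        cfg,
        effect_spec={},
        eive_shift={t: 0.0 for t in cfg.eive_shift},
    )
    return generate_dataset(null_cfg)
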