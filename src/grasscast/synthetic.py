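"""Synthetic landscapes with known truth for exercising the full pipeline.

Generates spatially autocorrelated environmental stacks (Gaussian-smoothed,
standardized white noise), virtual species with known logistic responses
assigned to vegetation types and functional classes, presence points sampled
proportional to true suitability, additive climate-scenario stacks, a
non-grassland exclusion mask, and a noisy truth-derived survey map.

Every generator is deterministic given its seed; a master seed derives all
sub-seeds by fixed offsets (see :func:`subseed`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .composite import SpeciesCatalog
from .occurrences import OccurrenceSet, write_occurrences
from .rasters import EnvStack, GridGeometry, write_ascii_grid

__all__ = [
    "LandscapeConfig", "TrueSpecies", "ScenarioDelta", "subseed",
    "generate_env_stack", "species_truth_map", "make_species_truths",
    "sample_occurrences", "apply_scenario", "default_scenarios",
    "make_survey_map", "make_exclusion_mask", "simulate_dataset",
]

#: warming (scaled units) attached to each scenario label
SSP_WARMING = {"SSP126": 2.0, "SSP245": 3.0, "SSP370": 4.1, "SSP585": 5.0}


def subseed(master: int, offset: int) -> int:
    """Derive a sub-seed from the master seed by a fixed offset (< 2^31)."""
    return int((master * 100_003 + offset) % (2**31 - 1))


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and statistical structure shared by all synthetic products."""

    n_rows: int = 64
    n_cols: int = 64
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    n_climate_layers: int = 3
    n_static_layers: int = 2
    autocorr_range: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.autocorr_range < 0:
            raise ValueError("autocorr_range must be >= 0")
        if self.n_climate_layers < 1:
            raise ValueError("need at least one climate layer")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.n_rows, self.n_cols,
                            self.origin[0], self.origin[1], self.cell_size)


@dataclass
class TrueSpecies:
    """A virtual species with a known (inverse-logit) environmental response."""

    species_id: str
    vegetation_type: int
    functional_class: str
    response_weights: dict[str, float]
    intercept: float
    response_shape: str = "linear"     # linear | hinge


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive per-layer shifts applied to climate layers only."""

    scenario_id: str
    shifts: dict[str, float] = field(default_factory=dict)


def generate_env_stack(config: LandscapeConfig) -> EnvStack:
    """Smoothed, standardized white-noise layers sharing one geometry.

    Each layer is white noise convolved with a Gaussian kernel of scale
    ``autocorr_range`` (cells), then standardized to mean 0 / sd 1 over valid
    cells.  Layers are named ``clim_01..`` (role climate) and ``stat_01..``
    (role static).
    """
    rng = np.random.default_rng(subseed(config.seed, 0))
    layers: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    specs = ([(f"clim_{i + 1:02d}", "climate") for i in range(config.n_climate_layers)]
             + [(f"stat_{i + 1:02d}", "static") for i in range(config.n_static_layers)])
    for name, role in specs:
        z = rng.standard_normal(config.geometry.shape)
        if config.autocorr_range > 0:
            z = ndimage.gaussian_filter(z, sigma=config.autocorr_range, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers[name] = z
        roles[name] = role
    return EnvStack(layers, config.geometry, roles, "baseline")


def species_truth_map(stack: EnvStack, weights: dict[str, float], intercept: float,
                      shape: str = "linear") -> np.ndarray:
    """True suitability: inverse-logit of the species' response to the stack.

    ``hinge`` responses rectify each layer at 0 (its mean) before weighting,
    giving a one-sided, hinge-like true response curve.
    """
    eta = np.full(stack.geometry.shape, float(intercept))
    for name, w in weights.items():
        x = stack.layers[name]
        eta = eta + w * (np.maximum(x, 0.0) if shape == "hinge" else x)
    out = expit(eta)
    out[~stack.valid] = np.nan
    return out


def make_species_truths(n_species: int, n_types: int, stack: EnvStack, seed: int,
                        wildlife_fraction: float = 0.3,
                        dominant_weight: float = 6.0,
                        minor_weight_sd: float = 0.3,
                        hinge_fraction: float = 0.25,
                        intercept_range: tuple[float, float] = (-9.0, -7.0),
                        ) -> tuple[list[TrueSpecies], dict[str, np.ndarray]]:
    """Virtual species assigned round-robin to vegetation types.

    Each species responds strongly (|w| = ``dominant_weight``) to one climate
    layer and weakly to the others; a ``hinge_fraction`` share get hinge-like
    (rectified, hence positive-dominant) responses.  The default weight and
    intercept ranges give narrow niches (per-species prevalence ~0.1) whose
    44-species composite covers roughly two thirds of the landscape.
    Vegetation types are split between the two functional classes, the last
    ``wildlife_fraction`` share of types being wildlife-habitat.
    """
    if n_types < 2:
        raise ValueError("need at least 2 vegetation types")
    if n_species < n_types:
        raise ValueError("need n_species >= n_types")
    n_wild = max(1, round(wildlife_fraction * n_types))
    rng = np.random.default_rng(seed)
    climate = stack.climate_layers
    names = stack.layer_names
    species: list[TrueSpecies] = []
    truths: dict[str, np.ndarray] = {}
    for i in range(n_species):
        sid = f"sp{i + 1:03d}"
        vtype = (i % n_types) + 1
        fclass = "wildlife" if vtype > n_types - n_wild else "productive"
        dom = climate[i % len(climate)]
        weights = {n: float(rng.normal(0.0, minor_weight_sd)) for n in names}
        sign = float(rng.choice([-1.0, 1.0]))
        intercept = float(rng.uniform(*intercept_range))
        shape = "hinge" if rng.random() < hinge_fraction else "linear"
        if shape == "hinge":
            sign = 1.0    # rectified responses need a rising dominant limb
        weights[dom] = sign * dominant_weight
        sp = TrueSpecies(sid, vtype, fclass, weights, intercept, shape)
        species.append(sp)
        truths[sid] = species_truth_map(stack, weights, intercept, shape)
    return species, truths


def sample_occurrences(truth: np.ndarray, geom: GridGeometry, n: int, seed: int,
                       species_id: str = "sp001") -> OccurrenceSet:
    """Draw n points with cell probability proportional to true suitability,
    jittered uniformly within the chosen cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = np.asarray(truth, dtype=float)
    p = np.where(np.isfinite(truth), truth, 0.0).ravel()
    if p.min() < 0 or (np.isfinite(truth) & (truth > 1)).any():
        raise ValueError("truth must lie in [0, 1]")
    total = p.sum()
    if total == 0:
        raise ValueError("truth is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    cells = rng.choice(p.size, size=n, p=p / total)
    rows, cols = np.unravel_index(cells, truth.shape)
    jx = rng.uniform(0, geom.cell_size, size=n)
    jy = rng.uniform(0, geom.cell_size, size=n)
    lon = geom.x_ll + cols * geom.cell_size + jx
    lat = geom.y_ll + (geom.n_rows - 1 - rows) * geom.cell_size + jy
    df = pd.DataFrame({"lon": lon, "lat": lat, "date": pd.NaT,
                       "record_id": [f"r{i:06d}" for i in range(n)]})
    return OccurrenceSet(species_id, df)


def apply_scenario(stack: EnvStack, delta: ScenarioDelta) -> EnvStack:
    """Shift climate layers additively; static layers and geometry unchanged."""
    unknown = set(delta.shifts) - set(stack.climate_layers)
    if unknown:
        raise ValueError(f"delta touches non-climate or unknown layers {sorted(unknown)}")
    out = stack.copy(scenario_id=delta.scenario_id)
    for name, shift in delta.shifts.items():
        layer = out.layers[name]
        layer[out.valid] += shift
    return out


def default_scenarios(stack: EnvStack, temp_scale: float = 0.2,
                      precip_scale: float = 0.05) -> list[ScenarioDelta]:
    """The four SSP warming deltas (+2 / +3 / +4.1 / +5 degrees by 2060).

    The first climate layer stands in for temperature; a degree of warming
    shifts it by ``temp_scale`` standardized units (the default 0.2 reflects a
    high-plateau mean-annual-temperature field whose spatial spread is around
    15 degrees, so one degree is about a fifth of a spatial standard
    deviation).  Remaining climate layers are precipitation-like and shift by
    ``precip_scale`` per degree, a modest wetting trend.
    """
    climate = stack.climate_layers
    temp = climate[0]
    out = []
    for sc, dT in SSP_WARMING.items():
        shifts = {temp: temp_scale * dT}
        for other in climate[1:]:
            shifts[other] = precip_scale * dT
        out.append(ScenarioDelta(sc, shifts))
    return out


def make_survey_map(truth_grassland: np.ndarray, flip_rate: float, seed: int) -> np.ndarray:
    """Noisy reference map: each valid pixel flips with probability flip_rate."""
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    truth = np.asarray(truth_grassland, dtype=float)
    rng = np.random.default_rng(seed)
    flips = rng.random(truth.shape) < flip_rate
    out = truth.copy()
    valid = np.isfinite(truth)
    out[valid & flips] = 1.0 - out[valid & flips]
    return out


def make_exclusion_mask(config: LandscapeConfig, fraction: float = 0.05,
                        seed: int | None = None) -> np.ndarray:
    """Contiguous excluded patches (urban/snow proxies) covering ~``fraction``
    of the grid, as a 0/1 mask (1 = excluded)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return np.zeros(config.geometry.shape)
    rng = np.random.default_rng(subseed(config.seed, 7) if seed is None else seed)
    z = ndimage.gaussian_filter(rng.standard_normal(config.geometry.shape),
                                sigma=max(config.autocorr_range, 1.0), mode="reflect")
    cut = np.quantile(z, 1.0 - fraction)
    return (z > cut).astype(float)


def simulate_dataset(out_dir, config: LandscapeConfig | None = None,
                     n_species: int = 44, n_types: int = 17,
                     n_occurrences: int = 70, flip_rate: float = 0.10,
                     mask_fraction: float = 0.05,
                     scenarios: list[ScenarioDelta] | None = None,
                     include_null_scenario: bool = False) -> dict[str, Path]:
    """Write a complete synthetic study to disk (stacks, occurrences, catalog,
    mask, survey) and return the paths the pipeline consumes.

    The survey map is the true composite grassland (max true suitability
    >= 0.2) with ``flip_rate`` pixel noise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or LandscapeConfig()
    geom = config.geometry
    stack = generate_env_stack(config)
    species, truths = make_species_truths(
        n_species, n_types, stack, seed=subseed(config.seed, 1))

    occ_sets = {}
    for i, sp in enumerate(species):
        occ_sets[sp.species_id] = sample_occurrences(
            truths[sp.species_id], geom, n_occurrences,
            seed=subseed(config.seed, 1000 + i), species_id=sp.species_id)
    occ_path = out_dir / "occurrences.csv"
    write_occurrences(occ_sets, occ_path)

    catalog = SpeciesCatalog(pd.DataFrame(
        [{"species_id": s.species_id, "vegetation_type": s.vegetation_type,
          "functional_class": s.functional_class} for s in species]))
    catalog_path = out_dir / "catalog.csv"
    catalog.to_csv(catalog_path)

    manifests = {"baseline": stack.write(out_dir / "stacks" / "baseline")}
    if scenarios is None:
        scenarios = default_scenarios(stack)
        if include_null_scenario:
            scenarios = [ScenarioDelta("SSP000", {})] + scenarios
    for delta in scenarios:
        shifted = apply_scenario(stack, delta)
        manifests[delta.scenario_id] = shifted.write(
            out_dir / "stacks" / delta.scenario_id)

    truth_stack = np.stack([truths[s.species_id] for s in species])
    truth_grass = (np.nanmax(truth_stack, axis=0) >= 0.2).astype(float)
    truth_grass[~stack.valid] = np.nan
    truth_path = out_dir / "truth_grassland.asc"
    write_ascii_grid(truth_path, truth_grass, geom)

    survey = make_survey_map(truth_grass, flip_rate, seed=subseed(config.seed, 2))
    survey_path = out_dir / "survey.asc"
    write_ascii_grid(survey_path, survey, geom)

    mask = make_exclusion_mask(config, mask_fraction)
    mask_path = out_dir / "mask.asc"
    write_ascii_grid(mask_path, mask, geom)

    return {"occurrences": occ_path, "catalog": catalog_path,
            "stacks": manifests, "survey": survey_path, "mask": mask_path,
            "truth_grassland": truth_path}
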