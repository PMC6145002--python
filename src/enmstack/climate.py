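"""Synthetic climate fields and virtual species.

Real studies of climate-driven range shifts start from gridded bioclimatic
rasters (baseline plus future projections per circulation model × emission
pathway) and museum/database occurrence records. This module generates a
self-contained analogue of those inputs: spatially autocorrelated covariate
fields on a planar km grid, future fields obtained by adding a pathway-scaled
trend plus a smooth model-specific perturbation, and virtual species with
known Gaussian-product niches from which presence records are sampled. Because
every species' true suitability surface — and hence its true range and the
true per-cell richness of any species set — is known exactly, the whole
downstream modelling pipeline can be validated against ground truth.

Grids are planar with Euclidean distances; the cell size defaults to 10 km,
a typical modelling resolution for continental-scale niche models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ScenarioTag",
    "ClimateStack",
    "VirtualSpecies",
    "OccurrenceSet",
    "generate_climate",
    "derived_layer",
    "shift_climate",
    "true_suitability",
    "true_range",
    "sample_occurrences",
    "TIME_SLICES",
]

TIME_SLICES = ("baseline", "2050", "2070")


@dataclass(frozen=True)
class ScenarioTag:
    """Identifies one climate realization: time slice × GCM × RCP.

    Baseline climates carry no GCM/RCP (``gcm_id = rcp_id = None``); future
    slices carry both.
    """

    time_slice: str
    gcm_id: str | None = None
    rcp_id: str | None = None

    def __post_init__(self) -> None:
        if self.time_slice not in TIME_SLICES:
            raise ValueError(f"unknown time slice {self.time_slice!r}")
        if self.time_slice == "baseline":
            if self.gcm_id is not None or self.rcp_id is not None:
                raise ValueError("baseline scenario must have gcm_id = rcp_id = None")
        elif self.gcm_id is None or self.rcp_id is None:
            raise ValueError("future scenario requires gcm_id and rcp_id")

    @property
    def label(self) -> str:
        if self.time_slice == "baseline":
            return "baseline"
        return f"{self.time_slice}_{self.gcm_id}_{self.rcp_id}"


@dataclass
class ClimateStack:
    """Named covariate rasters sharing one grid, tagged with a scenario."""

    grid_shape: tuple[int, int]
    cell_size_km: float
    layers: dict[str, np.ndarray]
    tag: ScenarioTag

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != tuple(self.grid_shape):
                raise ValueError(f"layer {name!r} shape {arr.shape} != {self.grid_shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} contains non-finite values")
            self.layers[name] = arr

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.grid_shape))

    def as_matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """Cells × variables matrix (row-major cell order)."""
        names = self.variable_names if variables is None else list(variables)
        return np.column_stack([self.layers[v].ravel() for v in names])

    def values_at(self, cells: np.ndarray, variables: list[str] | None = None) -> np.ndarray:
        """Covariate matrix at integer (row, col) cells."""
        cells = np.asarray(cells, dtype=int)
        names = self.variable_names if variables is None else list(variables)
        return np.column_stack([self.layers[v][cells[:, 0], cells[:, 1]] for v in names])

    def cell_centers_km(self, cells: np.ndarray) -> np.ndarray:
        """(x_km, y_km) centers of (row, col) cells; x along columns."""
        cells = np.asarray(cells, dtype=int)
        x = (cells[:, 1] + 0.5) * self.cell_size_km
        y = (cells[:, 0] + 0.5) * self.cell_size_km
        return np.column_stack([x, y])

    def coords_to_cells(self, xy_km: np.ndarray) -> np.ndarray:
        """Map (x_km, y_km) coordinates to integer (row, col) cells."""
        xy = np.asarray(xy_km, dtype=float)
        col = np.clip((xy[:, 0] / self.cell_size_km).astype(int), 0, self.grid_shape[1] - 1)
        row = np.clip((xy[:, 1] / self.cell_size_km).astype(int), 0, self.grid_shape[0] - 1)
        return np.column_stack([row, col])


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known multiplicative-Gaussian niche.

    Suitability of a cell is the product, over the layers the species
    responds to, of exp(-(v - optimum)^2 / (2 breadth^2)); the true range is
    the set of cells at or above ``occupancy_threshold``.
    """

    species_id: str
    niche_optimum: dict[str, float]
    niche_breadth: dict[str, float]
    occupancy_threshold: float = 0.2

    def __post_init__(self) -> None:
        if set(self.niche_optimum) != set(self.niche_breadth):
            raise ValueError("optimum and breadth must cover the same layers")
        if any(b <= 0 for b in self.niche_breadth.values()):
            raise ValueError("niche breadth must be strictly positive")
        if not (0.0 < self.occupancy_threshold < 1.0):
            raise ValueError("occupancy_threshold must lie in (0, 1)")


@dataclass
class OccurrenceSet:
    """Presence coordinates (and optional background) for one species."""

    species_id: str
    presences: np.ndarray  # (n, 2) of (x_km, y_km)
    background: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    seed: int | None = None

    def __post_init__(self) -> None:
        self.presences = np.asarray(self.presences, dtype=float).reshape(-1, 2)
        self.background = np.asarray(self.background, dtype=float).reshape(-1, 2)

    @property
    def n_presence(self) -> int:
        return len(self.presences)


def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                           sigma_cells: float) -> np.ndarray:
    """Gaussian random field: smoothed white noise, standardized to 0/1."""
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        fieldv = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="wrap")
    else:
        fieldv = noise
    sd = fieldv.std()
    if sd == 0:  # pathological (constant field); keep zeros
        return fieldv - fieldv.mean()
    return (fieldv - fieldv.mean()) / sd


def generate_climate(grid_shape: tuple[int, int], variable_names: list[str],
                     autocorr_length_km: float = 50.0, seed: int = 0,
                     cell_size_km: float = 10.0) -> ClimateStack:
    """Generate a baseline stack of spatially autocorrelated covariates.

    Each layer is white noise smoothed by a Gaussian kernel whose standard
    deviation is ``autocorr_length_km`` (in km), then standardized to mean 0
    and sd 1 over cells. Deterministic for a given seed.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError(f"degenerate grid {grid_shape}; need at least 2x2")
    if autocorr_length_km < 0:
        raise ValueError("autocorr_length_km must be >= 0")
    if not variable_names:
        raise ValueError("at least one variable name required")
    rng = np.random.default_rng(seed)
    sigma = autocorr_length_km / cell_size_km
    layers = {name: _smooth_standard_field(rng, (rows, cols), sigma)
              for name in variable_names}
    return ClimateStack(grid_shape=(rows, cols), cell_size_km=cell_size_km,
                        layers=layers, tag=ScenarioTag("baseline"))


def derived_layer(stack: ClimateStack, name: str, weights: dict[str, float],
                  noise_sd: float = 0.0, seed: int = 0) -> None:
    """Add a (near-)collinear layer: a linear combination of existing layers
    plus optional white noise, standardized. Used to exercise the collinearity
    filter the way redundant bioclim variables do.
    """
    combo = np.zeros(stack.grid_shape)
    for var, w in weights.items():
        combo = combo + w * stack.layers[var]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        combo = combo + noise_sd * rng.standard_normal(stack.grid_shape)
    sd = combo.std()
    if sd == 0:
        raise ValueError("derived layer is constant")
    stack.layers[name] = (combo - combo.mean()) / sd


def shift_climate(base: ClimateStack, trend: dict[str, float], gcm_noise_sd: float,
                  rcp_scale: float, time_slice: str, gcm_id: str, rcp_id: str,
                  seed: int = 0, perturb_length_km: float | None = None) -> ClimateStack:
    """Project a baseline stack into a future scenario.

    future layer = base + rcp_scale * trend[layer] + smooth GCM perturbation
    with sd ``gcm_noise_sd``. The perturbation field depends on the GCM, the
    slice, and the layer (not on the RCP): circulation models differ
    structurally, independent of the emission pathway driving them.
    """
    if time_slice == "baseline":
        raise ValueError("cannot shift to the baseline slice")
    if set(trend) != set(base.layers):
        raise ValueError("trend must provide one entry per layer")
    from ._seeds import child_seed

    if perturb_length_km is None:
        perturb_length_km = 5.0 * base.cell_size_km
    sigma = perturb_length_km / base.cell_size_km
    layers: dict[str, np.ndarray] = {}
    for name, arr in base.layers.items():
        fut = arr + rcp_scale * trend[name]
        if gcm_noise_sd > 0:
            rng = np.random.default_rng(child_seed(seed, "gcm", gcm_id, time_slice, name))
            fut = fut + gcm_noise_sd * _smooth_standard_field(rng, base.grid_shape, sigma)
        layers[name] = fut
    return ClimateStack(grid_shape=base.grid_shape, cell_size_km=base.cell_size_km,
                        layers=layers, tag=ScenarioTag(time_slice, gcm_id, rcp_id))


def true_suitability(sp: VirtualSpecies, clim: ClimateStack) -> np.ndarray:
    """Ground-truth suitability in [0, 1] at every cell."""
    missing = set(sp.niche_optimum) - set(clim.layers)
    if missing:
        raise ValueError(f"climate stack lacks layers {sorted(missing)}")
    log_s = np.zeros(clim.grid_shape)
    for name, opt in sp.niche_optimum.items():
        b = sp.niche_breadth[name]
        log_s = log_s - (clim.layers[name] - opt) ** 2 / (2.0 * b * b)
    return np.exp(log_s)


def true_range(sp: VirtualSpecies, clim: ClimateStack) -> np.ndarray:
    """Boolean mask of the species' true range under this climate."""
    return true_suitability(sp, clim) >= sp.occupancy_threshold


def sample_occurrences(sp: VirtualSpecies, clim: ClimateStack, n_presence: int,
                       bias_field: np.ndarray | None = None, seed: int = 0) -> OccurrenceSet:
    """Draw presence cells with probability proportional to true suitability.

    Sampling is without replacement at cell resolution, so duplicate records
    cannot arise (the analogue of duplicate-record cleaning in real occurrence
    data). An optional bias field multiplies the sampling weights to emulate
    uneven survey effort.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    w = true_suitability(sp, clim)
    if bias_field is not None:
        bias = np.asarray(bias_field, dtype=float)
        if bias.shape != tuple(clim.grid_shape):
            raise ValueError("bias_field shape does not match grid")
        if np.any(bias < 0):
            raise ValueError("bias_field must be non-negative")
        w = w * bias
    flat = w.ravel()
    admissible = np.flatnonzero(flat > 0)
    if len(admissible) < n_presence:
        raise ValueError(
            f"species {sp.species_id!r}: only {len(admissible)} cells with positive "
            f"sampling weight but {n_presence} presences requested")
    rng = np.random.default_rng(seed)
    p = flat[admissible] / flat[admissible].sum()
    chosen = rng.choice(admissible, size=n_presence, replace=False, p=p)
    cells = np.column_stack(np.unravel_index(chosen, clim.grid_shape))
    return OccurrenceSet(species_id=sp.species_id,
                         presences=clim.cell_centers_km(cells), seed=seed)
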