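"""Ensemble forecasting, binarization, and the dispersal/isolated-patch rule.

Per species and time slice, passing models are averaged cell-wise into one
suitability surface (baseline: over algorithms; future slices: over
algorithms × GCMs × RCPs) and binarized at the mean of the contributing
algorithms' sensitivity–specificity equality thresholds. Future binary ranges
are then dispersal-filtered: a connected patch of predicted presence survives
only if it overlaps the baseline prediction, lies within a dispersal cutoff
(default 400 km) of the main (largest) predicted patch, or lies within that
cutoff of a known occurrence record; more distant isolated patches are
treated as climatically suitable but unreachable, and removed. Baseline
ranges are never filtered — the rule concerns projections.

Patch continuity uses 8-connectivity (diagonal neighbours count as continuous
area); patch distances are minimum cell-center-to-cell-center distances, i.e.
edge-to-edge at cell resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .climate import ScenarioTag

__all__ = [
    "SuitabilityMap",
    "BinaryRange",
    "NoPassingModels",
    "ensemble_mean",
    "consensus_threshold",
    "binarize",
    "connected_components",
    "patch_distance_km",
    "dispersal_filter",
    "detect_total_loss",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=int)


class NoPassingModels(Exception):
    """Raised when a species has no model passing evaluation; the species is
    flagged unmodelable and excluded downstream."""


@dataclass
class SuitabilityMap:
    species_id: str
    tag: ScenarioTag
    values: np.ndarray
    members: list[tuple] = field(default_factory=list)  # (algorithm, gcm, rcp)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass
class BinaryRange:
    species_id: str
    tag: ScenarioTag
    mask: np.ndarray
    threshold_used: float
    cell_size_km: float = 1.0
    labels: np.ndarray = None
    n_patches: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels is None:
            self.labels, self.n_patches = ndimage.label(self.mask, structure=_STRUCTURE_8)

    @property
    def area_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def area_km2(self) -> float:
        return self.area_cells * self.cell_size_km**2

    def patch_table(self) -> pd.DataFrame:
        return connected_components(self.mask, self.cell_size_km)[1]


def ensemble_mean(member_maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Unweighted per-cell arithmetic mean over contributing members."""
    if not member_maps:
        raise NoPassingModels("no passing member maps to ensemble")
    shapes = {m.values.shape for m in member_maps}
    if len(shapes) > 1:
        raise ValueError(f"member maps on different grids: {shapes}")
    species = {m.species_id for m in member_maps}
    if len(species) > 1:
        raise ValueError(f"member maps from different species: {species}")
    values = np.mean([m.values for m in member_maps], axis=0)
    members = [mm for m in member_maps for mm in (m.members or [("?", None, None)])]
    return SuitabilityMap(species_id=member_maps[0].species_id,
                          tag=member_maps[0].tag, values=values, members=members)


def consensus_threshold(thresholds: list[float]) -> float:
    """Mean of the passing algorithms' equality thresholds."""
    if not thresholds:
        raise ValueError("at least one threshold required")
    return float(np.mean(thresholds))


def binarize(smap: SuitabilityMap, threshold: float, cell_size_km: float = 1.0) -> BinaryRange:
    """Presence where ensemble suitability >= threshold; patches labeled."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return BinaryRange(species_id=smap.species_id, tag=smap.tag,
                       mask=smap.values >= threshold, threshold_used=float(threshold),
                       cell_size_km=cell_size_km)


def connected_components(mask: np.ndarray, cell_size_km: float = 1.0
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """8-connectivity patch labeling with areas and centroid coordinates."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    rows = []
    for pid in range(1, n + 1):
        cells = np.argwhere(labels == pid)
        cx = (cells[:, 1].mean() + 0.5) * cell_size_km
        cy = (cells[:, 0].mean() + 0.5) * cell_size_km
        rows.append({"patch_id": pid, "area_cells": len(cells),
                     "area_km2": len(cells) * cell_size_km**2,
                     "centroid_x_km": cx, "centroid_y_km": cy})
    return labels, pd.DataFrame(rows, columns=["patch_id", "area_cells", "area_km2",
                                               "centroid_x_km", "centroid_y_km"])


def patch_distance_km(cells_a: np.ndarray, points_b_km: np.ndarray,
                      cell_size_km: float) -> float:
    """Minimum distance (km) from any cell center in A to any point in B."""
    if len(cells_a) == 0 or len(points_b_km) == 0:
        return np.inf
    centers = (np.asarray(cells_a, dtype=float)[:, ::-1] + 0.5) * cell_size_km
    tree = cKDTree(np.asarray(points_b_km, dtype=float))
    d, _ = tree.query(centers)
    return float(np.min(d))


def dispersal_filter(future: BinaryRange, baseline: BinaryRange,
                     occurrences_km: np.ndarray, max_km: float = 400.0
                     ) -> tuple[BinaryRange, pd.DataFrame]:
    """Remove isolated future patches farther than ``max_km`` from both the
    main predicted area and every known occurrence record, unless they overlap
    the baseline prediction.

    Retention rules (a patch survives if ANY holds):
      a. it overlaps >= 1 cell of the baseline mask (colonizable continuity);
      b. its minimum distance to the main predicted area (the largest patch
         of the future mask) is <= max_km — the boundary case exactly at
         max_km is retained, only strictly farther patches are deleted;
      c. its minimum distance to any occurrence record is <= max_km.

    An empty future mask is returned unchanged (the species has lost all
    suitable area). Returns the filtered range and a per-patch log.
    """
    if future.mask.shape != baseline.mask.shape:
        raise ValueError("future and baseline ranges must share one grid")
    cols = ["species_id", "patch_id", "area_cells", "dist_main_km", "dist_occ_km",
            "overlaps_baseline", "retained"]
    if future.area_cells == 0:
        return future, pd.DataFrame(columns=cols)
    labels, n = future.labels, future.n_patches
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    main_id = int(np.argmax(areas)) + 1  # ties -> smallest label id
    main_cells = np.argwhere(labels == main_id)
    main_centers = (main_cells[:, ::-1] + 0.5) * future.cell_size_km
    occ = np.asarray(occurrences_km, dtype=float).reshape(-1, 2)
    keep = np.zeros(n + 1, dtype=bool)
    log_rows = []
    for pid in range(1, n + 1):
        cells = np.argwhere(labels == pid)
        overlaps = bool(np.any(baseline.mask[cells[:, 0], cells[:, 1]]))
        d_main = 0.0 if pid == main_id else patch_distance_km(
            cells, main_centers, future.cell_size_km)
        d_occ = patch_distance_km(cells, occ, future.cell_size_km)
        retained = overlaps or d_main <= max_km or d_occ <= max_km
        keep[pid] = retained
        log_rows.append({"species_id": future.species_id, "patch_id": pid,
                         "area_cells": len(cells), "dist_main_km": d_main,
                         "dist_occ_km": d_occ, "overlaps_baseline": overlaps,
                         "retained": retained})
    new_mask = keep[labels]
    filtered = BinaryRange(species_id=future.species_id, tag=future.tag,
                           mask=new_mask, threshold_used=future.threshold_used,
                           cell_size_km=future.cell_size_km)
    return filtered, pd.DataFrame(log_rows, columns=cols)


def detect_total_loss(ranges: dict[str, dict[str, BinaryRange]],
                      future_slices: tuple[str, ...] = ("2050", "2070")
                      ) -> pd.DataFrame:
    """Species predicted to have no climatically suitable area per future
    slice, with the combined category ("2050/2070" vs single-slice losses)."""
    rows = []
    for sid, per_slice in ranges.items():
        empty = [s for s in future_slices
                 if s in per_slice and per_slice[s].area_cells == 0]
        if empty:
            rows.append({"species_id": sid, "time_slice": "/".join(empty)})
    return pd.DataFrame(rows, columns=["species_id", "time_slice"])
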