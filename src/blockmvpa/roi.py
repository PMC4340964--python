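"""ROI construction from a localizer statistic map.

Two selection schemes are provided: a fixed-size contiguous cluster of the
most selective voxels grown greedily from the suprathreshold peak (size
equalization across regions), and the full connected component of
suprathreshold voxels around the peak (the un-equalized control).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import ConfigurationError
from .glm import StatMap


@dataclass
class ROIMask:
    """A named set of voxels with their selectivity statistics."""

    name: str
    coords: np.ndarray  # (n, 3) int, 0-based grid indices
    stats: np.ndarray  # (n,) statistic per voxel (signed as in the input map)
    peak: tuple[int, int, int]
    voxel_mm: float = 2.0
    target_size: int | None = None
    under_sized: bool = False

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_mm**3

    def index_into(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Flat (C-order) voxel indices of the mask within a grid."""
        return np.ravel_multi_index(self.coords.T, grid_shape)

    def to_volume(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        vol = np.zeros(grid_shape, dtype=np.uint8)
        vol[tuple(self.coords.T)] = 1
        return vol

    @classmethod
    def from_volume(
        cls, vol: np.ndarray, name: str = "", voxel_mm: float = 2.0
    ) -> "ROIMask":
        coords = np.argwhere(vol > 0)
        if len(coords) == 0:
            raise ConfigurationError("empty mask volume")
        return cls(
            name=name,
            coords=coords,
            stats=np.zeros(len(coords)),
            peak=tuple(coords[0]),
            voxel_mm=voxel_mm,
        )


@dataclass(frozen=True)
class ROIConfig:
    threshold_p: float = 0.001
    target_sizes: tuple[int, ...] = (10, 20, 30, 40, 50)
    connectivity: int = 26  # 6, 18 or 26 neighbours
    direction: int = 1  # +1: positive contrast selects; -1: negative

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_p < 1.0):
            raise ConfigurationError("threshold_p must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError("connectivity must be 6, 18 or 26")
        if self.direction not in (-1, 1):
            raise ConfigurationError("direction must be +1 or -1")


def _neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(v) for v in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append(d)
    return offsets


def _suprathreshold(map: StatMap, cfg: ROIConfig) -> tuple[np.ndarray, np.ndarray]:
    """Signed statistic and boolean suprathreshold volume."""
    stat = cfg.direction * map.t
    t_crit = sstats.t.isf(cfg.threshold_p, map.df)
    supra = np.isfinite(stat) & (stat > t_crit)
    return stat, supra


def _peak(stat: np.ndarray, supra: np.ndarray) -> tuple[int, int, int] | None:
    if not supra.any():
        return None
    masked = np.where(supra, stat, -np.inf)
    best = masked.max()
    candidates = np.argwhere(masked == best)
    # lexicographic tie-break for determinism
    return tuple(candidates[np.lexsort(candidates.T[::-1])][0])


def localize_roi(
    map: StatMap, cfg: ROIConfig, target_size: int, name: str = "", voxel_mm: float = 2.0
) -> ROIMask | None:
    """Grow a fixed-size contiguous cluster of most selective voxels.

    Starting from the suprathreshold peak, repeatedly admit the
    suprathreshold neighbour (under ``cfg.connectivity``) with the highest
    statistic until ``target_size`` voxels are selected or the frontier is
    exhausted (the mask is then returned smaller and flagged
    ``under_sized``).  Returns ``None`` when no voxel passes the threshold —
    the region is not localizable in this subject.
    """
    if target_size < 1:
        raise ConfigurationError("target_size must be at least 1")
    stat, supra = _suprathreshold(map, cfg)
    peak = _peak(stat, supra)
    if peak is None:
        return None

    offsets = _neighbour_offsets(cfg.connectivity)
    shape = stat.shape
    selected: list[tuple[int, int, int]] = [peak]
    in_mask = {peak}
    frontier: dict[tuple[int, int, int], float] = {}

    def push_neighbours(v: tuple[int, int, int]) -> None:
        for d in offsets:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if any(c < 0 or c >= s for c, s in zip(w, shape)):
                continue
            if w in in_mask or not supra[w]:
                continue
            frontier[w] = float(stat[w])

    push_neighbours(peak)
    while len(selected) < target_size and frontier:
        # highest statistic wins; lexicographic coordinate order breaks ties
        best = min(frontier.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        del frontier[best]
        selected.append(best)
        in_mask.add(best)
        push_neighbours(best)

    coords = np.array(selected, dtype=int)
    return ROIMask(
        name=name,
        coords=coords,
        stats=map.t[tuple(coords.T)],
        peak=peak,
        voxel_mm=voxel_mm,
        target_size=target_size,
        under_sized=len(selected) < target_size,
    )


def full_size_roi(
    map: StatMap, cfg: ROIConfig, name: str = "", voxel_mm: float = 2.0
) -> ROIMask | None:
    """All suprathreshold voxels connected to the peak (flood fill)."""
    stat, supra = _suprathreshold(map, cfg)
    peak = _peak(stat, supra)
    if peak is None:
        return None
    offsets = _neighbour_offsets(cfg.connectivity)
    shape = stat.shape
    visited = {peak}
    queue = [peak]
    while queue:
        v = queue.pop()
        for d in offsets:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if any(c < 0 or c >= s for c, s in zip(w, shape)):
                continue
            if w in visited or not supra[w]:
                continue
            visited.add(w)
            queue.append(w)
    coords = np.array(sorted(visited), dtype=int)
    return ROIMask(
        name=name,
        coords=coords,
        stats=map.t[tuple(coords.T)],
        peak=peak,
        voxel_mm=voxel_mm,
    )


def roi_summary_row(mask: ROIMask | None, name: str) -> dict:
    """One row of the localization summary table."""
    if mask is None:
        return {"roi": name, "localized": False, "n_voxels": 0,
                "mean_stat": np.nan, "peak_x": np.nan, "peak_y": np.nan, "peak_z": np.nan}
    return {
        "roi": name,
        "localized": True,
        "n_voxels": mask.n_voxels,
        "mean_stat": float(np.mean(mask.stats)),
        "peak_x": mask.peak[0],
        "peak_y": mask.peak[1],
        "peak_z": mask.peak[2],
    }
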