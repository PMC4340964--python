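"""Overlapping-box search-light decoding with per-voxel accuracy averaging.

Every box is a ``box_edge``-cubed neighbourhood centred on a mask voxel and
intersected with the mask.  The full LOSO decoding chain runs on each box's
voxels and the resulting accuracy is credited to every member voxel; a
voxel's final value is the mean over all boxes it belonged to (running
sums, so the result is independent of box visiting order).  With step 3 the
boxes tile the mask and each voxel is classified exactly once (the
non-overlapping control scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decode import (
    DecodeConfig,
    PatternSet,
    block_averages,
    concat_pattern_sets,
    loso_decode,
    preprocess_session,
    subtract_condition_means,
)
from .design import BlockSchedule
from .errors import ConfigurationError
from .roi import ROIMask
from .simulate import BOLDRun
from .stats import bh_fdr, t_sf


@dataclass(frozen=True)
class SearchlightConfig:
    box_edge: int = 3
    step: int = 1
    min_voxels_per_box: int = 10

    def __post_init__(self) -> None:
        if self.box_edge < 1 or self.box_edge % 2 == 0:
            raise ConfigurationError("box_edge must be odd and positive")
        if self.step < 1:
            raise ConfigurationError("step must be at least 1")
        if self.min_voxels_per_box < 1:
            raise ConfigurationError("min_voxels_per_box must be at least 1")


@dataclass
class AccuracyMap:
    """Per-voxel mean decoding accuracy and the number of contributing boxes."""

    accuracy: np.ndarray  # grid-shaped, NaN outside coverage
    box_count: np.ndarray  # grid-shaped int
    grid_shape: tuple[int, int, int]

    def covered(self) -> np.ndarray:
        return self.box_count > 0


def _box_centers(coords: np.ndarray, cfg: SearchlightConfig) -> np.ndarray:
    if cfg.step == 1:
        return coords
    origin = coords.min(axis=0)
    radius = cfg.box_edge // 2
    phase = (coords - origin) % cfg.step
    keep = np.all(phase == radius % cfg.step, axis=1)
    return coords[keep]


def run_searchlight(
    runs: Sequence[BOLDRun],
    schedules: Sequence[BlockSchedule],
    mask: ROIMask,
    cfg: SearchlightConfig,
    decode_cfg: DecodeConfig,
) -> AccuracyMap:
    """Search-light decoding over ``mask`` for one subject.

    Sessions are preprocessed once and per-voxel block averages computed for
    the whole mask; each box then re-applies the per-condition mean
    subtraction on its own voxel subset before LOSO classification, exactly
    as if the box were a standalone ROI.
    """
    if mask.n_voxels == 0:
        raise ConfigurationError("empty search-light mask")
    grid_shape = runs[0].grid_shape

    flat_idx = mask.index_into(grid_shape)
    col_of: dict[tuple[int, int, int], int] = {
        tuple(c): i for i, c in enumerate(mask.coords)
    }

    sets = []
    for run, schedule in zip(runs, schedules):
        pre = preprocess_session(run, decode_cfg)
        sets.append(
            block_averages(pre, schedule, flat_idx, decode_cfg.class_pair, decode_cfg)
        )
    base = concat_pattern_sets(sets)

    radius = cfg.box_edge // 2
    acc_sum = np.zeros(grid_shape)
    count = np.zeros(grid_shape, dtype=int)
    for center in _box_centers(mask.coords, cfg):
        cols = []
        members = []
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                for dz in range(-radius, radius + 1):
                    v = (center[0] + dx, center[1] + dy, center[2] + dz)
                    col = col_of.get(v)
                    if col is not None:
                        cols.append(col)
                        members.append(v)
        if len(cols) < cfg.min_voxels_per_box:
            continue
        sub = PatternSet(
            patterns=base.patterns[:, cols],
            labels=base.labels,
            session_ids=base.session_ids,
            n_trs_averaged=base.n_trs_averaged,
        )
        accuracy, _ = loso_decode(subtract_condition_means(sub), decode_cfg)
        for v in members:
            acc_sum[v] += accuracy
            count[v] += 1

    with np.errstate(invalid="ignore"):
        accuracy_map = np.where(count > 0, acc_sum / np.maximum(count, 1), np.nan)
    return AccuracyMap(accuracy=accuracy_map, box_count=count, grid_shape=grid_shape)


@dataclass
class GroupSearchlightResult:
    t: np.ndarray  # grid-shaped, NaN where undefined
    p: np.ndarray  # one-tailed p, NaN where undefined
    significant: np.ndarray  # boolean grid
    p_threshold: float
    n_subjects: np.ndarray  # per-voxel subject support
    excluded: int  # voxels dropped for <2 subjects


def group_searchlight_stats(
    maps: Sequence[AccuracyMap],
    q: float = 0.05,
    chance: float = 0.5,
) -> GroupSearchlightResult:
    """Per-voxel one-tailed t vs chance across subjects, BH-FDR corrected."""
    if len(maps) < 2:
        raise ConfigurationError("group statistics need at least 2 subjects")
    grid_shape = maps[0].grid_shape
    stack = np.stack([m.accuracy for m in maps])  # (n_subj, x, y, z)
    defined = np.stack([m.covered() for m in maps])
    n_subj = defined.sum(axis=0)

    testable = n_subj >= 2
    excluded = int(np.sum((n_subj > 0) & ~testable))

    t_vol = np.full(grid_shape, np.nan)
    p_vol = np.full(grid_shape, np.nan)
    vox = np.argwhere(testable)
    pvals = []
    for v in vox:
        v = tuple(v)
        have = defined[(slice(None),) + v]
        vals = stack[(slice(None),) + v][have]
        n = vals.size
        mean = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            t = 0.0 if mean == chance else np.copysign(np.inf, mean - chance)
        else:
            t = (mean - chance) / (sd / np.sqrt(n))
        p = float(t_sf(t, n - 1))
        t_vol[v] = t
        p_vol[v] = p
        pvals.append(p)

    flags, threshold = bh_fdr(np.array(pvals), q)
    sig = np.zeros(grid_shape, dtype=bool)
    for flag, v in zip(flags, vox):
        sig[tuple(v)] = flag
    return GroupSearchlightResult(
        t=t_vol,
        p=p_vol,
        significant=sig,
        p_threshold=threshold,
        n_subjects=n_subj,
        excluded=excluded,
    )
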