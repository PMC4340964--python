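"""Synthetic multi-session BOLD data with a known category / identity code.

Each simulated subject has one or more rectangular-grid "brain" volumes per
session.  Selected regions respond to the superordinate categories (faces,
cups) and optionally carry a fine-grained multivoxel code for face identity
or cup type: every region voxel is assigned a Rademacher +/-1 identity
preference, fixed across sessions within a subject, and the face amplitude
is shifted by +/- identity_effect / 2 according to that preference and the
identity shown.  A linear classifier can therefore recover identity with an
accuracy that grows with ``identity_effect`` — the ground truth the decoding
stages are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import BlockSchedule, CUP_CONDITIONS, FACE_CONDITIONS
from .errors import ConfigurationError
from .hemo import HRFParams, condition_regressors

DECODABLE_CONDITIONS = FACE_CONDITIONS + CUP_CONDITIONS


@dataclass
class BOLDRun:
    """One session's 4-D voxel grid plus acquisition metadata."""

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    voxel_mm: float
    session_id: int

    @property
    def n_trs(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        return aff

    def flat(self) -> np.ndarray:
        """(n_voxels, n_trs) view of the data, C-order voxel raveling."""
        return self.data.reshape(-1, self.n_trs)


@dataclass(frozen=True)
class RegionSpec:
    """A responsive region and the strength of its condition coding."""

    name: str
    voxel_coords: tuple[tuple[int, int, int], ...]
    face_amplitude: float = 3.0
    cup_amplitude: float = 0.5
    identity_effect: float = 0.0
    cup_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.identity_effect < 0 or self.cup_effect < 0:
            raise ConfigurationError("pattern effect sizes must be non-negative")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)


@dataclass(frozen=True)
class SynthParams:
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_mm: float = 2.0
    regions: tuple[RegionSpec, ...] = ()
    baseline: float = 100.0
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    session_offset_sd: float = 0.5
    ar1_coef: float = 0.0  # optional AR(1) noise; 0 = white
    hrf: HRFParams = field(default_factory=HRFParams)
    n_sessions: int = 5
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not (0 <= self.ar1_coef < 1):
            raise ConfigurationError("ar1_coef must be in [0, 1)")
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be at least 1")
        for region in self.regions:
            for coord in region.voxel_coords:
                if any(c < 0 or c >= s for c, s in zip(coord, self.grid_shape)):
                    raise ConfigurationError(
                        f"region {region.name!r} voxel {coord} outside grid {self.grid_shape}"
                    )


@dataclass
class GroundTruth:
    """Per-region truth: member voxels and the identity-preference signs."""

    name: str
    coords: np.ndarray  # (n, 3) int
    identity_preference: np.ndarray  # (n,) +/-1
    cup_preference: np.ndarray  # (n,) +/-1


def _amplitude_table(
    params: SynthParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[GroundTruth]]:
    """(n_voxels, 4) amplitude per condition, plus per-region ground truth."""
    n_vox = int(np.prod(params.grid_shape))
    amps = np.zeros((n_vox, len(DECODABLE_CONDITIONS)))
    truths: list[GroundTruth] = []
    for region in params.regions:
        coords = np.array(region.voxel_coords, dtype=int)
        idx = np.ravel_multi_index(coords.T, params.grid_shape)
        id_pref = rng.choice([-1.0, 1.0], size=len(idx))
        cup_pref = rng.choice([-1.0, 1.0], size=len(idx))
        for j, cond in enumerate(DECODABLE_CONDITIONS):
            if cond in FACE_CONDITIONS:
                sign = 1.0 if cond == FACE_CONDITIONS[0] else -1.0
                amps[idx, j] += region.face_amplitude + sign * id_pref * region.identity_effect / 2.0
            else:
                sign = 1.0 if cond == CUP_CONDITIONS[0] else -1.0
                amps[idx, j] += region.cup_amplitude + sign * cup_pref * region.cup_effect / 2.0
        truths.append(GroundTruth(region.name, coords, id_pref, cup_pref))
    return amps, truths


def simulate_subject(
    params: SynthParams, schedules: Sequence[BlockSchedule]
) -> tuple[list[BOLDRun], list[GroundTruth]]:
    """Simulate one subject's sessions.

    Each run is the sum of HRF-convolved condition boxcars scaled by the
    per-voxel amplitude table, a constant baseline, a linear drift, a random
    session offset, and i.i.d. (or AR(1)) Gaussian noise.  Deterministic
    given ``params.seed``.
    """
    if len(schedules) != params.n_sessions:
        raise ConfigurationError(
            f"got {len(schedules)} schedules for n_sessions={params.n_sessions}"
        )
    rng = np.random.default_rng(params.seed)
    amps, truths = _amplitude_table(params, rng)
    n_vox = int(np.prod(params.grid_shape))

    runs: list[BOLDRun] = []
    for schedule in schedules:
        n_trs = schedule.n_trs
        regressors = condition_regressors(
            schedule,
            {c: (c,) for c in DECODABLE_CONDITIONS},
            n_trs,
            params.hrf,
            params.tr_seconds,
        )  # (n_trs, 4)
        signal = amps @ regressors.T  # (n_vox, n_trs)
        drift = params.drift_amplitude * np.linspace(-0.5, 0.5, n_trs)
        offset = rng.normal(0.0, params.session_offset_sd) if params.session_offset_sd > 0 else 0.0
        noise = np.zeros((n_vox, n_trs))
        if params.noise_sd > 0:
            noise = rng.normal(0.0, params.noise_sd, size=(n_vox, n_trs))
            if params.ar1_coef > 0:
                for t in range(1, n_trs):
                    noise[:, t] += params.ar1_coef * noise[:, t - 1]
        data = params.baseline + offset + signal + drift[None, :] + noise
        runs.append(
            BOLDRun(
                data=data.reshape(*params.grid_shape, n_trs),
                tr_seconds=params.tr_seconds,
                voxel_mm=params.voxel_mm,
                session_id=schedule.session_id,
            )
        )
    return runs, truths


def cube_region(
    name: str,
    corner: tuple[int, int, int],
    shape: tuple[int, int, int],
    **kwargs,
) -> RegionSpec:
    """Convenience: a rectangular region at ``corner`` with edge ``shape``."""
    coords = tuple(
        (corner[0] + i, corner[1] + j, corner[2] + k)
        for i in range(shape[0])
        for j in range(shape[1])
        for k in range(shape[2])
    )
    return RegionSpec(name=name, voxel_coords=coords, **kwargs)
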