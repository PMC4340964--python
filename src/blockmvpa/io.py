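"""Volume I/O, pipeline configuration, and the end-to-end experiment driver.

The driver mirrors the reference analysis sequence: session 1 is used only
to localize the selective ROI (two-regressor GLM, directional contrast,
fixed-size greedy cluster); all remaining sessions feed the univariate
plateau PSC and the LOSO pattern decoding.  Every output file embeds the
run seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .decode import DecodeConfig, build_patterns, loso_decode
from .design import (
    CUP_CONDITIONS,
    FACE_CONDITIONS,
    BlockSchedule,
    DesignParams,
    generate_session_schedule,
)
from .errors import BlockMVPAError, StageError
from .glm import contrast_map, fit_block_glm, plateau_psc
from .hemo import HRFParams
from .roi import ROIConfig, ROIMask, localize_roi, roi_summary_row
from .searchlight import (
    AccuracyMap,
    SearchlightConfig,
    group_searchlight_stats,
    run_searchlight,
)
from .simulate import BOLDRun, RegionSpec, SynthParams, simulate_subject
from .stats import bonferroni_threshold, one_sample_t

logger = logging.getLogger("blockmvpa")


class FormatError(BlockMVPAError, IOError):
    """A file could not be parsed as the expected on-disk format."""


# ---------------------------------------------------------------------------
# NIfTI volume I/O


def write_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_mm: float = 2.0,
    descrip: str = "",
) -> None:
    """Write an array as NIfTI-1 with an isotropic diagonal affine."""
    affine = np.diag([voxel_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a NIfTI-1 volume; returns (data, affine, voxel size in mm)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except Exception as err:  # nibabel raises several parse error types
        raise FormatError(
            f"malformed NIfTI file {path} (348-byte header at offset 0): {err}"
        ) from err
    voxel_mm = float(img.header.get_zooms()[0])
    return data, affine, voxel_mm


def write_bold_run(run: BOLDRun, path: str | Path, descrip: str = "") -> None:
    write_volume(run.data, path, run.voxel_mm, descrip)


def read_bold_run(path: str | Path, tr_seconds: float, session_id: int) -> BOLDRun:
    data, _, voxel_mm = read_volume(path)
    return BOLDRun(data=data, tr_seconds=tr_seconds, voxel_mm=voxel_mm, session_id=session_id)


def write_mask(mask: ROIMask, grid_shape: tuple[int, int, int], path: str | Path, descrip: str = "") -> None:
    write_volume(mask.to_volume(grid_shape), path, mask.voxel_mm, descrip)


def read_mask(path: str | Path, name: str = "") -> ROIMask:
    data, _, voxel_mm = read_volume(path)
    return ROIMask.from_volume(data, name=name, voxel_mm=voxel_mm)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the synthetic end-to-end experiment."""

    design: DesignParams = field(default_factory=DesignParams)
    synth: SynthParams = field(default_factory=lambda: _default_synth())
    roi: ROIConfig = field(default_factory=ROIConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    n_subjects: int = 16
    roi_target_size: int = 20
    run_searchlight: bool = False
    write_volumes: bool = False
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def _default_synth(identity_effect: float = 0.0, grid: int = 12) -> SynthParams:
    """A single face-selective cube region in the grid centre."""
    from .simulate import cube_region

    corner = (grid // 2 - 2, grid // 2 - 2, grid // 2 - 2)
    region = cube_region(
        "face_region",
        corner,
        (3, 3, 3),
        face_amplitude=3.0,
        cup_amplitude=0.5,
        identity_effect=identity_effect,
    )
    return SynthParams(grid_shape=(grid, grid, grid), regions=(region,))


def config_from_json(text: str) -> PipelineConfig:
    raw = json.loads(text)

    def sub(cls, key, **extra):
        data = dict(raw.get(key, {}))
        data.update(extra)
        return cls(**data)

    synth_raw = dict(raw.get("synth", {}))
    if "regions" in synth_raw:
        synth_raw["regions"] = tuple(
            RegionSpec(
                name=r["name"],
                voxel_coords=tuple(tuple(c) for c in r["voxel_coords"]),
                face_amplitude=r.get("face_amplitude", 3.0),
                cup_amplitude=r.get("cup_amplitude", 0.5),
                identity_effect=r.get("identity_effect", 0.0),
                cup_effect=r.get("cup_effect", 0.0),
            )
            for r in synth_raw["regions"]
        )
    if "hrf" in synth_raw:
        synth_raw["hrf"] = HRFParams(**synth_raw["hrf"])
    if "grid_shape" in synth_raw:
        synth_raw["grid_shape"] = tuple(synth_raw["grid_shape"])

    scalars = {
        k: raw[k]
        for k in (
            "n_subjects",
            "roi_target_size",
            "run_searchlight",
            "write_volumes",
            "alpha",
            "fdr_q",
            "seed",
        )
        if k in raw
    }
    roi_raw = dict(raw.get("roi", {}))
    if "target_sizes" in roi_raw:
        roi_raw["target_sizes"] = tuple(roi_raw["target_sizes"])
    decode_raw = dict(raw.get("decode", {}))
    if "class_pair" in decode_raw:
        decode_raw["class_pair"] = tuple(decode_raw["class_pair"])
    return PipelineConfig(
        design=sub(DesignParams, "design"),
        synth=SynthParams(**synth_raw) if synth_raw else _default_synth(),
        roi=ROIConfig(**roi_raw),
        decode=DecodeConfig(**decode_raw),
        searchlight=sub(SearchlightConfig, "searchlight"),
        **scalars,
    )


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class SubjectResult:
    subject: int
    roi: ROIMask | None
    accuracy: float | None
    n_folds: int | None
    psc: dict[str, float] | None
    searchlight_map: AccuracyMap | None = None


@dataclass
class ExperimentResult:
    config: PipelineConfig
    subjects: list[SubjectResult]
    accuracy_table: pd.DataFrame
    psc_table: pd.DataFrame
    roi_summary: pd.DataFrame
    group_stats: dict
    provenance: dict


def _subject_schedules(params: DesignParams, n_sessions: int, seed_seq: np.random.SeedSequence) -> list[BlockSchedule]:
    seeds = seed_seq.generate_state(n_sessions)
    return [
        generate_session_schedule(params, int(s), session_id=i)
        for i, s in enumerate(seeds)
    ]


def run_subject(
    config: PipelineConfig, subject: int, seed_seq: np.random.SeedSequence
) -> SubjectResult:
    """Simulate and analyse one subject.

    Session 0 is reserved for ROI localization; PSC and decoding run on the
    remaining sessions only.
    """
    design_seq, synth_seq = seed_seq.spawn(2)
    schedules = _subject_schedules(config.design, config.synth.n_sessions, design_seq)
    synth = dataclasses.replace(config.synth, seed=int(synth_seq.generate_state(1)[0]))
    runs, _ = simulate_subject(synth, schedules)

    # --- localization on session 0 only
    localizer_regressors = {"faces": FACE_CONDITIONS, "cups": CUP_CONDITIONS}
    glm = fit_block_glm([runs[0]], [schedules[0]], localizer_regressors, synth.hrf)
    stat = contrast_map(glm, [1.0, -1.0], name="faces>cups")
    mask = localize_roi(
        stat, config.roi, config.roi_target_size,
        name=f"sub-{subject:02d}_roi", voxel_mm=synth.voxel_mm,
    )
    if mask is None:
        logger.info("subject %d: ROI not localizable", subject)
        return SubjectResult(subject, None, None, None, None)

    # --- decoding and PSC on the held-back sessions
    decode_runs, decode_schedules = runs[1:], schedules[1:]
    patterns = build_patterns(decode_runs, decode_schedules, mask, config.decode)
    accuracy, n_folds = loso_decode(patterns, config.decode)
    psc = plateau_psc(
        decode_runs, decode_schedules, list(FACE_CONDITIONS + CUP_CONDITIONS),
        roi_coords=mask.coords,
    )

    sl_map = None
    if config.run_searchlight:
        sl_mask = _searchlight_mask(config, synth)
        sl_map = run_searchlight(
            decode_runs, decode_schedules, sl_mask, config.searchlight, config.decode
        )
    return SubjectResult(subject, mask, accuracy, n_folds, psc.plateau, sl_map)


def _searchlight_mask(config: PipelineConfig, synth: SynthParams) -> ROIMask:
    """Analysis mask: bounding box of the first region, dilated by one voxel."""
    region = synth.regions[0]
    coords = np.array(region.voxel_coords)
    lo = np.maximum(coords.min(axis=0) - 1, 0)
    hi = np.minimum(coords.max(axis=0) + 1, np.array(synth.grid_shape) - 1)
    grid = np.array(
        [(x, y, z)
         for x in range(lo[0], hi[0] + 1)
         for y in range(lo[1], hi[1] + 1)
         for z in range(lo[2], hi[2] + 1)]
    )
    return ROIMask(
        name="searchlight_mask",
        coords=grid,
        stats=np.zeros(len(grid)),
        peak=tuple(grid[0]),
        voxel_mm=synth.voxel_mm,
    )


def run_experiment(config: PipelineConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full synthetic experiment for ``config.n_subjects`` subjects."""
    t0 = time.time()
    cfg_hash = config.config_hash()
    stamp = f"seed={config.seed} config={cfg_hash}"
    root_seq = np.random.SeedSequence(config.seed)
    subject_seqs = root_seq.spawn(config.n_subjects)

    stage_times: dict[str, float] = {}
    subjects: list[SubjectResult] = []
    for i, seq in enumerate(subject_seqs):
        t_sub = time.time()
        try:
            subjects.append(run_subject(config, i, seq))
        except BlockMVPAError as err:
            raise StageError(f"subject-{i}", str(err)) from err
        stage_times[f"subject_{i}"] = time.time() - t_sub
        logger.info("subject %d done in %.2fs", i, stage_times[f"subject_{i}"])

    acc_rows = [
        {
            "subject": s.subject,
            "roi": s.roi.name if s.roi else None,
            "class_pair": "+".join(config.decode.class_pair),
            "accuracy": s.accuracy,
            "n_folds": s.n_folds,
        }
        for s in subjects
        if s.accuracy is not None
    ]
    accuracy_table = pd.DataFrame(
        acc_rows, columns=["subject", "roi", "class_pair", "accuracy", "n_folds"]
    )

    psc_rows = [
        {"subject": s.subject, "roi": s.roi.name, "condition": cond, "psc": value}
        for s in subjects
        if s.psc is not None
        for cond, value in s.psc.items()
    ]
    psc_table = pd.DataFrame(psc_rows, columns=["subject", "roi", "condition", "psc"])

    roi_summary = pd.DataFrame(
        [roi_summary_row(s.roi, f"sub-{s.subject:02d}") for s in subjects]
    )

    group_stats: dict = {"n_localized": int(accuracy_table.shape[0])}
    if len(accuracy_table) >= 2:
        test = one_sample_t(accuracy_table["accuracy"].to_numpy(), 0.5, tail="one")
        group_stats["accuracy_vs_chance"] = {
            "t": test.statistic,
            "df": test.df,
            "p": test.p,
            "bonferroni_level": bonferroni_threshold(config.alpha, 12),
        }
    sl_maps = [s.searchlight_map for s in subjects if s.searchlight_map is not None]
    sl_group = None
    if len(sl_maps) >= 2:
        sl_group = group_searchlight_stats(sl_maps, q=config.fdr_q)
        group_stats["searchlight"] = {
            "n_significant_voxels": int(sl_group.significant.sum()),
            "p_threshold": sl_group.p_threshold,
        }

    provenance = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "localization_sessions": [0],
        "decoding_sessions": list(range(1, config.synth.n_sessions)),
        "lag_trs": config.decode.lag_trs,
        "lag_seconds": config.decode.lag_trs * config.design.tr_seconds,
        "n_trs_averaged": config.design.block_trs - config.decode.discard_trs,
        "stage_seconds": stage_times,
        "total_seconds": time.time() - t0,
    }

    result = ExperimentResult(
        config=config,
        subjects=subjects,
        accuracy_table=accuracy_table,
        psc_table=psc_table,
        roi_summary=roi_summary,
        group_stats=group_stats,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), stamp, sl_group)
    return result


def _write_csv(frame: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, index=False)


def _write_outputs(result: ExperimentResult, out_dir: Path, stamp: str, sl_group) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_csv(result.accuracy_table, out_dir / "accuracy.csv", stamp)
    _write_csv(result.psc_table, out_dir / "psc.csv", stamp)
    _write_csv(result.roi_summary, out_dir / "roi_summary.csv", stamp)
    meta = {"stamp": stamp, **result.group_stats}
    (out_dir / "group_stats.json").write_text(json.dumps(meta, indent=2))
    (out_dir / "provenance.json").write_text(
        json.dumps({"stamp": stamp, **result.provenance}, indent=2)
    )
    (out_dir / "config.json").write_text(result.config.to_json())
    grid = result.config.synth.grid_shape
    if result.config.write_volumes:
        for s in result.subjects:
            if s.roi is not None:
                write_mask(s.roi, grid, out_dir / f"sub-{s.subject:02d}_roi.nii", stamp)
            if s.searchlight_map is not None:
                write_volume(
                    np.nan_to_num(s.searchlight_map.accuracy),
                    out_dir / f"sub-{s.subject:02d}_searchlight.nii",
                    result.config.synth.voxel_mm,
                    stamp,
                )
    if sl_group is not None and result.config.write_volumes:
        write_volume(
            np.nan_to_num(sl_group.t), out_dir / "searchlight_group_t.nii",
            result.config.synth.voxel_mm, stamp,
        )
        write_volume(
            sl_group.significant.astype(np.uint8),
            out_dir / "searchlight_group_sig.nii",
            result.config.synth.voxel_mm, stamp,
        )
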