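"""Block-design GLM fitting, contrasts, and plateau percent signal change."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats as sstats

from .design import BlockSchedule, FIXATION
from .errors import DesignError
from .hemo import HRFParams, condition_regressors
from .simulate import BOLDRun

#: 1-based inclusive plateau window, in TRs from block onset.
PLATEAU_WINDOW = (4, 10)


@dataclass
class GLMResult:
    """Ordinary-least-squares fit of HRF-convolved block regressors.

    ``beta`` has one row per design column, one column per voxel.  The first
    ``n_condition_regressors`` columns of the design are the condition
    regressors (in ``condition_names`` order); the rest are per-session
    intercept and linear-drift nuisance terms.
    """

    beta: np.ndarray  # (n_columns, n_voxels)
    sigma2: np.ndarray  # (n_voxels,) residual variance (SSE / df)
    df: int
    design: np.ndarray  # (n_timepoints, n_columns)
    xtx_inv: np.ndarray  # (n_columns, n_columns)
    column_names: list[str]
    condition_names: list[str]
    grid_shape: tuple[int, int, int]

    @property
    def n_condition_regressors(self) -> int:
        return len(self.condition_names)


@dataclass
class StatMap:
    """Per-voxel t statistics (with z equivalents) for a named contrast."""

    t: np.ndarray  # grid-shaped
    z: np.ndarray  # grid-shaped
    df: int
    contrast: np.ndarray
    name: str = ""
    flagged: np.ndarray | None = None  # voxels with zero residual variance


def _session_nuisance(n_trs_per_run: Sequence[int]) -> tuple[np.ndarray, list[str]]:
    total = sum(n_trs_per_run)
    cols = []
    names = []
    offset = 0
    for i, n in enumerate(n_trs_per_run):
        intercept = np.zeros(total)
        intercept[offset : offset + n] = 1.0
        drift = np.zeros(total)
        drift[offset : offset + n] = np.linspace(-0.5, 0.5, n)
        cols += [intercept, drift]
        names += [f"intercept_s{i}", f"drift_s{i}"]
        offset += n
    return np.column_stack(cols), names


def build_design_matrix(
    schedules: Sequence[BlockSchedule],
    regressors: Mapping[str, Sequence[str]],
    n_trs_per_run: Sequence[int],
    hrf: HRFParams,
    tr_seconds: float,
) -> tuple[np.ndarray, list[str]]:
    """Stack per-session condition regressors and nuisance columns."""
    cond_blocks = [
        condition_regressors(s, regressors, n, hrf, tr_seconds)
        for s, n in zip(schedules, n_trs_per_run)
    ]
    cond = np.vstack(cond_blocks)
    nuisance, nuisance_names = _session_nuisance(n_trs_per_run)
    X = np.hstack([cond, nuisance])
    return X, list(regressors) + nuisance_names


def fit_block_glm(
    runs: Sequence[BOLDRun],
    schedules: Sequence[BlockSchedule],
    regressors: Mapping[str, Sequence[str]] | Sequence[str],
    hrf: HRFParams | None = None,
) -> GLMResult:
    """Fit the block GLM to one or more runs by OLS.

    ``regressors`` is either a list of condition labels (one regressor per
    condition) or a mapping from regressor name to the pooled condition
    labels, e.g. ``{"faces": ("identity1", "identity2"), "cups": (...)}`` for
    the two-regressor localizer model.
    """
    if len(runs) == 0:
        raise DesignError("need at least one run")
    if len(runs) != len(schedules):
        raise DesignError("runs and schedules length mismatch")
    if not isinstance(regressors, Mapping):
        regressors = {c: (c,) for c in regressors}
    for name, conds in regressors.items():
        present = {b.condition for s in schedules for b in s.blocks}
        missing = set(conds) - present
        if missing:
            raise DesignError(f"regressor {name!r}: conditions {sorted(missing)} absent from schedules")

    hrf = hrf or HRFParams()
    n_trs_per_run = [r.n_trs for r in runs]
    X, names = build_design_matrix(schedules, regressors, n_trs_per_run, hrf, runs[0].tr_seconds)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the diagonal of R in a pivoted QR
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[piv[i]] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10 * abs(r[0, 0]))
        raise DesignError(f"design matrix rank deficient; collinear columns: {bad}")

    Y = np.vstack([r.flat().T for r in runs])  # (total_trs, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise DesignError(f"non-positive residual df ({df}); too few timepoints")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return GLMResult(
        beta=beta,
        sigma2=sigma2,
        df=df,
        design=X,
        xtx_inv=xtx_inv,
        column_names=names,
        condition_names=list(regressors),
        grid_shape=runs[0].grid_shape,
    )


def contrast_map(glm: GLMResult, weights: Sequence[float], name: str = "") -> StatMap:
    """t map for a linear contrast over the condition regressors.

    ``weights`` has one entry per condition regressor; nuisance columns get
    weight zero.  Voxels with zero residual variance are flagged and their t
    reported as +/-inf (0 when the contrast estimate is itself 0).
    """
    k = glm.n_condition_regressors
    if len(weights) != k:
        raise DesignError(f"expected {k} contrast weights, got {len(weights)}")
    c = np.zeros(glm.beta.shape[0])
    c[:k] = np.asarray(weights, dtype=float)
    effect = c @ glm.beta  # (n_voxels,)
    var_scale = float(c @ glm.xtx_inv @ c)
    var = glm.sigma2 * var_scale
    zero_var = var <= 0
    if np.any(zero_var) and np.any(c != 0):
        warnings.warn(
            f"{int(zero_var.sum())} voxel(s) with zero residual variance; t set to +/-inf",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.sign(effect) * np.inf, effect / np.sqrt(np.where(zero_var, 1.0, var)))
    t = np.where(zero_var & (effect == 0), 0.0, t)
    # z equivalent via the normal quantile of the t tail probability
    with np.errstate(over="ignore"):
        z = sstats.norm.isf(sstats.t.sf(t, glm.df))
    z = np.where(np.isinf(t), t, z)
    return StatMap(
        t=t.reshape(glm.grid_shape),
        z=z.reshape(glm.grid_shape),
        df=glm.df,
        contrast=c[:k],
        name=name,
        flagged=zero_var.reshape(glm.grid_shape),
    )


@dataclass
class PlateauPSC:
    """Event-locked percent-signal-change time courses and plateau means.

    ``timecourses[cond]`` is the block-onset-locked mean PSC course (one
    sample per TR, spanning the block plus the following fixation);
    ``plateau[cond]`` averages TRs 4..10 (1-based, inclusive) of that course.
    """

    timecourses: dict[str, np.ndarray]
    plateau: dict[str, float]
    baseline: float
    window: tuple[int, int] = PLATEAU_WINDOW


def plateau_psc(
    runs: Sequence[BOLDRun],
    schedules: Sequence[BlockSchedule],
    conditions: Sequence[str],
    roi_coords: np.ndarray | None = None,
    window_trs: int | None = None,
) -> PlateauPSC:
    """Event-locked PSC per condition over an ROI (or the whole grid).

    For every session the ROI-mean time course is converted to percent
    signal change against that session's fixation-TR mean, block-onset
    windows are extracted and averaged across blocks and sessions.
    """
    if len(runs) != len(schedules):
        raise DesignError("runs and schedules length mismatch")
    present = {b.condition for s in schedules for b in s.blocks}
    for cond in conditions:
        if cond not in present:
            raise DesignError(f"condition {cond!r} absent from schedules")

    windows: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    baselines = []
    for run, schedule in zip(runs, schedules):
        if roi_coords is None:
            series = run.flat().mean(axis=0)
        else:
            coords = np.asarray(roi_coords, dtype=int)
            idx = np.ravel_multi_index(coords.T, run.grid_shape)
            series = run.flat()[idx].mean(axis=0)
        fix_trs = np.concatenate(
            [np.arange(b.onset_tr, b.end_tr) for b in schedule.blocks_of(FIXATION)]
        )
        baseline = series[fix_trs].mean()
        if baseline == 0:
            raise DesignError("zero fixation baseline; PSC undefined")
        psc = 100.0 * (series - baseline) / baseline
        baselines.append(baseline)
        fix_blocks = schedule.blocks_of(FIXATION)
        fix_trs_len = fix_blocks[0].duration_trs if fix_blocks else 0
        for cond in conditions:
            for block in schedule.blocks_of(cond):
                # fixed event-locked span: block plus one fixation-length tail,
                # regardless of what actually follows this particular block
                n = window_trs or (block.duration_trs + fix_trs_len)
                if block.onset_tr + n > run.n_trs:
                    raise DesignError(
                        f"block at TR {block.onset_tr} lacks {n} usable post-onset samples"
                    )
                windows[cond].append(psc[block.onset_tr : block.onset_tr + n])

    lo, hi = PLATEAU_WINDOW
    timecourses = {}
    plateau = {}
    for cond in conditions:
        n_min = min(len(w) for w in windows[cond])
        course = np.mean([w[:n_min] for w in windows[cond]], axis=0)
        if n_min < hi:
            raise DesignError(
                f"condition {cond!r}: only {n_min} post-onset TRs, plateau needs {hi}"
            )
        timecourses[cond] = course
        plateau[cond] = float(course[lo - 1 : hi].mean())
    return PlateauPSC(
        timecourses=timecourses,
        plateau=plateau,
        baseline=float(np.mean(baselines)),
    )
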