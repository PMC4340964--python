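"""Multivoxel pattern decoding: session-wise preprocessing, block-pattern
extraction with per-condition mean subtraction, and leave-one-session-out
linear-SVM cross-validation.

Every transform operates strictly within one session, so no statistic from
a training session ever touches a held-out session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .design import BlockSchedule, FACE_CONDITIONS
from .errors import ConfigurationError, DesignError
from .roi import ROIMask
from .simulate import BOLDRun

VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class DecodeConfig:
    """Preprocessing and classifier settings for block-pattern decoding."""

    lag_trs: int = 2  # hemodynamic-lag shift, in whole TRs
    discard_trs: int = 2  # contaminated volumes dropped at block start
    svm_c: float = 1.0  # linear SVM regularization constant, no inner tuning
    class_pair: tuple[str, str] = FACE_CONDITIONS

    def __post_init__(self) -> None:
        if self.lag_trs < 0 or self.discard_trs < 0:
            raise ConfigurationError("lag_trs and discard_trs must be non-negative")
        if self.svm_c <= 0:
            raise ConfigurationError("svm_c must be positive")
        if len(self.class_pair) != 2 or self.class_pair[0] == self.class_pair[1]:
            raise ConfigurationError("class_pair must name two distinct conditions")


@dataclass
class PreprocessedSession:
    """Detrended, z-scored, lag-shifted voxel time series for one session."""

    data: np.ndarray  # (n_voxels, n_trs - lag_trs)
    session_id: int
    lag_trs: int
    tr_seconds: float
    grid_shape: tuple[int, int, int]
    flagged_voxels: np.ndarray  # flat indices that hit the variance floor

    @property
    def lag_seconds(self) -> float:
        return self.lag_trs * self.tr_seconds


def preprocess_session(run: BOLDRun, cfg: DecodeConfig) -> PreprocessedSession:
    """Detrend -> z-score -> shift one session's voxel time series.

    The linear trend is removed per voxel, the residual is standardized to
    zero mean / unit variance (sample sd) over the full session, and the
    series is shifted so that sample t is read from t + lag_trs, dropping
    the trailing ``lag_trs`` samples.
    """
    n_trs = run.n_trs
    if n_trs <= cfg.lag_trs:
        raise ConfigurationError(
            f"session of {n_trs} TRs too short for lag_trs={cfg.lag_trs}"
        )
    Y = run.flat().astype(float)

    # linear detrend via projection onto [1, t]
    t = np.arange(n_trs, dtype=float)
    X = np.column_stack([np.ones(n_trs), t - t.mean()])
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    detrended = Y - (X @ coef).T

    sd = detrended.std(axis=1, ddof=1)
    flagged = np.nonzero(sd**2 < VARIANCE_FLOOR)[0]
    if flagged.size:
        warnings.warn(
            f"{flagged.size} voxel(s) with ~zero variance; variance floor applied",
            RuntimeWarning,
            stacklevel=2,
        )
    sd = np.maximum(sd, np.sqrt(VARIANCE_FLOOR))
    standardized = detrended / sd[:, None]

    shifted = standardized[:, cfg.lag_trs :] if cfg.lag_trs else standardized
    return PreprocessedSession(
        data=shifted,
        session_id=run.session_id,
        lag_trs=cfg.lag_trs,
        tr_seconds=run.tr_seconds,
        grid_shape=run.grid_shape,
        flagged_voxels=flagged,
    )


@dataclass
class PatternSet:
    """One averaged multivoxel pattern per block, with labels and provenance."""

    patterns: np.ndarray  # (n_blocks, n_voxels)
    labels: np.ndarray  # (n_blocks,) condition strings
    session_ids: np.ndarray  # (n_blocks,)
    n_trs_averaged: int
    mean_subtracted: bool = False

    def __len__(self) -> int:
        return len(self.patterns)


def concat_pattern_sets(sets: Sequence[PatternSet]) -> PatternSet:
    if not sets:
        raise ValueError("no pattern sets to concatenate")
    counts = {s.n_trs_averaged for s in sets}
    if len(counts) > 1:
        raise ValueError(f"inconsistent n_trs_averaged across sessions: {counts}")
    return PatternSet(
        patterns=np.vstack([s.patterns for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        session_ids=np.concatenate([s.session_ids for s in sets]),
        n_trs_averaged=counts.pop(),
        mean_subtracted=all(s.mean_subtracted for s in sets),
    )


def block_averages(
    pre: PreprocessedSession,
    schedule: BlockSchedule,
    voxel_indices: np.ndarray,
    classes: Sequence[str],
    cfg: DecodeConfig,
) -> PatternSet:
    """Per-block temporal averages, without condition-mean subtraction.

    For every block of the listed classes the first ``discard_trs`` volumes
    are dropped and the remaining volumes averaged into one vector over the
    selected voxels.
    """
    rows = []
    labels = []
    for block in schedule.blocks:
        if block.condition not in classes:
            continue
        usable = block.duration_trs - cfg.discard_trs
        if usable < 1:
            raise DesignError(
                f"block of {block.duration_trs} TRs leaves no samples after "
                f"discarding {cfg.discard_trs}"
            )
        start = block.onset_tr + cfg.discard_trs
        stop = block.onset_tr + block.duration_trs
        if stop > pre.data.shape[1]:
            raise DesignError(
                f"block ending at TR {stop} exceeds shifted session length "
                f"{pre.data.shape[1]}"
            )
        rows.append(pre.data[voxel_indices, start:stop].mean(axis=1))
        labels.append(block.condition)
    usable = {b.duration_trs - cfg.discard_trs for b in schedule.blocks if b.condition in classes}
    return PatternSet(
        patterns=np.array(rows),
        labels=np.array(labels),
        session_ids=np.full(len(rows), pre.session_id),
        n_trs_averaged=usable.pop() if len(usable) == 1 else -1,
    )


def subtract_condition_means(patterns: PatternSet) -> PatternSet:
    """Remove, per (condition, session), the scalar mean over voxels and blocks.

    This is the per-condition global-signal subtraction; applied within each
    session only, so it is leakage-free under session-wise cross-validation.
    """
    out = patterns.patterns.copy()
    for sid in np.unique(patterns.session_ids):
        for cond in np.unique(patterns.labels):
            sel = (patterns.session_ids == sid) & (patterns.labels == cond)
            if sel.any():
                out[sel] -= out[sel].mean()
    return PatternSet(
        patterns=out,
        labels=patterns.labels,
        session_ids=patterns.session_ids,
        n_trs_averaged=patterns.n_trs_averaged,
        mean_subtracted=True,
    )


def extract_block_patterns(
    pre: PreprocessedSession,
    schedule: BlockSchedule,
    roi: ROIMask,
    classes: Sequence[str],
    cfg: DecodeConfig,
) -> PatternSet:
    """One pattern per block over the ROI voxels, condition means removed."""
    present = {b.condition for b in schedule.blocks}
    missing = set(classes) - present
    if missing:
        raise DesignError(f"classes {sorted(missing)} absent from session {schedule.session_id}")
    idx = roi.index_into(pre.grid_shape)
    raw = block_averages(pre, schedule, idx, classes, cfg)
    return subtract_condition_means(raw)


def build_patterns(
    runs: Sequence[BOLDRun],
    schedules: Sequence[BlockSchedule],
    roi: ROIMask,
    cfg: DecodeConfig,
) -> PatternSet:
    """Full per-subject chain: preprocess each session, extract, concatenate."""
    sets = []
    for run, schedule in zip(runs, schedules):
        pre = preprocess_session(run, cfg)
        sets.append(extract_block_patterns(pre, schedule, roi, cfg.class_pair, cfg))
    return concat_pattern_sets(sets)


def loso_decode(patterns: PatternSet, cfg: DecodeConfig) -> tuple[float, int]:
    """Leave-one-session-out linear-SVM accuracy.

    Returns (mean fraction correct over folds, number of folds).  Each fold
    holds out one session; the classifier is a linear SVM with fixed C.
    """
    sessions = np.unique(patterns.session_ids)
    if len(sessions) < 2:
        raise DesignError("leave-one-session-out needs at least 2 sessions")
    for sid in sessions:
        labels_here = set(patterns.labels[patterns.session_ids == sid])
        missing = set(cfg.class_pair) - labels_here
        if missing:
            raise DesignError(f"session {sid} lacks class(es) {sorted(missing)}")

    keep = np.isin(patterns.labels, cfg.class_pair)
    X = patterns.patterns[keep]
    y = patterns.labels[keep]
    sid = patterns.session_ids[keep]

    fold_acc = []
    for test_sid in sessions:
        train = sid != test_sid
        clf = SVC(kernel="linear", C=cfg.svm_c)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[~train])
        fold_acc.append(np.mean(pred == y[~train]))
    return float(np.mean(fold_acc)), len(sessions)
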