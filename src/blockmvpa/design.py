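"""Block-design schedules and within-block one-back trial sequences.

A session is a sequence of triplets, each holding one face block, one cup
block and one fixation block.  Within a triplet the face/cup order is
counterbalanced: half of the triplets present faces first, the other half
cups first, with the triplet order shuffled per session.  This guarantees
that two temporally adjacent stimulation blocks never share a superordinate
category (faces vs cups).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError

#: Condition labels.  The two face identities and the two cup types are the
#: decodable classes; fixation is the rest baseline.
FACE_CONDITIONS = ("identity1", "identity2")
CUP_CONDITIONS = ("cup1", "cup2")
FIXATION = "fixation"
ALL_CONDITIONS = FACE_CONDITIONS + CUP_CONDITIONS + (FIXATION,)

#: Number of distinct exemplar images per condition.
IMAGES_PER_CONDITION = 8


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the block design.

    Defaults reproduce the reference design: 2 s sampling, 16 s stimulation
    blocks (8 TRs), 8 s fixation blocks, 5 blocks per face identity / cup
    type, 16 stimuli per block (0.3 s on, 0.7 s inter-stimulus interval),
    at most 4 one-back targets per block and +/-20 px positional jitter.
    """

    tr_seconds: float = 2.0
    block_seconds: float = 16.0
    fixation_seconds: float = 8.0
    blocks_per_condition: int = 5
    n_conditions: int = 4
    stim_seconds: float = 0.3
    isi_seconds: float = 0.7
    max_oneback_targets: int = 4
    jitter_pixels: int = 20
    pad_trs_start: int = 0
    pad_trs_end: int = 0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        for name in ("block_seconds", "fixation_seconds"):
            value = getattr(self, name)
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")
            ratio = value / self.tr_seconds
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={value} is not an integer multiple of tr_seconds={self.tr_seconds}"
                )
        trial = self.stim_seconds + self.isi_seconds
        if trial <= 0:
            raise ConfigurationError("stim_seconds + isi_seconds must be positive")
        n_trials = self.block_seconds / trial
        if abs(n_trials - round(n_trials)) > 1e-9:
            raise ConfigurationError(
                "stim_seconds + isi_seconds must divide block_seconds evenly"
            )
        if self.blocks_per_condition < 0:
            raise ConfigurationError("blocks_per_condition must be non-negative")
        if self.n_conditions != 4:
            raise ConfigurationError("n_conditions must be 4 (two identities, two cup types)")
        if self.max_oneback_targets < 0:
            raise ConfigurationError("max_oneback_targets must be non-negative")
        if self.jitter_pixels < 0:
            raise ConfigurationError("jitter_pixels must be non-negative")
        if self.pad_trs_start < 0 or self.pad_trs_end < 0:
            raise ConfigurationError("session padding must be non-negative")

    @property
    def block_trs(self) -> int:
        return int(round(self.block_seconds / self.tr_seconds))

    @property
    def fixation_trs(self) -> int:
        return int(round(self.fixation_seconds / self.tr_seconds))

    @property
    def trials_per_block(self) -> int:
        return int(round(self.block_seconds / (self.stim_seconds + self.isi_seconds)))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DesignParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class Block:
    condition: str
    onset_tr: int
    duration_trs: int

    @property
    def end_tr(self) -> int:
        return self.onset_tr + self.duration_trs


@dataclass
class BlockSchedule:
    """Ordered, contiguous blocks of one session."""

    session_id: int
    blocks: list[Block]

    @property
    def n_trs(self) -> int:
        """Total number of TRs spanned (including any leading pad)."""
        return max((b.end_tr for b in self.blocks), default=0)

    def blocks_of(self, conditions: str | Iterable[str]) -> list[Block]:
        if isinstance(conditions, str):
            conditions = (conditions,)
        wanted = set(conditions)
        return [b for b in self.blocks if b.condition in wanted]

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.blocks:
            counts[b.condition] = counts.get(b.condition, 0) + 1
        return counts

    def validate(self) -> None:
        """Raise :class:`DesignError` if any schedule invariant is violated."""
        prev_end = None
        prev_cond = None
        for b in self.blocks:
            if prev_end is not None and b.onset_tr != prev_end:
                raise DesignError(
                    f"blocks not contiguous at TR {b.onset_tr} (previous ended {prev_end})"
                )
            if prev_cond is not None:
                if _category(prev_cond) is not None and _category(prev_cond) == _category(b.condition):
                    raise DesignError(
                        f"adjacent blocks share superordinate category: {prev_cond}, {b.condition}"
                    )
            prev_end = b.end_tr
            prev_cond = b.condition
        counts = self.condition_counts()
        n_face = sum(counts.get(c, 0) for c in FACE_CONDITIONS)
        n_cup = sum(counts.get(c, 0) for c in CUP_CONDITIONS)
        if self.blocks and n_face != n_cup:
            raise DesignError(f"face/cup block counts differ: {n_face} vs {n_cup}")


def _category(condition: str) -> str | None:
    if condition in FACE_CONDITIONS:
        return "faces"
    if condition in CUP_CONDITIONS:
        return "cups"
    return None


def generate_session_schedule(
    params: DesignParams, seed: int, session_id: int = 0
) -> BlockSchedule:
    """Generate one session's block schedule.

    The session consists of ``2 * blocks_per_condition`` triplets, each of the
    form faces-cups-fixation or cups-faces-fixation.  Exactly half of the
    triplets are faces-first; the triplet order and the identity / cup-type
    assignment within each superordinate category are seeded permutations.
    """
    rng = np.random.default_rng(seed)
    bpc = params.blocks_per_condition
    n_triplets = 2 * bpc
    if n_triplets == 0:
        return BlockSchedule(session_id=session_id, blocks=[])

    faces_first = np.array([True] * bpc + [False] * bpc)
    rng.shuffle(faces_first)
    identities = np.array([FACE_CONDITIONS[0]] * bpc + [FACE_CONDITIONS[1]] * bpc)
    rng.shuffle(identities)
    cup_types = np.array([CUP_CONDITIONS[0]] * bpc + [CUP_CONDITIONS[1]] * bpc)
    rng.shuffle(cup_types)

    blocks: list[Block] = []
    onset = params.pad_trs_start
    for i in range(n_triplets):
        face = str(identities[i])
        cup = str(cup_types[i])
        pair = (face, cup) if faces_first[i] else (cup, face)
        for cond in pair:
            blocks.append(Block(cond, onset, params.block_trs))
            onset += params.block_trs
        blocks.append(Block(FIXATION, onset, params.fixation_trs))
        onset += params.fixation_trs

    schedule = BlockSchedule(session_id=session_id, blocks=blocks)
    schedule.validate()
    return schedule


@dataclass(frozen=True)
class Trial:
    image_id: int
    is_oneback_target: bool
    jitter_xy: tuple[int, int]


@dataclass
class TrialSequence:
    """Per-block trial listings keyed by the block's index in the schedule."""

    session_id: int
    trials: dict[int, list[Trial]]


def generate_trial_sequence(
    schedule: BlockSchedule, params: DesignParams, seed: int
) -> TrialSequence:
    """Generate one-back trial sequences for every stimulation block.

    Each block presents ``trials_per_block`` images drawn from its
    condition's 8 exemplars.  Target trials repeat the immediately preceding
    image; the target count is drawn uniformly from
    ``{0..max_oneback_targets}`` and target positions never neighbour each
    other (a repeat of a repeat would be ambiguous to score).  Non-target
    trials always change the image so no unintended repeats occur.
    """
    rng = np.random.default_rng(seed)
    trials: dict[int, list[Trial]] = {}
    n_trials = params.trials_per_block
    for idx, block in enumerate(schedule.blocks):
        if block.condition == FIXATION:
            continue
        max_targets = min(params.max_oneback_targets, max(n_trials - 1, 0))
        n_targets = int(rng.integers(0, max_targets + 1))
        target_positions = _draw_nonadjacent_positions(rng, n_trials, n_targets)
        seq: list[Trial] = []
        prev_image = None
        for t in range(n_trials):
            if t in target_positions:
                image = prev_image
            else:
                choices = [i for i in range(1, IMAGES_PER_CONDITION + 1) if i != prev_image]
                image = int(rng.choice(choices))
            jitter = tuple(
                int(v)
                for v in rng.integers(
                    -params.jitter_pixels, params.jitter_pixels + 1, size=2
                )
            )
            seq.append(Trial(image, t in target_positions, jitter))
            prev_image = image
        trials[idx] = seq
    return TrialSequence(session_id=schedule.session_id, trials=trials)


def _draw_nonadjacent_positions(
    rng: np.random.Generator, n_trials: int, n_targets: int
) -> set[int]:
    """Draw target trial positions in 1..n_trials-1 with no two adjacent."""
    if n_targets == 0:
        return set()
    candidates = np.arange(1, n_trials)
    for _ in range(10_000):
        pick = np.sort(rng.choice(candidates, size=n_targets, replace=False))
        if n_targets == 1 or np.all(np.diff(pick) > 1):
            return set(int(p) for p in pick)
    raise DesignError(
        f"cannot place {n_targets} non-adjacent targets among {n_trials} trials"
    )


# ---------------------------------------------------------------------------
# Sidecar serialization


def schedules_to_frame(schedules: Sequence[BlockSchedule]) -> pd.DataFrame:
    rows = [
        {
            "session_id": s.session_id,
            "condition": b.condition,
            "onset_tr": b.onset_tr,
            "duration_trs": b.duration_trs,
        }
        for s in schedules
        for b in s.blocks
    ]
    return pd.DataFrame(rows, columns=["session_id", "condition", "onset_tr", "duration_trs"])


def frame_to_schedules(frame: pd.DataFrame) -> list[BlockSchedule]:
    schedules = []
    for sid, grp in frame.groupby("session_id", sort=True):
        blocks = [
            Block(str(r.condition), int(r.onset_tr), int(r.duration_trs))
            for r in grp.itertuples()
        ]
        schedules.append(BlockSchedule(session_id=int(sid), blocks=blocks))
    return schedules


def write_schedules_csv(schedules: Sequence[BlockSchedule], path, header_comment: str | None = None) -> None:
    frame = schedules_to_frame(schedules)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def read_schedules_csv(path) -> list[BlockSchedule]:
    frame = pd.read_csv(path, comment="#")
    return frame_to_schedules(frame)
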