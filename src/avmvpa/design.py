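"""Deterministic experiment timelines for the 4 (task) x 3 (stimulus) design.

The experiment crosses four feature-selective attention tasks (number, gender,
emotion, bi-feature) with three stimulus conditions (visual-only V,
auditory-only A, audiovisual AV; an incongruent-AV control exists for the
gender and emotion tasks).  A run holds 10 blocks of 8 trials; every trial
presents a face stimulus carrying two binary semantic features, gender
(male/female) and emotion (crying/laughing), balanced 4/4 within each block
in both dimensions.  Timing: a 10 s pre-stimulation baseline, then per block
a 4 s instruction followed by eight 14 s trials, with 20 s blanks between
blocks -- 1,350 s per run at TR = 2 s.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TR_S = 2.0
TRIAL_S = 14.0
FEATURES = ("gender", "emotion")

GENDER_CLASSES = ("male", "female")
EMOTION_CLASSES = ("crying", "laughing")


class Task(str, enum.Enum):
    NUMBER = "number"
    GENDER = "gender"
    EMOTION = "emotion"
    BIFEATURE = "bifeature"


class Condition(str, enum.Enum):
    V = "V"
    A = "A"
    AV = "AV"
    AV_INCONGRUENT = "AV_incongruent"


#: attended feature set per task (cardinality 0 / 1 / 1 / 2)
ATTENDED_FEATURES: dict[Task, frozenset[str]] = {
    Task.NUMBER: frozenset(),
    Task.GENDER: frozenset({"gender"}),
    Task.EMOTION: frozenset({"emotion"}),
    Task.BIFEATURE: frozenset({"gender", "emotion"}),
}


class DesignError(ValueError):
    """Invalid task/condition configuration."""


@dataclass(frozen=True)
class TaskSpec:
    task_id: Task
    attended_features: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "task_id", Task(self.task_id))
        expected = ATTENDED_FEATURES[self.task_id]
        if self.attended_features is None:
            object.__setattr__(self, "attended_features", expected)
        elif frozenset(self.attended_features) != expected:
            raise DesignError(
                f"task {self.task_id.value} attends {sorted(expected)}, "
                f"got {sorted(self.attended_features)}"
            )

    def attends(self, feature: str) -> bool:
        return feature in self.attended_features


@dataclass(frozen=True)
class StimulusCondition:
    condition: Condition

    def __post_init__(self):
        object.__setattr__(self, "condition", Condition(self.condition))

    @property
    def congruent(self) -> bool:
        return self.condition is not Condition.AV_INCONGRUENT

    @property
    def audiovisual(self) -> bool:
        return self.condition in (Condition.AV, Condition.AV_INCONGRUENT)


@dataclass(frozen=True)
class TrialEvent:
    onset_s: float
    gender_label: str
    emotion_label: str
    block_index: int
    trial_index_in_run: int
    duration_s: float = TRIAL_S


@dataclass(frozen=True)
class RunDesign:
    task: TaskSpec
    condition: StimulusCondition
    trials: tuple[TrialEvent, ...]
    n_blocks: int = 10
    trials_per_block: int = 8
    baseline_s: float = 10.0
    instruction_s: float = 4.0
    interblock_blank_s: float = 20.0
    tr_s: float = TR_S
    rng_seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        block_s = self.instruction_s + self.trials_per_block * TRIAL_S
        return (
            self.baseline_s
            + self.n_blocks * block_s
            + (self.n_blocks - 1) * self.interblock_blank_s
        )

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration_s / self.tr_s))

    def block_start_s(self, b: int) -> float:
        """Onset of block b's instruction period."""
        block_s = self.instruction_s + self.trials_per_block * TRIAL_S
        return self.baseline_s + b * (block_s + self.interblock_blank_s)

    def block_spans_s(self) -> list[tuple[float, float]]:
        """(start, end) of each block, instruction onset to last trial end."""
        block_s = self.instruction_s + self.trials_per_block * TRIAL_S
        return [(self.block_start_s(b), self.block_start_s(b) + block_s)
                for b in range(self.n_blocks)]

    def labels(self, feature: str) -> np.ndarray:
        """Binary labels (0/1) of all trials along one feature dimension."""
        if feature == "gender":
            return np.array([GENDER_CLASSES.index(t.gender_label) for t in self.trials])
        if feature == "emotion":
            return np.array([EMOTION_CLASSES.index(t.emotion_label) for t in self.trials])
        raise DesignError(f"unknown feature {feature!r}")

    def block_index(self) -> np.ndarray:
        return np.array([t.block_index for t in self.trials])

    def shifted(self, dt_s: float) -> "RunDesign":
        """Re-reference all onsets by dt_s (baseline removal bookkeeping)."""
        trials = tuple(replace(t, onset_s=t.onset_s + dt_s) for t in self.trials)
        return replace(self, trials=trials, baseline_s=self.baseline_s + dt_s)

    # -- serialization -----------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [t.onset_s for t in self.trials],
                "duration": [t.duration_s for t in self.trials],
                "block": [t.block_index for t in self.trials],
                "gender": [t.gender_label for t in self.trials],
                "emotion": [t.emotion_label for t in self.trials],
                "task": self.task.task_id.value,
                "condition": self.condition.condition.value,
            }
        )

    def header(self) -> dict:
        return {
            "task": self.task.task_id.value,
            "attended_features": sorted(self.task.attended_features),
            "condition": self.condition.condition.value,
            "congruent": self.condition.congruent,
            "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "baseline_s": self.baseline_s,
            "instruction_s": self.instruction_s,
            "interblock_blank_s": self.interblock_blank_s,
            "tr_s": self.tr_s,
            "total_duration_s": self.total_duration_s,
            "rng_seed": int(self.rng_seed),
        }

    def to_json(self) -> str:
        return json.dumps(self.header(), indent=2)


def build_run_design(
    task: TaskSpec | Task | str,
    condition: StimulusCondition | Condition | str,
    seed: int,
    n_blocks: int = 10,
    trials_per_block: int = 8,
    baseline_s: float = 10.0,
    instruction_s: float = 4.0,
    interblock_blank_s: float = 20.0,
) -> RunDesign:
    """Build one run's trial timeline with per-block balanced labels.

    The stimulus-to-trial assignment is a seeded permutation: each block
    receives exactly two stimuli of each (gender, emotion) joint category,
    shuffled within the block, which yields the 4/4 balance of both label
    dimensions inside every block and keeps the overall 80-stimulus label
    multiset identical across seeds.

    The incongruent-AV control condition is only defined for the gender and
    emotion tasks.
    """
    if not isinstance(task, TaskSpec):
        task = TaskSpec(Task(task))
    if not isinstance(condition, StimulusCondition):
        condition = StimulusCondition(Condition(condition))
    if condition.condition is Condition.AV_INCONGRUENT and task.task_id not in (
        Task.GENDER,
        Task.EMOTION,
    ):
        raise DesignError(
            "incongruent-AV control runs exist only for the gender and emotion tasks"
        )
    if trials_per_block % 4:
        raise DesignError("trials_per_block must be a multiple of 4 for 4/4 balance")

    rng = np.random.default_rng(seed)
    combos = [(g, e) for g in GENDER_CLASSES for e in EMOTION_CLASSES]
    per_combo = trials_per_block // 4

    trials: list[TrialEvent] = []
    for b in range(n_blocks):
        block_labels = combos * per_combo
        order = rng.permutation(len(block_labels))
        block_start = (
            baseline_s
            + b * (instruction_s + trials_per_block * TRIAL_S + interblock_blank_s)
        )
        for t, j in enumerate(order):
            g, e = block_labels[j]
            trials.append(
                TrialEvent(
                    onset_s=block_start + instruction_s + t * TRIAL_S,
                    gender_label=g,
                    emotion_label=e,
                    block_index=b,
                    trial_index_in_run=b * trials_per_block + t,
                )
            )
    return RunDesign(
        task=task,
        condition=condition,
        trials=tuple(trials),
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        baseline_s=baseline_s,
        instruction_s=instruction_s,
        interblock_blank_s=interblock_blank_s,
        rng_seed=int(seed),
    )


def trial_volume_window(
    trial: TrialEvent, tr_s: float = TR_S, n_volumes: int | None = None
) -> np.ndarray:
    """Volume indices of the last four volumes of a 14 s trial.

    A volume is indexed 0-based from run start and covers the TR-long
    interval beginning at its acquisition onset, so the 6th-to-14th-second
    window of a trial starting at an even second maps to in-trial volumes
    3..6 at TR = 2 s.  Accounts for the hemodynamic delay.
    """
    frac = trial.onset_s / tr_s
    base = int(round(frac))
    if abs(frac - base) > 1e-9:
        raise DesignError(f"trial onset {trial.onset_s} not aligned to TR grid {tr_s}")
    n_in_trial = int(round(trial.duration_s / tr_s))
    win = np.arange(base + n_in_trial - 4, base + n_in_trial)
    if n_volumes is not None and win[-1] >= n_volumes:
        raise DesignError(
            f"trial window {win.tolist()} extends past run end ({n_volumes} volumes)"
        )
    return win
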