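"""Trial data model for the two numerical-operation tasks.

The numerical operation task asks the animal to transform a *preoperational*
numerosity (0-6 visible items) into a remembered *target* numerosity (1-4) by
turning one of two hand-held devices; which device adds and which subtracts is
set by a block-wise rule (rule 1: left adds, right subtracts; rule 2 reversed).
The instructed task replaces the target with an explicit +/- instruction over
preoperational numerosities 1-3.

Every analysis factor -- arithmetic (addition vs subtraction), hand (left vs
right) and step (1 vs 2 device uses) -- is derivable from the trial conditions
and the active rule; this module owns those derivations plus the trial filters
used by all downstream stages.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# -- enums (kept as plain strings so trial tables stay human-readable CSV) ----
TASK_NUMERICAL = "numerical_operation"
TASK_INSTRUCTED = "instructed"
RULE1, RULE2 = "rule1", "rule2"
ADDITION, SUBTRACTION = "addition", "subtraction"
LEFT, RIGHT = "left", "right"
PLUS, MINUS, NO_INSTRUCTION = "plus", "minus", "none"
STANDARD, CONTROL = "standard", "control"

FACTORS = ("arithmetic", "hand", "step", "stimulus_type")

_ACTIONS_RE = re.compile(r"^[LR]*$")


@dataclass(frozen=True)
class EventTimeline:
    """Task epoch durations in ms and derived alignment constants.

    The concern period -- the analysis epoch -- runs from preoperational
    numerosity onset to 700 ms after the Go signal (2400 ms, 24 bins of
    100 ms). Bins 0-16 are aligned to preoperational onset and bins 17-23 to
    the Go signal; with the canonical timing the two stretches are seamless.
    """

    fixation_ms: int = 800
    target_on_ms: int = 700
    delay1_ms: int = 1000
    preop_on_ms: int = 700
    delay2_ms: int = 1000
    operation_window_ms: int = 700
    bin_width_ms: int = 100

    @property
    def preop_onset_ms(self) -> int:
        return self.fixation_ms + self.target_on_ms + self.delay1_ms

    @property
    def go_ms(self) -> int:
        return self.preop_onset_ms + self.preop_on_ms + self.delay2_ms

    @property
    def concern_duration_ms(self) -> int:
        return self.preop_on_ms + self.delay2_ms + self.operation_window_ms

    @property
    def n_bins(self) -> int:
        return self.concern_duration_ms // self.bin_width_ms

    def event_times(self) -> dict[str, int]:
        """Named event onsets (ms from fixation onset)."""
        return {
            "fixation": 0,
            "target_on": self.fixation_ms,
            "delay1": self.fixation_ms + self.target_on_ms,
            "preop_on": self.preop_onset_ms,
            "delay2": self.preop_onset_ms + self.preop_on_ms,
            "go": self.go_ms,
        }


DEFAULT_TIMELINE = EventTimeline()

#: periods of the concern epoch, as half-open bin ranges
PERIOD_BINS = {
    "preop": range(0, 7),
    "delay2": range(7, 17),
    "operation": range(17, 24),
}

EVENT_COLUMNS = [f"t_{k}" for k in DEFAULT_TIMELINE.event_times()]

TRIAL_COLUMNS = [
    "trial_id",
    "task",
    "rule",
    "target_numerosity",
    "preoperational_numerosity",
    "instruction",
    "stimulus_type",
    "actions",
    "chosen_numerosity",
    "correct",
    "reaction_time_ms",
    *EVENT_COLUMNS,
]

LABEL_COLUMNS = ["arithmetic", "hand", "step", "label_valid"]


@dataclass
class TrialRecord:
    """One behavioural trial (scalar view of a trial-table row)."""

    trial_id: int
    task: str
    rule: str
    target_numerosity: int | None
    preoperational_numerosity: int
    instruction: str
    stimulus_type: str
    actions: str
    chosen_numerosity: int
    correct: bool
    reaction_time_ms: float
    event_times_ms: dict[str, int] = field(default_factory=DEFAULT_TIMELINE.event_times)

    def validate(self) -> None:
        if self.task == TASK_NUMERICAL:
            if self.target_numerosity is None or self.instruction != NO_INSTRUCTION:
                raise ValueError(
                    "numerical_operation trials need a target and no instruction"
                )
        elif self.task == TASK_INSTRUCTED:
            if self.target_numerosity is not None or self.instruction == NO_INSTRUCTION:
                raise ValueError("instructed trials need an instruction and no target")
        else:
            raise ValueError(f"unknown task {self.task!r}")
        if not _ACTIONS_RE.match(self.actions):
            raise ValueError(f"actions must be a string over L/R, got {self.actions!r}")
        replay = replay_actions(
            self.preoperational_numerosity, self.actions, self.rule
        )
        if replay != self.chosen_numerosity:
            raise ValueError(
                f"replaying actions gives {replay}, recorded chosen "
                f"{self.chosen_numerosity}"
            )


@dataclass(frozen=True)
class OperationLabels:
    """Derived per-trial analysis factors; ``valid`` is False for trials the
    factor scheme does not cover (hold trials, >2-step trials)."""

    arithmetic: str | None
    hand: str | None
    step: int | None
    valid: bool


def required_hand(arithmetic: str, rule: str) -> str:
    """Device required for an operation under a rule.

    Rule 1 maps the left device to +1 and the right device to -1 per use;
    rule 2 reverses the mapping. Flipping the rule flips the hand.
    """
    if arithmetic not in (ADDITION, SUBTRACTION):
        raise ValueError(f"unknown operation {arithmetic!r}")
    if rule not in (RULE1, RULE2):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == RULE1:
        return LEFT if arithmetic == ADDITION else RIGHT
    return RIGHT if arithmetic == ADDITION else LEFT


def action_increment(hand: str, rule: str) -> int:
    """Displayed-numerosity change for one use of ``hand`` under ``rule``."""
    if rule == RULE1:
        return 1 if hand == LEFT else -1
    return 1 if hand == RIGHT else -1


def replay_actions(preop: int, actions: str, rule: str) -> int:
    """Replay a trial's device uses from the preoperational numerosity."""
    value = int(preop)
    for a in actions:
        value += action_increment(LEFT if a == "L" else RIGHT, rule)
    return value


def derive_labels(trial: TrialRecord) -> OperationLabels:
    """Factor labels for a single (correct, minimum-step) trial."""
    if trial.task == TASK_NUMERICAL:
        delta = trial.target_numerosity - trial.preoperational_numerosity
        if delta == 0:
            return OperationLabels(None, None, None, False)
        arithmetic = ADDITION if delta > 0 else SUBTRACTION
        step = abs(delta)
    else:
        arithmetic = ADDITION if trial.instruction == PLUS else SUBTRACTION
        step = len(trial.actions)
    if step not in (1, 2):
        return OperationLabels(None, None, None, False)
    hand = required_hand(arithmetic, trial.rule)
    return OperationLabels(arithmetic, hand, step, True)


def label_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive_labels` over a trial table.

    Returns a copy with ``arithmetic``, ``hand``, ``step`` and ``label_valid``
    columns appended. Instructed-task steps use the executed number of device
    uses; trials outside the 1-2 step analysis set get ``label_valid=False``.
    """
    df = trials.copy()
    numerical = df["task"] == TASK_NUMERICAL
    delta = df["target_numerosity"].fillna(0).astype(int) - df[
        "preoperational_numerosity"
    ].astype(int)
    n_actions = df["actions"].fillna("").str.len()

    arithmetic = pd.Series(pd.NA, index=df.index, dtype="object")
    arithmetic[numerical & (delta > 0)] = ADDITION
    arithmetic[numerical & (delta < 0)] = SUBTRACTION
    arithmetic[~numerical & (df["instruction"] == PLUS)] = ADDITION
    arithmetic[~numerical & (df["instruction"] == MINUS)] = SUBTRACTION

    step = pd.Series(0, index=df.index, dtype=int)
    step[numerical] = delta[numerical].abs()
    step[~numerical] = n_actions[~numerical]

    valid = arithmetic.notna() & step.isin([1, 2])

    hand = pd.Series(pd.NA, index=df.index, dtype="object")
    is_add = arithmetic == ADDITION
    is_r1 = df["rule"] == RULE1
    hand[valid & is_add & is_r1] = LEFT
    hand[valid & ~is_add & is_r1] = RIGHT
    hand[valid & is_add & ~is_r1] = RIGHT
    hand[valid & ~is_add & ~is_r1] = LEFT

    df["arithmetic"] = arithmetic
    df["hand"] = hand
    df["step"] = step.where(valid, other=pd.NA)
    df["label_valid"] = valid.to_numpy()
    return df


def filter_analysis_trials(
    trials: pd.DataFrame, exclude_extremes: bool = False
) -> pd.DataFrame:
    """Retain correct, minimum-step trials (order preserved, idempotent).

    Minimum-step means the executed device-use count equals |target - preop|
    for the numerical task and exactly one use for the instructed task, so
    switching-behaviour trials are dropped even when eventually correct. With
    ``exclude_extremes`` the forced-choice preoperational numerosities
    {0, 5, 6} are also removed.
    """
    numerical = trials["task"] == TASK_NUMERICAL
    n_actions = trials["actions"].fillna("").str.len()
    delta = (
        trials["target_numerosity"].fillna(0).astype(int)
        - trials["preoperational_numerosity"].astype(int)
    )
    min_step = np.where(numerical, n_actions == delta.abs(), n_actions == 1)
    keep = trials["correct"].astype(bool).to_numpy() & min_step
    if exclude_extremes:
        keep &= ~trials["preoperational_numerosity"].isin([0, 5, 6]).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("filter_analysis_trials dropped %d of %d trials",
                       dropped, len(trials))
    return trials.loc[keep]


def enumerate_conditions(
    task: str,
    max_step: int = 2,
    include_hold: bool = True,
    pairs: list[tuple[int, int]] | None = None,
) -> list[dict]:
    """Condition set for a task.

    The recorded numerical condition set (19 target/preoperational pairs) is
    reproduced by target in 1-4, preop in 0-6 and |target - preop| <= 2
    including the matched (hold) pairs; alternative enumerations can be
    supplied via ``pairs``. The instructed task crosses +/- instructions with
    preoperational numerosities 1-3 (6 combinations).
    """
    if task == TASK_NUMERICAL:
        if pairs is None:
            lo = 0 if include_hold else 1
            pairs = [
                (t, p)
                for t in range(1, 5)
                for p in range(0, 7)
                if lo <= abs(t - p) <= max_step
            ]
        return [{"target_numerosity": t, "preoperational_numerosity": p}
                for t, p in pairs]
    if task == TASK_INSTRUCTED:
        return [
            {"instruction": instr, "preoperational_numerosity": p}
            for instr in (PLUS, MINUS)
            for p in range(1, 4)
        ]
    raise ValueError(f"unknown task {task!r}")


# -- external interface: delimited trial tables + JSON sidecar ---------------

def write_trials(trials: pd.DataFrame, path: str | Path,
                 meta: dict | None = None) -> Path:
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS + LABEL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)
    if meta is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, dtype={"actions": "string"})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} missing columns {sorted(missing)}")
    df["actions"] = df["actions"].fillna("")
    bad = ~df["actions"].map(lambda s: bool(_ACTIONS_RE.match(s)))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"malformed actions string {df['actions'].iloc[row]!r} at row {row}"
        )
    df["target_numerosity"] = df["target_numerosity"].astype("Int64")
    df["correct"] = df["correct"].astype(bool)
    return df
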