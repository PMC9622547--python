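"""Generative task environments.

Two paradigms are modelled:

* A **probabilistic serial-reversal learning task**: two stimuli, one
  rewarded with high probability (the target) and one with low probability,
  with the target silently reversing at every stage boundary.  The default
  build has 11 stages — an initial discrimination, a first reversal, five
  SRL1 stages (80/20 contingencies, 1 credit per win) and four SRL2 stages
  (80/40 contingencies, 2 or 6 credits per win with equal probability).
  A stage completes when the agent makes six consecutive correct (target)
  choices.

* An **outcome-specific devaluation task**: instrumental training of two
  action–outcome associations (each token earned by a run of 5–10
  consecutive responses, comprehension questions every three rounds, six
  consecutive correct questions to criterion), followed by an extinction
  choice test of 10 blocks × 12 s with no feedback.

Every stochastic operation takes an explicit :class:`numpy.random.Generator`;
there is no module-level random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "StageSpec",
    "TaskConfig",
    "TrialRecord",
    "SessionData",
    "DevalConfig",
    "TrainingRecord",
    "DevalSession",
    "build_default_task",
    "build_fixed_length_task",
    "draw_outcome",
    "run_session",
    "run_instrumental_training",
    "run_choice_test",
    "save_task_config",
    "load_task_config",
]

DEFAULT_STAGE_LABELS = (
    "discrimination",
    "first_reversal",
    "SRL1_1",
    "SRL1_2",
    "SRL1_3",
    "SRL1_4",
    "SRL1_5",
    "SRL2_1",
    "SRL2_2",
    "SRL2_3",
    "SRL2_4",
)

#: 0-based stage indices of the two serial-reversal phases in the default task.
SRL1_STAGES = (2, 3, 4, 5, 6)
SRL2_STAGES = (7, 8, 9, 10)


@dataclass(frozen=True)
class StageSpec:
    """One stage of the reversal task: contingencies, credits and criterion."""

    stage_label: str
    target_option: int
    p_reward_target: float
    p_reward_nontarget: float
    win_credits: dict[int, float]  # credit value -> selection probability
    loss_credits: int = 0
    criterion_consecutive: int = 6
    max_trials: int = 80

    def __post_init__(self) -> None:
        if self.target_option not in (0, 1):
            raise ValueError(f"target_option must be 0 or 1, got {self.target_option}")
        if not 0.0 <= self.p_reward_nontarget < self.p_reward_target <= 1.0:
            raise ValueError(
                "require 0 <= p_reward_nontarget < p_reward_target <= 1, got "
                f"{self.p_reward_nontarget}/{self.p_reward_target}"
            )
        probs = list(self.win_credits.values())
        if not probs or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("win_credits probabilities must be non-negative and sum to 1")
        if any(int(c) <= 0 for c in self.win_credits):
            raise ValueError("win credit values must be positive integers")
        if self.criterion_consecutive < 1:
            raise ValueError("criterion_consecutive must be >= 1")
        if self.max_trials < self.criterion_consecutive:
            raise ValueError("max_trials must be >= criterion_consecutive")

    @property
    def mean_win_credit(self) -> float:
        return float(sum(c * p for c, p in self.win_credits.items()))

    def p_reward(self, choice: int) -> float:
        if choice not in (0, 1):
            raise ValueError(f"choice must be 0 or 1, got {choice}")
        return self.p_reward_target if choice == self.target_option else self.p_reward_nontarget


@dataclass(frozen=True)
class TaskConfig:
    """Ordered stage list for one run of the reversal task.

    The same stimulus pair is used throughout; options are abstract indices
    0/1.  ``advance_on_truncation`` controls whether an agent that exhausts
    ``max_trials`` without reaching criterion still proceeds to the next
    stage (used for fixed-length estimation sessions); by default the
    session stops and is marked incomplete from that stage.
    """

    stages: tuple[StageSpec, ...]
    advance_on_truncation: bool = False
    note: str = "same stimulus pair throughout; options are indices 0/1"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("TaskConfig requires at least one stage")
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.target_option == prev.target_option:
                raise ValueError(
                    f"target must reverse between consecutive stages "
                    f"({prev.stage_label} -> {nxt.stage_label})"
                )

    @property
    def n_stages(self) -> int:
        return len(self.stages)


@dataclass(frozen=True)
class TrialRecord:
    stage_index: int  # 0-based
    stage_label: str
    trial_in_stage: int  # 1-based
    choice: int
    correct: bool
    credits: int
    win: bool

    def __post_init__(self) -> None:
        if self.win != (self.credits > 0):
            raise ValueError("win flag must equal credits > 0")


@dataclass
class SessionData:
    """One subject's trial-by-trial reversal-learning history."""

    subject_id: str
    trials: list[TrialRecord]
    stage_completion: list[bool]  # per stage actually run
    group_label: Optional[str] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_stages_run(self) -> int:
        return len(self.stage_completion)

    @property
    def complete(self) -> bool:
        return all(self.stage_completion)

    def stage_trials(self, stage_index: int) -> list[TrialRecord]:
        return [t for t in self.trials if t.stage_index == stage_index]


def build_default_task(
    initial_target: int = 0, max_trials: int = 80, criterion: int = 6
) -> TaskConfig:
    """The 11-stage serial-reversal task.

    Stages 1–7 (discrimination, first reversal, SRL1×5) use 80/20 reward
    contingencies and pay 1 credit per win; SRL2 stages 8–11 use 80/40 and
    pay 2 or 6 credits with equal probability.  The target option reverses
    at every stage boundary.
    """
    stages = []
    target = initial_target
    for i, label in enumerate(DEFAULT_STAGE_LABELS):
        if label.startswith("SRL2"):
            p_non, credits = 0.40, {2: 0.5, 6: 0.5}
        else:
            p_non, credits = 0.20, {1: 1.0}
        stages.append(
            StageSpec(
                stage_label=label,
                target_option=target,
                p_reward_target=0.80,
                p_reward_nontarget=p_non,
                win_credits=credits,
                criterion_consecutive=criterion,
                max_trials=max_trials,
            )
        )
        target = 1 - target
    return TaskConfig(stages=tuple(stages))


def build_fixed_length_task(
    n_stages: int = 25,
    trials_per_stage: int = 20,
    p_reward_target: float = 0.80,
    p_reward_nontarget: float = 0.20,
    initial_target: int = 0,
) -> TaskConfig:
    """A long serial-reversal schedule with a reversal every fixed number of
    trials, for parameter-estimation sessions that need many trials.

    Criterion is set equal to ``trials_per_stage`` and truncation advances,
    so every stage contributes exactly ``trials_per_stage`` trials.
    """
    stages = []
    target = initial_target
    for i in range(n_stages):
        stages.append(
            StageSpec(
                stage_label=f"block_{i + 1}",
                target_option=target,
                p_reward_target=p_reward_target,
                p_reward_nontarget=p_reward_nontarget,
                win_credits={1: 1.0},
                criterion_consecutive=trials_per_stage,
                max_trials=trials_per_stage,
            )
        )
        target = 1 - target
    return TaskConfig(stages=tuple(stages), advance_on_truncation=True)


def draw_outcome(stage: StageSpec, choice: int, rng: np.random.Generator) -> int:
    """Draw the credit outcome for a choice: a win credit with the chosen
    option's reward probability, otherwise the stage's loss credits (0)."""
    p = stage.p_reward(choice)  # validates choice
    if rng.random() >= p:
        return stage.loss_credits
    u = rng.random()
    acc = 0.0
    for credit, prob in stage.win_credits.items():
        acc += prob
        if u < acc:
            return int(credit)
    return int(next(reversed(stage.win_credits)))  # numerical slack


Policy = Callable[[Sequence[TrialRecord]], int]


def run_session(
    config: TaskConfig,
    policy: Policy,
    rng: np.random.Generator,
    subject_id: str = "sim",
    group_label: Optional[str] = None,
) -> SessionData:
    """Run a policy through the task.

    Within each stage, trials accrue until the trailing
    ``criterion_consecutive`` choices are all correct (stage complete,
    target reverses) or ``max_trials`` is reached.  A truncated stage ends
    the session unless the config advances on truncation.

    The policy maps the full trial history so far to an option index; any
    exception it raises is re-raised with the trial context attached.
    """
    trials: list[TrialRecord] = []
    completion: list[bool] = []
    for s_idx, stage in enumerate(config.stages):
        streak = 0
        completed = False
        for t in range(1, stage.max_trials + 1):
            try:
                choice = policy(trials)
            except Exception as exc:
                raise RuntimeError(
                    f"policy failed at stage {s_idx} ({stage.stage_label}), trial {t}"
                ) from exc
            if choice not in (0, 1):
                raise ValueError(
                    f"policy returned invalid choice {choice!r} at stage {s_idx}, trial {t}"
                )
            credits = draw_outcome(stage, choice, rng)
            correct = choice == stage.target_option
            trials.append(
                TrialRecord(
                    stage_index=s_idx,
                    stage_label=stage.stage_label,
                    trial_in_stage=t,
                    choice=choice,
                    correct=correct,
                    credits=credits,
                    win=credits > 0,
                )
            )
            streak = streak + 1 if correct else 0
            if streak >= stage.criterion_consecutive:
                completed = True
                break
        completion.append(completed)
        if not completed and not config.advance_on_truncation:
            break  # session incomplete from this stage on
    return SessionData(
        subject_id=subject_id,
        trials=trials,
        stage_completion=completion,
        group_label=group_label,
    )


# ---------------------------------------------------------------------------
# Outcome-devaluation task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DevalConfig:
    """Structural constants of the devaluation procedure."""

    n_blocks: int = 10
    block_duration_s: float = 12.0
    fr_min: int = 5  # consecutive responses to earn a token
    fr_max: int = 10
    training_criterion_questions: int = 6
    max_training_questions: int = 40

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 1 <= self.fr_min <= self.fr_max:
            raise ValueError("require 1 <= fr_min <= fr_max")


@dataclass
class TrainingRecord:
    n_rounds: int
    n_questions: int
    responses_per_earn: list[int]
    completed: bool


@dataclass
class DevalSession:
    """Devaluation choice-test response counts plus ratings and probes."""

    valued_responses: list[int]  # per block
    devalued_responses: list[int]
    rating_pre: dict[str, int]  # token -> Likert 1-7
    rating_post: dict[str, int]
    probe_correct: int = 0
    devalued_token: str = "devalued"
    subject_id: str = "sim"
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.valued_responses) != len(self.devalued_responses):
            raise ValueError("valued and devalued block lists must have equal length")
        if any(c < 0 for c in self.valued_responses + self.devalued_responses):
            raise ValueError("response counts must be non-negative")
        for d in (self.rating_pre, self.rating_post):
            if any(not 1 <= r <= 7 for r in d.values()):
                raise ValueError("ratings must lie in 1..7")

    @property
    def n_blocks(self) -> int:
        return len(self.valued_responses)


def run_instrumental_training(
    accuracy: float, config: DevalConfig, rng: np.random.Generator
) -> TrainingRecord:
    """Simulate instrumental training: token-earning rounds (each a uniform
    5–10 consecutive responses by default) with a comprehension question
    after every three rounds; ends on six consecutive correct questions or
    at the question cap (incomplete)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    rounds = 0
    questions = 0
    streak = 0
    responses: list[int] = []
    while questions < config.max_training_questions:
        for _ in range(3):  # three token-earning rounds per question
            responses.append(int(rng.integers(config.fr_min, config.fr_max + 1)))
            rounds += 1
        questions += 1
        if rng.random() < accuracy:
            streak += 1
        else:
            streak = 0
        if streak >= config.training_criterion_questions:
            return TrainingRecord(rounds, questions, responses, completed=True)
    return TrainingRecord(rounds, questions, responses, completed=False)


def run_choice_test(
    valued_rate: float,
    devalued_rate: float,
    config: DevalConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> DevalSession:
    """Simulate the extinction choice test: per block, response counts for
    each action are Poisson with the given rate (responses/s) over the block
    duration.  No feedback is modelled."""
    if valued_rate < 0 or devalued_rate < 0:
        raise ValueError("response rates must be non-negative")
    dur = config.block_duration_s
    valued = [int(rng.poisson(valued_rate * dur)) for _ in range(config.n_blocks)]
    devalued = [int(rng.poisson(devalued_rate * dur)) for _ in range(config.n_blocks)]
    return DevalSession(
        valued_responses=valued,
        devalued_responses=devalued,
        rating_pre={},
        rating_post={},
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Config round-tripping
# ---------------------------------------------------------------------------


def task_config_to_dict(config: TaskConfig) -> dict:
    return {
        "advance_on_truncation": config.advance_on_truncation,
        "note": config.note,
        "stages": [
            {
                "stage_label": s.stage_label,
                "target_option": s.target_option,
                "p_reward_target": s.p_reward_target,
                "p_reward_nontarget": s.p_reward_nontarget,
                "win_credits": {str(k): v for k, v in s.win_credits.items()},
                "loss_credits": s.loss_credits,
                "criterion_consecutive": s.criterion_consecutive,
                "max_trials": s.max_trials,
            }
            for s in config.stages
        ],
    }


def task_config_from_dict(d: dict) -> TaskConfig:
    stages = tuple(
        StageSpec(
            stage_label=s["stage_label"],
            target_option=int(s["target_option"]),
            p_reward_target=float(s["p_reward_target"]),
            p_reward_nontarget=float(s["p_reward_nontarget"]),
            win_credits={int(k): float(v) for k, v in s["win_credits"].items()},
            loss_credits=int(s.get("loss_credits", 0)),
            criterion_consecutive=int(s.get("criterion_consecutive", 6)),
            max_trials=int(s.get("max_trials", 80)),
        )
        for s in d["stages"]
    )
    return TaskConfig(
        stages=stages,
        advance_on_truncation=bool(d.get("advance_on_truncation", False)),
        note=d.get("note", TaskConfig.__dataclass_fields__["note"].default),
    )


def save_task_config(config: TaskConfig, path: str | Path) -> None:
    """Write a TaskConfig to JSON or YAML (by file extension)."""
    path = Path(path)
    d = task_config_to_dict(config)
    if path.suffix.lower() in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_task_config(path: str | Path) -> TaskConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return task_config_from_dict(d)
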