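"""Model-free behavioural performance measures.

Reversal task: trials to criterion per stage (with phase aggregates over
the first reversal, SRL1 and SRL2), perseverative errors in a fixed window
after each reversal, and Win-stay / Lose-shift proportions over applicable
consecutive-trial pairs (optionally stratified by win magnitude for the
2-vs-6-credit stages).

Devaluation task: response rates toward the valued and devalued actions,
the preference ratio (response bias) valued / (valued + devalued), rating
changes and probe score.

Proportions always carry their denominators; a proportion with zero
applicable trials is ``None``, never 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .task import DevalConfig, DevalSession, SessionData, SRL1_STAGES, SRL2_STAGES

__all__ = [
    "WSLSResult",
    "BehaviorSummary",
    "DevalMetrics",
    "trials_to_criterion",
    "perseverative_errors",
    "win_stay_lose_shift",
    "devaluation_metrics",
    "summarize_session",
]


def trials_to_criterion(flags: Sequence[bool], criterion: int = 6) -> Optional[int]:
    """1-based trial count at which the trailing run of correct flags first
    reaches ``criterion``; None if it never does (incomplete stage).  The
    criterion trials themselves are counted."""
    if not flags:
        raise ValueError("flags must be non-empty")
    streak = 0
    for i, ok in enumerate(flags, start=1):
        streak = streak + 1 if ok else 0
        if streak >= criterion:
            return i
    return None


def perseverative_errors(session: SessionData, window: int = 6) -> list[int]:
    """For each stage after the first, the number of incorrect choices among
    the first ``min(window, stage length)`` trials — persistence with the
    pre-reversal target."""
    if session.n_stages_run < 2:
        raise ValueError("perseveration needs at least two stages")
    out = []
    for s in range(1, session.n_stages_run):
        head = session.stage_trials(s)[:window]
        out.append(sum(1 for t in head if not t.correct))
    return out


@dataclass
class WSLSResult:
    """Win-stay / Lose-shift proportions with their denominators."""

    win_stay: Optional[float]
    lose_shift: Optional[float]
    n_win_pairs: int
    n_loss_pairs: int
    n_win_stay: int
    n_lose_shift: int
    by_credit: dict[int, tuple[Optional[float], int, int]] = field(default_factory=dict)
    # credit -> (win_stay proportion, numerator, denominator)


def _pairs(trials, cross_stage: bool):
    for a, b in zip(trials, trials[1:]):
        if not cross_stage and a.stage_index != b.stage_index:
            continue
        yield a, b


def win_stay_lose_shift(
    session: SessionData,
    by_credit: bool = False,
    stages: Optional[Sequence[int]] = None,
    cross_stage: bool = True,
) -> WSLSResult:
    """Win-stay = P(same choice at t+1 | win at t); Lose-shift = P(switched
    choice at t+1 | loss at t), over applicable consecutive-trial pairs.

    By default pairs spanning stage boundaries count (the reversals are
    silent and the stimulus pair never changes); ``cross_stage=False``
    restricts to within-stage pairs.  ``stages`` restricts the analysis to a
    phase (e.g. the SRL1 stage indices); pairs with either trial outside the
    phase are excluded.  With ``by_credit``, win-stay is additionally
    stratified by the winning trial's credit magnitude.
    """
    if session.n_trials < 2:
        raise ValueError("need at least two trials")
    trials = session.trials
    if stages is not None:
        keep = set(stages)
        trials = [t for t in trials if t.stage_index in keep]
    n_win = n_loss = n_ws = n_ls = 0
    strata: dict[int, list[int]] = {}
    for a, b in _pairs(trials, cross_stage):
        stayed = a.choice == b.choice
        if a.win:
            n_win += 1
            n_ws += stayed
            if by_credit:
                num_den = strata.setdefault(a.credits, [0, 0])
                num_den[0] += stayed
                num_den[1] += 1
        else:
            n_loss += 1
            n_ls += not stayed
    return WSLSResult(
        win_stay=n_ws / n_win if n_win else None,
        lose_shift=n_ls / n_loss if n_loss else None,
        n_win_pairs=n_win,
        n_loss_pairs=n_loss,
        n_win_stay=n_ws,
        n_lose_shift=n_ls,
        by_credit={
            c: (num / den if den else None, num, den)
            for c, (num, den) in sorted(strata.items())
        },
    )


@dataclass
class DevalMetrics:
    valued_rate: float  # responses / s over the whole choice test
    devalued_rate: float
    preference_ratio: Optional[float]  # valued / (valued + devalued); None if no responses
    rating_change: dict[str, int]  # token -> post - pre
    probe_score: int
    n_valued: int = 0
    n_devalued: int = 0


def devaluation_metrics(deval: DevalSession, config: DevalConfig) -> DevalMetrics:
    """Rates, response bias and rating changes for one devaluation session."""
    if deval.n_blocks != config.n_blocks:
        raise ValueError(
            f"session has {deval.n_blocks} blocks, config expects {config.n_blocks}"
        )
    total_s = config.n_blocks * config.block_duration_s
    nv = sum(deval.valued_responses)
    nd = sum(deval.devalued_responses)
    change = {
        tok: deval.rating_post[tok] - deval.rating_pre[tok]
        for tok in deval.rating_pre
        if tok in deval.rating_post
    }
    return DevalMetrics(
        valued_rate=nv / total_s,
        devalued_rate=nd / total_s,
        preference_ratio=nv / (nv + nd) if nv + nd > 0 else None,
        rating_change=change,
        probe_score=deval.probe_correct,
        n_valued=nv,
        n_devalued=nd,
    )


@dataclass
class BehaviorSummary:
    """Per-subject reversal-task summary.

    Phase means average per-stage trials-to-criterion within the phase;
    incomplete stages are excluded from those means (and flagged) but their
    observed trials still enter the WSLS proportions.
    """

    subject_id: str
    trials_to_criterion: list[Optional[int]]  # per stage run
    discrimination_trials: Optional[int]
    first_reversal_trials: Optional[int]
    srl1_mean_trials: Optional[float]
    srl2_mean_trials: Optional[float]
    total_trials: int
    perseverative_errors: list[int]
    perseveration_mean: Optional[float]
    win_stay: Optional[float]
    lose_shift: Optional[float]
    srl1_win_stay: Optional[float]
    srl1_lose_shift: Optional[float]
    srl2_win_stay: Optional[float]
    srl2_lose_shift: Optional[float]
    win_stay_by_credit: dict[int, tuple[Optional[float], int, int]]
    denominators: dict[str, int]
    incomplete_stages: list[int]
    group_label: Optional[str] = None


def _phase_mean(ttc: list[Optional[int]], stages: Sequence[int]) -> Optional[float]:
    vals = [ttc[s] for s in stages if s < len(ttc) and ttc[s] is not None]
    return sum(vals) / len(vals) if vals else None


def summarize_session(
    session: SessionData,
    criterion: int = 6,
    window: int = 6,
    srl1_stages: Sequence[int] = SRL1_STAGES,
    srl2_stages: Sequence[int] = SRL2_STAGES,
) -> BehaviorSummary:
    """All model-free reversal measures for one session of the 11-stage task."""
    ttc: list[Optional[int]] = []
    for s in range(session.n_stages_run):
        flags = [t.correct for t in session.stage_trials(s)]
        ttc.append(trials_to_criterion(flags, criterion) if flags else None)
    persev = perseverative_errors(session, window) if session.n_stages_run >= 2 else []
    overall = win_stay_lose_shift(session)
    in_srl1 = [s for s in srl1_stages if s < session.n_stages_run]
    in_srl2 = [s for s in srl2_stages if s < session.n_stages_run]
    srl1 = win_stay_lose_shift(session, stages=srl1_stages) if in_srl1 else None
    srl2 = (
        win_stay_lose_shift(session, stages=srl2_stages, by_credit=True)
        if in_srl2
        else None
    )
    return BehaviorSummary(
        subject_id=session.subject_id,
        group_label=session.group_label,
        trials_to_criterion=ttc,
        discrimination_trials=ttc[0] if ttc else None,
        first_reversal_trials=ttc[1] if len(ttc) > 1 else None,
        srl1_mean_trials=_phase_mean(ttc, srl1_stages),
        srl2_mean_trials=_phase_mean(ttc, srl2_stages),
        total_trials=session.n_trials,
        perseverative_errors=persev,
        perseveration_mean=sum(persev) / len(persev) if persev else None,
        win_stay=overall.win_stay,
        lose_shift=overall.lose_shift,
        srl1_win_stay=srl1.win_stay if srl1 else None,
        srl1_lose_shift=srl1.lose_shift if srl1 else None,
        srl2_win_stay=srl2.win_stay if srl2 else None,
        srl2_lose_shift=srl2.lose_shift if srl2 else None,
        win_stay_by_credit=srl2.by_credit if srl2 else {},
        denominators={
            "win_pairs": overall.n_win_pairs,
            "loss_pairs": overall.n_loss_pairs,
            "srl1_win_pairs": srl1.n_win_pairs if srl1 else 0,
            "srl1_loss_pairs": srl1.n_loss_pairs if srl1 else 0,
            "srl2_win_pairs": srl2.n_win_pairs if srl2 else 0,
            "srl2_loss_pairs": srl2.n_loss_pairs if srl2 else 0,
        },
        incomplete_stages=[
            s for s, done in enumerate(session.stage_completion) if not done
        ],
    )
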