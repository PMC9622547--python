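"""CSV / JSON interchange for all pipeline artifacts.

Schemas (all CSV, UTF-8, header required, 0-based option indices, 1-based
trial numbering):

* trial table — ``subject_id, group, stage_index, stage_label,
  trial_in_stage, choice, correct, credits, win`` (one row per trial)
* devaluation table — ``subject_id, block, valued_responses,
  devalued_responses`` plus optional ``devalued_token, probe_correct``
  columns (constant per subject)
* ratings sidecar — ``subject_id, token, phase, rating`` with phase in
  {pre, post}
* fit results — one row per subject with raw and reporting-convention
  parameters
* cluster labels — subject, features, label and the boundary interval

Rows are re-ordered canonically (subject, stage, trial) on read, and
duplicate (subject, stage, trial) keys are rejected with row numbers.
Per-stage completion flags are reconstructed from the trailing run of
correct choices against the criterion (default 6) — exact for any session
the task environment itself produced.

Result-writing helpers embed the seed and a config hash in a manifest so
runs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .fitting import FitResult
from .metrics import BehaviorSummary, DevalMetrics
from .models import EWAParams, RPParams
from .task import DevalSession, SessionData, TrialRecord, task_config_to_dict

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_deval_tables",
    "read_deval_tables",
    "write_params",
    "read_params",
    "write_fit_results",
    "write_cluster_labels",
    "write_behavior_summaries",
    "config_hash",
    "write_manifest",
]

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "stage_index",
    "stage_label",
    "trial_in_stage",
    "choice",
    "correct",
    "credits",
    "win",
]


def write_trial_table(sessions: Sequence[SessionData], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group_label or "",
                    "stage_index": t.stage_index,
                    "stage_label": t.stage_label,
                    "trial_in_stage": t.trial_in_stage,
                    "choice": t.choice,
                    "correct": int(t.correct),
                    "credits": t.credits,
                    "win": int(t.win),
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} missing required column(s): {missing}")


def read_trial_table(path: str | Path, criterion: int = 6) -> list[SessionData]:
    """Read sessions from a trial table; rows are sorted canonically and
    completion flags reconstructed against ``criterion``."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS[:1] + TRIAL_COLUMNS[2:], "trial table")
    if df.empty:
        return []
    dup = df.duplicated(subset=["subject_id", "stage_index", "trial_in_stage"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header line + 1-based
        raise ValueError(f"duplicate (subject, stage, trial) keys at csv line(s) {rows}")
    df = df.sort_values(
        ["subject_id", "stage_index", "trial_in_stage"], kind="mergesort"
    )
    sessions = []
    for sid, sub in df.groupby("subject_id", sort=False):
        group = None
        if "group" in sub.columns:
            g = sub["group"].iloc[0]
            group = None if pd.isna(g) or g == "" else str(g)
        trials = [
            TrialRecord(
                stage_index=int(r.stage_index),
                stage_label=str(r.stage_label),
                trial_in_stage=int(r.trial_in_stage),
                choice=int(r.choice),
                correct=bool(r.correct),
                credits=int(r.credits),
                win=bool(r.win),
            )
            for r in sub.itertuples()
        ]
        completion = []
        for stage_idx in sorted({t.stage_index for t in trials}):
            flags = [t.correct for t in trials if t.stage_index == stage_idx]
            streak = 0
            done = False
            for ok in flags:
                streak = streak + 1 if ok else 0
                if streak >= criterion:
                    done = True
                    break
            completion.append(done)
        sessions.append(
            SessionData(
                subject_id=str(sid),
                trials=trials,
                stage_completion=completion,
                group_label=group,
            )
        )
    return sessions


def write_deval_tables(
    sessions: Sequence[DevalSession], counts_path: str | Path, ratings_path: str | Path
) -> None:
    counts, ratings = [], []
    for s in sessions:
        for b, (v, d) in enumerate(zip(s.valued_responses, s.devalued_responses), 1):
            counts.append(
                {
                    "subject_id": s.subject_id,
                    "block": b,
                    "valued_responses": v,
                    "devalued_responses": d,
                    "devalued_token": s.devalued_token,
                    "probe_correct": s.probe_correct,
                }
            )
        for phase, rates in (("pre", s.rating_pre), ("post", s.rating_post)):
            for tok, r in rates.items():
                ratings.append(
                    {"subject_id": s.subject_id, "token": tok, "phase": phase, "rating": r}
                )
    pd.DataFrame(
        counts,
        columns=[
            "subject_id",
            "block",
            "valued_responses",
            "devalued_responses",
            "devalued_token",
            "probe_correct",
        ],
    ).to_csv(counts_path, index=False)
    pd.DataFrame(
        ratings, columns=["subject_id", "token", "phase", "rating"]
    ).to_csv(ratings_path, index=False)


def read_deval_tables(
    counts_path: str | Path, ratings_path: Optional[str | Path] = None
) -> list[DevalSession]:
    df = pd.read_csv(counts_path)
    _require_columns(
        df, ["subject_id", "block", "valued_responses", "devalued_responses"], "deval table"
    )
    ratings = None
    if ratings_path is not None and Path(ratings_path).exists():
        ratings = pd.read_csv(ratings_path)
        _require_columns(ratings, ["subject_id", "token", "phase", "rating"], "ratings table")
    sessions = []
    for sid, sub in df.sort_values(["subject_id", "block"]).groupby("subject_id", sort=False):
        pre: dict[str, int] = {}
        post: dict[str, int] = {}
        if ratings is not None:
            rsub = ratings[ratings["subject_id"] == sid]
            for r in rsub.itertuples():
                (pre if r.phase == "pre" else post)[str(r.token)] = int(r.rating)
        sessions.append(
            DevalSession(
                valued_responses=[int(x) for x in sub["valued_responses"]],
                devalued_responses=[int(x) for x in sub["devalued_responses"]],
                rating_pre=pre,
                rating_post=post,
                probe_correct=int(sub["probe_correct"].iloc[0])
                if "probe_correct" in sub.columns
                else 0,
                devalued_token=str(sub["devalued_token"].iloc[0])
                if "devalued_token" in sub.columns
                else "devalued",
                subject_id=str(sid),
            )
        )
    return sessions


def write_params(
    params: EWAParams | RPParams,
    path: str | Path,
    model: Optional[str] = None,
    payoff_coding: str = "sign",
) -> None:
    """Flat key-value parameter file (JSON)."""
    if model is None:
        model = "ewa" if isinstance(params, EWAParams) else "rp"
    d = {"model": model, "payoff_coding": payoff_coding, **params.as_dict()}
    Path(path).write_text(json.dumps(d, indent=2))


def read_params(path: str | Path) -> tuple[str, EWAParams | RPParams, str]:
    d = json.loads(Path(path).read_text())
    model = d.get("model", "ewa")
    coding = d.get("payoff_coding", "sign")
    if model == "ewa":
        return model, EWAParams(phi=d["phi"], rho=d["rho"], beta=d["beta"]), coding
    if model == "rp":
        return model, RPParams(a_rew=d["a_rew"], a_pun=d["a_pun"], beta=d["beta"]), coding
    raise ValueError(f"unknown model {model!r} in {path}")


def write_fit_results(fits: Sequence[FitResult], path: str | Path) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {"subject_id": f.subject_id, "model": f.model}
        row.update(f.estimates())
        for k, v in f.params.reported().items():
            row[f"reported_{k}"] = v
        row["neg_log_posterior"] = f.neg_log_posterior
        row["n_trials"] = f.n_trials
        row["converged"] = f.converged
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_cluster_labels(result, path: str | Path) -> pd.DataFrame:
    df = result.labels.copy()
    df["boundary_low"] = result.boundary_low
    df["boundary_high"] = result.boundary_high
    df.to_csv(path, index=False)
    return df


def write_behavior_summaries(
    summaries: Sequence[BehaviorSummary],
    path: str | Path,
    deval: Optional[Sequence[DevalMetrics]] = None,
) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(summaries):
        row = {
            "subject_id": s.subject_id,
            "group": s.group_label or "",
            "discrimination_trials": s.discrimination_trials,
            "first_reversal_trials": s.first_reversal_trials,
            "srl1_mean_trials": s.srl1_mean_trials,
            "srl2_mean_trials": s.srl2_mean_trials,
            "total_trials": s.total_trials,
            "perseveration_mean": s.perseveration_mean,
            "win_stay": s.win_stay,
            "lose_shift": s.lose_shift,
            "srl1_win_stay": s.srl1_win_stay,
            "srl1_lose_shift": s.srl1_lose_shift,
            "srl2_win_stay": s.srl2_win_stay,
            "srl2_lose_shift": s.srl2_lose_shift,
            "n_incomplete_stages": len(s.incomplete_stages),
        }
        for credit, (p, num, den) in s.win_stay_by_credit.items():
            row[f"win_stay_credit{credit}"] = p
            row[f"win_stay_credit{credit}_n"] = den
        for k, v in s.denominators.items():
            row[f"n_{k}"] = v
        if deval is not None:
            d = deval[i]
            row.update(
                {
                    "valued_rate": d.valued_rate,
                    "devalued_rate": d.devalued_rate,
                    "preference_ratio": d.preference_ratio,
                    "probe_score": d.probe_score,
                }
            )
            for tok, ch in d.rating_change.items():
                row[f"rating_change_{tok}"] = ch
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable config (dataclasses with
    a to-dict path should be converted first; TaskConfig accepted directly)."""
    try:
        d = task_config_to_dict(obj)  # type: ignore[arg-type]
    except (AttributeError, TypeError):
        d = obj
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, seed: Optional[int], config, extra: Optional[dict] = None) -> None:
    d = {"seed": seed, "config_hash": config_hash(config)}
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, default=str))
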