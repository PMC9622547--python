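"""Synthetic cohorts: reversal sessions from EWA agents with
group-structured parameters, plus devaluation sessions with a bimodal
response-bias structure.

Every pipeline stage (fitting, metrics, subgrouping, simulation study) is
testable on these cohorts without any external data.  The default cohort
mirrors the study population structure: 34 controls (28 intact / 6
impaired goal-directed action) and 43 persistent-psychosis subjects (18
intact / 25 impaired).  Response bias in the devaluation choice test is
drawn from a two-component Beta mixture — intact component centred near
0.95, impaired near 0.5 — so the pooled bias histogram is bimodal and the
two modes straddle the empirical clustering boundary region (~0.72–0.81).

Default EWA parameters per group reproduce the qualitative orderings of
the fitted groups (psychosis: lower phi; impaired additionally: higher
rho, lower beta); they are configuration, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import EWAParams, simulate_agent
from .task import (
    DevalConfig,
    DevalSession,
    SessionData,
    TaskConfig,
    build_default_task,
    run_choice_test,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "default_cohort_spec",
    "sample_subject_params",
    "generate_cohort",
    "small_cohort_fixture",
]

# Frozen default group parameter sets (see docs/methods.md for the
# calibration rationale).  Orderings: psychosis groups have lower phi than
# controls; the impaired component has clearly higher rho and lower beta.
DEFAULT_EWA = {
    ("control", "intact"): EWAParams(phi=0.70, rho=0.30, beta=3.5),
    ("control", "impaired"): EWAParams(phi=0.55, rho=0.65, beta=1.5),
    ("psychosis", "intact"): EWAParams(phi=0.55, rho=0.35, beta=3.0),
    ("psychosis", "impaired"): EWAParams(phi=0.55, rho=0.65, beta=1.5),
}


@dataclass(frozen=True)
class GroupSpec:
    """One clinical-group x goal-directed-component cell of a cohort."""

    label: str  # clinical group, e.g. "control"
    component: str  # "intact" or "impaired" goal-directed action
    n_subjects: int
    ewa_mean: EWAParams
    ewa_sd: tuple[float, float, float] = (0.05, 0.05, 0.4)  # phi, rho, beta
    bias_mean: float = 0.95  # devaluation response-bias mixture component
    bias_concentration: float = 60.0
    total_rate_mean: float = 1.0  # responses/s in the choice test
    total_rate_sd: float = 0.2  # lognormal sd on the log scale is sd/mean approx
    devalued_rating_drop: float = 3.0  # mean post-pre drop for the devalued token
    probe_accuracy: float = 0.95
    n_probe_questions: int = 3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 < self.bias_mean < 1.0:
            raise ValueError("bias_mean must lie in (0, 1)")
        if self.bias_concentration <= 0 or self.total_rate_mean <= 0:
            raise ValueError("concentration and rate must be positive")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    task: TaskConfig
    deval: DevalConfig
    master_seed: int = 0

    def __post_init__(self) -> None:
        keys = [(g.label, g.component) for g in self.groups]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (group, component) cells in cohort spec")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


@dataclass
class Cohort:
    """Generated sessions plus ground truth for every subject."""

    spec: CohortSpec
    sessions: list[SessionData]
    deval_sessions: list[DevalSession]
    truth: pd.DataFrame  # subject_id, group, component, phi, rho, beta, bias, ...

    @property
    def n_subjects(self) -> int:
        return len(self.sessions)


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """The study-structured default cohort: 28/6 controls and 18/25
    psychosis subjects split into intact/impaired components."""
    cells = [
        ("control", "intact", 28, 0.95),
        ("control", "impaired", 6, 0.50),
        ("psychosis", "intact", 18, 0.93),
        ("psychosis", "impaired", 25, 0.50),
    ]
    groups = tuple(
        GroupSpec(
            label=lab,
            component=comp,
            n_subjects=n,
            ewa_mean=DEFAULT_EWA[(lab, comp)],
            bias_mean=bias,
            bias_concentration=60.0 if comp == "intact" else 40.0,
            devalued_rating_drop=3.0 if comp == "intact" else 1.0,
        )
        for lab, comp, n, bias in cells
    )
    return CohortSpec(
        groups=groups,
        task=build_default_task(),
        deval=DevalConfig(),
        master_seed=master_seed,
    )


def _trunc_unit(mean: float, sd: float, rng: np.random.Generator) -> float:
    # normal draw truncated to (eps, 1-eps) by resampling
    if sd == 0:
        return mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if 1e-4 < x < 1 - 1e-4:
            return float(x)
    return float(min(max(mean, 1e-4), 1 - 1e-4))


def sample_subject_params(group: GroupSpec, rng: np.random.Generator) -> EWAParams:
    """Draw one subject's EWA parameters from the group's truncated
    distributions (normal for phi/rho, truncated at the unit interval;
    normal truncated at zero for beta)."""
    m = group.ewa_mean
    s_phi, s_rho, s_beta = group.ewa_sd
    phi = _trunc_unit(m.phi, s_phi, rng)
    rho = _trunc_unit(m.rho, s_rho, rng)
    if s_beta == 0:
        beta = m.beta
    else:
        beta = -1.0
        for _ in range(100):
            beta = rng.normal(m.beta, s_beta)
            if beta > 0.05:
                break
        beta = max(beta, 0.05)
    return EWAParams(phi=phi, rho=rho, beta=float(beta))


def _simulate_deval(
    group: GroupSpec, subject_id: str, deval_cfg: DevalConfig, rng: np.random.Generator
) -> tuple[DevalSession, float]:
    a = group.bias_mean * group.bias_concentration
    b = (1.0 - group.bias_mean) * group.bias_concentration
    bias = float(rng.beta(a, b))
    total = float(rng.lognormal(np.log(group.total_rate_mean), group.total_rate_sd))
    sess = run_choice_test(
        bias * total, (1.0 - bias) * total, deval_cfg, rng, subject_id=subject_id
    )
    tokens = ("valued", "devalued")
    pre = {tok: int(rng.integers(4, 7)) for tok in tokens}
    drop = max(0, round(rng.normal(group.devalued_rating_drop, 0.7)))
    post = {
        "valued": int(np.clip(pre["valued"] + rng.integers(-1, 2), 1, 7)),
        "devalued": int(np.clip(pre["devalued"] - drop, 1, 7)),
    }
    sess.rating_pre = pre
    sess.rating_post = post
    sess.probe_correct = int(rng.binomial(group.n_probe_questions, group.probe_accuracy))
    sess.devalued_token = "devalued"
    sess.group_label = group.label
    return sess, bias


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> Cohort:
    """Generate a full cohort: per subject, EWA parameters sampled from the
    group cell, a reversal session simulated with those parameters, and a
    devaluation session with bias drawn from the cell's mixture component.
    Ground-truth labels and parameters are retained."""
    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    sessions: list[SessionData] = []
    devals: list[DevalSession] = []
    rows = []
    idx = 0
    for g in spec.groups:
        for _ in range(g.n_subjects):
            sid = f"S{idx:03d}"
            params = sample_subject_params(g, rng)
            sess = simulate_agent(
                "ewa", params, spec.task, rng, subject_id=sid, group_label=g.label
            )
            deval, bias = _simulate_deval(g, sid, spec.deval, rng)
            sessions.append(sess)
            devals.append(deval)
            rows.append(
                {
                    "subject_id": sid,
                    "group": g.label,
                    "component": g.component,
                    "phi": params.phi,
                    "rho": params.rho,
                    "beta": params.beta,
                    "bias": bias,
                    "n_trials": sess.n_trials,
                    "complete": sess.complete,
                }
            )
            idx += 1
    return Cohort(
        spec=spec, sessions=sessions, deval_sessions=devals, truth=pd.DataFrame(rows)
    )


def small_cohort_fixture(seed: int = 7) -> Cohort:
    """A small (26-subject) cohort with the full group/component structure,
    cheap enough to regenerate inside unit tests."""
    cells = [
        ("control", "intact", 10, 0.95),
        ("control", "impaired", 2, 0.50),
        ("psychosis", "intact", 6, 0.93),
        ("psychosis", "impaired", 8, 0.50),
    ]
    groups = tuple(
        GroupSpec(
            label=lab,
            component=comp,
            n_subjects=n,
            ewa_mean=DEFAULT_EWA[(lab, comp)],
            bias_mean=bias,
            bias_concentration=60.0 if comp == "intact" else 40.0,
            devalued_rating_drop=3.0 if comp == "intact" else 1.0,
        )
        for lab, comp, n, bias in cells
    )
    spec = CohortSpec(
        groups=groups,
        task=build_default_task(),
        deval=DevalConfig(),
        master_seed=seed,
    )
    return generate_cohort(spec)


def cohort_manifest(spec: CohortSpec) -> dict:
    """JSON-serialisable record of a cohort spec (for reproducibility)."""
    return {
        "master_seed": spec.master_seed,
        "n_subjects": spec.n_subjects,
        "groups": [
            {
                "label": g.label,
                "component": g.component,
                "n_subjects": g.n_subjects,
                "ewa_mean": g.ewa_mean.as_dict(),
                "ewa_sd": list(g.ewa_sd),
                "bias_mean": g.bias_mean,
                "bias_concentration": g.bias_concentration,
                "total_rate_mean": g.total_rate_mean,
                "total_rate_sd": g.total_rate_sd,
                "devalued_rating_drop": g.devalued_rating_drop,
                "probe_accuracy": g.probe_accuracy,
            }
            for g in spec.groups
        ],
    }
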