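"""Reinforcement-learning models of reversal-task choice.

Two model families are implemented as state-update rules, softmax choice
maps, likelihood functions and generative agents:

* **EWA (experience-weighted attraction)** — per-option attractions
  ``A_j`` updated as experience-weighted running averages.  For the chosen
  option ``c`` with payoff ``r``::

      n_c <- rho * n_c + 1
      A_c <- (phi * n_c_old * A_c + r) / n_c_new

  ``phi`` in [0, 1] is the decay of the prior attraction (reported in
  figures as learning rate), ``rho`` in [0, 1] the experience decay (how
  quickly the accumulated experience weight, and hence the inertia of the
  attraction, builds up), and ``beta >= 0`` the softmax inverse
  temperature.  Only the chosen option's attraction and weight update.

* **RP (reward/punishment)** — delta-rule values with separate learning
  rates for positive and negative prediction errors, plus a fictive update
  of the unchosen option toward the negated payoff with the
  opposite-valence rate (the standard dual-rate probabilistic-reversal
  convention).  A ``fictive=False`` switch restricts updating to the
  chosen option.

Payoff coding maps credit outcomes onto model payoffs.  The default
``"sign"`` coding scores any win as +1 and any loss as -1 regardless of
credit magnitude; the ``"magnitude"`` coding scores a win as
``credits / mean_win_credit`` of its stage (requires the task config) and
a loss as -1, for sensitivity analyses of the 2-vs-6-credit stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .task import SessionData, TaskConfig, TrialRecord, run_session

__all__ = [
    "EWAParams",
    "RPParams",
    "ModelState",
    "ewa_update",
    "rp_update",
    "choice_probabilities",
    "trial_payoffs",
    "log_likelihood",
    "simulate_agent",
    "ModelAgentPolicy",
]

ModelName = Literal["ewa", "rp"]
PayoffCoding = Literal["sign", "magnitude"]


def _check_unit(name: str, x: float) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return float(x)


@dataclass(frozen=True)
class EWAParams:
    """phi: prior-attraction decay; rho: experience decay; beta: inverse
    temperature.  Figure-style reporting uses 1 - phi ('learning rate');
    the update rule always uses raw phi."""

    phi: float
    rho: float
    beta: float

    def __post_init__(self) -> None:
        _check_unit("phi", self.phi)
        _check_unit("rho", self.rho)
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    def reported(self) -> dict[str, float]:
        """Reporting convention: learning rate = 1 - phi; rho, beta raw."""
        return {"learning_rate": 1.0 - self.phi, "rho": self.rho, "beta": self.beta}

    def as_dict(self) -> dict[str, float]:
        return {"phi": self.phi, "rho": self.rho, "beta": self.beta}


@dataclass(frozen=True)
class RPParams:
    """a_rew / a_pun: learning rates for positive / negative prediction
    errors; beta: inverse temperature."""

    a_rew: float
    a_pun: float
    beta: float

    def __post_init__(self) -> None:
        _check_unit("a_rew", self.a_rew)
        _check_unit("a_pun", self.a_pun)
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    def reported(self) -> dict[str, float]:
        """Inverted learning rates (1 - a) to match the EWA reporting."""
        return {
            "reward_learning": 1.0 - self.a_rew,
            "punishment_learning": 1.0 - self.a_pun,
            "beta": self.beta,
        }

    def as_dict(self) -> dict[str, float]:
        return {"a_rew": self.a_rew, "a_pun": self.a_pun, "beta": self.beta}


@dataclass(frozen=True)
class ModelState:
    """Per-option attractions/values; experience weights are EWA-only and
    stay (0, 0) for RP."""

    values: tuple[float, float] = (0.0, 0.0)
    experience_weights: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.experience_weights):
            raise ValueError("experience weights must be non-negative")


def ewa_update(
    state: ModelState, choice: int, payoff: float, params: EWAParams
) -> ModelState:
    """One EWA step: only the chosen option's attraction and weight move."""
    if choice not in (0, 1):
        raise ValueError(f"choice must be 0 or 1, got {choice}")
    a = list(state.values)
    n = list(state.experience_weights)
    n_old = n[choice]
    n_new = params.rho * n_old + 1.0
    a[choice] = (params.phi * n_old * a[choice] + payoff) / n_new
    n[choice] = n_new
    return ModelState(values=(a[0], a[1]), experience_weights=(n[0], n[1]))


def rp_update(
    state: ModelState,
    choice: int,
    payoff: float,
    params: RPParams,
    fictive: bool = True,
) -> ModelState:
    """One RP step.  The chosen option moves toward the payoff with the
    valence-matched rate; with ``fictive``, the unchosen option moves toward
    the negated payoff with the opposite-valence rate."""
    if choice not in (0, 1):
        raise ValueError(f"choice must be 0 or 1, got {choice}")
    v = list(state.values)
    other = 1 - choice
    rate_c = params.a_rew if payoff >= 0 else params.a_pun
    v[choice] += rate_c * (payoff - v[choice])
    if fictive:
        rate_u = params.a_pun if payoff >= 0 else params.a_rew
        v[other] += rate_u * (-payoff - v[other])
    return ModelState(values=(v[0], v[1]), experience_weights=state.experience_weights)


def choice_probabilities(values: Sequence[float], beta: float) -> tuple[float, float]:
    """Softmax P(j) = exp(beta v_j) / sum_k exp(beta v_k), computed stably."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x0, x1 = beta * values[0], beta * values[1]
    m = x0 if x0 > x1 else x1
    e0, e1 = math.exp(x0 - m), math.exp(x1 - m)
    z = e0 + e1
    return (e0 / z, e1 / z)


def trial_payoffs(
    session: SessionData,
    coding: PayoffCoding = "sign",
    config: Optional[TaskConfig] = None,
) -> list[float]:
    """Map each trial's credit outcome to a model payoff under a coding."""
    if coding == "sign":
        return [1.0 if t.win else -1.0 for t in session.trials]
    if coding == "magnitude":
        if config is None:
            raise ValueError("magnitude coding requires the task config")
        means = [s.mean_win_credit for s in config.stages]
        return [
            (t.credits / means[t.stage_index]) if t.win else -1.0
            for t in session.trials
        ]
    raise ValueError(f"unknown payoff coding {coding!r}")


def _ewa_loglik(
    choices: Sequence[int], payoffs: Sequence[float], phi: float, rho: float, beta: float
) -> float:
    # Tight scalar loop: called thousands of times inside the optimizer.
    a0 = a1 = 0.0
    n0 = n1 = 0.0
    ll = 0.0
    log1p = math.log1p
    exp = math.exp
    for c, r in zip(choices, payoffs):
        d = beta * (a1 - a0)  # log-odds of option 1 over option 0
        if c == 0:
            ll -= log1p(exp(d)) if d < 35.0 else d
            nn = rho * n0 + 1.0
            a0 = (phi * n0 * a0 + r) / nn
            n0 = nn
        else:
            ll -= log1p(exp(-d)) if d > -35.0 else -d
            nn = rho * n1 + 1.0
            a1 = (phi * n1 * a1 + r) / nn
            n1 = nn
    return ll


def _rp_loglik(
    choices: Sequence[int],
    payoffs: Sequence[float],
    a_rew: float,
    a_pun: float,
    beta: float,
    fictive: bool = True,
) -> float:
    v0 = v1 = 0.0
    ll = 0.0
    log1p = math.log1p
    exp = math.exp
    for c, r in zip(choices, payoffs):
        d = beta * (v1 - v0)
        if c == 0:
            ll -= log1p(exp(d)) if d < 35.0 else d
        else:
            ll -= log1p(exp(-d)) if d > -35.0 else -d
        rate_c = a_rew if r >= 0 else a_pun
        if c == 0:
            v0 += rate_c * (r - v0)
            if fictive:
                rate_u = a_pun if r >= 0 else a_rew
                v1 += rate_u * (-r - v1)
        else:
            v1 += rate_c * (r - v1)
            if fictive:
                rate_u = a_pun if r >= 0 else a_rew
                v0 += rate_u * (-r - v0)
    return ll


def log_likelihood(
    model: ModelName,
    params: EWAParams | RPParams,
    session: SessionData,
    coding: PayoffCoding = "sign",
    config: Optional[TaskConfig] = None,
    fictive: bool = True,
) -> float:
    """Total log-likelihood of a session's choice sequence under a model.

    The model state starts at zero, evolves with the model's update rule,
    and each trial contributes ``log P(observed choice | state)``.
    """
    if not session.trials:
        raise ValueError("session has no trials")
    choices = [t.choice for t in session.trials]
    payoffs = trial_payoffs(session, coding=coding, config=config)
    if model == "ewa":
        if not isinstance(params, EWAParams):
            raise TypeError("EWA model requires EWAParams")
        ll = _ewa_loglik(choices, payoffs, params.phi, params.rho, params.beta)
    elif model == "rp":
        if not isinstance(params, RPParams):
            raise TypeError("RP model requires RPParams")
        ll = _rp_loglik(
            choices, payoffs, params.a_rew, params.a_pun, params.beta, fictive=fictive
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    if not math.isfinite(ll):
        raise FloatingPointError(
            f"non-finite log-likelihood for model {model} on session "
            f"{session.subject_id} ({len(choices)} trials)"
        )
    return ll


class ModelAgentPolicy:
    """A generative policy: samples choices from the evolving model state.

    Usable directly as the ``policy`` argument of :func:`run_session`; it
    watches the growing trial history and applies the model update for each
    newly observed outcome before choosing.
    """

    def __init__(
        self,
        model: ModelName,
        params: EWAParams | RPParams,
        rng: np.random.Generator,
        coding: PayoffCoding = "sign",
        config: Optional[TaskConfig] = None,
        fictive: bool = True,
    ) -> None:
        if model == "ewa" and not isinstance(params, EWAParams):
            raise TypeError("EWA model requires EWAParams")
        if model == "rp" and not isinstance(params, RPParams):
            raise TypeError("RP model requires RPParams")
        self.model = model
        self.params = params
        self.rng = rng
        self.coding = coding
        self.config = config
        self.fictive = fictive
        self.state = ModelState()
        self._n_seen = 0

    def _payoff(self, trial: TrialRecord) -> float:
        if self.coding == "sign":
            return 1.0 if trial.win else -1.0
        mean = self.config.stages[trial.stage_index].mean_win_credit  # type: ignore[union-attr]
        return trial.credits / mean if trial.win else -1.0

    def __call__(self, history: Sequence[TrialRecord]) -> int:
        for trial in history[self._n_seen :]:
            r = self._payoff(trial)
            if self.model == "ewa":
                self.state = ewa_update(self.state, trial.choice, r, self.params)  # type: ignore[arg-type]
            else:
                self.state = rp_update(
                    self.state, trial.choice, r, self.params, fictive=self.fictive  # type: ignore[arg-type]
                )
            self._n_seen += 1
        p0, _ = choice_probabilities(self.state.values, self.params.beta)
        return 0 if self.rng.random() < p0 else 1


def simulate_agent(
    model: ModelName,
    params: EWAParams | RPParams,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "agent",
    group_label: Optional[str] = None,
    coding: PayoffCoding = "sign",
    fictive: bool = True,
) -> SessionData:
    """Simulate a model agent through the task and return its session."""
    policy = ModelAgentPolicy(
        model, params, rng, coding=coding, config=config, fictive=fictive
    )
    return run_session(config, policy, rng, subject_id=subject_id, group_label=group_label)
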