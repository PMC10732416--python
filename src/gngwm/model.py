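"""Generative model of go/no-go choice under Pavlovian bias.

Latent state per cue s (four cue types):

* instrumental action values ``Q(a, s)``, one per action, updated by the
  Rescorla-Wagner delta rule for the taken action only::

      Q_t(a_t, s_t) = Q_{t-1}(a_t, s_t) + eps * (rho * r_t - Q_{t-1}(a_t, s_t))

* a Pavlovian stimulus value ``V(s)`` updated with the same rule on every
  presentation of the cue, regardless of the action taken.

Outcomes r_t take values -1, 0, +1 and are scaled by a valence-specific
sensitivity (rho_rew for rewards, rho_pun for punishments), which plays the
role of an inverse temperature.  Action weights combine the instrumental
value with a go bias b and the Pavlovian value weighted by pi::

    W(go)   = Q(go, s) + b + pi * V(s)
    W(nogo) = Q(nogo, s)

and the go probability is a squashed softmax with irreducible noise xi::

    P(go) = logistic(W(go) - W(nogo)) * (1 - xi) + xi / 2

so that choice probabilities are bounded in [xi/2, 1 - xi/2]: at xi = 1
choice is fully random, at xi = 0 it is the plain softmax.

Q and V start at zero for every cue at the start of each task run (the two
tasks use disjoint fractal sets, so no latent state carries over).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .family import ModelSpec, effective_theta
from .task import CUE_TYPES, GO, _deliver


@dataclass(frozen=True)
class SubjectParams:
    """One subject's parameter vector on the constrained scale.

    The WM-load variants are present (non-None) only when the governing
    model splits that parameter between conditions.
    """

    eps: float
    rho_rew: float
    rho_pun: float
    b: float
    pi: float
    xi: float
    eps_wm: Optional[float] = None
    pi_wm: Optional[float] = None
    xi_wm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("eps", "xi", "eps_wm", "xi_wm"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rho_rew", "rho_pun"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None
        }


def update_value(prev: float, outcome: int, eps: float, rho: float) -> float:
    """One Rescorla-Wagner step: prev + eps * (rho * outcome - prev)."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps must lie in [0, 1], got {eps}")
    return prev + eps * (rho * outcome - prev)


def action_weights(
    q_go: float, q_nogo: float, v: float, b: float, pi: float
) -> tuple[float, float]:
    """Go and no-go action weights: (q_go + b + pi * v, q_nogo)."""
    return q_go + b + pi * v, q_nogo


def choice_prob_go(w_go: float, w_nogo: float, xi: float) -> float:
    """Squashed-softmax go probability, bounded in [xi/2, 1 - xi/2]."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    d = w_go - w_nogo
    if d >= 0:
        sm = 1.0 / (1.0 + np.exp(-d))
    else:
        e = np.exp(d)
        sm = e / (1.0 + e)
    return sm * (1.0 - xi) + xi / 2.0


def _select_rho(outcome: int, rho_rew: float, rho_pun: float) -> float:
    # rho scales the outcome, so the choice is immaterial at r = 0; by
    # design win cues only ever see {0, +1} and avoid cues {0, -1}.
    return rho_rew if outcome > 0 else rho_pun


def _check_ordered(trials: pd.DataFrame) -> None:
    if len(trials) == 0:
        raise ValueError("empty trial table")
    cols = ["task"]
    if "subject_id" in trials.columns:
        cols = ["subject_id", "task"]
    for _, grp in trials.groupby(cols, dropna=False, sort=False):
        idx = grp["trial_index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise ValueError("trials must be ordered by trial_index within task")


def simulate_agent(
    params: SubjectParams,
    trials: pd.DataFrame,
    spec: ModelSpec,
    rng: np.random.Generator,
    p_valid: float = 0.8,
) -> pd.DataFrame:
    """Simulate choices and outcomes over a prepared trial sequence.

    Each trial: compute action weights from the current latent state,
    sample go with probability :func:`choice_prob_go`, draw the
    probabilistic outcome, then update Q of the chosen action and V of the
    shown cue.  Latent state resets at each task boundary.  Returns a copy
    of ``trials`` with ``action``, ``outcome`` and ``feedback_valid``
    filled.
    """
    _check_ordered(trials)
    out = trials.copy()
    actions: list[str] = []
    outcomes: list[int] = []
    valids: list[bool] = []
    theta = effective_theta(spec, params)
    prev_task = None
    Q: dict[tuple[str, str], float] = {}
    V: dict[str, float] = {}
    for row in out.itertuples(index=False):
        if row.task != prev_task:
            Q = {(ct, a): 0.0 for ct in CUE_TYPES for a in ("go", "nogo")}
            V = {ct: 0.0 for ct in CUE_TYPES}
            prev_task = row.task
        wm = row.task == "WMGNG"
        eps = theta[1] if wm else theta[0]
        pi = theta[6] if wm else theta[5]
        xi = theta[8] if wm else theta[7]
        ct = row.cue_type
        w_go, w_nogo = action_weights(Q[(ct, "go")], Q[(ct, "nogo")], V[ct],
                                      theta[4], pi)
        go = rng.random() < choice_prob_go(w_go, w_nogo, xi)
        action = "go" if go else "nogo"
        outcome, valid = _deliver(ct, action, p_valid, rng)
        rho = _select_rho(outcome, theta[2], theta[3])
        Q[(ct, action)] = update_value(Q[(ct, action)], outcome, eps, rho)
        V[ct] = update_value(V[ct], outcome, eps, rho)
        actions.append(action)
        outcomes.append(outcome)
        valids.append(valid)
    out["action"] = pd.array(actions, dtype="string")
    out["outcome"] = pd.array(outcomes, dtype="Int64")
    out["feedback_valid"] = pd.array(valids, dtype="boolean")
    return out


def encode_trials(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Flat integer encoding of one subject's observed trials for the kernel.

    Requires ``action`` and ``outcome`` observed on every row.  Trials must
    be ordered with each task run contiguous.
    """
    _check_ordered(trials)
    if trials["action"].isna().any() or trials["outcome"].isna().any():
        raise ValueError("trial_loglik requires observed actions and outcomes")
    cue = np.array([CUE_TYPES.index(ct) for ct in trials["cue_type"]],
                   dtype=np.int64)
    wm = (trials["task"].to_numpy() == "WMGNG").astype(np.int64)
    task_vals = trials["task"].to_numpy()
    reset = np.zeros(len(trials), dtype=np.int64)
    reset[0] = 1
    reset[1:][task_vals[1:] != task_vals[:-1]] = 1
    action = (trials["action"].to_numpy() == GO).astype(np.int64)
    outcome = trials["outcome"].to_numpy().astype(np.int64)
    return {"cue": cue, "wm": wm, "reset": reset, "action": action,
            "outcome": outcome}


def trial_loglik(
    params: SubjectParams, trials: pd.DataFrame, spec: ModelSpec
) -> np.ndarray:
    """Per-trial log-probability of the observed actions.

    Replays the same update sequence as :func:`simulate_agent`, but
    conditioning on the observed actions and outcomes.  The total choice
    log-likelihood is the sum of the returned vector.
    """
    enc = encode_trials(trials)
    theta = np.asarray(effective_theta(spec, params), dtype=np.float64)
    n = len(trials)
    ll = np.empty(n)
    scratch = np.empty(n)
    _kernel.replay_subject(enc["cue"], enc["wm"], enc["reset"], enc["action"],
                           enc["outcome"], theta, ll, scratch, scratch.copy(),
                           scratch.copy())
    return ll


def replay_weights(
    params: SubjectParams, trials: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    """Trial-wise action weights and go probability under observed history.

    Returns a frame aligned with ``trials`` holding ``w_go``, ``w_nogo``,
    ``p_go`` and ``loglik`` computed at the given parameters while the
    observed actions/outcomes drive the value updates (one-step-ahead
    replay).
    """
    enc = encode_trials(trials)
    theta = np.asarray(effective_theta(spec, params), dtype=np.float64)
    n = len(trials)
    ll = np.empty(n)
    w_go = np.empty(n)
    w_nogo = np.empty(n)
    p_go = np.empty(n)
    _kernel.replay_subject(enc["cue"], enc["wm"], enc["reset"], enc["action"],
                           enc["outcome"], theta, ll, w_go, w_nogo, p_go)
    return pd.DataFrame(
        {"w_go": w_go, "w_nogo": w_nogo, "p_go": p_go, "loglik": ll},
        index=trials.index,
    )
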