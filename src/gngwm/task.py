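"""Orthogonalized go/no-go (GNG) task structures and probabilistic feedback.

The task crosses the required action (go / no-go) with outcome valence
(win / avoid losing), giving four cue types presented as fractal images.
Feedback is probabilistic: the better outcome follows a correct response on
80% of trials and an incorrect response on 20% of trials.  In the
working-memory load condition (WMGNG) the same task runs with a concurrent
2-back stream: on every trial the participant additionally judges whether
the current cue is identical to the cue two trials earlier.

This module builds trial sequences, delivers outcomes, and (together with
:mod:`gngwm.model`) simulates whole synthetic cohorts with heterogeneous
subject parameters drawn from group-level distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GO = "go"
NOGO = "nogo"
ACTIONS = (GO, NOGO)

GNG = "GNG"
WMGNG = "WMGNG"
TASKS = (GNG, WMGNG)

GO_TO_WIN = "go_to_win"
NOGO_TO_WIN = "nogo_to_win"
GO_TO_AVOID = "go_to_avoid"
NOGO_TO_AVOID = "nogo_to_avoid"
CUE_TYPES = (GO_TO_WIN, NOGO_TO_WIN, GO_TO_AVOID, NOGO_TO_AVOID)

#: Pavlovian-congruent cue types: the instinctive response (go toward reward,
#: withhold under threat) coincides with the instrumentally correct one.
CONGRUENT_CUES = (GO_TO_WIN, NOGO_TO_AVOID)
INCONGRUENT_CUES = (NOGO_TO_WIN, GO_TO_AVOID)

#: Columns of a trial table, in canonical order.
TRIAL_COLUMNS = (
    "subject_id",
    "task",
    "block",
    "trial_index",
    "cue_id",
    "cue_type",
    "required_action",
    "action",
    "outcome",
    "feedback_valid",
    "nback_truth",
)


def required_action(cue_type: str) -> str:
    """Correct response for a cue type: go for go_* cues, nogo otherwise."""
    if cue_type not in CUE_TYPES:
        raise ValueError(f"unknown cue_type: {cue_type!r}")
    return GO if cue_type in (GO_TO_WIN, GO_TO_AVOID) else NOGO


def is_win_cue(cue_type: str) -> bool:
    """True for cues whose outcomes are {+1, 0}; False for {0, -1} cues."""
    if cue_type not in CUE_TYPES:
        raise ValueError(f"unknown cue_type: {cue_type!r}")
    return cue_type in (GO_TO_WIN, NOGO_TO_WIN)


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of one task run.

    Defaults reproduce the study design: 30 trials per cue type (120 per
    task) in two 60-trial blocks, with the better outcome delivered on 80%
    of correct-response trials.
    """

    n_trials_per_type: int = 30
    p_valid_feedback: float = 0.8
    n_blocks: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials_per_type <= 0:
            raise ValueError("n_trials_per_type must be positive")
        if not 0.0 < self.p_valid_feedback <= 1.0:
            raise ValueError("p_valid_feedback must be in (0, 1]")
        if self.n_blocks <= 0 or (self.n_trials_per_type * 4) % self.n_blocks:
            raise ValueError("n_trials_per_type * 4 must divide into n_blocks")

    @property
    def n_trials(self) -> int:
        return 4 * self.n_trials_per_type


def nback_labels(cue_ids: Sequence[int]) -> list[str]:
    """2-back truth labels for a cue sequence.

    The first two trials have no comparison target and are labeled
    ``none``; thereafter the label is ``same`` iff the cue matches the cue
    two trials earlier.
    """
    labels = []
    for t, cue in enumerate(cue_ids):
        if t < 2:
            labels.append("none")
        else:
            labels.append("same" if cue == cue_ids[t - 2] else "diff")
    return labels


def generate_task(
    task: str,
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build one task's trial sequence with actions and outcomes unset.

    Cue types are uniformly shuffled over the whole task and the
    cue_id -> cue_type assignment is drawn at random (the fractal meanings
    were randomized across participants).  2-back truth labels are filled
    for WMGNG and set to ``none`` for GNG.

    Parameters
    ----------
    task:
        ``"GNG"`` or ``"WMGNG"``.
    config:
        Structural parameters; defaults to :class:`TaskConfig`.
    rng:
        Source of randomness.  If omitted, seeded from ``config.seed``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task: {task!r}; expected one of {TASKS}")
    config = config or TaskConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    cue_type_seq = np.repeat(np.arange(4), config.n_trials_per_type)
    rng.shuffle(cue_type_seq)
    # random assignment of fractal identity (cue_id 1..4) to cue type
    id_of_type = rng.permutation(4) + 1

    n = config.n_trials
    per_block = n // config.n_blocks
    cue_types = [CUE_TYPES[i] for i in cue_type_seq]
    cue_ids = [int(id_of_type[i]) for i in cue_type_seq]
    frame = pd.DataFrame(
        {
            "subject_id": pd.array([pd.NA] * n),
            "task": task,
            "block": np.arange(n) // per_block + 1,
            "trial_index": np.arange(1, n + 1),
            "cue_id": cue_ids,
            "cue_type": cue_types,
            "required_action": [required_action(ct) for ct in cue_types],
            "action": pd.array([pd.NA] * n, dtype="string"),
            "outcome": pd.array([pd.NA] * n, dtype="Int64"),
            "feedback_valid": pd.array([pd.NA] * n, dtype="boolean"),
            "nback_truth": nback_labels(cue_ids) if task == WMGNG else "none",
        }
    )
    return frame[list(TRIAL_COLUMNS)]


def _deliver(
    cue_type: str, action: str, p_valid: float, rng: np.random.Generator
) -> tuple[int, bool]:
    """Outcome and whether the 80% rule (rather than the 20% flip) applied."""
    if action not in ACTIONS:
        raise ValueError(f"unknown action: {action!r}")
    correct = action == required_action(cue_type)
    valid = bool(rng.random() < p_valid)
    # best outcome delivered when the response is correct and feedback is
    # valid, or incorrect and flipped
    best = correct == valid
    if is_win_cue(cue_type):
        outcome = 1 if best else 0
    else:
        outcome = 0 if best else -1
    return outcome, valid


def deliver_outcome(
    cue_type: str,
    action: str,
    p_valid: float = 0.8,
    rng: np.random.Generator | None = None,
) -> int:
    """Draw the probabilistic outcome r in {-1, 0, +1} for one response.

    Win cues pay +1 (best) or 0; avoid cues pay 0 (best) or -1.  The best
    outcome follows a correct response with probability ``p_valid`` and an
    incorrect response with probability ``1 - p_valid``.
    """
    if rng is None:
        rng = np.random.default_rng()
    outcome, _ = _deliver(cue_type, action, p_valid, rng)
    return outcome


#: Group-level distribution of subject parameters used for synthetic
#: cohorts, as (mean, sd) on the unconstrained sampling scale (probit scale
#: for the [0,1]-bounded eps / xi, log scale for the positive rho, identity
#: for b / pi).  Calibrated so a simulated cohort reproduces the study's
#: group-level behavior: overall accuracy ~0.80 (control) vs ~0.74 (load),
#: congruent-cue accuracy well above incongruent in both tasks, and the
#: load effects carried by a lower learning rate (eps ~0.27 vs eps_wm
#: ~0.14) and more irreducible noise (xi ~0.03 vs xi_wm ~0.12) with the
#: Pavlovian bias left unchanged (pi == pi_wm) -- the study's finding.
DEFAULT_GROUP_DISTS: Mapping[str, tuple[float, float]] = {
    "eps": (-0.6, 0.25),
    "rho_rew": (1.8, 0.25),
    "rho_pun": (1.8, 0.25),
    "b": (0.15, 0.25),
    "pi": (0.4, 0.25),
    "xi": (-1.9, 0.2),
    "pi_wm": (0.4, 0.25),
    "eps_wm": (-1.1, 0.25),
    "xi_wm": (-1.2, 0.2),
}


def draw_subject_params(
    spec,
    group_dists: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
):
    """Draw one subject's parameters from the group distributions.

    Values are drawn as Normal(mu, sigma) on the unconstrained scale and
    mapped to the constrained scale.  Returns a :class:`gngwm.model.SubjectParams`.
    """
    from .family import active_params
    from .fitting import transform_to_constrained
    from .model import SubjectParams

    values = {}
    for name in active_params(spec):
        if name not in group_dists:
            raise ValueError(f"group_dists missing parameter {name!r}")
        mu, sigma = group_dists[name]
        if sigma < 0:
            raise ValueError(f"negative group sd for {name!r}")
        u = rng.normal(mu, sigma)
        values[name] = transform_to_constrained(name, u)
    return SubjectParams(**values)


def generate_cohort(
    n_subjects: int,
    group_dists: Mapping[str, tuple[float, float]] | None = None,
    spec=None,
    config: TaskConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a synthetic cohort: one GNG and one WMGNG run per subject.

    Per subject, parameters are drawn from ``group_dists`` (default
    :data:`DEFAULT_GROUP_DISTS`), both task sequences are generated, and
    choices/outcomes are simulated from the generative model.  Every
    subject gets an independent RNG stream spawned from ``seed``, so the
    cohort is fully reproducible.

    Returns
    -------
    (trials, params):
        ``trials`` is a long-format trial table (49 subjects x 240 trials
        at study scale); ``params`` holds each subject's true parameters
        on the constrained scale, keyed by ``subject_id``.
    """
    from .family import active_params, build_model_spec
    from .model import simulate_agent

    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if spec is None:
        spec = build_model_spec(8)
    group_dists = dict(group_dists or DEFAULT_GROUP_DISTS)
    config = config or TaskConfig()

    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    trial_tables = []
    param_rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        subject = f"s{i + 1:03d}"
        params = draw_subject_params(spec, group_dists, rng)
        tables = []
        for task in TASKS:
            frame = generate_task(task, config, rng)
            frame = simulate_agent(
                params, frame, spec, rng, p_valid=config.p_valid_feedback
            )
            tables.append(frame)
        table = pd.concat(tables, ignore_index=True)
        table["subject_id"] = subject
        trial_tables.append(table)
        row = {"subject_id": subject}
        row.update({k: getattr(params, k) for k in active_params(spec)})
        param_rows.append(row)

    trials = pd.concat(trial_tables, ignore_index=True)
    params_table = pd.DataFrame(param_rows)
    return trials, params_table
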