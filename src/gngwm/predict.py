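"""Posterior predictive checks and recovery experiments.

One-step-ahead prediction conditions each trial's predicted go
probability on the subject's actual observed history up to that trial
(the observed actions and outcomes drive the value updates), evaluated at
posterior-median subject parameters.  The recovery harness validates the
whole generate -> fit -> compare pipeline: parameter recovery measures how
well subject-level parameters are re-estimated from simulated cohorts;
model recovery asks whether LOOIC selects the generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import compare_models
from .family import ModelSpec, active_params, build_model_spec
from .fitting import FitResult, MCMCConfig, fit_hierarchical
from .model import replay_weights
from .task import (
    CONGRUENT_CUES,
    DEFAULT_GROUP_DISTS,
    GO,
    TaskConfig,
    generate_cohort,
)


def one_step_ahead(
    fit: FitResult, trials: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-wise predicted go probability and accuracy per condition.

    For every trial, the subject's observed history up to t-1 drives the
    latent-state updates and the model predicts P(go) at the subject's
    posterior-median parameters.  Predicted accuracy is the predicted
    probability of the required action.  Deterministic given the fit.

    Returns
    -------
    (per_trial, summary):
        ``per_trial`` aligns with ``trials`` and adds ``p_go`` and
        ``p_correct``; ``summary`` aggregates predicted accuracy per
        subject x task x cue type and congruence.
    """
    params = fit.median_subject_params()
    missing = set(trials["subject_id"].unique()) - set(params)
    if missing:
        raise ValueError(f"subjects absent from fit: {sorted(missing)}")

    chunks = []
    for sid, grp in trials.groupby("subject_id", sort=False):
        rep = replay_weights(params[sid], grp, fit.spec)
        out = grp.copy()
        out["p_go"] = rep["p_go"].to_numpy()
        out["p_correct"] = np.where(grp["required_action"] == GO,
                                    out["p_go"], 1.0 - out["p_go"])
        chunks.append(out)
    per_trial = pd.concat(chunks).loc[trials.index]
    per_trial["congruence"] = np.where(
        per_trial["cue_type"].isin(CONGRUENT_CUES), "congruent", "incongruent"
    )
    by_cue = (per_trial.groupby(["subject_id", "task", "cue_type"])
              ["p_correct"].mean().rename("predicted_accuracy").reset_index())
    by_cue["grouping"] = "cue_type"
    by_cue = by_cue.rename(columns={"cue_type": "condition"})
    by_con = (per_trial.groupby(["subject_id", "task", "congruence"])
              ["p_correct"].mean().rename("predicted_accuracy").reset_index())
    by_con["grouping"] = "congruence"
    by_con = by_con.rename(columns={"congruence": "condition"})
    summary = pd.concat([by_cue, by_con], ignore_index=True)
    return per_trial, summary


@dataclass
class RecoveryReport:
    """Outcome of a parameter- or model-recovery experiment."""

    spec: ModelSpec
    per_parameter: pd.DataFrame
    per_replicate: pd.DataFrame
    seeds: list[int]
    config: dict
    failures: list[dict] = field(default_factory=list)


def parameter_recovery(
    spec: ModelSpec,
    group_dists: Mapping[str, tuple[float, float]] | None = None,
    n_subjects: int = 20,
    mcmc: MCMCConfig | None = None,
    seeds: Sequence[int] = (1,),
    task_config: TaskConfig | None = None,
) -> RecoveryReport:
    """Generate -> fit -> compare true vs posterior-median parameters.

    For each seed, a cohort is simulated from ``group_dists``, the same
    model is fitted, and subject-level true values are compared with
    posterior medians.  Reports Spearman rank correlation, bias
    (mean recovered - true) and RMSE per parameter, per replicate and
    pooled.  Fit failures are recorded per replicate, not fatal.
    """
    group_dists = dict(group_dists or DEFAULT_GROUP_DISTS)
    mcmc = mcmc or MCMCConfig(chains=4, iters=1000, warmup=500)
    rep_rows, failures = [], []
    for seed in seeds:
        try:
            trials, true_params = generate_cohort(
                n_subjects, group_dists, spec, task_config, seed=seed
            )
            fit = fit_hierarchical(trials, spec, mcmc, seed=seed)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            failures.append({"seed": seed, "error": repr(exc)})
            continue
        recovered = fit.posterior_median_params()
        truth = true_params.set_index("subject_id").loc[recovered.index]
        for name in active_params(spec):
            t = truth[name].to_numpy()
            r = recovered[name].to_numpy()
            rho = stats.spearmanr(t, r).statistic if len(t) > 2 else np.nan
            rep_rows.append({
                "seed": seed, "param": name,
                "rank_corr": float(rho),
                "bias": float(np.mean(r - t)),
                "rmse": float(np.sqrt(np.mean((r - t) ** 2))),
                "max_rhat": fit.max_rhat,
            })
    per_replicate = pd.DataFrame(rep_rows)
    if len(per_replicate):
        per_parameter = (per_replicate.groupby("param")
                         [["rank_corr", "bias", "rmse"]]
                         .mean().reset_index())
    else:
        per_parameter = pd.DataFrame(
            columns=["param", "rank_corr", "bias", "rmse"])
    return RecoveryReport(
        spec=spec,
        per_parameter=per_parameter,
        per_replicate=per_replicate,
        seeds=list(seeds),
        config={"n_subjects": n_subjects, "chains": mcmc.chains,
                "iters": mcmc.iters, "warmup": mcmc.warmup},
        failures=failures,
    )


def model_recovery(
    generating_ids: Sequence[int],
    fitted_ids: Sequence[int],
    n_replicates: int = 5,
    n_subjects: int = 20,
    group_dists: Mapping[str, tuple[float, float]] | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    task_config: TaskConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """LOOIC-winner confusion matrix across generating and fitted models.

    For each generating model and replicate, a cohort is simulated, every
    candidate model is fitted, and the LOOIC winner recorded.  Rows of the
    returned confusion matrix (generating model x winning model counts)
    sum to ``n_replicates`` minus any recorded failures.
    """
    bad = [i for i in (*generating_ids, *fitted_ids) if not 1 <= i <= 8]
    if bad:
        raise ValueError(f"model ids out of range 1..8: {bad}")
    group_dists = dict(group_dists or DEFAULT_GROUP_DISTS)
    mcmc = mcmc or MCMCConfig(chains=2, iters=800, warmup=400)
    confusion = pd.DataFrame(
        0, index=pd.Index(list(generating_ids), name="generating"),
        columns=pd.Index(list(fitted_ids), name="winner"),
    )
    failures: list[dict] = []
    base = np.random.SeedSequence(seed)
    for gen_id in generating_ids:
        gen_spec = build_model_spec(gen_id)
        dists = {k: v for k, v in group_dists.items()
                 if k in active_params(gen_spec)}
        for rep in range(n_replicates):
            rep_seed = int(base.spawn(1)[0].generate_state(1)[0] % (2**31))
            try:
                trials, _ = generate_cohort(
                    n_subjects, dists, gen_spec, task_config, seed=rep_seed
                )
                fits = {
                    fid: fit_hierarchical(trials, build_model_spec(fid),
                                          mcmc, seed=rep_seed + fid)
                    for fid in fitted_ids
                }
                table = compare_models(fits)
                winner = int(table.iloc[0]["model_id"])
                confusion.loc[gen_id, winner] += 1
            except Exception as exc:  # noqa: BLE001
                failures.append({"generating": gen_id, "replicate": rep,
                                 "seed": rep_seed, "error": repr(exc)})
    return confusion, failures
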