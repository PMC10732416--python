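"""Behavioral and model-derived analyses of the cohort.

Reproduces the task-performance analyses on the simulated cohort:

* accuracy per cue type and task, with the action x valence
  repeated-measures ANOVA per task;
* the Pavlovian bias index (congruent minus incongruent accuracy) and its
  GNG-vs-WMGNG paired t-test;
* smoothed learning curves (moving-average window 5) and the temporal
  development of the Pavlovian bias (window 3);
* choice-randomness decile profiles: go-ratio over quantiles of the
  action-weight difference W_go - W_nogo, and accuracy over quantiles of
  |W_go - W_nogo|, with per-decile paired t-tests between tasks.  Action
  weights are obtained by replaying each subject's observed history at the
  posterior-median parameters of the fitted model from 02 (falling back to
  the true generating parameters when no fit output is present).
"""

import argparse
from pathlib import Path

import pandas as pd

from gngwm.behavior import (
    accuracy_by_condition,
    learning_curve,
    paired_t,
    pavlovian_bias_index,
    profile_task_comparison,
    rm_anova_2x2,
    summarize_accuracy,
    temporal_pavlovian_bias,
    weight_quantile_profiles,
)
from gngwm.family import build_model_spec
from gngwm.io import read_params, read_trials
from gngwm.model import SubjectParams, replay_weights


def _weights(trials, params_table, spec):
    by_subject = params_table.set_index("subject_id")
    chunks = []
    for sid, grp in trials.groupby("subject_id", sort=False):
        p = SubjectParams(**by_subject.loc[sid].dropna().to_dict())
        chunks.append(replay_weights(p, grp, spec))
    return pd.concat(chunks)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort_trials.csv"))
    ap.add_argument("--fit-params", type=Path,
                    default=Path("results/fit_m8_subject_params.csv"))
    ap.add_argument("--model", type=int, default=8)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    trials = read_trials(args.data)
    args.out.mkdir(parents=True, exist_ok=True)

    acc = accuracy_by_condition(trials)
    summary = summarize_accuracy(acc)
    print("accuracy (group mean +/- SEM):")
    print(summary.round(3).to_string(index=False))
    acc.to_csv(args.out / "accuracy_by_condition.csv", index=False)

    overall = acc[acc.condition == "overall"].pivot(
        index="subject_id", columns="task", values="accuracy")
    t = paired_t(overall["GNG"], overall["WMGNG"])
    print(f"\noverall GNG vs WMGNG: t({t.df}) = {t.t:.2f}, p = {t.p:.4f}, "
          f"d = {t.d:.2f}")

    bias = pavlovian_bias_index(acc)
    wide = bias.pivot(index="subject_id", columns="task",
                      values="pavlovian_bias")
    tb = paired_t(wide["GNG"], wide["WMGNG"])
    print(f"Pavlovian bias: GNG {wide['GNG'].mean():.3f}, "
          f"WMGNG {wide['WMGNG'].mean():.3f}; "
          f"t({tb.df}) = {tb.t:.2f}, p = {tb.p:.4f}")
    bias.to_csv(args.out / "pavlovian_bias.csv", index=False)

    for task in ("GNG", "WMGNG"):
        cue_rows = acc[acc.condition.str.contains("_to_")
                       & (acc.task == task)].copy()
        cue_rows["action"] = cue_rows.condition.map(
            lambda c: "go" if c.startswith("go") else "nogo")
        cue_rows["valence"] = cue_rows.condition.map(
            lambda c: "win" if c.endswith("win") else "avoid")
        anova = rm_anova_2x2(cue_rows)
        print(f"\n{task} action x valence ANOVA:")
        print(anova.round(4).to_string(index=False))
        anova.to_csv(args.out / f"anova_{task.lower()}.csv", index=False)

    curve = learning_curve(trials, window=5)
    curve.to_csv(args.out / "learning_curves.csv", index=False)
    temporal, peaks = temporal_pavlovian_bias(trials, window=3)
    temporal.to_csv(args.out / "temporal_bias.csv", index=False)
    print(f"\ntemporal Pavlovian bias peaks (presentation index): {peaks}")

    params_path = (args.fit_params if args.fit_params.exists()
                   else args.data.parent / "cohort_params.csv")
    source = "posterior-median" if args.fit_params.exists() else "true"
    params_table = read_params(params_path)
    spec = build_model_spec(args.model)
    weights = _weights(trials, params_table, spec)
    go_prof, acc_prof = weight_quantile_profiles(trials, weights)
    go_prof.to_csv(args.out / "decile_go_ratio.csv", index=False)
    acc_prof.to_csv(args.out / "decile_accuracy.csv", index=False)
    comp = profile_task_comparison(go_prof, "go_ratio")
    comp.to_csv(args.out / "decile_go_ratio_tests.csv", index=False)
    print(f"\ndecile go-ratio task comparison ({source} parameters):")
    print(comp.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
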