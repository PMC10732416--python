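import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gngwm.behavior import (
    accuracy_by_condition,
    learning_curve,
    moving_average,
    paired_t,
    pavlovian_bias_index,
    profile_task_comparison,
    quantile_bins,
    rm_anova_2x2,
    summarize_accuracy,
    temporal_pavlovian_bias,
    weight_quantile_profiles,
)
from gngwm.family import build_model_spec
from gngwm.model import SubjectParams, replay_weights, simulate_agent
from gngwm.task import TaskConfig, generate_cohort, generate_task


def _toy_trials(cells):
    """Build a trial table from (subject, task, cue_type, n, n_correct)."""
    rows = []
    for sid, task, cue_type, n, n_correct in cells:
        req = "go" if cue_type in ("go_to_win", "go_to_avoid") else "nogo"
        other = "nogo" if req == "go" else "go"
        for i in range(n):
            rows.append({
                "subject_id": sid, "task": task, "block": 1,
                "trial_index": len(rows) + 1, "cue_id": 1,
                "cue_type": cue_type, "required_action": req,
                "action": req if i < n_correct else other,
                "outcome": 0, "feedback_valid": True, "nback_truth": "none",
            })
    return pd.DataFrame(rows)


class TestAccuracy:
    def test_toy_fraction(self):
        t = _toy_trials([("s1", "GNG", "go_to_win", 30, 27)])
        acc = accuracy_by_condition(t)
        gw = acc[(acc.condition == "go_to_win")]["accuracy"].iloc[0]
        assert gw == pytest.approx(0.9)

    def test_all_go_responder(self):
        t = _toy_trials([
            ("s1", "GNG", "go_to_win", 10, 10),
            ("s1", "GNG", "nogo_to_win", 10, 0),
        ])
        acc = accuracy_by_condition(t).set_index("condition")["accuracy"]
        assert acc["go_to_win"] == 1.0
        assert acc["nogo_to_win"] == 0.0

    def test_empty_condition_is_missing_not_zero(self):
        t = _toy_trials([("s1", "GNG", "go_to_win", 10, 9)])
        acc = accuracy_by_condition(t).set_index("condition")["accuracy"]
        assert np.isnan(acc["nogo_to_avoid"])

    def test_summary_sem(self):
        t = _toy_trials([
            ("s1", "GNG", "go_to_win", 10, 10),
            ("s2", "GNG", "go_to_win", 10, 5),
        ])
        s = summarize_accuracy(accuracy_by_condition(t))
        row = s[(s.condition == "go_to_win")].iloc[0]
        assert row["mean"] == pytest.approx(0.75)
        assert row["sem"] == pytest.approx(0.25)


class TestPavlovianBiasIndex:
    def test_arithmetic(self):
        t = _toy_trials([
            ("s1", "GNG", "go_to_win", 10, 9),
            ("s1", "GNG", "nogo_to_win", 10, 6),
            ("s1", "GNG", "go_to_avoid", 10, 7),
            ("s1", "GNG", "nogo_to_avoid", 10, 8),
        ])
        bias = pavlovian_bias_index(accuracy_by_condition(t))
        assert bias["pavlovian_bias"].iloc[0] == pytest.approx(0.2)

    def test_identical_accuracies_zero(self):
        t = _toy_trials([
            ("s1", "GNG", ct, 10, 7)
            for ct in ("go_to_win", "nogo_to_win", "go_to_avoid",
                       "nogo_to_avoid")
        ])
        bias = pavlovian_bias_index(accuracy_by_condition(t))
        assert bias["pavlovian_bias"].iloc[0] == pytest.approx(0.0)

    def test_antisymmetric_under_condition_swap(self):
        congruent = [("s1", "GNG", "go_to_win", 10, 9),
                     ("s1", "GNG", "nogo_to_avoid", 10, 8)]
        incongruent = [("s1", "GNG", "nogo_to_win", 10, 6),
                       ("s1", "GNG", "go_to_avoid", 10, 5)]
        fwd = pavlovian_bias_index(
            accuracy_by_condition(_toy_trials(congruent + incongruent)))
        swapped = [("s1", "GNG", "go_to_win", 10, 6),
                   ("s1", "GNG", "nogo_to_avoid", 10, 5),
                   ("s1", "GNG", "nogo_to_win", 10, 9),
                   ("s1", "GNG", "go_to_avoid", 10, 8)]
        rev = pavlovian_bias_index(accuracy_by_condition(_toy_trials(swapped)))
        assert fwd["pavlovian_bias"].iloc[0] == pytest.approx(
            -rev["pavlovian_bias"].iloc[0])

    def test_missing_cell_propagates(self):
        t = _toy_trials([("s1", "GNG", "go_to_win", 10, 9)])
        bias = pavlovian_bias_index(accuracy_by_condition(t))
        assert np.isnan(bias["pavlovian_bias"].iloc[0])

    def test_unbiased_cohort_near_zero(self, spec1):
        dists = {"eps": (-1.0, 0.1), "rho_rew": (1.2, 0.1),
                 "rho_pun": (1.2, 0.1), "b": (0.0, 0.0), "pi": (0.0, 0.0),
                 "xi": (-1.5, 0.1)}
        trials, _ = generate_cohort(60, dists, spec1, None, seed=23)
        bias = pavlovian_bias_index(accuracy_by_condition(trials))
        group = bias.groupby("task")["pavlovian_bias"]
        for task, vals in group:
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 3 * sem + 1e-9


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(12, 0.7), 5), 0.7)

    def test_window_one_identity(self):
        x = np.array([0.1, 0.9, 0.4])
        np.testing.assert_allclose(moving_average(x, 1), x)

    def test_edge_shrinking_hand_computed(self):
        out = moving_average(np.array([0.0, 0, 1, 1, 1]), 3)
        np.testing.assert_allclose(out, [0, 1 / 3, 2 / 3, 1, 1])

    def test_oversized_window_collapses_to_mean(self):
        x = np.array([0.0, 1.0, 1.0])
        np.testing.assert_allclose(moving_average(x, 7), x.mean())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(5), 4)

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=30))
    @settings(max_examples=100)
    def test_mean_conserved_with_flat_edges(self, vals):
        """Window-3 smoothing conserves the sum whenever the two first and
        the two last points are equal (the edge-shrink weights cancel)."""
        x = np.array([vals[0], vals[0]] + vals + [vals[-1], vals[-1]])
        out = moving_average(x, 3)
        assert out.sum() == pytest.approx(x.sum(), abs=1e-8)


class TestLearningCurve:
    def test_shape_and_range(self, small_cohort):
        trials, _ = small_cohort
        curve = learning_curve(trials, window=5)
        assert set(curve["task"]) == {"GNG", "WMGNG"}
        per = curve.groupby(["subject_id", "task"]).size()
        assert per.eq(30).all()
        assert curve["accuracy"].between(0, 1).all()

    def test_trial_axis_option(self, small_cohort):
        trials, _ = small_cohort
        curve = learning_curve(trials, window=5, axis="trial")
        assert curve.groupby(["subject_id", "task"]).size().eq(120).all()
        with pytest.raises(ValueError):
            learning_curve(trials, window=5, axis="session")


class TestTemporalPavlovianBias:
    def test_identical_series_zero(self):
        cells = []
        for ct in ("go_to_win", "nogo_to_win", "go_to_avoid",
                   "nogo_to_avoid"):
            cells.append(("s1", "GNG", ct, 10, 10))
        table, _ = temporal_pavlovian_bias(_toy_trials(cells), window=3)
        np.testing.assert_allclose(table["bias"], 0.0)

    def test_constant_separation(self):
        cells = [("s1", "GNG", "go_to_win", 10, 10),
                 ("s1", "GNG", "nogo_to_avoid", 10, 10),
                 ("s1", "GNG", "nogo_to_win", 10, 0),
                 ("s1", "GNG", "go_to_avoid", 10, 0)]
        table, peaks = temporal_pavlovian_bias(_toy_trials(cells), window=3)
        np.testing.assert_allclose(table["bias"], 1.0)
        assert peaks["GNG"] >= 1

    def test_wm_load_delays_bias_acquisition(self):
        """A lower learning rate under load delays the rise of the
        group-mean Pavlovian bias: the smoothed bias reaches 80% of its
        maximum later in the WMGNG task."""
        dists = {"eps": (-0.3, 0.1), "eps_wm": (-1.7, 0.1),
                 "rho_rew": (1.6, 0.1), "rho_pun": (1.6, 0.1),
                 "b": (0.0, 0.1), "pi": (1.0, 0.2), "pi_wm": (1.0, 0.2),
                 "xi": (-1.9, 0.1), "xi_wm": (-1.9, 0.1)}
        trials, _ = generate_cohort(80, dists, build_model_spec(8), None,
                                    seed=29)
        table, _ = temporal_pavlovian_bias(trials, window=3)
        g = table.groupby(["task", "x"])["bias"].mean().unstack(0)
        rise = {t: int(g[t][g[t] >= 0.8 * g[t].max()].index.min())
                for t in ("GNG", "WMGNG")}
        assert rise["WMGNG"] > rise["GNG"]


class TestQuantileBins:
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=100),
           st.integers(1, 10))
    @settings(max_examples=100)
    def test_partition_property(self, vals, n_bins):
        bins = quantile_bins(np.array(vals), n_bins)
        counts = np.bincount(bins, minlength=n_bins + 1)[1:]
        assert counts.sum() == len(vals)
        present = counts[counts > 0]
        assert counts.max() - counts.min() <= 1 or len(vals) < n_bins

    def test_sorted_assignment(self):
        bins = quantile_bins(np.array([3.0, 1.0, 2.0, 4.0]), 2)
        np.testing.assert_array_equal(bins, [2, 1, 1, 2])


class TestWeightQuantileProfiles:
    def _profiles(self, params, seed, n_subjects=20, spec_id=1):
        spec = build_model_spec(spec_id)
        rng = np.random.default_rng(seed)
        tables = []
        weights = []
        for s in range(n_subjects):
            frame = generate_task("GNG", TaskConfig(seed=seed * 100 + s), rng)
            sim = simulate_agent(params, frame, spec, rng)
            sim["subject_id"] = f"s{s:02d}"
            tables.append(sim)
            weights.append(replay_weights(params, sim, spec))
        trials = pd.concat(tables, ignore_index=True)
        w = pd.concat(weights, ignore_index=True)
        return weight_quantile_profiles(trials, w)

    def test_deterministic_agent_extreme_bins(self):
        p = SubjectParams(eps=0.6, rho_rew=8.0, rho_pun=8.0, b=0.0, pi=0.0,
                          xi=0.0)
        go_prof, _ = self._profiles(p, seed=31)
        means = go_prof.groupby("bin")["go_ratio"].mean()
        assert means.loc[1] < 0.15
        assert means.loc[10] > 0.85

    def test_pure_noise_flat_profile(self):
        p = SubjectParams(eps=0.2, rho_rew=3.0, rho_pun=3.0, b=0.0, pi=0.0,
                          xi=1.0)
        go_prof, _ = self._profiles(p, seed=32)
        means = go_prof.groupby("bin")["go_ratio"].mean()
        assert (means - 0.5).abs().max() < 0.12

    def test_noisier_cohort_has_shallower_slope(self):
        slopes = {}
        for xi, seed in ((0.1, 33), (0.4, 34)):
            p = SubjectParams(eps=0.3, rho_rew=4.0, rho_pun=4.0, b=0.0,
                              pi=0.0, xi=xi)
            go_prof, _ = self._profiles(p, seed=seed)
            means = go_prof.groupby("bin")["go_ratio"].mean()
            slopes[xi] = means.loc[10] - means.loc[1]
        assert slopes[0.4] < slopes[0.1]

    def test_alignment_validation(self, small_cohort):
        trials, _ = small_cohort
        with pytest.raises(ValueError, match="align"):
            weight_quantile_profiles(trials, pd.DataFrame(
                {"w_go": [0.0], "w_nogo": [0.0]}))


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.d) == (0.0, 0.0)
        assert not res.undefined

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.undefined
        assert np.isnan(res.t)

    def test_hand_computed(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = paired_t(x, np.zeros(5))
        assert res.t == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.d == pytest.approx(3 / 1.5811, abs=1e-4)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestRmAnova:
    @staticmethod
    def _acc_frame(fn, n=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            base = rng.normal(0.7, 0.05)
            for a in ("go", "nogo"):
                for v in ("win", "avoid"):
                    rows.append({"subject_id": f"s{s}", "action": a,
                                 "valence": v,
                                 "accuracy": fn(base, a, v, rng)})
        return pd.DataFrame(rows)

    def test_no_effect_gives_zero_f(self):
        acc = self._acc_frame(lambda base, a, v, rng: base)
        out = rm_anova_2x2(acc).set_index("effect")
        np.testing.assert_allclose(out["F"], 0.0)

    def test_pure_action_effect(self):
        acc = self._acc_frame(
            lambda base, a, v, rng: base + (0.15 if a == "go" else 0.0)
            + rng.normal(0, 0.01)
        )
        out = rm_anova_2x2(acc).set_index("effect")
        assert out.loc["action", "F"] > 50
        assert out.loc["action * valence", "F"] < 5

    def test_pavlovian_cohort_interaction(self, spec1):
        dists = {"eps": (-0.8, 0.1), "rho_rew": (1.2, 0.1),
                 "rho_pun": (1.2, 0.1), "b": (0.0, 0.1), "pi": (2.0, 0.2),
                 "xi": (-2.0, 0.1)}
        trials, _ = generate_cohort(40, dists, spec1, None, seed=37)
        acc = accuracy_by_condition(trials)
        cue_rows = acc[acc.condition.str.contains("_to_")].copy()
        cue_rows["action"] = np.where(
            cue_rows.condition.isin(["go_to_win", "go_to_avoid"]), "go",
            "nogo")
        cue_rows["valence"] = np.where(
            cue_rows.condition.isin(["go_to_win", "nogo_to_win"]), "win",
            "avoid")
        gng = cue_rows[cue_rows.task == "GNG"]
        out = rm_anova_2x2(gng).set_index("effect")
        assert out.loc["action * valence", "p"] < 0.001

    def test_incomplete_subject_dropped(self):
        acc = self._acc_frame(lambda base, a, v, rng: base + rng.normal(0, .02))
        out_full = rm_anova_2x2(acc)
        acc_broken = pd.concat([
            acc,
            pd.DataFrame([{"subject_id": "extra", "action": "go",
                           "valence": "win", "accuracy": 0.5}]),
        ])
        out = rm_anova_2x2(acc_broken)
        pd.testing.assert_frame_equal(out, out_full)


class TestProfileTaskComparison:
    def test_detects_task_difference(self, small_cohort, spec8):
        trials, params = small_cohort
        weights = []
        by_subject = params.set_index("subject_id")
        for sid, grp in trials.groupby("subject_id", sort=False):
            p = SubjectParams(**by_subject.loc[sid].to_dict())
            weights.append(replay_weights(p, grp, spec8))
        w = pd.concat(weights)
        go_prof, acc_prof = weight_quantile_profiles(trials, w)
        comp = profile_task_comparison(go_prof, "go_ratio")
        assert len(comp) == 10
        assert comp["df"].eq(11).all()
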