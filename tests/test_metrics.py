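"""Switch/stay, run-history, choice-frequency, criterion and latency metrics."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_session, random_toy_sessions
from revlearn.metrics import (
    NOT_REACHED,
    akb_event,
    akb_table,
    choice_frequency_table,
    fixed_early_late,
    latency_summary,
    switch_stay_table,
    trials_to_criterion,
    v1_choice_summary,
)


class TestSwitchStay:
    def test_enumerated_example(self):
        s = make_session([0, 0, 1, 2], [1, 1, 1, 1])
        t = switch_stay_table([s])
        row = t[t.prior_outcome == "reward"].iloc[0]
        assert row.n_events == 3
        assert row.p_switch == pytest.approx(2 / 3)

    def test_uniform_random_switch_rate(self, rng):
        choices = rng.integers(0, 3, size=30_000)
        s = make_session(choices, np.ones_like(choices))
        t = switch_stay_table([s])
        p = t.loc[t.prior_outcome == "reward", "p_switch"].iloc[0]
        assert p == pytest.approx(2 / 3, abs=0.01)

    def test_all_stay(self):
        s = make_session([1] * 10, [1, 0] * 5)
        t = switch_stay_table([s])
        assert np.all(t.p_switch == 0)

    def test_split_reversal_segments(self):
        choices = np.concatenate([np.zeros(150, int), np.ones(150, int)])
        s = make_session(choices, np.ones(300, int), kind="stable", reversal=150)
        t = switch_stay_table([s], split_reversal=True)
        pre = t[(t.segment == "pre_reversal") & (t.prior_outcome == "reward")].iloc[0]
        post = t[(t.segment == "post_reversal") & (t.prior_outcome == "reward")].iloc[0]
        assert pre.n_events == 149  # current trials 2..150
        assert post.n_events == 150  # current trials 151..300
        assert pre.n_switch == 0
        assert post.n_switch == 1  # the single flip at trial 151

    def test_matches_brute_force_oracle(self, rng):
        sessions = random_toy_sessions(rng, 50)
        t = switch_stay_table(sessions)
        for outcome, rew_val in (("reward", 1), ("no_reward", 0)):
            n_ev = n_sw = 0
            for s in sessions:
                ch, rw = s.choices, s.rewards
                for n in range(1, len(ch)):
                    if rw[n - 1] == rew_val:
                        n_ev += 1
                        n_sw += ch[n] != ch[n - 1]
            sub = t[t.prior_outcome == outcome]
            assert sub.n_events.sum() == n_ev
            assert sub.n_switch.sum() == n_sw


def oracle_akb_events(choices, rewards):
    """Independent A_kB scanner: explicit per-bin pattern matching."""
    events = []
    for n in range(2, len(choices)):
        b = choices[n - 1]
        window = list(choices[max(0, n - 8) : n - 1])  # lags 2..8, oldest first
        window.reverse()  # lag order: 2, 3, ...
        if not window or window[0] == b:
            continue
        a = window[0]
        k = 0
        for c in window:
            if c == a:
                k += 1
            else:
                break
        if a in window[k:]:
            continue  # A recurs later in the history: not a clean run
        events.append((min(k, 7), "reward" if rewards[n - 1] else "no_reward", n))
    return events


class TestAkB:
    def test_three_a_run_example(self):
        # C A A A B(rewarded) ? -> one event in bin 3
        s = make_session([2, 0, 0, 0, 1, 1], [0, 0, 0, 0, 1, 0])
        t = akb_table([s]).set_index(["condition", "prior_outcome"])
        row = t.loc[("3", "reward")]
        assert row.n_events == 1
        assert row.p_next_B == 1.0  # next choice was B again

    def test_long_run_pooled(self):
        s = make_session([0, 0, 0, 0, 0, 1, 2], [0] * 7, session_id="x")
        t = akb_table([s])
        assert list(t.condition) == ["4-7"]
        assert t.iloc[0].p_next_C == 1.0

    def test_mixed_history_excluded(self):
        # C A C B ? : the run option recurs within the history, so the
        # trial after B is not a clean run condition
        choices = np.array([2, 0, 2, 1, 0])
        assert akb_event(choices, 4) is None
        # the table therefore contains no bin-2-or-longer event for this
        # session, only the short early-history events
        t = akb_table([make_session(choices, [0] * 5)])
        assert set(t.condition) <= {"1"}

    def test_events_disjoint_across_bins(self, rng):
        sessions = random_toy_sessions(rng, 50)
        t = akb_table(sessions)
        n_from_table = t.n_events.sum()
        n_from_oracle = sum(
            len(oracle_akb_events(s.choices, s.rewards)) for s in sessions
        )
        assert n_from_table == n_from_oracle

    def test_matches_brute_force_oracle(self, rng):
        sessions = random_toy_sessions(rng, 60)
        t = akb_table(sessions)
        from collections import Counter

        oracle = Counter()
        for s in sessions:
            for k, outcome, _ in oracle_akb_events(s.choices, s.rewards):
                label = str(k) if k <= 3 else "4-7"
                oracle[(label, outcome)] += 1
        for row in t.itertuples():
            assert oracle[(row.condition, row.prior_outcome)] == row.n_events

    def test_probabilities_sum_to_one(self, rng):
        sessions = random_toy_sessions(rng, 40)
        t = akb_table(sessions)
        np.testing.assert_allclose(t.p_next_B + t.p_next_A + t.p_next_C, 1.0, atol=1e-12)

    def test_at_least_mode_includes_shorter_bins(self):
        # A A B ? : maximal -> bin 2 only; at-least -> bins 1 and 2
        s = make_session([0, 0, 1, 2], [0] * 4)
        assert list(akb_table([s]).condition) == ["2"]
        relaxed = akb_table([s], require_maximal=False)
        assert sorted(relaxed.condition) == ["1", "2"]

    def test_event_detector_spec_cases(self):
        assert akb_event(np.array([2, 0, 0, 0, 1, 1]), 5) == (3, 0, 1)
        assert akb_event(np.array([0, 0, 0, 0, 0, 1, 2]), 6) == (5, 0, 1)
        assert akb_event(np.array([2, 0, 2, 1, 0]), 4) is None


class TestChoiceFrequency:
    def test_count_extremes(self):
        # B at n-1 and all of n-2..n-6 -> count 5
        s = make_session([1] * 8, [1] * 8)
        t = choice_frequency_table([s])
        assert list(t.condition) == [5]
        # B only at n-1 -> count 0
        s2 = make_session([0, 0, 0, 0, 0, 0, 1, 2], [0] * 8)
        t2 = choice_frequency_table([s2])
        assert 0 in list(t2.condition)

    def test_matches_brute_force_oracle(self, rng):
        sessions = random_toy_sessions(rng, 60)
        t = choice_frequency_table(sessions)
        from collections import Counter

        n_oracle, rep_oracle = Counter(), Counter()
        for s in sessions:
            ch, rw = s.choices, s.rewards
            for n in range(6, len(ch)):
                b = ch[n - 1]
                freq = sum(ch[n - 2 - m] == b for m in range(5))
                key = (freq, "reward" if rw[n - 1] else "no_reward")
                n_oracle[key] += 1
                rep_oracle[key] += ch[n] == b
        for row in t.itertuples():
            key = (row.condition, row.prior_outcome)
            assert n_oracle[key] == row.n_events
            assert rep_oracle[key] / n_oracle[key] == pytest.approx(row.p_repeat)

    def test_win_stay_agent_reward_effect(self):
        import revlearn as rl
        from revlearn.agents import AgentParams, RWPolicy

        sessions = [
            rl.play_session(
                rl.generate_varying_schedule("stable", i),
                RWPolicy(AgentParams(alpha=0.4, beta_sm=6.0)),
                seed=300 + i,
            )
            for i in range(10)
        ]
        t = choice_frequency_table(sessions)
        piv = t.pivot_table(index="condition", columns="prior_outcome", values="p_repeat")
        piv = piv.dropna()
        assert (piv["reward"] > piv["no_reward"]).all()


class TestCriterion:
    def test_all_correct_reaches_at_window(self):
        s = make_session([0] * 60, [1] * 60)
        res = trials_to_criterion([s], [np.zeros(60, int)])
        assert res.per_session.criterion_trial.iloc[0] == 20

    def test_never_correct(self):
        s = make_session([1] * 60, [1] * 60)
        res = trials_to_criterion([s], [np.zeros(60, int)])
        assert res.per_session.criterion_trial.iloc[0] == NOT_REACHED

    def test_boundary_inclusive(self):
        # exactly 13/20 = 0.65 in the first window
        choices = np.array([0] * 13 + [1] * 7 + [1] * 20)
        s = make_session(choices, np.ones_like(choices))
        res = trials_to_criterion([s], [np.zeros(40, int)])
        assert res.per_session.criterion_trial.iloc[0] == 20

    def test_post_reversal_segment_counts_from_reversal(self):
        choices = np.concatenate([np.zeros(150, int), np.ones(150, int)])
        labels = np.concatenate([np.zeros(150, int), np.ones(150, int)])
        s = make_session(choices, np.ones(300, int), kind="stable", reversal=150)
        res = trials_to_criterion([s], [labels], segment="post_reversal")
        assert res.per_session.criterion_trial.iloc[0] == 20

    def test_short_segment_not_reached(self):
        s = make_session([0] * 10, [1] * 10)
        res = trials_to_criterion([s], [np.zeros(10, int)])
        assert res.per_session.criterion_trial.iloc[0] == NOT_REACHED

    def test_subject_median(self):
        sessions, labels = [], []
        for i, lead in enumerate([20, 30, 40]):
            choices = np.array([1] * (lead - 20) + [0] * (80 - (lead - 20)))
            sessions.append(make_session(choices, np.ones_like(choices), session_id=f"s{i}"))
            labels.append(np.zeros(80, int))
        # criterion needs 13 correct in a trailing window of 20: sessions
        # with 0 / 10 / 20 leading errors reach it at trials 20 / 23 / 33
        res = trials_to_criterion(sessions, labels)
        assert list(res.per_session.criterion_trial) == [20, 23, 33]
        assert res.per_subject.median_criterion_trial.iloc[0] == 23


class TestV1Summary:
    def test_all_v1(self):
        s = make_session([0] * 40, [1] * 40)
        df = v1_choice_summary([s], [np.zeros(40, int)])
        assert df.p_v1.iloc[0] == 1.0

    def test_halves_split(self):
        choices = np.concatenate([np.zeros(150, int), np.ones(150, int)])
        labels = np.zeros(300, int)
        s = make_session(choices, np.ones(300, int), kind="stable", reversal=150)
        df = v1_choice_summary([s], [labels])
        assert df.p_v1_first_half.iloc[0] == 1.0
        assert df.p_v1_second_half.iloc[0] == 0.0

    def test_ex_v1_perseveration_window(self):
        labels = np.concatenate([np.zeros(150, int), np.ones(150, int)])
        choices = np.concatenate([np.zeros(175, int), np.ones(125, int)])
        s = make_session(choices, np.ones(300, int), kind="stable", reversal=150)
        df = v1_choice_summary([s], [labels], ex_v1_window=50)
        assert df.p_ex_v1_post.iloc[0] == pytest.approx(0.5)


class TestLatency:
    def test_constant_latency_log(self):
        s = make_session([0, 1, 1], [1, 1, 1], latencies=[100.0, 100.0, 100.0])
        summary, hist = latency_summary([s])
        assert np.allclose(summary.mean_log_latency, np.log(100))
        assert set(summary.transition) == {"stay", "switch"}

    def test_histogram_bins(self):
        s = make_session([0, 1], [1, 1], latencies=[50.0, 150.0])
        _, hist = latency_summary([s])
        assert hist.loc[hist.bin_left_ms == 0, "count"].iloc[0] == 1
        assert hist.loc[hist.bin_left_ms == 100, "count"].iloc[0] == 1

    def test_nonpositive_latency_rejected(self):
        bad = make_session([0, 1], [1, 1], latencies=[1.0, 2.0])
        object.__setattr__(bad.trials[1], "latency_ms", -5.0)  # corrupt after validation
        with pytest.raises(ValueError, match="latency"):
            latency_summary([bad])


class TestFixedEarlyLate:
    def test_classification_thresholds(self):
        labels = np.zeros(60, int)
        low = make_session(np.array([0] * 4 + [1] * 56), np.ones(60, int), session_id="low")
        high = make_session(np.array([0] * 16 + [1] * 4 + [0] * 40), np.ones(60, int), session_id="high")
        mid = make_session(np.array([0] * 10 + [1] * 10 + [0] * 40), np.ones(60, int), session_id="mid")
        per_session, _ = fixed_early_late([low, high, mid], [labels] * 3)
        by_id = per_session.set_index("session_id")
        assert by_id.loc["low", "early_class"] == "EARLY_LOW"  # 4/20 = 0.2
        assert by_id.loc["high", "early_class"] == "EARLY_HIGH"  # 16/20 = 0.8
        assert by_id.loc["high", "p_v1_late"] == 1.0
        assert by_id.loc["mid", "early_class"] == "neither"  # 0.5

    def test_group_summary_medians(self):
        labels = np.zeros(40, int)
        sessions = []
        for g, late_choice in (("control", 0), ("mdmc", 1)):
            for i in range(3):
                # early segment never picks the best option (class EARLY_LOW);
                # controls recover late, the lesion group does not
                choices = np.array([1] * 20 + [late_choice] * 20)
                sessions.append(
                    make_session(choices, np.ones(40, int), group=g, session_id=f"{g}{i}", phase="post")
                )
        per_session, summary = fixed_early_late(sessions, [labels] * len(sessions))
        low = summary[summary.early_class == "EARLY_LOW"].set_index("group")
        assert low.loc["control", "median_p_v1_late"] == 1.0
        assert low.loc["mdmc", "median_p_v1_late"] == 0.0
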