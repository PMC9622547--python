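"""Model-free behaviour measures: trials to criterion, perseveration,
win-stay/lose-shift, devaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn.metrics import (
    devaluation_metrics,
    perseverative_errors,
    summarize_session,
    trials_to_criterion,
    win_stay_lose_shift,
)
from revlearn.models import EWAParams, simulate_agent
from revlearn.task import (
    DevalConfig,
    DevalSession,
    SessionData,
    TrialRecord,
    build_default_task,
)


def session_from(records):
    """records: list of (stage_index, choice, correct, credits)."""
    trials = []
    counter = {}
    for s, c, ok, cr in records:
        counter[s] = counter.get(s, 0) + 1
        trials.append(
            TrialRecord(
                stage_index=s,
                stage_label=f"stage{s}",
                trial_in_stage=counter[s],
                choice=c,
                correct=ok,
                credits=cr,
                win=cr > 0,
            )
        )
    n_stages = max(s for s, *_ in records) + 1
    return SessionData("t", trials, [True] * n_stages)


class TestTrialsToCriterion:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([1, 1, 1, 1, 1, 1], 6),
            ([0, 1, 1, 1, 1, 1, 1], 7),
            ([1, 0, 1, 0, 1, 0, 1, 0], None),
            ([1, 1, 1, 0, 1, 1, 1, 1, 1, 1], 10),
        ],
    )
    def test_examples(self, flags, expected):
        assert trials_to_criterion([bool(f) for f in flags], 6) == expected

    @pytest.mark.parametrize("criterion", range(1, 11))
    def test_perfect_sequence_equals_criterion(self, criterion):
        assert trials_to_criterion([True] * 15, criterion) == criterion

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trials_to_criterion([], 6)


class TestPerseverativeErrors:
    def test_immediate_switch_scores_zero(self):
        records = [(0, 0, True, 1)] * 6 + [(1, 1, True, 1)] * 6
        assert perseverative_errors(session_from(records)) == [0]

    def test_persistent_old_target_scores_window(self):
        records = [(0, 0, True, 1)] * 6 + [(1, 0, False, 0)] * 8
        assert perseverative_errors(session_from(records)) == [6]

    def test_window_clipped_to_stage_length(self):
        records = [(0, 0, True, 1)] * 6 + [(1, 0, False, 0)] * 3
        assert perseverative_errors(session_from(records)) == [3]

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            perseverative_errors(session_from([(0, 0, True, 1)] * 6))


class TestWinStayLoseShift:
    def test_hand_enumeration(self):
        # choices A A B A, outcomes win win loss -: WS=1/2, LS=1/1
        records = [(0, 0, True, 1), (0, 0, True, 1), (0, 1, False, 0), (0, 0, True, 1)]
        res = win_stay_lose_shift(session_from(records))
        assert (res.n_win_stay, res.n_win_pairs) == (1, 2)
        assert res.win_stay == pytest.approx(0.5)
        assert (res.n_lose_shift, res.n_loss_pairs) == (1, 1)
        assert res.lose_shift == pytest.approx(1.0)

    def test_all_win_constant_choice(self):
        records = [(0, 0, True, 1)] * 5
        res = win_stay_lose_shift(session_from(records))
        assert res.win_stay == 1.0
        assert res.lose_shift is None  # zero applicable, never 0/0

    def test_strict_alternation_all_wins(self):
        records = [(0, i % 2, True, 1) for i in range(6)]
        res = win_stay_lose_shift(session_from(records))
        assert res.win_stay == 0.0

    def test_cross_stage_pairs_counted_by_default_and_excludable(self):
        records = [(0, 0, True, 1)] * 2 + [(1, 0, True, 1)] * 2
        sess = session_from(records)
        assert win_stay_lose_shift(sess).n_win_pairs == 3
        assert win_stay_lose_shift(sess, cross_stage=False).n_win_pairs == 2

    def test_stage_restriction(self):
        records = [(0, 0, True, 1)] * 3 + [(1, 0, True, 1)] * 3
        res = win_stay_lose_shift(session_from(records), stages=[1])
        assert res.n_win_pairs == 2

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            win_stay_lose_shift(session_from([(0, 0, True, 1)]))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        records = [
            (int(i // 10), int(rng.integers(0, 2)), bool(rng.random() < 0.5), int(rng.random() < 0.6))
            for i in range(n)
        ]
        sess = session_from(records)
        res = win_stay_lose_shift(sess)
        ws = [int(a.choice == b.choice) for a, b in zip(sess.trials, sess.trials[1:]) if a.win]
        ls = [int(a.choice != b.choice) for a, b in zip(sess.trials, sess.trials[1:]) if not a.win]
        assert res.n_win_pairs == len(ws) and res.n_loss_pairs == len(ls)
        if ws:
            assert res.win_stay == pytest.approx(np.mean(ws))
        if ls:
            assert res.lose_shift == pytest.approx(np.mean(ls))

    def test_credit_strata_sum_to_unstratified_totals(self):
        rng = np.random.default_rng(8)
        sess = simulate_agent(
            "ewa", EWAParams(0.7, 0.3, 3.0), build_default_task(), rng
        )
        from revlearn.task import SRL2_STAGES

        res = win_stay_lose_shift(sess, stages=SRL2_STAGES, by_credit=True)
        num = sum(n for _, n, _ in res.by_credit.values())
        den = sum(d for *_, d in res.by_credit.values())
        assert (num, den) == (res.n_win_stay, res.n_win_pairs)
        assert set(res.by_credit) <= {2, 6}

    def test_greedy_agent_win_stay_approaches_one_in_srl1(self):
        rng = np.random.default_rng(4)
        sess = simulate_agent(
            "ewa", EWAParams(1.0, 0.0, 50.0), build_default_task(), rng
        )
        from revlearn.task import SRL1_STAGES

        res = win_stay_lose_shift(sess, stages=SRL1_STAGES)
        assert res.win_stay is not None and res.win_stay > 0.95


class TestDevaluationMetrics:
    def make_deval(self, valued, devalued):
        return DevalSession(
            valued_responses=valued,
            devalued_responses=devalued,
            rating_pre={"valued": 5, "devalued": 5},
            rating_post={"valued": 5, "devalued": 2},
        )

    def test_bias_arithmetic(self):
        d = self.make_deval([3] * 10, [1] * 10)  # 30 vs 10 responses
        m = devaluation_metrics(d, DevalConfig())
        assert m.preference_ratio == pytest.approx(0.75)

    def test_equal_counts_give_half(self):
        m = devaluation_metrics(self.make_deval([2] * 10, [2] * 10), DevalConfig())
        assert m.preference_ratio == pytest.approx(0.5)

    def test_rate_is_responses_per_second(self):
        # 120 valued responses over 10 x 12 s -> 1.0 /s
        m = devaluation_metrics(self.make_deval([12] * 10, [0] * 10), DevalConfig())
        assert m.valued_rate == pytest.approx(1.0)

    def test_zero_responses_undefined_bias(self):
        m = devaluation_metrics(self.make_deval([0] * 10, [0] * 10), DevalConfig())
        assert m.preference_ratio is None

    def test_rating_change(self):
        m = devaluation_metrics(self.make_deval([1] * 10, [1] * 10), DevalConfig())
        assert m.rating_change == {"valued": 0, "devalued": -3}

    def test_block_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            devaluation_metrics(self.make_deval([1] * 5, [1] * 5), DevalConfig())


class TestSummarizeSession:
    def test_summary_phase_aggregates(self, ewa_session):
        s = summarize_session(ewa_session)
        assert len(s.trials_to_criterion) == ewa_session.n_stages_run
        for stage_idx, ttc in enumerate(s.trials_to_criterion):
            if ttc is not None:
                assert ttc >= 6
        if s.srl1_mean_trials is not None:
            assert s.srl1_mean_trials >= 6
        assert s.denominators["win_pairs"] + s.denominators["loss_pairs"] == (
            ewa_session.n_trials - 1
        )

    def test_incomplete_stages_flagged_and_excluded_from_means(self):
        records = [(0, 0, True, 1)] * 6 + [(1, 0, False, 0)] * 10
        sess = session_from(records)
        sess.stage_completion = [True, False]
        s = summarize_session(sess)
        assert s.incomplete_stages == [1]
        assert s.first_reversal_trials is None
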