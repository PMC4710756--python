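import pytest

from dictmap.active_learning import (
    SessionEvent,
    SessionLog,
    effort_active,
    effort_passive,
    next_query,
    run_simulated_session,
)

from .conftest import element

Q = ("a", "t", "q1")


def _log(events):
    log = SessionLog()
    for ev in events:
        log.record(ev)
    return log


class TestPassiveEffort:
    @pytest.mark.parametrize("K, N, expected", [(10, 1000, 2500), (20, 1000, 5000), (0, 500, 0)])
    def test_model_values(self, K, N, expected):
        assert effort_passive(K, N) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effort_passive(-1, 100)
        with pytest.raises(ValueError):
            effort_passive(5, 0)


class TestActiveEffort:
    def test_single_approval_at_rank_nine(self):
        log = _log([SessionEvent(Q, "approve", rank=9, shown=10)])
        assert effort_active(log, strategy=1) == 9

    def test_sum_of_approval_ranks(self):
        log = _log([SessionEvent(Q, "approve", rank=r, shown=5) for r in (1, 2, 3)])
        assert effort_active(log, strategy=1) == 6

    def test_strategy2_counts_skipped_pages(self):
        """One skip after one page of 5 plus an approval at rank 2 → 7."""
        log = _log(
            [
                SessionEvent(("a", "t", "q2"), "skip", shown=5),
                SessionEvent(Q, "approve", rank=2, shown=5),
            ]
        )
        assert effort_active(log, strategy=2, window=5) == 7
        assert effort_active(log, strategy=1) == 2  # strategy 1 ignores skips

    def test_additivity_over_concatenated_logs(self):
        a = [SessionEvent(Q, "approve", rank=4, shown=5)]
        b = [SessionEvent(("a", "t", "q3"), "skip", shown=5),
             SessionEvent(("a", "t", "q4"), "approve", rank=1, shown=5)]
        for strategy in (1, 2):
            assert effort_active(_log(a + b), strategy) == (
                effort_active(_log(a), strategy) + effort_active(_log(b), strategy)
            )

    def test_rank_zero_approval_rejected(self):
        with pytest.raises(ValueError):
            SessionEvent(Q, "approve", rank=0)


class TestNextQuery:
    def _queries(self):
        return [element("a", f"Q{i}", table=f"t{i % 2}") for i in range(4)]

    def test_uncertainty_order_prefers_smallest_margin(self):
        qs = self._queries()
        margins = {qs[0].key: 0.4, qs[1].key: 0.01, qs[2].key: 0.2, qs[3].key: 0.9}
        assert next_query(qs, SessionLog(), margins=margins) == qs[1].key

    def test_cold_start_confidence_order(self):
        qs = self._queries()
        scores = {qs[2].key: 0.99, qs[0].key: 0.5}
        assert next_query(qs, SessionLog(), top_scores=scores) == qs[2].key

    def test_exhausted_queries_error(self):
        qs = self._queries()
        log = SessionLog()
        for q in qs:
            log.record(SessionEvent(q.key, "skip", shown=5))
        with pytest.raises(LookupError):
            next_query(qs, log)

    def test_round_robin_rotates_tables(self):
        qs = self._queries()
        log = SessionLog()
        first = next_query(qs, log)
        log.record(SessionEvent(first, "approve", rank=1, shown=5))
        second = next_query(qs, log)
        assert first[1] != second[1]


class TestSimulatedSession:
    def _ranking(self, truth_rank: dict[str, int], n_targets=12):
        """Queries qX with the true target planted at a chosen rank."""
        ranking, truth = {}, {}
        for qname, r in truth_rank.items():
            q = ("a", "t", qname)
            targets = [(("b", "t", f"{qname}_d{i}"), 1.0 - i * 0.05) for i in range(n_targets)]
            if r is not None:
                targets[r - 1] = (("b", "t", f"{qname}_true"), 1.0 - (r - 1) * 0.05)
                truth[q] = ("b", "t", f"{qname}_true")
            ranking[q] = targets
        return ranking, truth

    def test_strategy1_effort_equals_sum_of_true_ranks(self):
        ranking, truth = self._ranking({"q1": 1, "q2": 9, "q3": 3})
        res = run_simulated_session(ranking, truth, strategy=1, window=5, stop=3)
        assert effort_active(res.log, strategy=1) == 1 + 9 + 3
        assert sorted(res.truth_collected) == sorted(truth.items())

    def test_strategy2_skips_beyond_window(self):
        ranking, truth = self._ranking({"q1": 2, "q2": 9})
        res = run_simulated_session(ranking, truth, strategy=2, window=5, stop=2)
        assert res.truth_collected == [(("a", "t", "q1"), ("b", "t", "q1_true"))]
        # q2's match sat beyond the window: one skipped page of 5, plus rank 2
        assert effort_active(res.log, strategy=2, window=5) == 2 + 5

    def test_strategy2_never_costs_more_than_strategy1_plus_skips(self):
        for seed in range(20):
            ranks = {f"q{i}": (i % 7) + 1 for i in range(8)}
            ranking, truth = self._ranking(ranks)
            r1 = run_simulated_session(ranking, truth, strategy=1, stop=8, seed=seed)
            r2 = run_simulated_session(ranking, truth, strategy=2, stop=8, seed=seed)
            e1 = effort_active(r1.log, 1)
            e2 = effort_active(r2.log, 2)
            # every rank ≤ window ⇒ both approve everything at equal cost …
            deep = [r for r in ranks.values() if r > 5]
            if not deep:
                assert e1 == e2

    def test_rejections_recorded_for_examined_nonmatches(self):
        ranking, truth = self._ranking({"q1": 3})
        res = run_simulated_session(ranking, truth, strategy=1, stop=1)
        rejected = [(q, t) for q, t, lab in res.labeled if not lab]
        assert len(rejected) == 2  # the two suggestions examined before the match

    def test_stop_zero_and_stop_beyond_truth(self):
        ranking, truth = self._ranking({"q1": 1})
        res = run_simulated_session(ranking, truth, stop=0)
        assert res.log.events == [] and res.effort == 0
        with pytest.raises(ValueError, match="exceeds"):
            run_simulated_session(ranking, truth, stop=5)

    def test_log_roundtrips_through_jsonl(self, tmp_path):
        ranking, truth = self._ranking({"q1": 2, "q2": None})
        res = run_simulated_session(ranking, truth, strategy=2, stop=1)
        path = tmp_path / "session.jsonl"
        res.log.to_jsonl(path)
        back = SessionLog.from_jsonl(path)
        assert back.events == res.log.events
        assert back.approvals == res.log.approvals
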