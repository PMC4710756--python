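"""Active-learning session loop and user-effort accounting.

Training labels come from a human approving/rejecting suggestions.  The
cost of collecting them is measured in *data elements examined*.  With
the system presenting targets in description-similarity rank order, an
approved query costs the rank of its correct match: at rank 9 the user
examines 9 elements in serial order and stops.  The total effort over a
session is ``E = Σ_i r(e_i)``.

Two user strategies are modelled: **Strategy 1** keeps requesting more
suggestion pages until the correct match appears; **Strategy 2** skips a
query when the match is not in the initial window (a skip costs the
suggestions actually shown).  The passive baseline — reading the
dictionaries brute force — is estimated at ``N/4`` elements examined per
collected instance (``N`` = target-source size), i.e. ``E = K·N/4`` for
``K`` instances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

from .dictionary_model import ElementKey, ElementMetadata

ACTIONS = ("approve", "reject", "more", "skip", "end")


@dataclass(frozen=True)
class SessionEvent:
    query: ElementKey
    action: str
    rank: int | None = None  # rank acted on (approve)
    shown: int = 0  # suggestions shown to the user so far for this query

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "approve" and (self.rank is None or self.rank < 1):
            raise ValueError("approval must carry a rank ≥ 1")


@dataclass
class SessionLog:
    """Ordered record of session decisions with effort counters."""

    events: list[SessionEvent] = field(default_factory=list)
    elements_examined: int = 0
    approvals: int = 0

    def record(self, event: SessionEvent, examined: int = 0) -> None:
        if examined < 0:
            raise ValueError("examined count cannot decrease")
        self.events.append(event)
        self.elements_examined += examined
        if event.action == "approve":
            self.approvals += 1

    def queries(self) -> list[ElementKey]:
        seen: dict[ElementKey, None] = {}
        for ev in self.events:
            seen.setdefault(ev.query, None)
        return list(seen)

    # ---- JSON-lines persistence --------------------------------------

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(
                    json.dumps(
                        {"query": list(ev.query), "action": ev.action, "rank": ev.rank, "shown": ev.shown}
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "SessionLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                log.record(SessionEvent(tuple(d["query"]), d["action"], d.get("rank"), d.get("shown", 0)))
        return log


def effort_passive(K: int, N: int) -> float:
    """Estimated passive-learning effort E = K·N/4 (elements examined)."""
    if K < 0 or N < 1:
        raise ValueError("need K ≥ 0 and N ≥ 1")
    return K * N / 4


def effort_active(log: SessionLog, strategy: int = 1, window: int = 5) -> int:
    """Elements examined in a session under the given strategy's accounting.

    Strategy 1: every approved query contributes the rank of its approved
    match (``E = Σ r(e_i)``).  Strategy 2: approvals contribute rank and
    each skipped query contributes the suggestions shown before skipping.
    """
    if strategy not in (1, 2):
        raise ValueError("strategy must be 1 or 2")
    total = 0
    for ev in log.events:
        if ev.action == "approve":
            if ev.rank is None or ev.rank < 1:
                raise ValueError("approval with rank < 1 in log")
            total += ev.rank
        elif ev.action == "skip" and strategy == 2:
            total += ev.shown if ev.shown else window
    return total


def next_query(
    queries: Sequence[ElementMetadata],
    log: SessionLog,
    *,
    margins: dict[ElementKey, float] | None = None,
    top_scores: dict[ElementKey, float] | None = None,
) -> ElementKey:
    """Select the next unlabeled query element.

    With a trained model available, uncertainty sampling applies:
    smallest top-score margin first.  Before a model exists the cold
    start is description-similarity confidence order (highest top score
    first), falling back to round-robin over tables when no scores are
    available either.
    """
    done = set(log.queries())
    remaining = [q for q in queries if q.key not in done]
    if not remaining:
        raise LookupError("no unlabeled query elements remain")
    if margins is not None:
        return min(remaining, key=lambda q: (margins.get(q.key, math.inf), q.key)).key
    if top_scores is not None:
        return max(remaining, key=lambda q: (top_scores.get(q.key, -math.inf), tuple(-ord(c) for c in str(q.key)))).key
    # round-robin over tables
    by_table: dict[str, list[ElementMetadata]] = {}
    for q in remaining:
        by_table.setdefault(q.table_name.casefold(), []).append(q)
    served: dict[str, int] = {}
    for ev in log.events:
        served[ev.query[1]] = served.get(ev.query[1], 0) + 1
    table = min(sorted(by_table), key=lambda t: served.get(t, 0))
    return min(by_table[table], key=lambda q: q.key).key


@dataclass
class SessionResult:
    log: SessionLog
    labeled: list[tuple[ElementKey, ElementKey, bool]]
    truth_collected: list[tuple[ElementKey, ElementKey]]

    @property
    def effort(self) -> int:
        return self.log.elements_examined


def _serve_query(
    q: ElementKey,
    targets: list[tuple[ElementKey, float]],
    true_t: ElementKey | None,
    strategy: int,
    window: int,
    page: int,
    max_pages: int,
    log: SessionLog,
    labeled: list,
    collected: list,
) -> bool:
    """Replay the oracle user on one query; returns True on approval."""
    rank = None
    if true_t is not None:
        for i, (t, _score) in enumerate(targets, start=1):
            if t == true_t:
                rank = i
                break
    if strategy == 2 and (rank is None or rank > window):
        shown = min(window, len(targets))
        for t, _ in targets[:shown]:
            labeled.append((q, t, False))
        log.record(SessionEvent(q, "skip", shown=shown), examined=shown)
        return False
    cap = min(max_pages * page, len(targets))
    if rank is None or rank > cap:
        # Strategy 1 with no findable match: page up to the cap, give
        # up; only the carefully vetted first window is marked red.
        for t, _ in targets[: min(window, cap)]:
            labeled.append((q, t, False))
        log.record(SessionEvent(q, "skip", shown=cap), examined=cap)
        return False
    shown = min(window, len(targets))
    while shown < rank:  # request more pages until the match is visible
        log.record(SessionEvent(q, "more", shown=shown))
        shown = min(shown + page, len(targets))
    for t, _ in targets[: rank - 1]:
        labeled.append((q, t, False))
    labeled.append((q, true_t, True))
    collected.append((q, true_t))
    log.record(SessionEvent(q, "approve", rank=rank, shown=shown), examined=rank)
    return True


def run_simulated_session(
    ranking: dict[ElementKey, list[tuple[ElementKey, float]]],
    truth: dict[ElementKey, ElementKey],
    strategy: int = 2,
    window: int = 5,
    stop: int = 30,
    seed: int = 0,
    page_size: int | None = None,
    max_pages: int = 10,
    order: str = "tables",
) -> SessionResult:
    """Replay a perfect-oracle user collecting ``stop`` training matches.

    ``ranking`` maps each query key to its post-blocking targets in
    description-similarity order (with scores).  ``order`` picks the
    query-serving policy: ``"tables"`` (default) round-robins over the
    query source's tables — before a model exists this samples a
    representative mix of easy, hard and unmatchable queries, so the
    red-marked rejections include informative near-miss negatives;
    ``"confidence"`` serves highest top-similarity first.

    The oracle approves the true target when shown and marks the
    suggestions it examined without approving as rejected (for skipped
    queries, the first window — the page the user vetted).  Strategy 1
    pages through more suggestions (``page_size`` per page, defaulting to
    the window) until the match appears, giving up after ``max_pages``
    pages; Strategy 2 skips unless the match is in the first window.

    Deterministic: the seed only disambiguates otherwise-tied orderings.
    """
    if strategy not in (1, 2):
        raise ValueError("strategy must be 1 or 2")
    if stop < 0:
        raise ValueError("stop must be ≥ 0")
    if stop > len(truth):
        raise ValueError(f"stop={stop} exceeds available truth mappings ({len(truth)})")
    page = page_size or window

    log = SessionLog()
    labeled: list[tuple[ElementKey, ElementKey, bool]] = []
    collected: list[tuple[ElementKey, ElementKey]] = []
    if stop == 0:
        return SessionResult(log, labeled, collected)

    if order == "confidence":
        served = sorted(
            ranking,
            key=lambda q: (-(ranking[q][0][1] if ranking[q] else -math.inf), q),
        )
    elif order == "tables":
        by_table: dict[str, list[ElementKey]] = {}
        for q in sorted(ranking):
            by_table.setdefault(q[1], []).append(q)
        served = []
        cols = [by_table[t] for t in sorted(by_table)]
        depth_i = 0
        while any(depth_i < len(c) for c in cols):
            for c in cols:
                if depth_i < len(c):
                    served.append(c[depth_i])
            depth_i += 1
    else:
        raise ValueError(f"unknown query order {order!r}")
    for q in served:
        _serve_query(
            q, ranking[q], truth.get(q), strategy, window, page, max_pages,
            log, labeled, collected,
        )
        if len(collected) >= stop:
            break
    if served:
        log.record(SessionEvent(served[-1], "end"))
    return SessionResult(log, labeled, collected)


def run_active_session(
    pipeline,
    truth: dict[ElementKey, ElementKey],
    strategy: int = 1,
    window: int = 5,
    stop: int = 30,
    seed: int = 0,
    retrain_every: int = 5,
    negative_ratio: int = 3,
    algorithm: str = "smo",
    max_pages: int = 10,
    page_size: int | None = None,
):
    """Label collection with the model in the loop (uncertainty sampling).

    Like :func:`run_simulated_session`, but after every ``retrain_every``
    approvals the match classifier is refit on the labels gathered so
    far and the remaining queries are re-ordered by uncertainty — the
    smallest margin between the query's best match score and the 0.5
    decision boundary first — so the oracle's subsequent labels fall
    where the model is least sure.  Before the first refit, queries are
    served round-robin over tables.

    ``pipeline`` is a fitted :class:`~dictmap.pipeline.MappingPipeline`.
    Returns ``(SessionResult, final MatchModel or None)``; the final
    model is fitted on everything the session labeled.
    """
    from .classifier import train
    from .features import build_training_set

    if stop > len(truth):
        raise ValueError(f"stop={stop} exceeds available truth mappings ({len(truth)})")
    page = page_size or window
    ranking = pipeline.rankings()
    shortlist = pipeline.config.shortlist or 20

    log = SessionLog()
    labeled: list[tuple[ElementKey, ElementKey, bool]] = []
    collected: list[tuple[ElementKey, ElementKey]] = []
    done: set[ElementKey] = set()
    model = None

    def refit():
        if not any(lab for *_, lab in labeled) or not any(not lab for *_, lab in labeled):
            return None
        training = build_training_set(labeled, pipeline, negative_ratio=negative_ratio, seed=seed)
        return train(training, algorithm=algorithm, seed=seed)

    def margins() -> dict[ElementKey, float]:
        out = {}
        for q in ranking:
            if q in done or not ranking[q]:
                continue
            feats = [pipeline.feature_vector(q, t) for t, _ in ranking[q][:shortlist]]
            best = float(model.score(feats).max())
            out[q] = abs(best - 0.5)
        return out

    while len(collected) < stop:
        if model is None:
            queue = [q for q in sorted(ranking) if q not in done]
            # round-robin over tables before a model exists
            by_table: dict[str, list[ElementKey]] = {}
            for q in queue:
                by_table.setdefault(q[1], []).append(q)
            cols = [by_table[t] for t in sorted(by_table)]
            queue = [c[d] for d in range(max(map(len, cols), default=0)) for c in cols if d < len(c)]
        else:
            m = margins()
            queue = sorted(m, key=lambda q: (m[q], q))
        if not queue:
            break
        approvals_this_round = 0
        for q in queue:
            done.add(q)
            if _serve_query(
                q, ranking[q], truth.get(q), strategy, window, page, max_pages,
                log, labeled, collected,
            ):
                approvals_this_round += 1
            if len(collected) >= stop or approvals_this_round >= retrain_every:
                break
        new_model = refit()
        if new_model is not None:
            model = new_model
    if done:
        log.record(SessionEvent(next(iter(done)), "end"))
    return SessionResult(log, labeled, collected), model
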