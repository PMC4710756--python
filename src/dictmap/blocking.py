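"""Constraint-based blocking of improbable candidate pairs.

Dictionary metadata constrains what an element can possibly be: an
element coded over five distinct values cannot map to one measured on a
continuous 90–140 range.  Blocking removes such irreconcilable pairs
*before* any text scoring, shrinking the candidate space; it is
deliberately conservative — absence of constraint evidence (free-text or
unknown kinds) never blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dictionary_model import CODED, NUMERIC_RANGE, ElementMetadata
from .text_similarity import SimilarityEvidence

log = logging.getLogger(__name__)


@dataclass
class BlockingPolicy:
    """Tolerances governing which constraint combinations survive.

    ``cardinality_tolerance`` is the allowed difference between two coded
    elements' cardinalities (codes such as an ``8 = N/A`` sentinel come
    and go between datasets, so the default allows ±1); ``None`` means
    unlimited.  Range compatibility is an overlap test.
    """

    cardinality_tolerance: int | None = 1
    allow_coded_vs_text: bool = True
    allow_range_vs_text: bool = True
    enabled: bool = True


@dataclass
class CandidatePair:
    """A (query, target) pair surviving blocking, with similarity evidence."""

    query: ElementMetadata
    target: ElementMetadata
    evidence: SimilarityEvidence = field(default_factory=SimilarityEvidence)
    match_score: float | None = None


def compatible(e1: ElementMetadata, e2: ElementMetadata, policy: BlockingPolicy | None = None) -> bool:
    """True unless the two elements' constraint kinds are irreconcilable.

    Symmetric.  coded-vs-range is always incompatible; coded-vs-coded is
    incompatible when cardinalities differ beyond the tolerance;
    range-vs-range when the ranges are disjoint.  Any side without a hard
    constraint (free text / unknown) is compatible with everything,
    subject to the ``allow_*_vs_text`` switches.
    """
    policy = policy or BlockingPolicy()
    if not policy.enabled:
        return True
    k1, k2 = e1.value_kind, e2.value_kind
    hard = {CODED, NUMERIC_RANGE}
    if k1 not in hard or k2 not in hard:
        if k1 == CODED or k2 == CODED:
            return policy.allow_coded_vs_text
        if k1 == NUMERIC_RANGE or k2 == NUMERIC_RANGE:
            return policy.allow_range_vs_text
        return True
    if k1 != k2:  # coded vs numeric_range
        return False
    if k1 == CODED:
        if policy.cardinality_tolerance is None:
            return True
        assert e1.cardinality is not None and e2.cardinality is not None
        return abs(e1.cardinality - e2.cardinality) <= policy.cardinality_tolerance
    # both numeric ranges: block only if disjoint
    assert e1.range_min is not None and e2.range_min is not None
    return e1.range_min <= e2.range_max and e2.range_min <= e1.range_max  # type: ignore[operator]


def filter_candidates(
    query: ElementMetadata,
    targets: list[ElementMetadata],
    policy: BlockingPolicy | None = None,
) -> list[CandidatePair]:
    """Restrict a query's cross-product to compatible pairs.

    Returns an empty list (query unmappable on constraints) when every
    target is blocked; the blocked count is logged per query.
    """
    policy = policy or BlockingPolicy()
    survivors = [
        CandidatePair(query=query, target=t)
        for t in targets
        if compatible(query, t, policy)
    ]
    blocked = len(targets) - len(survivors)
    if blocked:
        log.debug("query %s: blocked %d of %d targets", query.element_name, blocked, len(targets))
    if not survivors:
        log.warning("query %s: all %d targets blocked (unmappable)", query.element_name, len(targets))
    return survivors


def compatibility_matrix(
    queries: list[ElementMetadata],
    targets: list[ElementMetadata],
    policy: BlockingPolicy | None = None,
) -> np.ndarray:
    """Vectorised |queries| × |targets| boolean compatibility mask.

    Agrees elementwise with :func:`compatible`; used by the pipeline to
    avoid a Python-level double loop on thousands of elements.
    """
    policy = policy or BlockingPolicy()
    nq, nt = len(queries), len(targets)
    if not policy.enabled:
        return np.ones((nq, nt), dtype=bool)

    def kinds(elems):
        return np.array([e.value_kind for e in elems])

    kq, kt = kinds(queries), kinds(targets)
    coded_q, coded_t = kq == CODED, kt == CODED
    range_q, range_t = kq == NUMERIC_RANGE, kt == NUMERIC_RANGE
    soft_q, soft_t = ~(coded_q | range_q), ~(coded_t | range_t)

    mask = np.ones((nq, nt), dtype=bool)
    # coded vs numeric_range: always blocked
    mask &= ~(coded_q[:, None] & range_t[None, :])
    mask &= ~(range_q[:, None] & coded_t[None, :])
    # soft sides gated by policy switches
    if not policy.allow_coded_vs_text:
        mask &= ~(coded_q[:, None] & soft_t[None, :])
        mask &= ~(soft_q[:, None] & coded_t[None, :])
    if not policy.allow_range_vs_text:
        mask &= ~(range_q[:, None] & soft_t[None, :])
        mask &= ~(soft_q[:, None] & range_t[None, :])
    # coded vs coded: cardinality tolerance
    if policy.cardinality_tolerance is not None:
        card_q = np.array([e.cardinality or 0 for e in queries], dtype=float)
        card_t = np.array([e.cardinality or 0 for e in targets], dtype=float)
        both_coded = coded_q[:, None] & coded_t[None, :]
        diff = np.abs(card_q[:, None] - card_t[None, :])
        mask &= ~(both_coded & (diff > policy.cardinality_tolerance))
    # range vs range: overlap
    lo_q = np.array([e.range_min if e.range_min is not None else np.nan for e in queries])
    hi_q = np.array([e.range_max if e.range_max is not None else np.nan for e in queries])
    lo_t = np.array([e.range_min if e.range_min is not None else np.nan for e in targets])
    hi_t = np.array([e.range_max if e.range_max is not None else np.nan for e in targets])
    both_range = range_q[:, None] & range_t[None, :]
    with np.errstate(invalid="ignore"):
        disjoint = (lo_q[:, None] > hi_t[None, :]) | (lo_t[None, :] > hi_q[:, None])
    mask &= ~(both_range & disjoint)
    return mask
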