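"""Per-pair feature vectors for match classification.

Each candidate (query, target) pair is described by a fixed, documented
14-feature vector combining description-text similarity (TF-IDF and
topic cosine scores and their ordinal ranks, word edit distance), the
element-name match, the metadata constraints of both sides, and the
table-correspondence score (TCS).

TCS generalizes table membership: literal table names would not transfer
to unseen tables, but the *proportion* of a source table's elements
whose best description-similarity match lands in a given target table
does.  For tables ``S`` and ``T``::

    TCS(S, T) = |{e ∈ S : best_match(e) ∈ T}| / min(|S|, |T|)

where ``best_match`` is the heuristic (blocking + similarity rank-1)
assignment, so no truth labels leak into the feature.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .blocking import CandidatePair
from .dictionary_model import ElementKey, ElementMetadata
from .name_match import SynonymMap, name_match_score
from .text_similarity import TextModels, word_edit_distance

#: Fixed feature order — stable across versions; CSV exports use it.
FEATURE_NAMES: tuple[str, ...] = (
    "tfidf_score",
    "topic_score",
    "tfidf_rank",
    "topic_rank",
    "edit_distance",
    "name_match_applicable",
    "name_score",
    "source_cardinality",
    "target_cardinality",
    "source_min",
    "source_max",
    "target_min",
    "target_max",
    "table_score",
)

#: Absent numeric constraints are encoded as NaN; the classifier layer
#: imputes them (to −1) for estimators that cannot represent missingness.
MISSING = float("nan")


@dataclass(frozen=True)
class FeatureVector:
    tfidf_score: float
    topic_score: float
    tfidf_rank: int
    topic_rank: int
    edit_distance: int
    name_match_applicable: bool
    name_score: float
    source_cardinality: float = MISSING
    target_cardinality: float = MISSING
    source_min: float = MISSING
    source_max: float = MISSING
    target_min: float = MISSING
    target_max: float = MISSING
    table_score: float = 0.0

    def to_array(self) -> np.ndarray:
        vals = []
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if v is None:
                v = MISSING
            vals.append(float(v))
        return np.array(vals, dtype=float)


def feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    return np.vstack([v.to_array() for v in vectors]) if vectors else np.empty((0, len(FEATURE_NAMES)))


def _tables(store_or_elements) -> dict[str, list[ElementMetadata]]:
    elements = list(store_or_elements)
    out: dict[str, list[ElementMetadata]] = {}
    for e in elements:
        out.setdefault(e.table_name.casefold(), []).append(e)
    return out


def table_correspondence_scores(
    storeS,
    storeT,
    best_match: dict[ElementKey, ElementKey],
) -> dict[tuple[str, str], float]:
    """Per-table-pair TCS from the heuristic best-match assignment.

    ``best_match`` maps query element keys to their description-similarity
    rank-1 target key (post blocking).  Table pairs with no crossing best
    match are simply absent (score 0).  Values are clamped to [0, 1].
    """
    tablesS = _tables(storeS)
    tablesT = _tables(storeT)
    for name, elems in list(tablesS.items()) + list(tablesT.items()):
        if not elems:
            raise ValueError(f"empty table {name!r}")
    sizeT = {t: len(v) for t, v in tablesT.items()}
    scores: dict[tuple[str, str], float] = {}
    for tabS, elems in tablesS.items():
        counts: dict[str, int] = {}
        for e in elems:
            bm = best_match.get(e.key)
            if bm is not None:
                counts[bm[1]] = counts.get(bm[1], 0) + 1
        for tabT, c in counts.items():
            denom = min(len(elems), sizeT[tabT])
            scores[(tabS, tabT)] = min(c / denom, 1.0)
    return scores


def per_pair_table_score(
    pair: CandidatePair,
    best_match: dict[ElementKey, ElementKey],
    storeS,
    storeT,
) -> float:
    """The literal per-pair TCS variant: M(eS,eT) / min table size.

    ``M`` is 1 when the query's best match lies in the target's table.
    Kept for comparison with the per-table-pair proportion used by
    default.
    """
    tablesS = _tables(storeS)
    tablesT = _tables(storeT)
    bm = best_match.get(pair.query.key)
    m = 1.0 if bm is not None and bm[1] == pair.target.table_name.casefold() else 0.0
    denom = min(
        len(tablesS[pair.query.table_name.casefold()]),
        len(tablesT[pair.target.table_name.casefold()]),
    )
    return m / denom


def extract_features(
    pair: CandidatePair,
    models: TextModels,
    tcs_map: dict[tuple[str, str], float],
    synonyms: SynonymMap | None = None,
    name_vocabulary: frozenset[str] | None = None,
) -> FeatureVector:
    """Assemble the full feature vector for one candidate pair.

    Pure in (pair evidence, models, tcs_map): similarity scores and the
    edit distance are filled from the pair's evidence when present and
    computed from the models otherwise; the *ranks* must already be
    assigned (they depend on the whole candidate set, not the pair).
    """
    q, t = pair.query, pair.target
    ev = pair.evidence
    if ev.tfidf_rank is None or ev.topic_rank is None:
        raise ValueError(
            f"pair ({q.element_name}, {t.element_name}): similarity ranks not "
            "assigned; rank the candidate set first"
        )
    tfidf = ev.tfidf_score if ev.tfidf_score is not None else models.tfidf_similarity(q, t)
    topic = ev.topic_score if ev.topic_score is not None else models.topic_similarity(q, t)
    edit = ev.edit_distance
    if edit is None:
        edit = word_edit_distance(q.description, t.description)
        ev.edit_distance = edit
    applicable, name_score = name_match_score(
        q.element_name, t.element_name, synonyms=synonyms, vocabulary=name_vocabulary
    )
    return FeatureVector(
        tfidf_score=tfidf,
        topic_score=topic,
        tfidf_rank=ev.tfidf_rank,
        topic_rank=ev.topic_rank,
        edit_distance=edit,
        name_match_applicable=applicable,
        name_score=name_score,
        source_cardinality=q.cardinality if q.cardinality is not None else MISSING,
        target_cardinality=t.cardinality if t.cardinality is not None else MISSING,
        source_min=q.range_min if q.range_min is not None else MISSING,
        source_max=q.range_max if q.range_max is not None else MISSING,
        target_min=t.range_min if t.range_min is not None else MISSING,
        target_max=t.range_max if t.range_max is not None else MISSING,
        table_score=tcs_map.get((q.table_name.casefold(), t.table_name.casefold()), 0.0),
    )


def build_training_set(
    labeled: list[tuple[ElementKey, ElementKey, bool]],
    featurizer,
    negative_ratio: int = 3,
    seed: int = 0,
) -> tuple[list[FeatureVector], list[bool]]:
    """Turn labeled pairs into (feature vector, label) training rows.

    ``labeled`` carries the approved matches (label True) and any
    explicitly rejected suggestions (label False, included exactly once).
    For each positive, ``negative_ratio`` additional negatives are
    sampled (seeded) from the query's unblocked non-matching targets, so
    the class balance is controlled regardless of how many rejections the
    session produced.  ``featurizer`` is a fitted pipeline exposing
    ``feature_vector(query_key, target_key)`` and
    ``unblocked_targets(query_key)``.
    """
    positives = [(q, t) for q, t, lab in labeled if lab]
    if not positives:
        raise ValueError("training set needs at least one labeled match")
    rng = random.Random(seed)
    rows: list[tuple[ElementKey, ElementKey, bool]] = []
    seen: set[tuple[ElementKey, ElementKey]] = set()
    for q, t, lab in labeled:
        if (q, t) not in seen:
            seen.add((q, t))
            rows.append((q, t, lab))
    n_sampled = 0
    for q, t in positives:
        pool = [tk for tk in featurizer.unblocked_targets(q) if tk != t and (q, tk) not in seen]
        take = min(negative_ratio, len(pool))
        for tk in rng.sample(pool, take):
            seen.add((q, tk))
            rows.append((q, tk, False))
            n_sampled += 1
    if n_sampled == 0 and not any(not lab for _, _, lab in labeled):
        raise ValueError("no negative examples available after blocking")
    X = [featurizer.feature_vector(q, t) for q, t, _ in rows]
    y = [lab for _, _, lab in rows]
    return X, y


def export_feature_csv(path, vectors: list[FeatureVector], labels: list[bool] | None = None) -> None:
    """Audit export: one row per pair, header in the documented order."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = list(FEATURE_NAMES) + (["label"] if labels is not None else [])
        w.writerow(header)
        for i, v in enumerate(vectors):
            row = [getattr(v, n) for n in FEATURE_NAMES]
            if labels is not None:
                row.append(int(labels[i]))
            w.writerow(row)
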