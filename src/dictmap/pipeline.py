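"""End-to-end mapping pipeline: extract → filter → score → classify → suggest.

:class:`MappingPipeline` fits the text models over a loaded store pair,
applies constraint blocking, precomputes the TF-IDF/topic similarity and
rank matrices (vectorised — the per-pair operations in the sibling
modules remain the reference semantics), derives the table-correspondence
scores from the heuristic best-match assignment, and then serves both
mapping paths:

* the **heuristic path** — rank candidates purely by description
  similarity after blocking;
* the **classifier path** — re-rank a per-query shortlist with a trained
  match classifier.

A query is *emitted* (gets a suggestion window) only when its top score
clears the path's threshold; everything else is flagged unmappable, so
queries with no counterpart do not flood the windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocking import BlockingPolicy, CandidatePair, compatibility_matrix
from .classifier import MappingSuggestion, MatchModel, suggest_matches
from .dictionary_model import ElementKey, ElementMetadata, MetadataStore
from .features import FeatureVector, extract_features, table_correspondence_scores
from .name_match import SynonymMap, load_synonyms, segment_name
from .text_similarity import SimilarityEvidence, TextModels


@dataclass
class PipelineConfig:
    topic_count: int = 20
    seed: int = 0
    window: int = 5
    #: classifier path scores only the top-``shortlist`` targets per query
    #: (by TF-IDF similarity, post blocking); ``None`` scores them all.
    shortlist: int | None = 20
    #: emission thresholds — minimum top score for a window to be emitted
    min_heuristic_score: float = 0.5
    min_match_score: float = 0.5
    negative_ratio: int = 3
    algorithm: str = "smo"
    blocking: BlockingPolicy = field(default_factory=BlockingPolicy)
    stem: bool = False


@dataclass
class MappingReport:
    """Per-query suggestion windows plus the unmappable queries."""

    suggestions: dict[ElementKey, list[MappingSuggestion]]
    unmappable: list[ElementKey]
    path: str  # "heuristic" or "classifier"
    window: int

    def to_tsv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["query", "target", "score", "rank"])
            for q in sorted(self.suggestions):
                for s in self.suggestions[q]:
                    w.writerow([f"{q[1]}/{q[2]}", f"{s.target[1]}/{s.target[2]}", f"{s.score:.6f}", s.rank])
            for q in sorted(self.unmappable):
                w.writerow([f"{q[1]}/{q[2]}", "", "", ""])


class MappingPipeline:
    """Fitted mapping machinery over one (query source, target source) pair."""

    def __init__(
        self,
        store: MetadataStore,
        sources: tuple[str, str],
        config: PipelineConfig | None = None,
        synonyms: SynonymMap | None = None,
    ) -> None:
        self.store = store
        self.sources = sources
        self.config = config or PipelineConfig()
        self.synonyms = synonyms if synonyms is not None else load_synonyms()
        self._fitted = False

    # ---- fitting ------------------------------------------------------

    def fit(self) -> "MappingPipeline":
        cfg = self.config
        src_q, src_t = self.sources
        self.queries: list[ElementMetadata] = sorted(self.store.elements_of(src_q), key=lambda e: e.key)
        self.targets: list[ElementMetadata] = sorted(self.store.elements_of(src_t), key=lambda e: e.key)
        if not self.queries or not self.targets:
            raise ValueError(f"both sources must be loaded; got {len(self.queries)} query "
                             f"and {len(self.targets)} target elements")
        self.qkeys = [e.key for e in self.queries]
        self.tkeys = [e.key for e in self.targets]
        self._qidx = {k: i for i, k in enumerate(self.qkeys)}
        self._tidx = {k: i for i, k in enumerate(self.tkeys)}

        self.models = TextModels(
            self.store, self.sources, topic_count=cfg.topic_count, seed=cfg.seed, stem=cfg.stem
        )
        rows_q = self.models.rows(self.qkeys)
        rows_t = self.models.rows(self.tkeys)
        Mq = self.models.tfidf_matrix[rows_q]
        Mt = self.models.tfidf_matrix[rows_t]
        self.sim_tfidf = np.asarray((Mq @ Mt.T).todense())
        T = self.models.topic_matrix
        Tn = T / np.maximum(np.linalg.norm(T, axis=1, keepdims=True), 1e-300)
        self.sim_topic = Tn[rows_q] @ Tn[rows_t].T
        empty_q = np.array([self.models.is_empty(k) for k in self.qkeys])
        empty_t = np.array([self.models.is_empty(k) for k in self.tkeys])
        self.sim_tfidf[empty_q, :] = 0.0
        self.sim_tfidf[:, empty_t] = 0.0
        self.sim_topic[empty_q, :] = 0.0
        self.sim_topic[:, empty_t] = 0.0
        np.clip(self.sim_tfidf, 0.0, 1.0, out=self.sim_tfidf)
        np.clip(self.sim_topic, 0.0, 1.0, out=self.sim_topic)

        self.mask = compatibility_matrix(self.queries, self.targets, cfg.blocking)

        t_names = np.array([e.element_name.casefold() for e in self.targets])
        t_tables = np.array([e.table_name.casefold() for e in self.targets])
        self.rank_tfidf, self._order_tfidf = self._rank_matrix(self.sim_tfidf, t_names, t_tables)
        self.rank_topic, _ = self._rank_matrix(self.sim_topic, t_names, t_tables)

        # heuristic best match (similarity rank 1 post blocking) → TCS
        best: dict[ElementKey, ElementKey] = {}
        for i, q in enumerate(self.qkeys):
            order = self._order_tfidf[i]
            if order.size and self.mask[i, order[0]]:
                best[q] = self.tkeys[order[0]]
        self.best_match = best
        self.tcs_map = table_correspondence_scores(self.queries, self.targets, best)

        vocab: set[str] = set()
        for e in list(self.queries) + list(self.targets):
            vocab.update(segment_name(e.element_name).components)
        vocab.update(self.synonyms)
        self.name_vocabulary = frozenset(vocab)
        self._fv_cache: dict[tuple[ElementKey, ElementKey], FeatureVector] = {}
        self._fitted = True
        return self

    def _rank_matrix(self, sims: np.ndarray, t_names, t_tables) -> tuple[np.ndarray, list]:
        """Ordinal ranks (1 = best) over unblocked targets per query row.

        Tie-break (score desc, target name asc, target table asc) — the
        same ordering as :func:`dictmap.text_similarity.rank_targets`.
        Blocked targets get rank 0 (invalid).
        """
        nq, nt = sims.shape
        ranks = np.zeros((nq, nt), dtype=np.int32)
        orders = []
        for i in range(nq):
            s = np.where(self.mask[i], sims[i], -np.inf)
            order = np.lexsort((t_tables, t_names, -s))
            n_ok = int(self.mask[i].sum())
            order = order[:n_ok] if n_ok else order[:0]
            # lexsort put blocked (-inf) rows last only among equal names;
            # filter explicitly to be safe
            order = order[self.mask[i][order]]
            ranks[i, order] = np.arange(1, len(order) + 1)
            orders.append(order)
        return ranks, orders

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("pipeline not fitted; call fit() first")

    # ---- per-pair services -------------------------------------------

    def unblocked_targets(self, qkey: ElementKey) -> list[ElementKey]:
        self._require_fitted()
        i = self._qidx[qkey]
        return [self.tkeys[j] for j in np.flatnonzero(self.mask[i])]

    def evidence(self, qkey: ElementKey, tkey: ElementKey) -> SimilarityEvidence:
        self._require_fitted()
        i, j = self._qidx[qkey], self._tidx[tkey]
        return SimilarityEvidence(
            tfidf_score=float(self.sim_tfidf[i, j]),
            topic_score=float(self.sim_topic[i, j]),
            tfidf_rank=int(self.rank_tfidf[i, j]) or None,
            topic_rank=int(self.rank_topic[i, j]) or None,
        )

    def pair(self, qkey: ElementKey, tkey: ElementKey) -> CandidatePair:
        return CandidatePair(
            query=self.store.get(qkey), target=self.store.get(tkey), evidence=self.evidence(qkey, tkey)
        )

    def feature_vector(self, qkey: ElementKey, tkey: ElementKey) -> FeatureVector:
        self._require_fitted()
        hit = self._fv_cache.get((qkey, tkey))
        if hit is not None:
            return hit
        fv = extract_features(
            self.pair(qkey, tkey),
            self.models,
            self.tcs_map,
            synonyms=self.synonyms,
            name_vocabulary=self.name_vocabulary,
        )
        self._fv_cache[(qkey, tkey)] = fv
        return fv

    # ---- session support ---------------------------------------------

    def rankings(self, depth: int | None = 50) -> dict[ElementKey, list[tuple[ElementKey, float]]]:
        """Per-query post-blocking targets in similarity order, truncated
        to ``depth`` (the active-learning session never pages deeper)."""
        self._require_fitted()
        out: dict[ElementKey, list[tuple[ElementKey, float]]] = {}
        for i, q in enumerate(self.qkeys):
            order = self._order_tfidf[i][:depth]
            out[q] = [(self.tkeys[j], float(self.sim_tfidf[i, j])) for j in order]
        return out

    # ---- reports ------------------------------------------------------

    def heuristic_report(self, window: int | None = None, min_score: float | None = None) -> MappingReport:
        """Blocking + description-similarity ranking (no classifier)."""
        self._require_fitted()
        window = window or self.config.window
        min_score = self.config.min_heuristic_score if min_score is None else min_score
        suggestions: dict[ElementKey, list[MappingSuggestion]] = {}
        unmappable: list[ElementKey] = []
        for i, q in enumerate(self.qkeys):
            order = self._order_tfidf[i][:window]
            if order.size == 0 or self.sim_tfidf[i, order[0]] < min_score:
                unmappable.append(q)
                continue
            suggestions[q] = [
                MappingSuggestion(query=q, target=self.tkeys[j], score=float(self.sim_tfidf[i, j]), rank=r)
                for r, j in enumerate(order, start=1)
            ]
        return MappingReport(suggestions, unmappable, path="heuristic", window=window)

    def classifier_report(
        self,
        model: MatchModel,
        window: int | None = None,
        min_score: float | None = None,
        shortlist: int | None = None,
    ) -> MappingReport:
        """Re-rank each query's similarity shortlist with the match model."""
        self._require_fitted()
        window = window or self.config.window
        min_score = self.config.min_match_score if min_score is None else min_score
        shortlist = shortlist if shortlist is not None else self.config.shortlist
        suggestions: dict[ElementKey, list[MappingSuggestion]] = {}
        unmappable: list[ElementKey] = []
        for i, q in enumerate(self.qkeys):
            order = self._order_tfidf[i]
            if shortlist is not None:
                order = order[:shortlist]
            if order.size == 0:
                unmappable.append(q)
                continue
            cands = [self.pair(q, self.tkeys[j]) for j in order]
            feats = [self.feature_vector(q, self.tkeys[j]) for j in order]
            window_suggestions = suggest_matches(self.store.get(q), model, cands, feats, window=window)
            if not window_suggestions or window_suggestions[0].score < min_score:
                unmappable.append(q)
                continue
            suggestions[q] = window_suggestions
        return MappingReport(suggestions, unmappable, path="classifier", window=window)
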