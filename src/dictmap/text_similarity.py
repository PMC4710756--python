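"""Description-text similarity between data elements.

Two unsupervised similarity routes over the element descriptions:

* **TF-IDF cosine** on a bag-of-words representation;
* **topic-model cosine** on per-document topic distributions from a
  latent Dirichlet allocation model fitted over all descriptions of the
  two sources being mapped.

Plus a word-level (token-sequence) Levenshtein distance and ordinal
ranking of candidate targets per query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import (
    ENGLISH_STOP_WORDS,
    CountVectorizer,
    TfidfVectorizer,
)

from .dictionary_model import ElementKey, ElementMetadata, MetadataStore

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str, stopwords: frozenset[str] | None = None, stem: bool = False) -> list[str]:
    """Lowercase, split on non-alphanumerics, optionally drop stopwords.

    ``stem=True`` applies a minimal plural-stripping rule (trailing ``s``
    on tokens longer than three characters); full stemming is deliberately
    not the default since element descriptions are short and stemming can
    conflate clinically distinct terms.
    """
    toks = _TOKEN_RE.findall(text.lower())
    if stopwords is not None:
        toks = [t for t in toks if t not in stopwords]
    if stem:
        toks = [t[:-1] if len(t) > 3 and t.endswith("s") and not t.endswith("ss") else t for t in toks]
    return toks


DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)


@dataclass
class SimilarityEvidence:
    """Similarity measurements attached to one candidate pair.

    ``None`` means not yet computed (empty descriptions legitimately
    score 0.0, so absence must be distinguishable from zero).
    """

    tfidf_score: float | None = None
    topic_score: float | None = None
    tfidf_rank: int | None = None
    topic_rank: int | None = None
    edit_distance: int | None = None


class _Analyzer:
    """Picklable tokenizer closure for the sklearn vectorizers."""

    def __init__(self, stopwords: frozenset[str], stem: bool) -> None:
        self.stopwords = stopwords
        self.stem = stem

    def __call__(self, text: str) -> list[str]:
        return tokenize(text, self.stopwords, self.stem)


class TextModels:
    """TF-IDF vectorizer + topic model fitted over two sources' descriptions.

    The corpus is every element description of both sources, ordered by
    element key for reproducibility.  With a fixed ``seed`` the topic
    distributions are bit-identical across runs.
    """

    def __init__(
        self,
        store: MetadataStore,
        sources: tuple[str, str],
        topic_count: int = 20,
        seed: int = 0,
        stopwords: frozenset[str] | None = DEFAULT_STOPWORDS,
        stem: bool = False,
    ) -> None:
        if topic_count < 2:
            raise ValueError("topic_count must be ≥ 2")
        self.sources = sources
        self.topic_count = topic_count
        self.seed = seed
        self._analyzer = _Analyzer(stopwords if stopwords is not None else frozenset(), stem)

        elements = sorted(
            (e for s in sources for e in store.elements_of(s)), key=lambda e: e.key
        )
        if not elements:
            raise ValueError(f"no elements loaded for sources {sources}")
        self._keys: list[ElementKey] = [e.key for e in elements]
        self._index: dict[ElementKey, int] = {k: i for i, k in enumerate(self._keys)}
        corpus = [e.description for e in elements]
        n_nonempty = sum(1 for d in corpus if self._analyzer(d))
        if n_nonempty == 0:
            raise ValueError("all element descriptions are empty; nothing to fit")
        if n_nonempty < topic_count:
            raise ValueError(
                f"only {n_nonempty} non-empty descriptions for {topic_count} topics"
            )

        self._tfidf = TfidfVectorizer(analyzer=self._analyzer)
        self.tfidf_matrix = self._tfidf.fit_transform(corpus)  # rows l2-normalised

        self._counts = CountVectorizer(analyzer=self._analyzer)
        counts = self._counts.fit_transform(corpus)
        self._lda = LatentDirichletAllocation(
            n_components=topic_count,
            random_state=seed,
            learning_method="batch",
            max_iter=30,
        )
        self.topic_matrix = self._lda.fit_transform(counts)
        self._empty = np.asarray(counts.sum(axis=1)).ravel() == 0

    # ---- lookups ------------------------------------------------------

    def keys(self, source_id: str | None = None) -> list[ElementKey]:
        if source_id is None:
            return list(self._keys)
        return [k for k in self._keys if k[0] == source_id]

    def row(self, key: ElementKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"element {key} not in the fitted corpus") from None

    def rows(self, keys: Iterable[ElementKey]) -> np.ndarray:
        return np.array([self.row(k) for k in keys], dtype=int)

    def is_empty(self, key: ElementKey) -> bool:
        """True when the element's description has no tokens after analysis."""
        return bool(self._empty[self.row(key)])

    def vocabulary(self) -> list[str]:
        return list(self._tfidf.get_feature_names_out())

    # ---- similarities -------------------------------------------------

    def tfidf_similarity(self, e1: ElementKey | ElementMetadata, e2: ElementKey | ElementMetadata) -> float:
        i, j = self.row(_key(e1)), self.row(_key(e2))
        if self._empty[i] or self._empty[j]:
            return 0.0
        v = (self.tfidf_matrix[i] @ self.tfidf_matrix[j].T).toarray().item()
        return float(min(max(v, 0.0), 1.0))

    def topic_similarity(self, e1: ElementKey | ElementMetadata, e2: ElementKey | ElementMetadata) -> float:
        i, j = self.row(_key(e1)), self.row(_key(e2))
        if self._empty[i] or self._empty[j]:
            return 0.0
        return float(_cosine(self.topic_matrix[i], self.topic_matrix[j]))


def _key(e: ElementKey | ElementMetadata) -> ElementKey:
    return e.key if isinstance(e, ElementMetadata) else e


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def build_text_models(
    store: MetadataStore,
    sources: tuple[str, str],
    topic_count: int = 20,
    seed: int = 0,
    **kwargs,
) -> TextModels:
    """Fit TF-IDF and topic models over both sources' descriptions."""
    return TextModels(store, sources, topic_count=topic_count, seed=seed, **kwargs)


def tfidf_similarity(e1, e2, models: TextModels) -> float:
    """Cosine of the two elements' TF-IDF vectors; 0 if either is empty."""
    return models.tfidf_similarity(e1, e2)


def topic_similarity(e1, e2, models: TextModels) -> float:
    """Cosine of the two elements' topic distributions."""
    return models.topic_similarity(e1, e2)


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Unit-cost Levenshtein distance between two sequences (DP, O(|a||b|))."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def word_edit_distance(d1: str, d2: str) -> int:
    """Token-level Levenshtein distance between two free texts.

    Tokens are the raw lowercase alphanumeric runs — stopwords are kept,
    so the distance reflects the full wording, not the bag-of-words view.
    """
    return levenshtein(tokenize(d1), tokenize(d2))


def rank_targets(query: ElementMetadata, candidates: list, key: str = "tfidf") -> list:
    """Assign ordinal ranks (1 = best) to a query's candidate pairs.

    ``key`` selects the score ranked: ``"tfidf"``, ``"topic"`` or
    ``"match"`` (classifier score).  Ties break deterministically by
    (score desc, target element name asc, target table asc); the rank
    fields of each candidate's evidence are updated in place and the
    candidates are returned sorted.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if any(c.query.key != query.key for c in candidates):
        raise ValueError("candidates must all share the query element")

    def score(c) -> float:
        if key == "tfidf":
            return c.evidence.tfidf_score
        if key == "topic":
            return c.evidence.topic_score
        if key == "match":
            return c.match_score
        raise ValueError(f"unknown ranking key {key!r}")

    ordered = sorted(
        candidates,
        key=lambda c: (-score(c), c.target.element_name.casefold(), c.target.table_name.casefold()),
    )
    for rank, c in enumerate(ordered, start=1):
        if key == "tfidf":
            c.evidence.tfidf_rank = rank
        elif key == "topic":
            c.evidence.topic_rank = rank
    return ordered
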