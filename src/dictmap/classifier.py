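"""Match/non-match classification over candidate-pair feature vectors.

A small suite of supervised classifiers (the hybrid SMO-style SVM is the
default, as it performs best for this task) is trained on labeled
element pairs; every fitted model exposes a calibrated match score in
[0, 1] so suggestion windows are comparable across algorithms.
Non-probabilistic margins are mapped through a logistic link on the
decision value.
"""

from __future__ import annotations

import pickle
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .blocking import CandidatePair
from .dictionary_model import ElementKey
from .features import FEATURE_NAMES, FeatureVector, feature_matrix

_ARCHIVE_VERSION = 1

#: Supported algorithm tags.
ALGORITHMS = ("smo", "linear-margin", "logistic", "random-forest", "decision-tree", "mlp")


def _make_estimator(algorithm: str, seed: int):
    # estimator hyperparameters stay at library defaults; the session
    # training sets are negative-heavy, which an unweighted margin turns
    # into a deliberately conservative match boundary
    scaled = True
    if algorithm == "smo":
        est = SVC(kernel="rbf", C=1.0, random_state=seed)
    elif algorithm == "linear-margin":
        est = LinearSVC(C=1.0, random_state=seed, max_iter=10_000)
    elif algorithm == "logistic":
        est = LogisticRegression(max_iter=5_000, random_state=seed)
    elif algorithm == "random-forest":
        est = RandomForestClassifier(n_estimators=200, random_state=seed)
        scaled = False
    elif algorithm == "decision-tree":
        est = DecisionTreeClassifier(random_state=seed)  # CART
        scaled = False
    elif algorithm == "mlp":
        est = MLPClassifier(hidden_layer_sizes=(16,), max_iter=3_000, random_state=seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    steps = [("impute", SimpleImputer(strategy="constant", fill_value=-1.0))]
    if scaled:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", est))
    return Pipeline(steps)


@dataclass
class MatchModel:
    """A fitted match classifier with its training metadata."""

    algorithm: str
    pipeline: Pipeline
    seed: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    trained_at: float = field(default_factory=time.time)

    def score(self, X) -> np.ndarray:
        """Match scores in [0, 1] for feature vectors or a feature matrix."""
        if isinstance(X, FeatureVector):
            X = [X]
        if isinstance(X, list) and X and isinstance(X[0], FeatureVector):
            X = feature_matrix(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        clf = self.pipeline.named_steps["clf"]
        if hasattr(clf, "predict_proba"):
            return self.pipeline.predict_proba(X)[:, 1]
        return expit(self.pipeline.decision_function(X))

    def save(self, path) -> None:
        """Write a versioned, self-describing model archive."""
        payload = {
            "format_version": _ARCHIVE_VERSION,
            "algorithm": self.algorithm,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "trained_at": self.trained_at,
            "pipeline": self.pipeline,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MatchModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {payload.get('format_version')}")
        if tuple(payload["feature_names"]) != FEATURE_NAMES:
            raise ValueError("model archive feature order differs from this version's")
        return cls(
            algorithm=payload["algorithm"],
            pipeline=payload["pipeline"],
            seed=payload["seed"],
            feature_names=tuple(payload["feature_names"]),
            trained_at=payload["trained_at"],
        )


def train(training_set, algorithm: str = "smo", seed: int = 0) -> MatchModel:
    """Fit a match classifier on (feature vectors, labels).

    ``training_set`` is a ``(X, y)`` pair where X is a list of
    :class:`FeatureVector` or an array.  Both classes must be present.
    Fixed seed reproduces identical predictions.
    """
    X, y = training_set
    if isinstance(X, list) and X and isinstance(X[0], FeatureVector):
        X = feature_matrix(X)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; cannot fit")
    pipe = _make_estimator(algorithm, seed)
    pipe.fit(X, y)
    return MatchModel(algorithm=algorithm, pipeline=pipe, seed=seed)


@dataclass(frozen=True)
class MappingSuggestion:
    """One ranked, scored proposed match inside a suggestion window."""

    query: ElementKey
    target: ElementKey
    score: float
    rank: int


def suggest_matches(
    query,
    model: MatchModel,
    candidates: list[CandidatePair],
    features: list[FeatureVector],
    window: int = 5,
) -> list[MappingSuggestion]:
    """Top-``window`` candidates by match score (fewer if scarce).

    Scores are written back onto the candidates; ties break by (score
    desc, target name asc, target table asc) as everywhere else.
    """
    if not candidates:
        return []
    if len(candidates) != len(features):
        raise ValueError("candidates and features must align")
    scores = model.score(features)
    for c, s in zip(candidates, scores):
        c.match_score = float(s)
    ordered = sorted(
        candidates,
        key=lambda c: (-c.match_score, c.target.element_name.casefold(), c.target.table_name.casefold()),
    )
    return [
        MappingSuggestion(query=c.query.key, target=c.target.key, score=c.match_score, rank=r)
        for r, c in enumerate(ordered[:window], start=1)
    ]


# ---- feature diagnostics ---------------------------------------------


def _entropy(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(col: np.ndarray, max_bins: int = 10) -> np.ndarray:
    """Bin one feature column: NaN is its own bin; ≤ ``max_bins`` distinct
    values are kept as categories; otherwise equal-width bins over the
    observed range."""
    out = np.full(col.shape, -1, dtype=int)  # NaN bin
    finite = np.isfinite(col)
    vals = col[finite]
    if vals.size == 0:
        return out
    uniq = np.unique(vals)
    if uniq.size <= max_bins:
        out[finite] = np.searchsorted(uniq, vals)
        return out
    lo, hi = vals.min(), vals.max()
    width = (hi - lo) / max_bins
    bins = np.minimum(((vals - lo) / width).astype(int), max_bins - 1)
    out[finite] = bins
    return out


def feature_information_gain(training_set, max_bins: int = 10) -> list[tuple[str, float]]:
    """Entropy-based information gain of each feature for the match label.

    IG(f) = H(label) − Σ_b p(b)·H(label | bin b), with continuous
    features discretized into at most ``max_bins`` equal-width bins (NaN
    forms its own bin).  Returned sorted by gain, descending.
    """
    X, y = training_set
    if isinstance(X, list) and X and isinstance(X[0], FeatureVector):
        X = feature_matrix(X)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("labeled set is empty")
    base = _entropy(y)
    gains: list[tuple[str, float]] = []
    for j, name in enumerate(FEATURE_NAMES[: X.shape[1]]):
        bins = _discretize(X[:, j], max_bins)
        cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            cond += mask.mean() * _entropy(y[mask])
        gains.append((name, max(base - cond, 0.0)))
    gains.sort(key=lambda kv: (-kv[1], kv[0]))
    return gains
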