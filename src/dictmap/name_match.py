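"""Component-wise element-name matching.

Biomedical element names are frequently compounds — ``SUBJECT_AGE``,
``MMSESCORE``, ``BPSYS`` — so whole-string comparison is brittle.  Names
are first segmented into *components* (delimiter splits, case
transitions, then greedy longest-match against a vocabulary of known
components), and component pairs are aligned and scored: exact or
synonym matches count 1, everything else a normalized character edit
similarity, with a penalty for components left unaligned.

The original system framed this as a learned "name match classifier";
here it is a deterministic rule-based scorer behind the same interface,
so a trained scorer can be substituted without touching callers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .text_similarity import levenshtein

_DELIMS_RE = re.compile(r"[^0-9A-Za-z]+")
#: split camel-case boundaries only; digits stay attached to their run
#: so opaque codes like "Q7X" remain one component
_CASE_BOUNDARY_RE = re.compile(r"(?<=[a-z])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")

SynonymMap = dict[str, frozenset[str]]


@dataclass(frozen=True)
class NameComponents:
    original: str
    components: tuple[str, ...]


def _case_split(run: str) -> list[str]:
    return [p for p in _CASE_BOUNDARY_RE.split(run) if p] or [run]


def _greedy_vocab_split(run: str, vocabulary: frozenset[str]) -> list[str]:
    """Longest-match-first segmentation of one run against a vocabulary.

    Scans left to right taking the longest vocabulary prefix at each
    position; characters that start no vocabulary word accumulate into a
    residual component kept whole.
    """
    out: list[str] = []
    residual = ""
    i = 0
    while i < len(run):
        best = 0
        for j in range(len(run), i, -1):
            if run[i:j] in vocabulary:
                best = j
                break
        if best:
            if residual:
                out.append(residual)
                residual = ""
            out.append(run[i:best])
            i = best
        else:
            residual += run[i]
            i += 1
    if residual:
        out.append(residual)
    return out


def segment_name(name: str, vocabulary: frozenset[str] | None = None) -> NameComponents:
    """Split an element name into lowercase components.

    Splits on delimiters (``_ - . `` space) and lower/upper case
    transitions; residual runs are greedily matched against the
    vocabulary (longest match first), unsegmentable runs are kept whole.
    Component concatenation preserves the name's alphanumeric content.
    """
    if not name or not name.strip():
        raise ValueError("empty element name")
    vocab = frozenset(v.lower() for v in vocabulary) if vocabulary else frozenset()
    components: list[str] = []
    for run in _DELIMS_RE.split(name):
        if not run:
            continue
        for piece in _case_split(run):
            piece_l = piece.lower()
            if piece_l in vocab or not vocab:
                components.append(piece_l)
            else:
                components.extend(_greedy_vocab_split(piece_l, vocab))
    return NameComponents(original=name, components=tuple(components))


def _component_similarity(c1: str, c2: str, synonyms: SynonymMap) -> float:
    if c1 == c2:
        return 1.0
    if c2 in synonyms.get(c1, frozenset()) or c1 in synonyms.get(c2, frozenset()):
        return 1.0
    longest = max(len(c1), len(c2))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein(c1, c2) / longest


def name_match_score(
    n1: str,
    n2: str,
    synonyms: SynonymMap | None = None,
    vocabulary: frozenset[str] | None = None,
    min_opaque_length: int = 4,
) -> tuple[bool, float]:
    """Score two element names component-wise; returns (applicable, score).

    Components are aligned greedily by best pairwise similarity; the
    score is the sum of aligned similarities divided by the larger
    component count, so unaligned components act as a penalty.  The score
    is *not applicable* when either name is a single opaque run — not in
    the vocabulary and shorter than ``min_opaque_length`` characters —
    since such names (``Q7X``) carry no lexical signal.  Identical names
    always score 1 and are applicable.
    """
    synonyms = synonyms or {}
    s1 = segment_name(n1, vocabulary)
    s2 = segment_name(n2, vocabulary)
    vocab = frozenset(v.lower() for v in vocabulary) if vocabulary else frozenset()
    # terms known through the synonym map are vocabulary for applicability
    vocab = vocab | frozenset(synonyms) | frozenset(s for v in synonyms.values() for s in v)

    def opaque(seg: NameComponents) -> bool:
        return (
            len(seg.components) == 1
            and seg.components[0] not in vocab
            and len(seg.components[0]) < min_opaque_length
        )

    applicable = n1.casefold() == n2.casefold() or not (opaque(s1) or opaque(s2))

    pairs = sorted(
        (
            (-_component_similarity(a, b, synonyms), min(a, b), max(a, b), min(i, j), max(i, j), i, j)
            for i, a in enumerate(s1.components)
            for j, b in enumerate(s2.components)
        ),
    )
    used1: set[int] = set()
    used2: set[int] = set()
    total = 0.0
    for negsim, _, _, _, _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        total += -negsim
    denom = max(len(s1.components), len(s2.components))
    score = total / denom if denom else 0.0
    return applicable, float(min(max(score, 0.0), 1.0))


def load_synonyms(path: str | Path | None = None) -> SynonymMap:
    """Load a two-column (term, synonym) delimited synonym file.

    With no path, the bundled medical-abbreviation starter list is used.
    The map is symmetric: each line adds both directions.
    """
    if path is None:
        text = resources.files("dictmap.data").joinpath("synonyms.tsv").read_text()
    else:
        text = Path(path).read_text()
    pairs: dict[str, set[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,;]+", line.lower())
        if len(parts) < 2:
            continue
        a, rest = parts[0], parts[1:]
        for b in rest:
            pairs.setdefault(a, set()).add(b)
            pairs.setdefault(b, set()).add(a)
    return {k: frozenset(v) for k, v in pairs.items()}
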