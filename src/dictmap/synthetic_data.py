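"""Paired synthetic data dictionaries with known ground truth.

Real dictionary pairs for clinical cohorts are rarely redistributable,
so every other module is exercised against generated pairs that mimic
their structure: a shared pool of assessment *concepts* (cognitive
testing, activities of daily living, vitals, demographics …) each
described in both sources with paraphrased wording, divergent element
names, consistent-unless-perturbed value constraints, and grouping into
corresponding tables — plus distractor elements unique to each source.

The generator is fully seeded; a config and seed reproduce the stores
and truth map bit-for-bit.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, replace

from .dictionary_model import (
    CODED,
    FREE_TEXT,
    NUMERIC_RANGE,
    ElementKey,
    ElementMetadata,
    MetadataStore,
)

# ---- word bank -------------------------------------------------------
# Cognitive/clinical assessment phrasing so fixtures read like real
# dictionary entries ("ability to handle bills", "blood pressure" ...).

TOPICS = [
    "memory", "recall", "recognition", "orientation", "attention", "concentration",
    "language", "naming", "fluency", "comprehension", "judgment", "reasoning",
    "bills", "finances", "shopping", "cooking", "housekeeping", "laundry",
    "dressing", "bathing", "grooming", "toileting", "feeding", "ambulation",
    "walking", "balance", "tremor", "gait", "rigidity", "posture",
    "mood", "anxiety", "depression", "apathy", "agitation", "irritability",
    "sleep", "appetite", "weight", "height", "pulse", "temperature",
    "glucose", "cholesterol", "hemoglobin", "creatinine", "vision", "hearing",
    "smoking", "alcohol", "education", "occupation", "income", "residence",
    "stroke", "diabetes", "hypertension", "headache", "dizziness", "fatigue",
]

ATTRIBUTES = [
    "score", "rating", "status", "level", "frequency", "duration",
    "severity", "count", "total", "measurement", "history", "onset",
    "change", "impairment", "ability", "difficulty", "category", "stage",
    "response", "result", "presence", "decline", "quality", "capacity",
    "type", "source", "method", "version", "flag", "comment",
    "age", "year", "interval", "percent", "ratio", "rank",
]

QUALIFIERS = [
    "subject", "informant", "clinician", "baseline", "followup", "screening",
    "recent", "current", "prior", "daily", "weekly", "monthly",
    "immediate", "delayed", "overall", "partial", "left", "right",
]

FILLERS = [
    "interview", "questionnaire", "battery", "checklist", "protocol", "session",
    "caregiver", "spouse", "household", "community", "clinic", "home",
    "morning", "evening", "year", "month", "week", "episode",
    "task", "trial", "item", "probe", "cue", "list",
    "independence", "assistance", "supervision", "reminder", "aid", "device",
    "worsening", "improvement", "stability", "fluctuation", "complaint", "concern",
    "standing", "sitting", "resting", "fasting", "repeated", "corrected",
    "verbal", "written", "visual", "auditory", "motor", "manual",
    "errors", "omissions", "intrusions", "repetitions", "latency", "speed",
    "units", "points", "percentile", "threshold", "cutoff", "norm",
    "consent", "refusal", "missing", "unknown", "estimated", "reported",
    "neurological", "cognitive", "functional", "behavioral", "physical", "social",
]

#: Paraphrase synonyms; substitution keeps descriptions on-vocabulary.
SYNONYMS: dict[str, list[str]] = {
    "memory": ["remembrance"], "recall": ["retrieval"], "recognition": ["identification"],
    "orientation": ["awareness"], "attention": ["focus"], "concentration": ["persistence"],
    "language": ["speech"], "naming": ["labeling"], "fluency": ["verbosity"],
    "comprehension": ["understanding"], "judgment": ["discernment"], "reasoning": ["logic"],
    "bills": ["payments"], "finances": ["money"], "shopping": ["errands"],
    "cooking": ["meals"], "housekeeping": ["chores"], "laundry": ["washing"],
    "dressing": ["clothing"], "bathing": ["washing"], "grooming": ["hygiene"],
    "toileting": ["continence"], "feeding": ["eating"], "ambulation": ["mobility"],
    "walking": ["locomotion"], "balance": ["stability"], "tremor": ["shaking"],
    "gait": ["stride"], "rigidity": ["stiffness"], "posture": ["stance"],
    "mood": ["affect"], "anxiety": ["worry"], "depression": ["sadness"],
    "apathy": ["indifference"], "agitation": ["restlessness"], "irritability": ["annoyance"],
    "sleep": ["rest"], "appetite": ["hunger"], "weight": ["mass"],
    "height": ["stature"], "pulse": ["heartbeat"], "temperature": ["fever"],
    "glucose": ["sugar"], "cholesterol": ["lipids"], "hemoglobin": ["hgb"],
    "creatinine": ["kidney"], "vision": ["eyesight"], "hearing": ["audition"],
    "smoking": ["tobacco"], "alcohol": ["drinking"], "education": ["schooling"],
    "occupation": ["employment"], "income": ["earnings"], "residence": ["housing"],
    "score": ["points"], "rating": ["grade"], "status": ["state"],
    "level": ["degree"], "frequency": ["rate"], "duration": ["length"],
    "severity": ["intensity"], "count": ["number"], "total": ["sum"],
    "measurement": ["reading"], "history": ["record"], "onset": ["start"],
    "change": ["shift"], "impairment": ["deficit"], "ability": ["capability"],
    "difficulty": ["trouble"], "category": ["class"], "stage": ["phase"],
    "response": ["answer"], "result": ["outcome"], "presence": ["occurrence"],
    "decline": ["deterioration"], "quality": ["caliber"], "capacity": ["capability"],
    "subject": ["participant"], "informant": ["caregiver"], "clinician": ["examiner"],
    "baseline": ["initial"], "followup": ["subsequent"], "screening": ["intake"],
    "recent": ["latest"], "current": ["present"], "prior": ["previous"],
    "daily": ["everyday"], "weekly": ["hebdomadal"], "monthly": ["periodic"],
    "immediate": ["instant"], "delayed": ["deferred"], "overall": ["global"],
    "partial": ["incomplete"], "left": ["sinistral"], "right": ["dextral"],
    "stroke": ["infarct"], "diabetes": ["diabetic"], "hypertension": ["bp"],
    "headache": ["migraine"], "dizziness": ["vertigo"], "fatigue": ["tiredness"],
    "type": ["kind"], "source": ["origin"], "method": ["procedure"],
    "version": ["revision"], "flag": ["indicator"], "comment": ["note"],
    "age": ["years"], "year": ["date"], "interval": ["gap"],
    "percent": ["percentage"], "ratio": ["proportion"], "rank": ["position"],
}

RENAME_STYLES = ("none", "abbreviate", "delimiter", "synonym", "mixed")


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of the synthetic benchmark.

    Defaults match the standard benchmark: 200 shared concepts plus 800
    distractors per source (1000 elements per side), moderate paraphrase
    and dropout noise, small constraint noise.
    """

    n_concepts: int = 200
    n_distractors_per_source: int = 800
    n_tables: int = 10
    paraphrase_rate: float = 0.3
    dropout_rate: float = 0.1
    rename_style: str = "mixed"
    constraint_noise: float = 0.05
    table_shuffle: float = 0.1
    seed: int = 0
    source_ids: tuple[str, str] = ("source_a", "source_b")

    def __post_init__(self) -> None:
        for name in ("paraphrase_rate", "dropout_rate", "constraint_noise", "table_shuffle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be ≥ 1")
        if self.rename_style not in RENAME_STYLES:
            raise ValueError(f"rename_style must be one of {RENAME_STYLES}")


@dataclass(frozen=True)
class _Concept:
    qualifier: str
    topic: str
    attribute: str
    fillers: tuple[str, ...]
    kind: str
    allowed: frozenset[str] | None
    lo: float | None
    hi: float | None


def _sample_concepts(rng: random.Random, n: int) -> list[tuple[str, str, str]]:
    """Draw ``n`` concepts with pairwise-distinct (topic, attribute) cores.

    Two elements whose descriptions differ only in a qualifier would be
    the same measurement, not distinct concepts, so uniqueness is
    enforced on the (topic, attribute) pair; the qualifier and fillers
    add within-concept detail.
    """
    space = len(TOPICS) * len(ATTRIBUTES)
    if n > space:
        raise ValueError(f"cannot draw {n} unique concepts from a space of {space}")
    picks = rng.sample(range(space), n)
    out = []
    for p in picks:
        t, a = divmod(p, len(ATTRIBUTES))
        out.append((rng.choice(QUALIFIERS), TOPICS[t], ATTRIBUTES[a]))
    return out


def _make_concept(rng: random.Random, triple: tuple[str, str, str]) -> _Concept:
    qual, topic, attr = triple
    fillers = tuple(rng.sample(FILLERS, 3))
    u = rng.random()
    if u < 0.4:
        card = rng.randint(2, 8)
        codes = [str(i) for i in range(card - 1)] + (["8"] if rng.random() < 0.5 else [str(card - 1)])
        return _Concept(qual, topic, attr, fillers, CODED, frozenset(codes), None, None)
    if u < 0.7:
        lo = float(rng.randint(0, 100))
        hi = lo + rng.randint(1, 200)
        return _Concept(qual, topic, attr, fillers, NUMERIC_RANGE, None, lo, hi)
    return _Concept(qual, topic, attr, fillers, FREE_TEXT, None, None, None)


def _paraphrase(tokens: list[str], rng: random.Random, p_sub: float, p_drop: float) -> list[str]:
    out = []
    for tok in tokens:
        if p_drop and rng.random() < p_drop:
            continue
        if p_sub and tok in SYNONYMS and rng.random() < p_sub:
            tok = rng.choice(SYNONYMS[tok])
        out.append(tok)
    return out


def _descriptions(c: _Concept, rng: random.Random, noisy: bool, cfg: GeneratorConfig) -> tuple[str, str]:
    short = [c.topic, c.attribute]
    long_ = [c.qualifier, c.topic, c.attribute] + list(c.fillers)
    if noisy:
        short = _paraphrase(short, rng, cfg.paraphrase_rate, cfg.dropout_rate)
        long_ = _paraphrase(long_, rng, cfg.paraphrase_rate, cfg.dropout_rate)
    return " ".join(short), "the " + " ".join(long_[:3]) + " of the " + " ".join(long_[3:])


def _rename(c: _Concept, rng: random.Random, style: str) -> str:
    if style == "mixed":
        style = rng.choice(("none", "abbreviate", "delimiter", "synonym"))
    comps = [c.qualifier, c.topic, c.attribute]
    if style == "synonym":
        comps = [rng.choice(SYNONYMS[w]) if w in SYNONYMS and rng.random() < 0.5 else w for w in comps]
        return "_".join(w.upper() for w in comps)
    if style == "abbreviate":
        return "_".join(w[:4].upper() for w in comps)
    if style == "delimiter":
        return "".join(w.upper() for w in comps)
    return "_".join(w.upper() for w in comps)


def _perturb_constraint(c: _Concept, rng: random.Random) -> _Concept:
    if c.kind == CODED:
        assert c.allowed is not None
        codes = sorted(c.allowed)
        if len(codes) > 2 and rng.random() < 0.5:
            codes = codes[:-1]  # drop a sentinel-ish code
        else:
            codes = codes + [str(len(codes) + 90)]  # add a code like "97 = N/A"
        return replace(c, allowed=frozenset(codes))
    if c.kind == NUMERIC_RANGE:
        assert c.lo is not None and c.hi is not None
        width = c.hi - c.lo
        shift = (rng.random() - 0.5) * 0.5 * width  # ≤ 25% shift keeps overlap
        return replace(c, lo=round(c.lo + shift, 1), hi=round(c.hi + shift, 1))
    return c


class _NameRegistry:
    def __init__(self) -> None:
        self.seen: set[tuple[str, str]] = set()

    def unique(self, table: str, name: str) -> str:
        cand, i = name, 2
        while (table, cand.casefold()) in self.seen:
            cand = f"{name}{i}"
            i += 1
        self.seen.add((table, cand.casefold()))
        return cand


def _element(
    source_id: str,
    table: str,
    name: str,
    c: _Concept,
    rng: random.Random,
    noisy: bool,
    cfg: GeneratorConfig,
) -> ElementMetadata:
    short, long_ = _descriptions(c, rng, noisy, cfg)
    return ElementMetadata(
        source_id=source_id,
        element_name=name,
        table_name=table,
        short_description=short,
        long_description=long_,
        value_kind=c.kind,
        allowed_values=c.allowed,
        range_min=c.lo,
        range_max=c.hi,
    )


def generate_pair(
    config: GeneratorConfig | None = None,
) -> tuple[MetadataStore, MetadataStore, dict[ElementKey, ElementKey]]:
    """Generate two dictionary stores and the ground-truth mapping.

    Each shared concept yields one element per source: the query-source
    copy keeps the canonical phrasing and name; the target copy is
    paraphrased/renamed/perturbed per the config rates.  Concepts land in
    corresponding tables (``form_i`` ↔ ``section_i``) unless shuffled.
    The truth map has exactly ``n_concepts`` entries.
    """
    cfg = config or GeneratorConfig()
    rng = random.Random(cfg.seed)
    total = cfg.n_concepts + 2 * cfg.n_distractors_per_source
    triples = _sample_concepts(rng, total)
    src_a, src_b = cfg.source_ids
    storeS, storeT = MetadataStore(), MetadataStore()
    regS, regT = _NameRegistry(), _NameRegistry()
    truth: dict[ElementKey, ElementKey] = {}

    for triple in triples[: cfg.n_concepts]:
        c = _make_concept(rng, triple)
        ti = rng.randrange(cfg.n_tables)
        tj = ti if rng.random() >= cfg.table_shuffle else rng.randrange(cfg.n_tables)
        cT = _perturb_constraint(c, rng) if rng.random() < cfg.constraint_noise else c
        nameS = regS.unique(f"form_{ti:02d}", _rename(c, rng, "none"))
        nameT = regT.unique(f"section_{tj:02d}", _rename(c, rng, cfg.rename_style))
        eS = _element(src_a, f"form_{ti:02d}", nameS, c, rng, noisy=False, cfg=cfg)
        eT = _element(src_b, f"section_{tj:02d}", nameT, cT, rng, noisy=True, cfg=cfg)
        storeS.add(eS)
        storeT.add(eT)
        truth[eS.key] = eT.key

    for k, triple in enumerate(triples[cfg.n_concepts :]):
        c = _make_concept(rng, triple)
        tab = rng.randrange(cfg.n_tables)
        if k < cfg.n_distractors_per_source:
            table = f"form_{tab:02d}"
            name = regS.unique(table, _rename(c, rng, "none"))
            storeS.add(_element(src_a, table, name, c, rng, noisy=False, cfg=cfg))
        else:
            table = f"section_{tab:02d}"
            name = regT.unique(table, _rename(c, rng, cfg.rename_style))
            storeT.add(_element(src_b, table, name, c, rng, noisy=True, cfg=cfg))
    return storeS, storeT, truth


def write_truth_tsv(path, truth: dict[ElementKey, ElementKey]) -> None:
    """Truth map as two-column TSV of ``table/element`` keys."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for ks, kt in truth.items():
            w.writerow([f"{ks[1]}/{ks[2]}", f"{kt[1]}/{kt[2]}"])


def read_truth_tsv(path, source_ids: tuple[str, str]) -> dict[ElementKey, ElementKey]:
    truth: dict[ElementKey, ElementKey] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or len(row) < 2:
                continue
            ts, ns = row[0].split("/", 1)
            tt, nt = row[1].split("/", 1)
            truth[(source_ids[0], ts.casefold(), ns.casefold())] = (
                source_ids[1],
                tt.casefold(),
                nt.casefold(),
            )
    return truth
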