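"""Text preparation, dictionary NER and trigger-pattern event extraction.

This stage mirrors the front half of a semi-automated curation pipeline:
clean PDF-derived text, keep the factual sections (abstract / methods /
results), split sentences, recognize entities by dictionary longest-match,
and detect regulation events from trigger verbs.  The NER and event
extractors are deliberately rule-based stand-ins for heavyweight tools
(ProMiner-style dictionary taggers; SVM event extractors such as TEES) with
the same output contracts, so real tools can be plugged in behind the same
interface.

All character offsets are 0-based, half-open, over the *cleaned* text.
"""

from __future__ import annotations

import csv
import enum
import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Section",
    "Passage",
    "Dictionary",
    "DictionaryError",
    "Mention",
    "EventType",
    "Event",
    "RecallReport",
    "clean_text",
    "select_sections",
    "segment_sentences",
    "ner",
    "extract_events",
    "evaluate_recall",
    "DEFAULT_TRIGGERS",
]


class Section(enum.Enum):
    abstract = "abstract"
    methods = "methods"
    results = "results"
    introduction = "introduction"
    discussion = "discussion"
    conclusion = "conclusion"
    other = "other"


#: sections retained for knowledge extraction (factual content)
RETAINED_SECTIONS = frozenset({Section.abstract, Section.methods, Section.results})


@dataclass
class Passage:
    """A section-scoped stretch of cleaned article text."""

    pmid: str
    section: Section
    text: str
    sentences: list[tuple[tuple[int, int], str]] = field(default_factory=list)


class BelClass(enum.Enum):
    """Entity class a dictionary maps to, deciding the BEL function later."""

    gene_protein = "gene_protein"
    chemical = "chemical"
    process = "process"
    complex = "complex"
    family = "family"


class DictionaryError(ValueError):
    pass


#: gene symbols are short and case-significant; longer words are not
SHORT_TOKEN_LIMIT = 4


@dataclass
class Dictionary:
    """A namespace-scoped synonym dictionary for longest-match NER.

    ``entries`` maps the preferred id to its synonym set (the preferred name
    should be included).  A synonym mapping to two ids within one dictionary
    is a curation error and is rejected at load time.
    """

    namespace: str
    bel_class: BelClass
    entries: dict[str, set[str]]
    case_policy: str = "case-insensitive-long-words"  # or "exact"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pref_id, synonyms in self.entries.items():
            if not synonyms:
                raise DictionaryError(f"{self.namespace}:{pref_id} has no synonyms")
            for syn in synonyms:
                key = self._fold(syn)
                if key in seen and seen[key] != pref_id:
                    raise DictionaryError(
                        f"synonym {syn!r} maps to both {seen[key]!r} and "
                        f"{pref_id!r} in {self.namespace}"
                    )
                seen[key] = pref_id
        self._index = seen
        self._max_tokens = max(
            (len(_tokenize_words(s)) for syns in self.entries.values() for s in syns),
            default=1,
        )

    def _fold(self, synonym: str) -> str:
        if self.case_policy == "exact" or len(synonym) <= SHORT_TOKEN_LIMIT:
            return synonym
        return synonym.lower()

    def lookup(self, text: str) -> Optional[str]:
        """Preferred id for a surface form, honouring the case policy."""
        return self._index.get(self._fold(text))

    @classmethod
    def from_tsv(
        cls, stream, bel_class: BelClass, namespace: Optional[str] = None
    ) -> "Dictionary":
        """Load from TSV with columns id, preferred_name, synonyms (pipe-sep), namespace."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        reader = csv.DictReader(stream, delimiter="\t")
        entries: dict[str, set[str]] = {}
        ns = namespace
        for row in reader:
            ns = ns or row["namespace"]
            syns = {row["preferred_name"]}
            if row.get("synonyms"):
                syns.update(s for s in row["synonyms"].split("|") if s)
            entries[row["id"]] = syns
        if ns is None:
            raise DictionaryError("empty dictionary TSV: no namespace")
        return cls(namespace=ns, bel_class=bel_class, entries=entries)


@dataclass(frozen=True)
class Mention:
    """A normalized entity mention inside one sentence."""

    char_span: tuple[int, int]  # offsets within the sentence
    matched_text: str
    namespace: str
    id: str
    bel_class: BelClass


class EventType(enum.Enum):
    Positive_regulation = "Positive_regulation"
    Negative_regulation = "Negative_regulation"


@dataclass(frozen=True)
class Event:
    """A typed regulation event; absent cause yields a fragment downstream."""

    type: EventType
    trigger_span: tuple[int, int]
    trigger_word: str
    theme: Mention
    cause: Optional[Mention] = None
    negated: bool = False


# ---------------------------------------------------------------------------
# Step-2 text preparation

_CONTROL_RE = re.compile(r"[\x00-\x08\x0b\x0c\x0e-\x1f\x7f]")
_HYPHEN_BREAK_RE = re.compile(r"(\w)-\s*\n\s*(\w)")
_LIGATURES = {
    "ﬁ": "fi",
    "ﬂ": "fl",
    "ﬀ": "ff",
    "ﬃ": "ffi",
    "ﬄ": "ffl",
    "‘": "'",
    "’": "'",
    "‚": "'",
    "“": '"',
    "”": '"',
    "„": '"',
    "–": "-",
    "—": "-",
    "−": "-",
    " ": " ",
    " ": " ",
    " ": " ",
    "​": "",
}


def clean_text(raw: str) -> str:
    """Normalize PDF-derived text for machine parsing; idempotent.

    Rejoins words hyphenated at line breaks, converts in-paragraph newlines
    to spaces, strips control characters, maps smart punctuation and
    ligatures to ASCII and collapses runs of spaces.
    """
    text = raw
    for k, v in _LIGATURES.items():
        text = text.replace(k, v)
    text = _CONTROL_RE.sub("", text)
    text = _HYPHEN_BREAK_RE.sub(r"\1\2", text)
    text = re.sub(r"\s*\n\s*", " ", text)
    text = re.sub(r"[ \t]+", " ", text)
    return text.strip()


def select_sections(passages: Sequence[Passage]) -> list[Passage]:
    """Keep abstract/methods/results passages only, order preserved.

    Introduction, discussion and conclusion sections mostly restate results
    or speculate, so they are excluded from causal-knowledge extraction.
    """
    retained = [p for p in passages if p.section in RETAINED_SECTIONS]
    pmids = {p.pmid for p in passages}
    kept = {p.pmid for p in retained}
    for pmid in sorted(pmids - kept):
        warnings.warn(
            f"article {pmid}: no abstract/methods/results passage retained",
            stacklevel=2,
        )
    return retained


# common abbreviations that end with a period but do not end a sentence
_ABBREVIATIONS = {
    "al", "fig", "figs", "dr", "e.g", "i.e", "vs", "et", "cf", "approx",
    "no", "ref", "refs", "eq", "resp",
}

_SENT_END_RE = re.compile(r"[.!?]+(?=\s)|[.!?]+$")


def segment_sentences(passage: Passage) -> Passage:
    """Sentence-split a cleaned passage in place; abbreviation-safe.

    A candidate boundary is a run of .!? followed by whitespace and an
    upper-case letter or digit; decimals ("34.1"), known abbreviations
    ("et al.", "Fig.") and periods inside parentheses do not split.
    """
    text = passage.text
    boundaries: list[int] = []
    for m in _SENT_END_RE.finditer(text):
        end = m.end()
        if end < len(text):
            rest = text[end:].lstrip()
            if not rest or not (rest[0].isupper() or rest[0].isdigit()):
                continue
        before = text[: m.start()]
        last_word = re.search(r"([A-Za-z][A-Za-z.]*)$", before)
        if last_word and last_word.group(1).lower().rstrip(".") in _ABBREVIATIONS:
            continue
        # "34. 1"-style OCR decimals: digit before the dot, digit right after
        if m.group().startswith(".") and before and before[-1].isdigit():
            after = text[end:].lstrip()
            if after and after[0].isdigit():
                continue
        if before.count("(") > before.count(")"):
            continue  # inside parenthetical
        boundaries.append(end)
    if not boundaries or boundaries[-1] < len(text):
        boundaries.append(len(text))

    sentences: list[tuple[tuple[int, int], str]] = []
    start = 0
    for b in boundaries:
        chunk = text[start:b]
        stripped = chunk.strip()
        if stripped:
            s0 = start + chunk.index(stripped[0])
            span = (s0, s0 + len(stripped))
            sentences.append((span, text[span[0]:span[1]]))
        start = b
    passage.sentences = sentences
    return passage


# ---------------------------------------------------------------------------
# dictionary NER

_WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'/+-]*")


def _tokenize_words(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def ner(sentence: str, dictionaries: Sequence[Dictionary]) -> list[Mention]:
    """Token-boundary-anchored longest-match entity recognition.

    Overlapping candidates are resolved by longer span first, then by the
    order of ``dictionaries`` (the configured priority).  Deterministic for
    a fixed sentence and dictionary priority.
    """
    tokens = _tokenize_words(sentence)
    candidates: list[tuple[int, int, int, Mention]] = []  # (start, -len, prio, mention)
    for prio, d in enumerate(dictionaries):
        max_tok = d._max_tokens
        for i in range(len(tokens)):
            for j in range(min(len(tokens), i + max_tok), i, -1):
                start, end = tokens[i][0], tokens[j - 1][1]
                surface = sentence[start:end]
                pref = d.lookup(surface)
                if pref is not None:
                    candidates.append(
                        (
                            start,
                            -(end - start),
                            prio,
                            Mention((start, end), surface, d.namespace, pref, d.bel_class),
                        )
                    )
                    break  # longest match at this start for this dictionary
    # greedy resolution: longer spans win, then dictionary priority
    chosen: list[Mention] = []
    occupied: list[tuple[int, int]] = []
    for _, neg_len, _, mention in sorted(
        candidates, key=lambda c: (c[1], c[0], c[2])
    ):
        s, e = mention.char_span
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        chosen.append(mention)
        occupied.append((s, e))
    chosen.sort(key=lambda m: m.char_span)
    return chosen


# ---------------------------------------------------------------------------
# trigger-pattern event extraction

#: default trigger lemmas -> event polarity
DEFAULT_TRIGGERS: dict[str, EventType] = {
    "increase": EventType.Positive_regulation,
    "induce": EventType.Positive_regulation,
    "promote": EventType.Positive_regulation,
    "upregulate": EventType.Positive_regulation,
    "enhance": EventType.Positive_regulation,
    "decrease": EventType.Negative_regulation,
    "inhibit": EventType.Negative_regulation,
    "reduce": EventType.Negative_regulation,
    "suppress": EventType.Negative_regulation,
    "downregulate": EventType.Negative_regulation,
}

_SUFFIXES = ("", "s", "d", "ed", "es", "ing")
_NEGATION_WORDS = {"not", "no", "never", "neither", "nor", "failed"}


def _trigger_forms(lexicon: dict[str, EventType]) -> dict[str, EventType]:
    forms: dict[str, EventType] = {}
    for lemma, etype in lexicon.items():
        stem = lemma[:-1] if lemma.endswith("e") else lemma
        for suffix in _SUFFIXES:
            forms[lemma + suffix] = etype
            forms[stem + suffix] = etype
    return forms


def extract_events(
    sentence: str,
    mentions: Sequence[Mention],
    triggers: Optional[dict[str, EventType]] = None,
    keep_negated: bool = False,
) -> list[Event]:
    """Detect regulation events around trigger verbs within one sentence.

    cause = nearest mention preceding the trigger, theme = nearest mention
    following it; a trigger without a following mention yields no event.
    Negated triggers ("did not increase") are dropped unless
    ``keep_negated`` is set, in which case the event carries negated=True
    (mapped downstream to causesNoChange).
    """
    forms = _trigger_forms(triggers or DEFAULT_TRIGGERS)
    mention_spans = [m.char_span for m in mentions]
    events: list[Event] = []
    for start, end in _tokenize_words(sentence):
        word = sentence[start:end]
        etype = forms.get(word.lower())
        if etype is None:
            continue
        if any(s <= start and end <= e for s, e in mention_spans):
            continue  # trigger word inside an entity name
        preceding = [m for m in mentions if m.char_span[1] <= start]
        following = [m for m in mentions if m.char_span[0] >= end]
        if not following:
            continue
        theme = min(following, key=lambda m: m.char_span[0])
        cause = max(preceding, key=lambda m: m.char_span[1]) if preceding else None
        window = sentence[max(0, start - 30):start].lower()
        negated = any(w in _NEGATION_WORDS for w in re.findall(r"[a-z]+", window)[-3:])
        if negated and not keep_negated:
            continue
        events.append(
            Event(etype, (start, end), word, theme=theme, cause=cause, negated=negated)
        )
    return events


# ---------------------------------------------------------------------------
# recall evaluation

@dataclass
class RecallReport:
    """Per-namespace detection recall against a gold mention set."""

    per_namespace: dict[str, dict[str, float]]
    overall_gold: int
    overall_found: int
    overall_matched: int

    @property
    def overall_recall(self) -> float:
        return 100.0 * self.overall_matched / self.overall_gold if self.overall_gold else 0.0

    @property
    def overall_precision(self) -> float:
        return 100.0 * self.overall_matched / self.overall_found if self.overall_found else 0.0


def _mention_key(m: Mention, sentence_id) -> tuple:
    return (sentence_id, m.char_span, m.namespace, m.id)


def evaluate_recall(
    found: Iterable[tuple[object, Mention]],
    gold: Iterable[tuple[object, Mention]],
    namespaces: Optional[Sequence[str]] = None,
) -> RecallReport:
    """Recall of gold mentions, matched by (sentence, span, namespace, id).

    ``found`` and ``gold`` are (sentence_id, Mention) pairs so mentions from
    many sentences can be pooled.  Raises if a requested namespace has no
    gold mentions (recall undefined).
    """
    gold_list = list(gold)
    found_list = list(found)
    gold_keys = {_mention_key(m, sid) for sid, m in gold_list}
    found_keys = {_mention_key(m, sid) for sid, m in found_list}
    if namespaces:
        for ns in namespaces:
            if not any(k[2] == ns for k in gold_keys):
                raise ValueError(f"no gold mentions for namespace {ns!r}")

    all_ns = sorted({k[2] for k in gold_keys} | {k[2] for k in found_keys})
    per_ns: dict[str, dict[str, float]] = {}
    for ns in all_ns:
        g = {k for k in gold_keys if k[2] == ns}
        f = {k for k in found_keys if k[2] == ns}
        matched = len(g & f)
        per_ns[ns] = {
            "gold": len(g),
            "found": len(f),
            "matched": matched,
            "recall": 100.0 * matched / len(g) if g else 0.0,
            "precision": 100.0 * matched / len(f) if f else 0.0,
        }
    return RecallReport(
        per_namespace=per_ns,
        overall_gold=len(gold_keys),
        overall_found=len(found_keys),
        overall_matched=len(gold_keys & found_keys),
    )
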