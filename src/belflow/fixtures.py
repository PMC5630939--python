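"""Deterministic synthetic-data generators.

Every pipeline stage is testable without downloads: templated article
passages with planted entities and regulation triggers plus exactly
matching gold annotations, synthetic BEL corpora with a known duplicate
rate, and random graphs (preferential-attachment and uniform) returned in
KAM form so all topology operations apply.

The corpus generator emulates the study conditions of a small curation
exercise — seven articles, short factual sentences about vascular biology
in the ApoE-/- mouse, entities drawn from bundled HGNC/GOBP/CHEBI excerpt
dictionaries — and plants sentences that the rule-based extractors resolve
exactly, so end-to-end recall is 100% in the clean setting.  A withheld-
synonym rate renders that fraction of planted mentions with a surface form
absent from the dictionaries, degrading recall by the planted rate.
Everything is driven by one integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import networkx as nx

from .bel_core import (
    AnnotationSet,
    BelDocument,
    BelFunction,
    Evidence,
    NamespaceValue,
    Relation,
    Statement,
    StatementBlock,
    Term,
)
from .extraction import (
    DEFAULT_TRIGGERS,
    BelClass,
    Dictionary,
    EventType,
    Mention,
    Passage,
    Section,
)
from .kam import Kam

__all__ = [
    "GeneratorConfig",
    "GoldCorpus",
    "bundled_dictionaries",
    "generate_corpus",
    "generate_bel_corpus",
    "generate_graph",
    "random_statement",
    "random_statements",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """One config drives all three generators; same config, same bytes."""

    seed: int = 0
    # corpus
    n_articles: int = 7
    sentences_per_article: int = 20
    withheld_synonym_rate: float = 0.0
    fragment_rate: float = 0.1
    negation_rate: float = 0.05
    distractor_rate: float = 0.25
    # BEL corpus
    n_documents: int = 5
    statements_per_document: int = 40
    duplicate_rate: float = 0.1
    # graphs
    graph_n: int = 500
    graph_m: int = 2
    graph_p: float = 0.01
    graph_mode: str = "preferential-attachment"  # or "uniform"


def bundled_dictionaries() -> list[Dictionary]:
    """The bundled HGNC / CHEBI / GOBP excerpts, in priority order."""
    specs = [
        ("hgnc.tsv", BelClass.gene_protein),
        ("chebi.tsv", BelClass.chemical),
        ("gobp.tsv", BelClass.process),
    ]
    out = []
    for fname, bel_class in specs:
        text = resources.files("belflow.data").joinpath(fname).read_text()
        out.append(Dictionary.from_tsv(text, bel_class))
    return out


# ---------------------------------------------------------------------------
# annotated corpus


#: templates; A = cause slot, B = theme slot, T = trigger (past tense)
# templates never start with an entity slot: sentence boundaries stay
# detectable regardless of entity-name casing
_CAUSE_TEMPLATES = [
    "Notably, {A} significantly {T} {B} in ApoE-/- mice.",
    "In lesions, {A} markedly {T} {B}.",
    "Treatment with {A} {T} {B} in advanced lesions.",
    "Overexpression of {A} {T} {B} in the aortic arch.",
]
_FRAGMENT_TEMPLATES = [
    "The intervention significantly {T} {B} in ApoE-/- mice.",
    "Dietary treatment {T} {B} in the carotid artery.",
]
_NEGATION_TEMPLATES = [
    "However, {A} did not {TL} {B} in ApoE-/- mice.",
]
_DISTRACTORS = [
    "Sections were stained and examined by light microscopy.",
    "Animals were maintained on a chow diet for twelve weeks.",
    "Statistical testing used analysis of variance throughout.",
    "Samples were flash-frozen and stored until processing.",
    "All procedures were approved by the animal care committee.",
]

_PAST = {
    "increase": "increased",
    "induce": "induced",
    "promote": "promoted",
    "upregulate": "upregulated",
    "enhance": "enhanced",
    "decrease": "decreased",
    "inhibit": "inhibited",
    "reduce": "reduced",
    "suppress": "suppressed",
    "downregulate": "downregulated",
}

_CLASS_FUNCTION = {
    BelClass.gene_protein: BelFunction.proteinAbundance,
    BelClass.chemical: BelFunction.abundance,
    BelClass.process: BelFunction.biologicalProcess,
}


@dataclass
class GoldCorpus:
    """Generated passages with gold mentions, events and statements.

    Gold mention/event lists are keyed by (pmid, section, sentence index
    within the passage); statements are the BEL forms of the *detectable*
    gold events.  Withheld-synonym mentions stay in the gold mention set
    (they are the planted recall loss); an event whose theme is withheld is
    dropped from gold events, one whose cause is withheld becomes a
    cause-less (fragment) gold event.
    """

    passages: list[Passage]
    gold_mentions: list[tuple[tuple[str, int], Mention]]
    gold_events: list[tuple[tuple[str, int], dict]]
    gold_statements: list[Statement]
    dictionaries: list[Dictionary]


def _entity_pool(dictionaries: list[Dictionary]) -> list[tuple[str, str, BelClass]]:
    pool = []
    for d in dictionaries:
        for pref_id in sorted(d.entries):
            pool.append((d.namespace, pref_id, d.bel_class))
    return pool


def generate_corpus(
    cfg: GeneratorConfig, dictionaries: Optional[list[Dictionary]] = None
) -> GoldCorpus:
    rng = random.Random(cfg.seed)
    dicts = dictionaries or bundled_dictionaries()
    pool = _entity_pool(dicts)
    genes = [e for e in pool if e[2] is BelClass.gene_protein]
    chems = [e for e in pool if e[2] is BelClass.chemical]
    procs = [e for e in pool if e[2] is BelClass.process]
    triggers = sorted(DEFAULT_TRIGGERS)

    passages: list[Passage] = []
    gold_mentions: list[tuple[tuple[str, int], Mention]] = []
    gold_events: list[tuple[tuple[str, int], dict]] = []
    gold_statements: list[Statement] = []

    for art in range(cfg.n_articles):
        pmid = f"9{cfg.seed % 100:02d}{art:04d}"
        for section in (Section.abstract, Section.results):
            sentences: list[str] = []
            marks: list[Optional[dict]] = []  # planting info per sentence
            n_sent = max(1, cfg.sentences_per_article // 2)
            for _ in range(n_sent):
                roll = rng.random()
                if roll < cfg.distractor_rate:
                    sentences.append(rng.choice(_DISTRACTORS))
                    marks.append(None)
                    continue
                lemma = rng.choice(triggers)
                etype = DEFAULT_TRIGGERS[lemma]
                cause = rng.choice(genes if rng.random() < 0.7 else chems)
                theme = rng.choice(procs if rng.random() < 0.6 else genes)
                if theme == cause:
                    theme = rng.choice(procs)
                negated = rng.random() < cfg.negation_rate
                fragment = not negated and rng.random() < cfg.fragment_rate
                withheld_cause = rng.random() < cfg.withheld_synonym_rate
                withheld_theme = rng.random() < cfg.withheld_synonym_rate
                cause_text = cause[1] + "-v2" if withheld_cause else cause[1]
                theme_text = theme[1] + "-v2" if withheld_theme else theme[1]
                if negated:
                    tmpl = rng.choice(_NEGATION_TEMPLATES)
                    sentence = tmpl.format(A=cause_text, TL=lemma, B=theme_text)
                elif fragment:
                    tmpl = rng.choice(_FRAGMENT_TEMPLATES)
                    sentence = tmpl.format(T=_PAST[lemma], B=theme_text)
                else:
                    tmpl = rng.choice(_CAUSE_TEMPLATES)
                    sentence = tmpl.format(A=cause_text, T=_PAST[lemma], B=theme_text)
                sentences.append(sentence)
                marks.append(
                    {
                        "cause": None if fragment else cause,
                        "theme": theme,
                        "cause_text": None if fragment else cause_text,
                        "theme_text": theme_text,
                        "withheld_cause": withheld_cause and not fragment,
                        "withheld_theme": withheld_theme,
                        "etype": etype,
                        "negated": negated,
                        "sentence": sentence,
                    }
                )
            text = " ".join(sentences)
            passage = Passage(pmid=pmid, section=section, text=text)
            # sentence spans by construction
            offset = 0
            spans = []
            for s in sentences:
                spans.append(((offset, offset + len(s)), s))
                offset += len(s) + 1
            passage.sentences = spans
            passages.append(passage)

            for si, mark in enumerate(marks):
                if mark is None:
                    continue
                key = (pmid, section.value, si)
                sentence = mark["sentence"]
                mention_of = {}
                for role in ("cause", "theme"):
                    ent = mark[role]
                    if ent is None:
                        continue
                    surface = mark[f"{role}_text"]
                    start = sentence.index(surface)
                    ns, pid, bel_class = ent
                    m = Mention((start, start + len(surface)), surface, ns, pid, bel_class)
                    mention_of[role] = m
                    # withheld-synonym mentions stay in the gold standard:
                    # the dictionary lacks their surface form, so they are
                    # exactly the planted recall loss
                    gold_mentions.append((key, m))
                if mark["negated"]:
                    continue  # conservative default: negation yields no event
                if mark["withheld_theme"]:
                    continue  # theme undetectable: no event at all
                if mark["withheld_cause"]:
                    mention_of.pop("cause", None)  # extractor sees a fragment
                gold_events.append(
                    (
                        key,
                        {
                            "type": mark["etype"],
                            "cause": mention_of.get("cause"),
                            "theme": mention_of["theme"],
                        },
                    )
                )
                theme_term = Term(
                    _CLASS_FUNCTION[mark["theme"][2]],
                    (NamespaceValue(mark["theme"][0], mark["theme"][1]),),
                )
                cause_term = None
                if mention_of.get("cause") is not None:
                    cause_term = Term(
                        _CLASS_FUNCTION[mark["cause"][2]],
                        (NamespaceValue(mark["cause"][0], mark["cause"][1]),),
                    )
                relation = (
                    Relation.increases
                    if mark["etype"] is EventType.Positive_regulation
                    else Relation.decreases
                )
                gold_statements.append(Statement(cause_term, relation, theme_term))

        # excluded sections exercise select_sections
        intro = Passage(
            pmid=pmid,
            section=Section.introduction,
            text=rng.choice(_DISTRACTORS),
        )
        intro.sentences = [((0, len(intro.text)), intro.text)]
        passages.append(intro)

    return GoldCorpus(passages, gold_mentions, gold_events, gold_statements, dicts)


# ---------------------------------------------------------------------------
# random BEL statements and corpora


def random_term(rng: random.Random, pool: list[tuple[str, str, BelClass]]) -> Term:
    ns, pid, bel_class = rng.choice(pool)
    base = Term(_CLASS_FUNCTION[bel_class], (NamespaceValue(ns, pid),))
    roll = rng.random()
    if bel_class is BelClass.gene_protein and roll < 0.25:
        wrapper = rng.choice(
            [
                BelFunction.molecularActivity,
                BelFunction.kinaseActivity,
                BelFunction.peptidaseActivity,
                BelFunction.catalyticActivity,
                BelFunction.transcriptionalActivity,
                BelFunction.degradation,
                BelFunction.cellSecretion,
            ]
        )
        return Term(wrapper, (base,))
    if bel_class is BelClass.chemical and roll < 0.15:
        return Term(BelFunction.cellSecretion, (base,))
    if roll > 0.92:
        other = rng.choice([p for p in pool if p[2] is not BelClass.process])
        if other[:2] != (ns, pid) and bel_class is not BelClass.process:
            return Term(
                BelFunction.complexAbundance,
                (base, Term(_CLASS_FUNCTION[other[2]], (NamespaceValue(other[0], other[1]),))),
            )
    return base


def random_statement(
    rng: random.Random,
    pool: Optional[list[tuple[str, str, BelClass]]] = None,
    allow_fragment: bool = False,
    allow_nested: bool = True,
) -> Statement:
    """One random structurally valid statement; exercises the full grammar."""
    if pool is None:
        pool = _entity_pool(bundled_dictionaries())
    relation = rng.choice(
        [
            Relation.increases,
            Relation.decreases,
            Relation.directlyIncreases,
            Relation.directlyDecreases,
            Relation.causesNoChange,
            Relation.association,
        ]
    )
    subject = random_term(rng, pool)
    if allow_fragment and rng.random() < 0.15:
        if rng.random() < 0.5:
            return Statement(subject, relation, None)
        return Statement(None, relation, random_term(rng, pool))
    if allow_nested and rng.random() < 0.12:
        inner = Statement(random_term(rng, pool), Relation.increases, random_term(rng, pool))
        return Statement(subject, relation, inner)
    return Statement(subject, relation, random_term(rng, pool))


def random_statements(
    rng: random.Random, n: int, allow_fragment: bool = False
) -> list[Statement]:
    pool = _entity_pool(bundled_dictionaries())
    return [random_statement(rng, pool, allow_fragment=allow_fragment) for _ in range(n)]


def generate_bel_corpus(
    cfg: GeneratorConfig, dictionaries: Optional[list[Dictionary]] = None
) -> list[BelDocument]:
    """Synthetic BEL documents with a known duplicate-statement rate.

    Each statement gets its own evidence sentence; with probability
    ``duplicate_rate`` a statement repeats an earlier one (fresh evidence),
    so compile-time deduplication is observable in edge evidence counts.
    """
    rng = random.Random(cfg.seed + 1)
    dicts = dictionaries or bundled_dictionaries()
    pool = _entity_pool(dicts)
    from .bel_convert import DEFAULT_NAMESPACE_RESOURCES

    docs: list[BelDocument] = []
    emitted: list[Statement] = []
    for di in range(cfg.n_documents):
        doc = BelDocument(
            name=f"synthetic BEL corpus document {di}",
            version="1.0",
            annotation_definitions={"Species": "taxonomy"},
        )
        pmid = f"8{cfg.seed % 100:02d}{di:04d}"
        for si in range(cfg.statements_per_document):
            if emitted and rng.random() < cfg.duplicate_rate:
                stmt = rng.choice(emitted)
            else:
                stmt = random_statement(rng, pool, allow_fragment=False)
                emitted.append(stmt)
            ev = Evidence(
                text=f"Synthetic evidence sentence {di}-{si} for {stmt}.",
                pmid=pmid,
                section="results",
            )
            doc.blocks.append(
                StatementBlock(
                    ev,
                    AnnotationSet.from_dict({"Species": "10090"}),
                    (stmt,),
                )
            )
        for s in doc.statements():
            for part in (s.subject, s.object):
                terms = []
                if isinstance(part, Term):
                    terms = [part]
                elif isinstance(part, Statement):
                    terms = [t for t in (part.subject, part.object) if isinstance(t, Term)]
                for t in terms:
                    for nsv in t.namespace_values():
                        doc.namespaces.setdefault(
                            nsv.namespace,
                            DEFAULT_NAMESPACE_RESOURCES.get(nsv.namespace, "urn:belflow:user"),
                        )
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# random graphs in KAM form


def generate_graph(cfg: GeneratorConfig) -> Kam:
    """A random graph wrapped as a KAM so topology operations apply.

    "preferential-attachment" mode (Barabási–Albert, mean degree ~ 2m) is
    the positive control for the scale-free check; "uniform" mode
    (Erdős–Rényi G(n, p), mean degree ~ (n-1)p) the negative control.
    """
    if cfg.graph_mode == "preferential-attachment":
        if cfg.graph_n <= cfg.graph_m:  # attachment needs m existing nodes
            g = nx.empty_graph(cfg.graph_n)
        else:
            g = nx.barabasi_albert_graph(cfg.graph_n, cfg.graph_m, seed=cfg.seed)
    elif cfg.graph_mode == "uniform":
        g = nx.gnp_random_graph(cfg.graph_n, cfg.graph_p, seed=cfg.seed)
    else:
        raise ValueError(f"unknown graph_mode {cfg.graph_mode!r}")
    kam = Kam()
    for n in g.nodes:
        kam.graph.add_node(
            f"p(HGNC:GEN{n})", function="p", namespace="HGNC", value=f"GEN{n}"
        )
    rng = random.Random(cfg.seed + 2)
    for u, v in g.edges():
        rel = rng.choice([Relation.increases, Relation.decreases])
        kam.add_edge(f"p(HGNC:GEN{u})", f"p(HGNC:GEN{v})", rel)
    return kam
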