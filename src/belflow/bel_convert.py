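"""Event-to-BEL conversion, document assembly, sidecar emission and
programmatic curation edits with automatic re-validation.

The converter turns typed regulation events into BEL statements (fragments
when the cause is missing), groups them into evidence-scoped document
blocks, and writes a JSON *sidecar* alongside the XBEL: per-statement
information that BEL itself cannot carry but a curation interface needs —
entity text locations and alternative namespace candidates.

Curation edits never mutate the input document: the original is preserved
and an edited copy is returned, every surviving statement re-validated.
"""

from __future__ import annotations

import copy
import enum
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bel_core import (
    AnnotationSet,
    BelDocument,
    BelFunction,
    Evidence,
    FragmentKind,
    NamespaceValue,
    Relation,
    Statement,
    StatementBlock,
    Term,
    parse_statement,
    serialize_statement,
    validate_statement,
)
from .bel_core.parser import BelSyntaxError
from .extraction import BelClass, Dictionary, Event, EventType, Mention, Passage

__all__ = [
    "DEFAULT_CLASS_MAP",
    "ConversionError",
    "CurationError",
    "CurationEdit",
    "EditKind",
    "ExtractedStatement",
    "SidecarRecord",
    "apply_edits",
    "build_document",
    "convert_passages",
    "event_to_statement",
    "sidecar_to_json",
    "sidecar_from_json",
]

#: entity class -> BEL function for the generated term
DEFAULT_CLASS_MAP: dict[BelClass, BelFunction] = {
    BelClass.gene_protein: BelFunction.proteinAbundance,
    BelClass.chemical: BelFunction.abundance,
    BelClass.process: BelFunction.biologicalProcess,
    BelClass.complex: BelFunction.complexAbundance,
    BelClass.family: BelFunction.proteinAbundance,  # family namespace, protein term
}

#: default resource URLs declared for generated documents
DEFAULT_NAMESPACE_RESOURCES = {
    "HGNC": "https://www.genenames.org",
    "MGI": "http://www.informatics.jax.org",
    "CHEBI": "https://www.ebi.ac.uk/chebi",
    "SCHEM": "https://www.openbel.org/schem",
    "CHEMBL": "https://www.ebi.ac.uk/chembl",
    "GOBP": "http://www.geneontology.org",
    "GO": "http://www.geneontology.org",
    "MESHD": "https://www.nlm.nih.gov/mesh",
    "SFAM": "https://www.openbel.org/sfam",
    "SCOMP": "https://www.openbel.org/scomp",
}

ANNOTATION_RESOURCES = {
    "Species": "https://www.ncbi.nlm.nih.gov/taxonomy",
    "Tissue": "https://www.ebi.ac.uk/ols/ontologies/uberon",
    "Cell": "https://www.ebi.ac.uk/ols/ontologies/cl",
    "Disease": "https://www.nlm.nih.gov/mesh",
}


class ConversionError(ValueError):
    pass


def _mention_term(m: Mention, class_map: dict[BelClass, BelFunction]) -> Term:
    func = class_map.get(m.bel_class)
    if func is None:
        raise ConversionError(
            f"no BEL function mapped for class {m.bel_class.value!r} "
            f"(mention {m.namespace}:{m.id})"
        )
    return Term(func, (NamespaceValue(m.namespace, m.id),))


def event_to_statement(
    e: Event,
    class_map: Optional[dict[BelClass, BelFunction]] = None,
    negated_as_no_change: bool = False,
) -> Statement:
    """Map a regulation event to a BEL statement (fragment if cause absent).

    Positive_regulation -> increases, Negative_regulation -> decreases; the
    indirect forms, since a text-mined trigger cannot establish directness.
    Negated events map to causesNoChange when ``negated_as_no_change``.
    """
    cmap = DEFAULT_CLASS_MAP if class_map is None else class_map
    theme_term = _mention_term(e.theme, cmap)
    if e.negated and negated_as_no_change:
        relation = Relation.causesNoChange
    elif e.type is EventType.Positive_regulation:
        relation = Relation.increases
    else:
        relation = Relation.decreases
    cause_term = _mention_term(e.cause, cmap) if e.cause is not None else None
    return Statement(cause_term, relation, theme_term)


@dataclass
class ExtractedStatement:
    """A statement plus its provenance links, the converter's unit of work."""

    statement: Statement
    pmid: str
    section: str
    sentence_span: tuple[int, int]  # within the passage
    sentence_text: str
    mentions: list[Mention] = field(default_factory=list)
    alternatives: dict[tuple[int, int], list[tuple[str, str]]] = field(
        default_factory=dict
    )  # mention span -> [(namespace, id), ...]


@dataclass
class SidecarRecord:
    """Curation-interface data for one emitted statement."""

    statement_index: int
    evidence_span: tuple[int, int]
    pmid: str
    mentions: list[dict]  # char_span, matched_text, namespace, id, alternatives


def convert_passages(
    passages: Sequence[Passage],
    dictionaries: Sequence[Dictionary],
    triggers=None,
    class_map: Optional[dict[BelClass, BelFunction]] = None,
    keep_negated: bool = False,
    negated_as_no_change: bool = False,
) -> list[ExtractedStatement]:
    """Run NER + event extraction over segmented passages; convert to BEL."""
    from .extraction import extract_events, ner

    out: list[ExtractedStatement] = []
    for passage in passages:
        for (s0, s1), sentence in passage.sentences:
            mentions = ner(sentence, dictionaries)
            events = extract_events(
                sentence, mentions, triggers=triggers, keep_negated=keep_negated
            )
            for ev in events:
                stmt = event_to_statement(
                    ev, class_map=class_map, negated_as_no_change=negated_as_no_change
                )
                used = [m for m in (ev.cause, ev.theme) if m is not None]
                alts: dict[tuple[int, int], list[tuple[str, str]]] = {}
                for m in used:
                    alt: list[tuple[str, str]] = []
                    for d in dictionaries:
                        if d.namespace == m.namespace:
                            continue
                        pref = d.lookup(m.matched_text)
                        if pref is not None:
                            alt.append((d.namespace, pref))
                    alts[m.char_span] = alt
                out.append(
                    ExtractedStatement(
                        statement=stmt,
                        pmid=passage.pmid,
                        section=passage.section.value,
                        sentence_span=(s0, s1),
                        sentence_text=sentence,
                        mentions=used,
                        alternatives=alts,
                    )
                )
    return out


def build_document(
    extracted: Sequence[ExtractedStatement],
    name: str = "belflow generated document",
    description: str = "",
    document_annotations: Optional[dict[str, str]] = None,
) -> tuple[BelDocument, list[SidecarRecord]]:
    """Assemble extracted statements into a BEL document plus sidecar.

    One evidence block per distinct statement-bearing sentence; blocks and
    statements ordered by (pmid, sentence span, subject serialization) so
    identical inputs yield identical documents.  ``document_annotations``
    (e.g. {"Species": "10090"} for an ApoE-/- mouse corpus) are applied to
    every block.
    """
    annos = dict(document_annotations or {})
    for key in annos:
        if key not in ANNOTATION_RESOURCES:
            raise ConversionError(f"annotation key {key!r} has no definition")
    for rec in extracted:
        if rec.sentence_text == "" or rec.pmid == "":
            raise ConversionError(
                f"statement {serialize_statement(rec.statement)!r} lacks an evidence link"
            )

    ordered = sorted(
        extracted,
        key=lambda r: (
            r.pmid,
            r.sentence_span,
            serialize_statement(r.statement),
        ),
    )

    doc = BelDocument(name=name, description=description)
    doc.annotation_definitions = dict(ANNOTATION_RESOURCES)
    sidecar: list[SidecarRecord] = []
    anno_set = AnnotationSet.from_dict(annos)

    # group consecutive records by sentence
    index = 0
    i = 0
    while i < len(ordered):
        j = i
        key = (ordered[i].pmid, ordered[i].sentence_span)
        while j < len(ordered) and (ordered[j].pmid, ordered[j].sentence_span) == key:
            j += 1
        group = ordered[i:j]
        ev = Evidence(
            text=group[0].sentence_text,
            pmid=group[0].pmid,
            section=group[0].section,
            char_span=group[0].sentence_span,
        )
        doc.blocks.append(
            StatementBlock(ev, anno_set, tuple(r.statement for r in group))
        )
        for rec in group:
            sidecar.append(
                SidecarRecord(
                    statement_index=index,
                    evidence_span=rec.sentence_span,
                    pmid=rec.pmid,
                    mentions=[
                        {
                            "char_span": list(m.char_span),
                            "matched_text": m.matched_text,
                            "namespace": m.namespace,
                            "id": m.id,
                            "alternatives": [
                                list(a) for a in rec.alternatives.get(m.char_span, [])
                            ],
                        }
                        for m in rec.mentions
                    ],
                )
            )
            index += 1
        i = j

    for stmt in doc.statements():
        for part in (stmt.subject, stmt.object):
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
    return doc, sidecar


def sidecar_to_json(sidecar: Sequence[SidecarRecord]) -> str:
    return json.dumps(
        [
            {
                "statement_index": r.statement_index,
                "evidence_span": list(r.evidence_span),
                "pmid": r.pmid,
                "mentions": r.mentions,
            }
            for r in sidecar
        ],
        indent=2,
    )


def sidecar_from_json(text: str) -> list[SidecarRecord]:
    return [
        SidecarRecord(
            statement_index=d["statement_index"],
            evidence_span=tuple(d["evidence_span"]),
            pmid=d["pmid"],
            mentions=d["mentions"],
        )
        for d in json.loads(text)
    ]


# ---------------------------------------------------------------------------
# curation edits


class EditKind(enum.Enum):
    accept = "accept"
    reject = "reject"
    modify_statement = "modify_statement"
    assemble_fragments = "assemble_fragments"
    set_annotation = "set_annotation"


@dataclass(frozen=True)
class CurationEdit:
    kind: EditKind
    targets: tuple[int, ...]
    payload: Optional[str] = None  # replacement text, or "Key=Value"

    @classmethod
    def from_json_line(cls, line: str) -> "CurationEdit":
        d = json.loads(line)
        return cls(EditKind(d["kind"]), tuple(d.get("targets", ())), d.get("payload"))


class CurationError(ValueError):
    """An edit was refused; carries the validator's violations when relevant."""

    def __init__(self, message: str, violations=()):
        super().__init__(message)
        self.violations = list(violations)


def _global_statement_slots(doc: BelDocument) -> list[tuple[int, int]]:
    """(block index, position) of each statement, in document order."""
    slots = []
    for bi, block in enumerate(doc.blocks):
        for si in range(len(block.statements)):
            slots.append((bi, si))
    return slots


def apply_edits(
    doc: BelDocument,
    sidecar: Optional[Sequence[SidecarRecord]],
    edits: Sequence[CurationEdit],
) -> BelDocument:
    """Apply curation edits to a copy of ``doc``; the original is untouched.

    Statement targets are global 0-based indices in document order (the
    sidecar's indexing).  Every statement surviving the edits is
    re-validated; an edit that would produce an invalid statement is refused
    with the violation list.
    """
    new = copy.deepcopy(doc)
    slots = _global_statement_slots(new)
    # mutable view: per-block statement lists with removal markers
    blocks = [
        {"evidence": b.evidence, "annotations": dict(b.annotations.values),
         "statements": list(b.statements)}
        for b in new.blocks
    ]
    removed: set[int] = set()

    def check_index(i: int) -> tuple[int, int]:
        if i < 0 or i >= len(slots):
            raise CurationError(f"statement index {i} out of range (0..{len(slots) - 1})")
        if i in removed:
            raise CurationError(f"statement index {i} was already removed")
        return slots[i]

    for edit in edits:
        if edit.kind is EditKind.accept:
            for t in edit.targets:
                check_index(t)
        elif edit.kind is EditKind.reject:
            for t in edit.targets:
                bi, si = check_index(t)
                blocks[bi]["statements"][si] = None
                removed.add(t)
        elif edit.kind is EditKind.modify_statement:
            if len(edit.targets) != 1 or edit.payload is None:
                raise CurationError("modify_statement needs one target and a payload")
            bi, si = check_index(edit.targets[0])
            try:
                stmt = parse_statement(edit.payload)
            except BelSyntaxError as exc:
                raise CurationError(f"replacement does not parse: {exc}") from exc
            violations = validate_statement(stmt, new, allow_fragment=True)
            if violations:
                raise CurationError("replacement statement is invalid", violations)
            blocks[bi]["statements"][si] = stmt
        elif edit.kind is EditKind.assemble_fragments:
            if len(edit.targets) != 2:
                raise CurationError("assemble_fragments needs exactly two targets")
            (bi1, si1), (bi2, si2) = (check_index(t) for t in edit.targets)
            s1 = blocks[bi1]["statements"][si1]
            s2 = blocks[bi2]["statements"][si2]
            frags = {s1.fragment_kind, s2.fragment_kind}
            if frags != {FragmentKind.subject_relation, FragmentKind.relation_object}:
                raise CurationError(
                    "assembly requires one subject_relation and one relation_object fragment"
                )
            left, right = (
                (s1, s2) if s1.fragment_kind is FragmentKind.subject_relation else (s2, s1)
            )
            if left.relation is not right.relation:
                raise CurationError(
                    f"fragment relations disagree: {left.relation.name} vs {right.relation.name}"
                )
            assembled = Statement(left.subject, left.relation, right.object)
            violations = validate_statement(assembled, new)
            if violations:
                raise CurationError("assembled statement is invalid", violations)
            if s1.fragment_kind is FragmentKind.subject_relation:
                blocks[bi1]["statements"][si1] = assembled
                blocks[bi2]["statements"][si2] = None
                removed.add(edit.targets[1])
            else:
                blocks[bi2]["statements"][si2] = assembled
                blocks[bi1]["statements"][si1] = None
                removed.add(edit.targets[0])
        elif edit.kind is EditKind.set_annotation:
            if edit.payload is None or "=" not in edit.payload:
                raise CurationError("set_annotation payload must be 'Key=Value'")
            key, _, value = edit.payload.partition("=")
            key = key.strip()
            if key not in new.annotation_definitions:
                raise CurationError(f"annotation key {key!r} is not defined")
            for t in edit.targets:
                bi, _ = check_index(t)
                blocks[bi]["annotations"][key] = value.strip()
        else:  # pragma: no cover - enum is closed
            raise CurationError(f"unknown edit kind {edit.kind}")

    new.blocks = []
    for b in blocks:
        statements = tuple(s for s in b["statements"] if s is not None)
        if not statements:
            continue
        new.blocks.append(
            StatementBlock(
                b["evidence"], AnnotationSet.from_dict(b["annotations"]), statements
            )
        )

    for stmt in new.statements():
        violations = validate_statement(stmt, new, allow_fragment=True)
        if violations:  # pragma: no cover - defended upstream
            raise CurationError("edited document fails re-validation", violations)
    return new
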