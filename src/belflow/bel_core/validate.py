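"""Syntax/structure validator for BEL terms, statements and documents.

Violations are returned as data, never raised: the curation workflow needs
to show the curator *every* problem with a proposed statement, and a
document is compiled only once it validates cleanly.

Rules enforced
  term-arity        abundance functions take exactly one namespace value;
                    wrappers (act/pep/kin/cat/tscript/deg/sec) exactly one
                    abundance-class inner term; complex/composite one value
                    or >=2 member terms
  term-depth        term nesting depth <= 2
  statement-depth   a nested statement object must be complete and may not
                    itself nest
  fragment          fragments are reported (a document is only valid once
                    fragments are assembled or rejected)
  namespace         every namespace keyword is declared by the document
  annotation        every annotation key is defined by the document
"""

from __future__ import annotations

from typing import Optional

from .model import (
    ABUNDANCE_FUNCTIONS,
    MOLECULAR_ABUNDANCE_FUNCTIONS,
    GROUP_FUNCTIONS,
    WRAPPER_FUNCTIONS,
    BelDocument,
    NamespaceValue,
    Statement,
    Term,
    Violation,
)
from .parser import serialize_statement, serialize_term

__all__ = ["validate_term", "validate_statement", "validate_document"]

MAX_TERM_DEPTH = 2


def validate_term(term: Term, declared_namespaces: Optional[set[str]] = None) -> list[Violation]:
    violations: list[Violation] = []
    _check_term(term, violations, declared_namespaces)
    if term.depth() > MAX_TERM_DEPTH:
        violations.append(
            Violation(
                "term-depth",
                serialize_term(term),
                f"term nesting depth {term.depth()} exceeds {MAX_TERM_DEPTH}",
            )
        )
    return violations


def _check_term(
    term: Term,
    violations: list[Violation],
    declared: Optional[set[str]],
) -> None:
    f = term.function
    text = serialize_term(term)
    values = [a for a in term.args if isinstance(a, NamespaceValue)]
    terms = [a for a in term.args if isinstance(a, Term)]

    if f in ABUNDANCE_FUNCTIONS:
        if len(term.args) != 1 or not values:
            violations.append(
                Violation(
                    "term-arity", text,
                    f"{f.short}() takes exactly one namespace value",
                )
            )
    elif f in WRAPPER_FUNCTIONS:
        if len(term.args) != 1 or not terms:
            violations.append(
                Violation("term-arity", text, f"{f.short}() takes exactly one inner term")
            )
        elif terms[0].function not in MOLECULAR_ABUNDANCE_FUNCTIONS:
            violations.append(
                Violation(
                    "term-arity", text,
                    f"{f.short}() requires a molecular-abundance inner term "
                    f"(a/p/r/g), got {terms[0].function.short}()",
                )
            )
    elif f in GROUP_FUNCTIONS:
        ok = (len(term.args) == 1 and len(values) == 1) or (
            len(terms) == len(term.args) and len(terms) >= 2
        )
        if not ok:
            violations.append(
                Violation(
                    "term-arity", text,
                    f"{f.short}() takes one namespace value or >=2 member terms",
                )
            )

    for v in values:
        if not v.value:
            violations.append(Violation("term-arity", text, "empty namespace value"))
        if declared is not None and v.namespace not in declared:
            violations.append(
                Violation(
                    "namespace", str(v),
                    f"namespace {v.namespace!r} is not declared in the document",
                )
            )
    for t in terms:
        _check_term(t, violations, declared)


def validate_statement(
    s: Statement,
    doc_context: Optional[BelDocument] = None,
    allow_fragment: bool = False,
) -> list[Violation]:
    """Return every rule violation of ``s``; empty list means valid."""
    declared = set(doc_context.namespaces) if doc_context is not None else None
    violations: list[Violation] = []
    text = serialize_statement(s)

    if not s.is_complete and not allow_fragment:
        violations.append(
            Violation("fragment", text, f"statement is a {s.fragment_kind.value} fragment")
        )
    if s.subject is not None:
        violations.extend(validate_term(s.subject, declared))
    if isinstance(s.object, Term):
        violations.extend(validate_term(s.object, declared))
    elif isinstance(s.object, Statement):
        inner = s.object
        if not inner.is_complete:
            violations.append(
                Violation("statement-depth", text, "nested statement object must be complete")
            )
        if isinstance(inner.object, Statement):
            violations.append(
                Violation(
                    "statement-depth", text,
                    "nested statement object may not itself nest",
                )
            )
        if inner.subject is not None:
            violations.extend(validate_term(inner.subject, declared))
        if isinstance(inner.object, Term):
            violations.extend(validate_term(inner.object, declared))
    return violations


def validate_document(doc: BelDocument, allow_fragments: bool = True) -> list[Violation]:
    """Validate every statement plus annotation-key definitions.

    Fragments are legal curation intermediates, so documents straight out of
    the converter pass by default; compilation re-validates with
    ``allow_fragments=False``.
    """
    violations: list[Violation] = []
    defined_keys = set(doc.annotation_definitions)
    for block in doc.blocks:
        for key, _ in block.annotations.values:
            if key not in defined_keys:
                violations.append(
                    Violation(
                        "annotation", key,
                        f"annotation key {key!r} is not defined in the document",
                    )
                )
        for s in block.statements:
            violations.extend(validate_statement(s, doc, allow_fragment=allow_fragments))
    return violations
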