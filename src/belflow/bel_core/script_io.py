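"""BEL Script reader/writer.

The line-oriented dialect used here:

    SET DOCUMENT Name = "Atherosclerosis plaque destabilization"
    SET DOCUMENT Description = "..."
    SET DOCUMENT Version = "1.0"
    DEFINE NAMESPACE HGNC AS URL "..."
    DEFINE ANNOTATION Species AS URL "..."
    SET PMID = "21120482"
    SET Section = "results"
    SET Span = "120:245"            # optional evidence offsets
    SET Evidence = "CYP4A11 transfection significantly increased ..."
    SET Species = "10090"
    p(HGNC:CYP4A11) -> bp(GOBP:angiogenesis)
    UNSET Species

A ``SET Evidence`` directive opens a new statement block; PMID/Section/Span
set before it describe that evidence.  Annotation SETs persist until UNSET
or until overwritten, as in classic BEL Script.  Annotation keys must be
DEFINEd and statement namespaces DECLAREd, otherwise reading fails with the
line number.
"""

from __future__ import annotations

import re

from .model import (
    AnnotationSet,
    BelDocument,
    Evidence,
    StatementBlock,
)
from .parser import BelSyntaxError, parse_statement

__all__ = ["BelScriptError", "read_bel_script", "write_bel_script"]

_RESERVED_SETS = {"Evidence", "PMID", "Section", "Span"}


class BelScriptError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _quote(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n") + '"'


def _unquote(raw: str, line: int) -> str:
    raw = raw.strip()
    if len(raw) < 2 or raw[0] != '"' or raw[-1] != '"':
        raise BelScriptError(f"expected a double-quoted value, found {raw!r}", line)
    body = raw[1:-1]
    out: list[str] = []
    i = 0
    while i < len(body):
        c = body[i]
        if c == "\\" and i + 1 < len(body):
            nxt = body[i + 1]
            out.append({"n": "\n", '"': '"', "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


_SET_DOC_RE = re.compile(r"^SET\s+DOCUMENT\s+(\w+)\s*=\s*(.+)$")
_SET_RE = re.compile(r"^SET\s+(\w+)\s*=\s*(.+)$")
_UNSET_RE = re.compile(r"^UNSET\s+(\w+)\s*$")
_DEF_NS_RE = re.compile(r"^DEFINE\s+NAMESPACE\s+(\S+)\s+AS\s+URL\s+(.+)$", re.IGNORECASE)
_DEF_ANNO_RE = re.compile(r"^DEFINE\s+ANNOTATION\s+(\w+)\s+AS\s+URL\s+(.+)$", re.IGNORECASE)


def read_bel_script(text: str) -> BelDocument:
    doc = BelDocument()
    annotations: dict[str, str] = {}
    pending = {"PMID": "", "Section": "results", "Span": ""}
    current_evidence: Evidence | None = None
    current_statements: list = []
    current_annotations: dict[str, str] = {}

    def flush_block() -> None:
        nonlocal current_evidence, current_statements
        if current_evidence is not None and current_statements:
            doc.blocks.append(
                StatementBlock(
                    current_evidence,
                    AnnotationSet.from_dict(current_annotations),
                    tuple(current_statements),
                )
            )
        current_evidence = None
        current_statements = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("//"):
            continue

        m = _SET_DOC_RE.match(line)
        if m:
            key, value = m.group(1), _unquote(m.group(2), lineno)
            if key == "Name":
                doc.name = value
            elif key == "Description":
                doc.description = value
            elif key == "Version":
                doc.version = value
            else:
                raise BelScriptError(f"unknown DOCUMENT property {key!r}", lineno)
            continue

        m = _DEF_NS_RE.match(line)
        if m:
            doc.namespaces[m.group(1).upper()] = _unquote(m.group(2), lineno)
            continue

        m = _DEF_ANNO_RE.match(line)
        if m:
            doc.annotation_definitions[m.group(1)] = _unquote(m.group(2), lineno)
            continue

        m = _SET_RE.match(line)
        if m:
            key, value = m.group(1), _unquote(m.group(2), lineno)
            if key == "Evidence":
                flush_block()
                span = None
                if pending["Span"]:
                    start, _, end = pending["Span"].partition(":")
                    span = (int(start), int(end))
                current_evidence = Evidence(
                    text=value,
                    pmid=pending["PMID"],
                    section=pending["Section"],
                    char_span=span,
                )
                current_annotations = dict(annotations)
                pending["Span"] = ""
            elif key in _RESERVED_SETS:
                pending[key] = value
            else:
                if key not in doc.annotation_definitions:
                    raise BelScriptError(
                        f"annotation key {key!r} used without DEFINE ANNOTATION", lineno
                    )
                annotations[key] = value
                current_annotations = dict(annotations)
            continue

        m = _UNSET_RE.match(line)
        if m:
            annotations.pop(m.group(1), None)
            continue

        # anything else is a statement line
        try:
            stmt = parse_statement(line)
        except BelSyntaxError as exc:
            raise BelScriptError(f"statement syntax error: {exc}", lineno) from exc
        if current_evidence is None:
            raise BelScriptError("statement before any SET Evidence", lineno)
        for nsv in _statement_namespace_values(stmt):
            if nsv.namespace not in doc.namespaces:
                raise BelScriptError(
                    f"namespace {nsv.namespace!r} is not declared", lineno
                )
        current_statements.append(stmt)

    flush_block()
    return doc


def _statement_namespace_values(stmt):
    from .model import Statement, Term

    parts = [stmt.subject, stmt.object]
    for part in parts:
        if isinstance(part, Term):
            yield from part.namespace_values()
        elif isinstance(part, Statement):
            yield from _statement_namespace_values(part)


def write_bel_script(doc: BelDocument) -> str:
    """Serialize a document; read_bel_script inverts this on structured content."""
    lines: list[str] = []
    lines.append(f"SET DOCUMENT Name = {_quote(doc.name)}")
    if doc.description:
        lines.append(f"SET DOCUMENT Description = {_quote(doc.description)}")
    lines.append(f"SET DOCUMENT Version = {_quote(doc.version)}")
    lines.append("")
    for ns in sorted(doc.namespaces):
        lines.append(f"DEFINE NAMESPACE {ns} AS URL {_quote(doc.namespaces[ns])}")
    for key in sorted(doc.annotation_definitions):
        lines.append(
            f"DEFINE ANNOTATION {key} AS URL {_quote(doc.annotation_definitions[key])}"
        )
    for block in doc.blocks:
        lines.append("")
        ev = block.evidence
        if ev.pmid:
            lines.append(f"SET PMID = {_quote(ev.pmid)}")
        lines.append(f"SET Section = {_quote(ev.section)}")
        if ev.char_span is not None:
            lines.append(f'SET Span = "{ev.char_span[0]}:{ev.char_span[1]}"')
        lines.append(f"SET Evidence = {_quote(ev.text)}")
        for key, value in block.annotations.values:
            lines.append(f"SET {key} = {_quote(value)}")
        for stmt in block.statements:
            lines.append(str(stmt))
        for key, _ in block.annotations.values:
            lines.append(f"UNSET {key}")
    lines.append("")
    return "\n".join(lines)
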