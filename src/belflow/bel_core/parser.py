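"""BEL term/statement parser and canonical serializer.

Hand-rolled tokenizer + recursive descent, so syntax errors carry exact
character offsets.  The grammar is the curation-workflow subset: the 15
functions (long or short spelling on input, short canonical on output),
namespace-qualified values with single-quoted forms, one level of term
wrapping/complex membership (term nesting depth <= 2), the nine relations
(symbolic or keyword spelling), one level of statement nesting, and
subject_relation / relation_object fragments.

PDF-derived text carries typographic quotes (e.g. CHEBI:‘ 20-HETE ’);
those are normalized to ASCII before tokenization.
"""

from __future__ import annotations

import re
from typing import Optional, Union

from .model import (
    FUNCTION_BY_NAME,
    RELATION_BY_TOKEN,
    NamespaceValue,
    Relation,
    Statement,
    Term,
)

__all__ = [
    "BelSyntaxError",
    "parse_term",
    "parse_statement",
    "serialize_term",
    "serialize_statement",
    "quote_value",
]


class BelSyntaxError(ValueError):
    """Syntax error with the 0-based character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


_SMART_CHARS = {
    "‘": "'",
    "’": "'",
    "‚": "'",
    "“": '"',
    "”": '"',
    "„": '"',
    "′": "'",
    "″": '"',
}


def _normalize_quotes(text: str) -> str:
    for k, v in _SMART_CHARS.items():
        text = text.replace(k, v)
    return text


# one token: punctuation, quoted string, or a bare word (incl. relation symbols)
_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<quoted>'(?:[^'\\]|\\.)*'|"(?:[^"\\]|\\.)*")
  | (?P<punct>[(),:])
  | (?P<rel>->|-\||=>|=\||--)
  | (?P<word>[A-Za-z0-9_][A-Za-z0-9_\-./+]*)
    """,
    re.VERBOSE,
)


class _Token:
    __slots__ = ("kind", "text", "offset")

    def __init__(self, kind: str, text: str, offset: int):
        self.kind = kind
        self.text = text
        self.offset = offset

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"_Token({self.kind!r}, {self.text!r}, {self.offset})"


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise BelSyntaxError(f"unexpected character {text[pos]!r}", pos)
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        tokens.append(_Token(kind, m.group(), m.start()))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    # --- token helpers -------------------------------------------------
    def peek(self) -> Optional[_Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise BelSyntaxError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.text != text:
            raise BelSyntaxError(f"expected {text!r}, found {tok.text!r}", tok.offset)
        return tok

    def at_end(self) -> bool:
        return self.i >= len(self.tokens)

    def require_end(self) -> None:
        tok = self.peek()
        if tok is not None:
            raise BelSyntaxError(f"unexpected trailing input {tok.text!r}", tok.offset)

    # --- grammar -------------------------------------------------------
    def term(self) -> Term:
        tok = self.next()
        if tok.kind != "word" or tok.text not in FUNCTION_BY_NAME:
            raise BelSyntaxError(f"unknown function keyword {tok.text!r}", tok.offset)
        function = FUNCTION_BY_NAME[tok.text]
        open_tok = self.expect("(")
        args: list[Union[NamespaceValue, Term]] = []
        while True:
            tok = self.peek()
            if tok is None:
                raise BelSyntaxError("unbalanced parenthesis", len(self.text))
            if tok.text == ")":
                if not args:
                    raise BelSyntaxError("empty argument list", open_tok.offset + 1)
                self.next()
                return Term(function, tuple(args))
            if args:
                self.expect(",")
            args.append(self.argument())

    def argument(self) -> Union[NamespaceValue, Term]:
        tok = self.peek()
        if tok is None:
            raise BelSyntaxError("unexpected end of input", len(self.text))
        if tok.text == ")" or tok.text == ",":
            raise BelSyntaxError("empty argument", tok.offset)
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
        if tok.kind == "word" and tok.text in FUNCTION_BY_NAME and nxt is not None and nxt.text == "(":
            return self.term()
        return self.namespace_value()

    def namespace_value(self) -> NamespaceValue:
        ns_tok = self.next()
        if ns_tok.kind != "word":
            raise BelSyntaxError(f"expected namespace keyword, found {ns_tok.text!r}", ns_tok.offset)
        self.expect(":")
        val_tok = self.next()
        if val_tok.kind == "quoted":
            value = val_tok.text[1:-1].replace("\\'", "'").replace('\\"', '"')
        elif val_tok.kind == "word":
            value = val_tok.text
        else:
            raise BelSyntaxError(f"expected value, found {val_tok.text!r}", val_tok.offset)
        if not value:
            raise BelSyntaxError("empty namespace value", val_tok.offset)
        # namespace keywords are case-insensitive; upper-case is canonical
        return NamespaceValue(ns_tok.text.upper(), value)

    def relation(self) -> Relation:
        tok = self.next()
        rel = RELATION_BY_TOKEN.get(tok.text)
        if rel is None:
            raise BelSyntaxError(f"unknown relation token {tok.text!r}", tok.offset)
        return rel

    def statement(self, allow_nested_object: bool = True) -> Statement:
        tok = self.peek()
        if tok is None:
            raise BelSyntaxError("empty statement", 0)
        # relation_object fragment: starts with a relation token
        if tok.text in RELATION_BY_TOKEN:
            rel = self.relation()
            obj = self.statement_object(allow_nested_object)
            return Statement(None, rel, obj)
        subject = self.term()
        if self.at_end():
            raise BelSyntaxError("missing relation", len(self.text))
        rel = self.relation()
        if self.at_end():
            return Statement(subject, rel, None)  # subject_relation fragment
        obj = self.statement_object(allow_nested_object)
        return Statement(subject, rel, obj)

    def statement_object(self, allow_nested: bool) -> Union[Term, Statement]:
        tok = self.peek()
        if tok is None:
            raise BelSyntaxError("missing statement object", len(self.text))
        if tok.text == "(":
            open_tok = self.next()
            if not allow_nested:
                raise BelSyntaxError(
                    "nested statement objects may not themselves nest", open_tok.offset
                )
            inner = self.statement(allow_nested_object=False)
            if not inner.is_complete:
                raise BelSyntaxError("nested statement must be complete", open_tok.offset)
            self.expect(")")
            return inner
        return self.term()


def parse_term(text: str) -> Term:
    """Parse a single BEL term expression into its AST."""
    p = _Parser(_normalize_quotes(text))
    term = p.term()
    p.require_end()
    return term


def parse_statement(text: str) -> Statement:
    """Parse a BEL statement, possibly a fragment, in BEL Script syntax."""
    p = _Parser(_normalize_quotes(text))
    stmt = p.statement()
    p.require_end()
    return stmt


_PLAIN_VALUE_RE = re.compile(r"^[A-Za-z0-9_-]+$")


def quote_value(value: str) -> str:
    """Quote a namespace value iff it contains characters beyond [A-Za-z0-9_-]."""
    if _PLAIN_VALUE_RE.match(value):
        return value
    return "'" + value.replace("'", "\\'") + "'"


def serialize_term(term: Term) -> str:
    args = ", ".join(
        str(a) if isinstance(a, NamespaceValue) else serialize_term(a) for a in term.args
    )
    return f"{term.function.short}({args})"


def serialize_statement(s: Statement) -> str:
    """Deterministic canonical text; inverse of parse_statement."""
    rel = s.relation.canonical
    if s.subject is None:
        left = ""
    else:
        left = serialize_term(s.subject) + " "
    if s.object is None:
        return f"{left}{rel}"
    if isinstance(s.object, Statement):
        right = f"({serialize_statement(s.object)})"
    else:
        right = serialize_term(s.object)
    return f"{left}{rel} {right}"
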