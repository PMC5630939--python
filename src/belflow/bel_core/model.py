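"""Core BEL data model.

Biological Expression Language (BEL) encodes scientific findings as
subject–predicate–object triples over typed biological entities.  The model
here covers the function inventory and relation set used in curated
cardiovascular-disease networks: abundance-class terms (chemicals, proteins,
RNAs, genes, processes, pathologies), complex/composite terms, activity and
secretion/degradation wrappers, nine relations with a causal/non-causal
split, evidence-scoped statement blocks and context annotations.

All AST types are frozen dataclasses: structural equality and hashability
are what round-tripping, deduplication and graph compilation rely on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

__all__ = [
    "BelFunction",
    "Relation",
    "NamespaceValue",
    "Term",
    "Statement",
    "FragmentKind",
    "Evidence",
    "AnnotationSet",
    "StatementBlock",
    "BelDocument",
    "Violation",
    "ABUNDANCE_FUNCTIONS",
    "MOLECULAR_ABUNDANCE_FUNCTIONS",
    "ACTIVITY_FUNCTIONS",
    "WRAPPER_FUNCTIONS",
    "GROUP_FUNCTIONS",
    "CAUSAL_RELATIONS",
]


class BelFunction(enum.Enum):
    """The 15 BEL functions, with their short (canonical) forms."""

    abundance = "a"
    proteinAbundance = "p"
    rnaAbundance = "r"
    geneAbundance = "g"
    complexAbundance = "complex"
    compositeAbundance = "composite"
    molecularActivity = "act"
    peptidaseActivity = "pep"
    kinaseActivity = "kin"
    catalyticActivity = "cat"
    transcriptionalActivity = "tscript"
    degradation = "deg"
    cellSecretion = "sec"
    biologicalProcess = "bp"
    pathology = "path"

    @property
    def short(self) -> str:
        return self.value

    @property
    def long(self) -> str:
        return self.name


#: molecular abundances: admissible inner terms of activity/deg/sec wrappers
MOLECULAR_ABUNDANCE_FUNCTIONS = frozenset(
    {
        BelFunction.abundance,
        BelFunction.proteinAbundance,
        BelFunction.rnaAbundance,
        BelFunction.geneAbundance,
    }
)

#: functions taking exactly one NamespaceValue argument
ABUNDANCE_FUNCTIONS = MOLECULAR_ABUNDANCE_FUNCTIONS | {
    BelFunction.biologicalProcess,
    BelFunction.pathology,
}

#: activity wrappers taking one abundance-class Term argument
ACTIVITY_FUNCTIONS = frozenset(
    {
        BelFunction.molecularActivity,
        BelFunction.peptidaseActivity,
        BelFunction.kinaseActivity,
        BelFunction.catalyticActivity,
        BelFunction.transcriptionalActivity,
    }
)

#: all single-term wrappers (activities plus deg/sec)
WRAPPER_FUNCTIONS = ACTIVITY_FUNCTIONS | {
    BelFunction.degradation,
    BelFunction.cellSecretion,
}

#: complex/composite: one NamespaceValue or >=2 Term members
GROUP_FUNCTIONS = frozenset(
    {BelFunction.complexAbundance, BelFunction.compositeAbundance}
)

# long and short spellings -> function
FUNCTION_BY_NAME: dict[str, BelFunction] = {}
for _f in BelFunction:
    FUNCTION_BY_NAME[_f.name] = _f
    FUNCTION_BY_NAME[_f.value] = _f


class Relation(enum.Enum):
    """BEL relations; five have symbolic short forms."""

    increases = "increases"
    decreases = "decreases"
    directlyIncreases = "directlyIncreases"
    directlyDecreases = "directlyDecreases"
    causesNoChange = "causesNoChange"
    association = "association"
    hasComponent = "hasComponent"
    transcribedTo = "transcribedTo"
    translatedTo = "translatedTo"

    @property
    def symbol(self) -> Optional[str]:
        return _RELATION_SYMBOLS.get(self)

    @property
    def causal(self) -> bool:
        return self in CAUSAL_RELATIONS

    @property
    def canonical(self) -> str:
        """Symbol where one exists, keyword otherwise."""
        return self.symbol if self.symbol is not None else self.name


_RELATION_SYMBOLS: dict["Relation", str] = {
    Relation.increases: "->",
    Relation.decreases: "-|",
    Relation.directlyIncreases: "=>",
    Relation.directlyDecreases: "=|",
    Relation.association: "--",
}


CAUSAL_RELATIONS = frozenset(
    {
        Relation.increases,
        Relation.decreases,
        Relation.directlyIncreases,
        Relation.directlyDecreases,
        Relation.causesNoChange,
    }
)

RELATION_BY_TOKEN: dict[str, Relation] = {}
for _r in Relation:
    RELATION_BY_TOKEN[_r.name] = _r
    if _r.symbol is not None:
        RELATION_BY_TOKEN[_r.symbol] = _r


@dataclass(frozen=True)
class NamespaceValue:
    """A namespace-qualified entity identifier, e.g. HGNC:CYP4A11."""

    namespace: str
    value: str

    def __str__(self) -> str:
        from .parser import quote_value  # local import: avoid cycle

        return f"{self.namespace}:{quote_value(self.value)}"


@dataclass(frozen=True)
class Term:
    """A BEL term: a function applied to namespace values and/or inner terms."""

    function: BelFunction
    args: tuple[Union[NamespaceValue, "Term"], ...]

    def __str__(self) -> str:
        inner = ", ".join(str(a) for a in self.args)
        return f"{self.function.short}({inner})"

    def depth(self) -> int:
        sub = [a.depth() for a in self.args if isinstance(a, Term)]
        return 1 + (max(sub) if sub else 0)

    def walk(self) -> Iterator["Term"]:
        """This term, then every nested term, depth-first."""
        yield self
        for a in self.args:
            if isinstance(a, Term):
                yield from a.walk()

    def namespace_values(self) -> Iterator[NamespaceValue]:
        for a in self.args:
            if isinstance(a, NamespaceValue):
                yield a
            else:
                yield from a.namespace_values()

    @property
    def entity(self) -> Optional[NamespaceValue]:
        """The innermost namespace value, when the term has exactly one."""
        vals = list(self.namespace_values())
        return vals[0] if len(vals) == 1 else None


class FragmentKind(enum.Enum):
    complete = "complete"
    subject_relation = "subject_relation"
    relation_object = "relation_object"


@dataclass(frozen=True)
class Statement:
    """A BEL statement or fragment.

    ``object`` may be a Term, a nested (complete, non-nested) Statement, or
    None for a subject_relation fragment; ``subject`` is None only for a
    relation_object fragment.
    """

    subject: Optional[Term]
    relation: Relation
    object: Optional[Union[Term, "Statement"]] = None

    @property
    def fragment_kind(self) -> FragmentKind:
        if self.subject is not None and self.object is not None:
            return FragmentKind.complete
        if self.subject is not None:
            return FragmentKind.subject_relation
        return FragmentKind.relation_object

    @property
    def is_complete(self) -> bool:
        return self.fragment_kind is FragmentKind.complete

    def __str__(self) -> str:
        from .parser import serialize_statement

        return serialize_statement(self)


@dataclass(frozen=True)
class Evidence:
    """The source sentence supporting a statement block."""

    text: str
    pmid: str = ""
    section: str = "results"
    char_span: Optional[tuple[int, int]] = None


#: the four context dimensions used throughout the workflow
STANDARD_ANNOTATION_KEYS = ("Species", "Tissue", "Cell", "Disease")


@dataclass(frozen=True)
class AnnotationSet:
    """Experimental-context annotations attached to a statement block."""

    values: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "AnnotationSet":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.values)

    def get(self, key: str) -> Optional[str]:
        return dict(self.values).get(key)


@dataclass(frozen=True)
class StatementBlock:
    evidence: Evidence
    annotations: AnnotationSet
    statements: tuple[Statement, ...]


@dataclass
class BelDocument:
    """A BEL document: header, declarations, and evidence-scoped blocks."""

    name: str = ""
    description: str = ""
    version: str = "1.0"
    namespaces: dict[str, str] = field(default_factory=dict)  # keyword -> resource
    annotation_definitions: dict[str, str] = field(default_factory=dict)
    blocks: list[StatementBlock] = field(default_factory=list)

    def statements(self) -> Iterator[Statement]:
        for block in self.blocks:
            yield from block.statements

    def statement_evidence_pairs(self) -> Iterator[tuple[Statement, Evidence]]:
        for block in self.blocks:
            for s in block.statements:
                yield s, block.evidence


@dataclass(frozen=True)
class Violation:
    """One validator finding: the rule violated and the offending expression."""

    rule: str
    expression: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.message}: {self.expression}"
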