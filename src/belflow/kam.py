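"""Knowledge assembly model (KAM): compiling BEL documents into a network.

Nodes are canonical BEL terms (one node per distinct term across all input
documents, including inner terms of wrappers and complex members); edges
carry a relation, a causal flag and the supporting evidence.  Duplicate
statements merge into one edge accumulating evidence.  Non-causal
*structural* edges are inferred between alternative forms of the same
entity — gene → RNA (transcribedTo), RNA → protein (translatedTo), complex
or wrapper → component (hasComponent) — which is how a network whose source
statements are all causal still acquires non-causal edges.  Each inference
rule is independently switchable.

The graph is a networkx MultiDiGraph keyed by (source, target, relation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from lxml import etree

from .bel_core import (
    BelDocument,
    BelFunction,
    NamespaceValue,
    Relation,
    Statement,
    Term,
    parse_term,
    serialize_term,
    validate_document,
)

__all__ = [
    "Kam",
    "KamError",
    "InferenceRules",
    "compile_documents",
    "merge",
    "edge_census",
    "node_census",
    "export_xgmml",
    "import_xgmml",
    "kam_to_json",
    "kam_from_json",
]


class KamError(ValueError):
    def __init__(self, message: str, violations=()):
        super().__init__(message)
        self.violations = list(violations)


@dataclass(frozen=True)
class InferenceRules:
    """Structural (non-causal) edge inference toggles; all on by default."""

    transcribed_to: bool = True   # g(X) -> r(X)
    translated_to: bool = True    # r(X) -> p(X)
    has_component: bool = True    # complex -> member
    wrapper_component: bool = True  # act/deg/sec wrapper -> inner term


@dataclass
class Kam:
    """A compiled knowledge assembly model."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    provenance: list[str] = field(default_factory=list)

    # -- nodes ---------------------------------------------------------
    def add_term(self, term: Term) -> str:
        key = serialize_term(term)
        if key not in self.graph:
            entity = term.entity
            self.graph.add_node(
                key,
                function=term.function.short,
                namespace=entity.namespace if entity else "",
                value=entity.value if entity else "",
            )
        return key

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    # -- edges ---------------------------------------------------------
    def add_edge(
        self,
        source: str,
        target: str,
        relation: Relation,
        evidence: Optional[tuple[str, str]] = None,
        annotations: Optional[dict[str, str]] = None,
    ) -> None:
        """Add or merge an edge keyed by (source, target, relation)."""
        key = relation.name
        if self.graph.has_edge(source, target, key=key):
            data = self.graph[source][target][key]
        else:
            self.graph.add_edge(
                source,
                target,
                key=key,
                relation=relation.name,
                causal=relation.causal,
                evidence=[],
                annotations={},
            )
            data = self.graph[source][target][key]
        if evidence is not None:
            data["evidence"].append(list(evidence))
        if annotations:
            data["annotations"].update(annotations)

    def edges(self) -> Iterable[tuple[str, str, str, dict]]:
        return self.graph.edges(keys=True, data=True)

    def structural_equal(self, other: "Kam") -> bool:
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {(u, v, k) for u, v, k in self.graph.edges(keys=True)}
        theirs = {(u, v, k) for u, v, k in other.graph.edges(keys=True)}
        return mine == theirs


# ---------------------------------------------------------------------------
# compilation


def _register_term(kam: Kam, term: Term, rules: InferenceRules) -> str:
    """Add the term node plus inner-term nodes and structural edges."""
    key = kam.add_term(term)
    for arg in term.args:
        if isinstance(arg, Term):
            inner_key = _register_term(kam, arg, rules)
            if term.function in (
                BelFunction.complexAbundance,
                BelFunction.compositeAbundance,
            ):
                if rules.has_component:
                    kam.add_edge(key, inner_key, Relation.hasComponent)
            elif rules.wrapper_component:
                kam.add_edge(key, inner_key, Relation.hasComponent)
    return key


def _statement_edges(
    kam: Kam,
    s: Statement,
    evidence: tuple[str, str],
    annotations: dict[str, str],
    rules: InferenceRules,
) -> None:
    subj_key = _register_term(kam, s.subject, rules)
    if isinstance(s.object, Term):
        obj_key = _register_term(kam, s.object, rules)
        kam.add_edge(subj_key, obj_key, s.relation, evidence, annotations)
    else:  # nested statement: inner edge + outer subject -> inner object
        inner = s.object
        inner_subj = _register_term(kam, inner.subject, rules)
        inner_obj = _register_term(kam, inner.object, rules)
        kam.add_edge(inner_subj, inner_obj, inner.relation, evidence, annotations)
        kam.add_edge(subj_key, inner_obj, s.relation, evidence, annotations)


def _infer_form_edges(kam: Kam, rules: InferenceRules) -> None:
    """g(X) -> r(X) -> p(X) links for same namespace:value present in the graph."""
    by_entity: dict[tuple[str, str], dict[str, str]] = {}
    for key, data in kam.graph.nodes(data=True):
        if data["namespace"] and data["function"] in ("g", "r", "p"):
            entity = (data["namespace"], data["value"])
            # only plain abundance nodes, not wrappers sharing the entity
            if key == serialize_term(
                Term(
                    {"g": BelFunction.geneAbundance,
                     "r": BelFunction.rnaAbundance,
                     "p": BelFunction.proteinAbundance}[data["function"]],
                    (NamespaceValue(*entity),),
                )
            ):
                by_entity.setdefault(entity, {})[data["function"]] = key
    for forms in by_entity.values():
        if rules.transcribed_to and "g" in forms and "r" in forms:
            kam.add_edge(forms["g"], forms["r"], Relation.transcribedTo)
        if rules.translated_to and "r" in forms and "p" in forms:
            kam.add_edge(forms["r"], forms["p"], Relation.translatedTo)


def compile_documents(
    docs: Sequence[BelDocument],
    rules: Optional[InferenceRules] = None,
) -> Kam:
    """Compile validated BEL documents into a single KAM.

    Refuses to compile if any document has validation violations (fragments
    included: they must be assembled or rejected during curation first).
    Compilation is order-independent and deterministic.
    """
    rules = rules or InferenceRules()
    for doc in docs:
        violations = validate_document(doc, allow_fragments=False)
        if violations:
            raise KamError(
                f"document {doc.name!r} does not validate", violations
            )
    kam = Kam()
    for doc in docs:
        for block in doc.blocks:
            for s in block.statements:
                _statement_edges(
                    kam,
                    s,
                    (block.evidence.pmid, block.evidence.text),
                    block.annotations.as_dict(),
                    rules,
                )
        for pmid in sorted({b.evidence.pmid for b in doc.blocks}):
            if pmid and pmid not in kam.provenance:
                kam.provenance.append(pmid)
    _infer_form_edges(kam, rules)
    kam.provenance.sort()
    return kam


def merge(kams: Sequence[Kam]) -> Kam:
    """Union of KAMs: node keys unify, edge evidence concatenates.

    merge([K]) == K and merge([K, K]) == K up to evidence multiplicity;
    structurally, merge is idempotent.
    """
    out = Kam()
    seen_evidence: set[tuple[str, str, str, str, str]] = set()
    for kam in kams:
        for key, data in kam.graph.nodes(data=True):
            if key not in out.graph:
                out.graph.add_node(key, **data)
        for u, v, k, data in kam.edges():
            rel = Relation[data["relation"]]
            out.add_edge(u, v, rel, annotations=data.get("annotations") or None)
            for pmid, text in data.get("evidence", []):
                tag = (u, v, k, pmid, text)
                if tag not in seen_evidence:
                    seen_evidence.add(tag)
                    out.graph[u][v][k]["evidence"].append([pmid, text])
        for pmid in kam.provenance:
            if pmid not in out.provenance:
                out.provenance.append(pmid)
    out.provenance.sort()
    return out


# ---------------------------------------------------------------------------
# censuses


def edge_census(kam: Kam) -> dict:
    """Causal/non-causal split and per-relation edge counts."""
    by_relation: dict[str, int] = {}
    causal = 0
    for _, _, _, data in kam.edges():
        by_relation[data["relation"]] = by_relation.get(data["relation"], 0) + 1
        if data["causal"]:
            causal += 1
    total = kam.edge_count
    return {
        "total": total,
        "causal": causal,
        "non_causal": total - causal,
        "by_relation": dict(sorted(by_relation.items())),
    }


def node_census(kam: Kam) -> dict[str, int]:
    """Node counts per BEL function; always all 15 entries."""
    census = {f.short: 0 for f in BelFunction}
    for _, data in kam.graph.nodes(data=True):
        census[data["function"]] += 1
    return census


# ---------------------------------------------------------------------------
# XGMML (Cytoscape) export / import


_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def export_xgmml(kam: Kam, path: str, label: str = "belflow KAM") -> None:
    root = etree.Element(
        "graph",
        nsmap={None: _XGMML_NS},
        label=label,
        directed="1",
    )
    ids = {key: str(i) for i, key in enumerate(sorted(kam.graph.nodes))}
    for key in sorted(kam.graph.nodes):
        data = kam.graph.nodes[key]
        node = etree.SubElement(root, "node", id=ids[key], label=key)
        etree.SubElement(
            node, "att", name="bel_function", type="string", value=data["function"]
        )
    for u, v, k, data in sorted(kam.edges(), key=lambda e: (e[0], e[1], e[2])):
        edge = etree.SubElement(
            root, "edge", source=ids[u], target=ids[v], label=data["relation"]
        )
        etree.SubElement(edge, "att", name="relation", type="string", value=data["relation"])
        etree.SubElement(
            edge, "att", name="causal", type="boolean",
            value="true" if data["causal"] else "false",
        )
        etree.SubElement(
            edge, "att", name="evidence_count", type="integer",
            value=str(len(data.get("evidence", []))),
        )
    tree = etree.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _xg(tag: str) -> str:
    return f"{{{_XGMML_NS}}}{tag}"


def import_xgmml(path: str) -> Kam:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise KamError(f"malformed XGMML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "graph":
        raise KamError(f"unexpected root element at /{etree.QName(root).localname}")
    kam = Kam()
    labels: dict[str, str] = {}
    for node in root.iterfind(_xg("node")):
        nid, label = node.get("id"), node.get("label")
        if nid is None or label is None:
            raise KamError(f"node missing id/label at {tree.getpath(node)}")
        labels[nid] = label
        function = ""
        for att in node.iterfind(_xg("att")):
            if att.get("name") == "bel_function":
                function = att.get("value", "")
        try:
            term = parse_term(label)
            entity = term.entity
        except Exception:
            entity = None
        kam.graph.add_node(
            label,
            function=function,
            namespace=entity.namespace if entity else "",
            value=entity.value if entity else "",
        )
    for edge in root.iterfind(_xg("edge")):
        src, tgt = edge.get("source"), edge.get("target")
        if src not in labels or tgt not in labels:
            raise KamError(f"edge references unknown node at {tree.getpath(edge)}")
        attrs = {
            att.get("name"): att.get("value", "")
            for att in edge.iterfind(_xg("att"))
        }
        rel_name = attrs.get("relation", edge.get("label", ""))
        try:
            rel = Relation[rel_name]
        except KeyError as exc:
            raise KamError(
                f"unknown relation {rel_name!r} at {tree.getpath(edge)}"
            ) from exc
        kam.add_edge(labels[src], labels[tgt], rel)
        data = kam.graph[labels[src]][labels[tgt]][rel.name]
        data["evidence_count"] = int(attrs.get("evidence_count", "0"))
    return kam


# ---------------------------------------------------------------------------
# JSON graph serialization (tests, pipeline artifacts)


def kam_to_json(kam: Kam) -> str:
    return json.dumps(
        {
            "provenance": kam.provenance,
            "nodes": [
                {"key": k, **kam.graph.nodes[k]} for k in sorted(kam.graph.nodes)
            ],
            "edges": [
                {
                    "source": u,
                    "target": v,
                    "relation": data["relation"],
                    "causal": data["causal"],
                    "evidence": data.get("evidence", []),
                    "annotations": data.get("annotations", {}),
                }
                for u, v, k, data in sorted(
                    kam.edges(), key=lambda e: (e[0], e[1], e[2])
                )
            ],
        },
        indent=2,
    )


def kam_from_json(text: str) -> Kam:
    obj = json.loads(text)
    kam = Kam(provenance=list(obj.get("provenance", [])))
    for nd in obj["nodes"]:
        nd = dict(nd)
        key = nd.pop("key")
        kam.graph.add_node(key, **nd)
    for ed in obj["edges"]:
        rel = Relation[ed["relation"]]
        kam.add_edge(ed["source"], ed["target"], rel, annotations=ed.get("annotations") or None)
        kam.graph[ed["source"]][ed["target"]][rel.name]["evidence"] = [
            list(e) for e in ed.get("evidence", [])
        ]
    return kam
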