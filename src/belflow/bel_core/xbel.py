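"""XBEL: XML serialization of BEL documents.

Element schema (UTF-8; documented here and in docs/methods.md):

    <document xmlns="http://belflow.dev/xbel">
      <header><name/><description/><version/></header>
      <namespaceGroup>
        <namespace keyword="HGNC" resource="..."/>
      </namespaceGroup>
      <annotationDefinitionGroup>
        <annotationDefinition id="Species" resource="..."/>
      </annotationDefinitionGroup>
      <statementGroup>
        <evidence pmid="21120482" section="results" start="120" end="245">
          text ...
        </evidence>
        <annotation refID="Species">10090</annotation>
        <statement relationship="increases" fragment="complete">
          <subject><term function="p">
            <parameter namespace="HGNC">CYP4A11</parameter>
          </term></subject>
          <object>
            <term .../>  |  <statement .../>   <!-- one nesting level -->
          </object>
        </statement>
      </statementGroup>
    </document>

Fragments omit the <subject> or <object> element and carry the fragment
kind in the ``fragment`` attribute.
"""

from __future__ import annotations

from lxml import etree

from .model import (
    FUNCTION_BY_NAME,
    RELATION_BY_TOKEN,
    AnnotationSet,
    BelDocument,
    Evidence,
    NamespaceValue,
    Statement,
    StatementBlock,
    Term,
)

__all__ = ["XBEL_NS", "XbelError", "read_xbel", "write_xbel"]

XBEL_NS = "http://belflow.dev/xbel"
_NSMAP = {None: XBEL_NS}


class XbelError(ValueError):
    """Malformed or semantically invalid XBEL, with the element path."""

    def __init__(self, message: str, element: etree._Element | None = None):
        path = element.getroottree().getpath(element) if element is not None else "?"
        super().__init__(f"{message} (at {path})")


def _q(tag: str) -> str:
    return f"{{{XBEL_NS}}}{tag}"


# ---------------------------------------------------------------------------
# writing


def _term_element(term: Term) -> etree._Element:
    el = etree.Element(_q("term"), function=term.function.short)
    for arg in term.args:
        if isinstance(arg, NamespaceValue):
            p = etree.SubElement(el, _q("parameter"), namespace=arg.namespace)
            p.text = arg.value
        else:
            el.append(_term_element(arg))
    return el


def _statement_element(s: Statement) -> etree._Element:
    el = etree.Element(
        _q("statement"),
        relationship=s.relation.name,
        fragment=s.fragment_kind.value,
    )
    if s.subject is not None:
        subj = etree.SubElement(el, _q("subject"))
        subj.append(_term_element(s.subject))
    if s.object is not None:
        obj = etree.SubElement(el, _q("object"))
        if isinstance(s.object, Statement):
            obj.append(_statement_element(s.object))
        else:
            obj.append(_term_element(s.object))
    return el


def write_xbel(doc: BelDocument) -> bytes:
    root = etree.Element(_q("document"), nsmap=_NSMAP)
    header = etree.SubElement(root, _q("header"))
    etree.SubElement(header, _q("name")).text = doc.name
    etree.SubElement(header, _q("description")).text = doc.description
    etree.SubElement(header, _q("version")).text = doc.version

    nsg = etree.SubElement(root, _q("namespaceGroup"))
    for kw in sorted(doc.namespaces):
        etree.SubElement(nsg, _q("namespace"), keyword=kw, resource=doc.namespaces[kw])
    adg = etree.SubElement(root, _q("annotationDefinitionGroup"))
    for key in sorted(doc.annotation_definitions):
        etree.SubElement(
            adg, _q("annotationDefinition"), id=key, resource=doc.annotation_definitions[key]
        )

    for block in doc.blocks:
        sg = etree.SubElement(root, _q("statementGroup"))
        ev = block.evidence
        attrs = {"pmid": ev.pmid, "section": ev.section}
        if ev.char_span is not None:
            attrs["start"] = str(ev.char_span[0])
            attrs["end"] = str(ev.char_span[1])
        ev_el = etree.SubElement(sg, _q("evidence"), **attrs)
        ev_el.text = ev.text
        for key, value in block.annotations.values:
            a = etree.SubElement(sg, _q("annotation"), refID=key)
            a.text = value
        for s in block.statements:
            sg.append(_statement_element(s))

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# reading


def _parse_term_el(el: etree._Element) -> Term:
    fname = el.get("function", "")
    func = FUNCTION_BY_NAME.get(fname)
    if func is None:
        raise XbelError(f"unknown function {fname!r}", el)
    args: list[NamespaceValue | Term] = []
    for child in el:
        if child.tag == _q("parameter"):
            ns = child.get("namespace")
            if not ns:
                raise XbelError("parameter without namespace", child)
            args.append(NamespaceValue(ns.upper(), child.text or ""))
        elif child.tag == _q("term"):
            args.append(_parse_term_el(child))
        else:
            raise XbelError(f"unexpected element in term: {child.tag}", child)
    if not args:
        raise XbelError("term with no arguments", el)
    return Term(func, tuple(args))


def _parse_statement_el(el: etree._Element, nested: bool = False) -> Statement:
    rel_name = el.get("relationship", "")
    rel = RELATION_BY_TOKEN.get(rel_name)
    if rel is None:
        raise XbelError(f"unknown relationship {rel_name!r}", el)
    subject = None
    obj = None
    for child in el:
        if child.tag == _q("subject"):
            subject = _parse_term_el(child[0])
        elif child.tag == _q("object"):
            inner = child[0]
            if inner.tag == _q("statement"):
                if nested:
                    raise XbelError("nested statement object may not itself nest", inner)
                obj = _parse_statement_el(inner, nested=True)
            else:
                obj = _parse_term_el(inner)
        else:
            raise XbelError(f"unexpected element in statement: {child.tag}", child)
    if subject is None and obj is None:
        raise XbelError("statement with neither subject nor object", el)
    return Statement(subject, rel, obj)


def read_xbel(data: bytes | str) -> BelDocument:
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise XbelError(f"not well-formed XML: {exc}") from exc
    if root.tag != _q("document"):
        raise XbelError(f"unexpected root element {root.tag}", root)

    doc = BelDocument()
    header = root.find(_q("header"))
    if header is not None:
        doc.name = header.findtext(_q("name"), "") or ""
        doc.description = header.findtext(_q("description"), "") or ""
        doc.version = header.findtext(_q("version"), "1.0") or "1.0"
    for ns in root.iterfind(f"{_q('namespaceGroup')}/{_q('namespace')}"):
        doc.namespaces[ns.get("keyword", "").upper()] = ns.get("resource", "")
    for ad in root.iterfind(
        f"{_q('annotationDefinitionGroup')}/{_q('annotationDefinition')}"
    ):
        doc.annotation_definitions[ad.get("id", "")] = ad.get("resource", "")

    for sg in root.iterfind(_q("statementGroup")):
        ev_el = sg.find(_q("evidence"))
        if ev_el is None:
            raise XbelError("statementGroup without evidence", sg)
        span = None
        if ev_el.get("start") is not None:
            span = (int(ev_el.get("start")), int(ev_el.get("end", "0")))
        evidence = Evidence(
            text=ev_el.text or "",
            pmid=ev_el.get("pmid", ""),
            section=ev_el.get("section", "results"),
            char_span=span,
        )
        annos: dict[str, str] = {}
        for a in sg.iterfind(_q("annotation")):
            key = a.get("refID", "")
            if key not in doc.annotation_definitions:
                raise XbelError(f"annotation key {key!r} not defined", a)
            annos[key] = a.text or ""
        statements = tuple(
            _parse_statement_el(el) for el in sg.iterfind(_q("statement"))
        )
        doc.blocks.append(
            StatementBlock(evidence, AnnotationSet.from_dict(annos), statements)
        )
    return doc
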