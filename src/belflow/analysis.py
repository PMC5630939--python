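"""Network topology, network comparison, evidence overlap and
curation-efficiency metrics.

Topology follows the conventions of Cytoscape's Network Analyzer: degrees
are computed on the undirected simple-graph projection by default (parallel
edges collapsed; directed and multi-edge modes behind flags), *hubs* are
the nodes whose degree strictly exceeds the network's mean degree, and the
scale-free check is a least-squares line on the log10 degree–frequency
plot rather than a maximum-likelihood power-law fit (an MLE exponent is
reported alongside for reference).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bel_core import BelDocument
from .kam import Kam

__all__ = [
    "DegreeReport",
    "HubSet",
    "ScaleFreeReport",
    "ComparisonReport",
    "CurationLog",
    "CurationMetrics",
    "degree_report",
    "find_hubs",
    "scale_free_check",
    "compare_networks",
    "evidence_overlap",
    "curation_metrics",
    "evaluate_recall_pipeline",
]


# ---------------------------------------------------------------------------
# degrees and hubs


@dataclass
class DegreeReport:
    degrees: dict[str, int]          # undirected (or total) degree per node
    in_degrees: dict[str, int]
    out_degrees: dict[str, int]
    histogram: dict[int, int]        # degree -> number of nodes
    mean_degree: float

    @property
    def n_nodes(self) -> int:
        return len(self.degrees)


def degree_report(kam: Kam, multi_edge_policy: str = "collapse") -> DegreeReport:
    """Degree statistics for a KAM.

    ``multi_edge_policy``: "collapse" (default; parallel edges and the two
    directions of a reciprocal pair count once, Network Analyzer style) or
    "count" (every parallel edge counts).
    """
    g = kam.graph
    if multi_edge_policy == "collapse":
        undirected = set()
        for u, v in g.edges():
            undirected.add((u, v) if u <= v else (v, u))
        degrees = {n: 0 for n in g.nodes}
        for u, v in undirected:
            degrees[u] += 1
            if v != u:
                degrees[v] += 1
            else:
                degrees[u] += 1  # self-loop contributes 2 in the handshake sum
    elif multi_edge_policy == "count":
        degrees = {n: 0 for n in g.nodes}
        for u, v in g.edges():
            degrees[u] += 1
            degrees[v] += 1
    else:
        raise ValueError(f"unknown multi_edge_policy {multi_edge_policy!r}")

    in_deg = {n: 0 for n in g.nodes}
    out_deg = {n: 0 for n in g.nodes}
    seen = set()
    for u, v, k in g.edges(keys=True):
        key = (u, v) if multi_edge_policy == "collapse" else (u, v, k)
        if key in seen:
            continue
        seen.add(key)
        out_deg[u] += 1
        in_deg[v] += 1

    histogram: dict[int, int] = {}
    for d in degrees.values():
        histogram[d] = histogram.get(d, 0) + 1
    mean = sum(degrees.values()) / len(degrees) if degrees else 0.0
    return DegreeReport(degrees, in_deg, out_deg, dict(sorted(histogram.items())), mean)


@dataclass
class HubSet:
    """Nodes whose degree strictly exceeds the mean degree."""

    hubs: list[tuple[str, int]]   # (node, degree), highest degree first
    threshold: float              # the mean degree used

    @property
    def names(self) -> set[str]:
        return {n for n, _ in self.hubs}


def find_hubs(kam: Kam, multi_edge_policy: str = "collapse") -> HubSet:
    report = degree_report(kam, multi_edge_policy)
    if report.n_nodes == 0:
        raise ValueError("hub detection requires at least one node")
    hubs = sorted(
        ((n, d) for n, d in report.degrees.items() if d > report.mean_degree),
        key=lambda x: (-x[1], x[0]),
    )
    return HubSet(hubs, report.mean_degree)


# ---------------------------------------------------------------------------
# scale-free check


@dataclass
class ScaleFreeReport:
    exponent: Optional[float]
    r_squared: Optional[float]
    verdict: str                      # "scale-free" | "not scale-free" | "indeterminate"
    mle_exponent: Optional[float] = None

    @property
    def is_scale_free(self) -> bool:
        return self.verdict == "scale-free"


def scale_free_check(
    report: DegreeReport,
    r2_threshold: float = 0.7,
    exponent_range: tuple[float, float] = (-4.0, -1.0),
) -> ScaleFreeReport:
    """Log-log least-squares fit of the degree distribution.

    Fits log10(frequency) against log10(degree) over degrees >= 1; the
    verdict is "scale-free" when the slope lies in ``exponent_range`` and
    r^2 >= ``r2_threshold``.  Fewer than 10 distinct degree values make the
    fit meaningless and yield "indeterminate".  A discrete maximum-
    likelihood exponent estimate is attached for reference.
    """
    points = [(d, f) for d, f in report.histogram.items() if d >= 1]
    if len(points) < 10:
        return ScaleFreeReport(None, None, "indeterminate")
    x = np.log10([d for d, _ in points])
    y = np.log10([f for _, f in points])
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    lo, hi = exponent_range
    verdict = "scale-free" if lo <= fit.slope <= hi and r2 >= r2_threshold else "not scale-free"

    degrees = [d for n, d in report.degrees.items() if d >= 1]
    mle = None
    if degrees:
        dmin = min(degrees)
        # discrete power-law MLE (Clauset et al. approximation)
        s = sum(math.log(d / (dmin - 0.5)) for d in degrees)
        if s > 0:
            mle = -(1.0 + len(degrees) / s)
    return ScaleFreeReport(float(fit.slope), float(r2), verdict, mle)


# ---------------------------------------------------------------------------
# network comparison


@dataclass
class ComparisonReport:
    nodes_a: int
    nodes_b: int
    edges_a: int
    edges_b: int
    shared_nodes: int
    shared_edges: int
    shared_hubs: int
    shared_hub_names: list[str]


def compare_networks(k1: Kam, k2: Kam) -> ComparisonReport:
    """Structural overlap of two KAMs.

    Nodes are shared by canonical term key, edges by (source, target,
    relation), hubs via ``find_hubs`` on each network.  Symmetric in its
    shared counts.
    """
    nodes1, nodes2 = set(k1.graph.nodes), set(k2.graph.nodes)
    edges1 = {(u, v, k) for u, v, k in k1.graph.edges(keys=True)}
    edges2 = {(u, v, k) for u, v, k in k2.graph.edges(keys=True)}
    hubs1 = find_hubs(k1).names if nodes1 else set()
    hubs2 = find_hubs(k2).names if nodes2 else set()
    shared_hubs = hubs1 & hubs2
    return ComparisonReport(
        nodes_a=len(nodes1),
        nodes_b=len(nodes2),
        edges_a=len(edges1),
        edges_b=len(edges2),
        shared_nodes=len(nodes1 & nodes2),
        shared_edges=len(edges1 & edges2),
        shared_hubs=len(shared_hubs),
        shared_hub_names=sorted(shared_hubs),
    )


# ---------------------------------------------------------------------------
# evidence overlap


_PUNCT_RE = re.compile(r"[^\w\s]")


def _normalize_sentence(text: str) -> str:
    return re.sub(r"\s+", " ", _PUNCT_RE.sub("", text.lower())).strip()


def evidence_overlap(
    docs_a: Sequence[BelDocument], docs_b: Sequence[BelDocument]
) -> dict[str, float]:
    """Overlap of evidence sentences between two document sets, as percent.

    Sentences are normalized (lower-case, punctuation stripped, whitespace
    collapsed).  The headline figure is the Jaccard index |A∩B|/|A∪B|;
    per-set fractions |A∩B|/|A| and |A∩B|/|B| are reported alongside since
    an "x% of the sentences overlapped" phrasing leaves the denominator
    open.
    """
    sents_a = {
        _normalize_sentence(b.evidence.text) for d in docs_a for b in d.blocks
    }
    sents_b = {
        _normalize_sentence(b.evidence.text) for d in docs_b for b in d.blocks
    }
    sents_a.discard("")
    sents_b.discard("")
    inter = len(sents_a & sents_b)
    union = len(sents_a | sents_b)
    return {
        "jaccard": 100.0 * inter / union if union else 0.0,
        "of_a": 100.0 * inter / len(sents_a) if sents_a else 0.0,
        "of_b": 100.0 * inter / len(sents_b) if sents_b else 0.0,
        "intersection": float(inter),
        "union": float(union),
    }


# ---------------------------------------------------------------------------
# curation-efficiency metrics


@dataclass(frozen=True)
class CurationLog:
    """Per-arm totals of a timed curation exercise."""

    arm: str
    minutes: float
    statements: int
    annotations: int = 0


@dataclass(frozen=True)
class CurationMetrics:
    arm: str
    minutes: float
    statements: int
    annotations: int
    time_per_statement: float
    time_per_statement_and_annotation: float


def _round1(x: float) -> float:
    """Round half-up to one decimal (ties like 1.25 -> 1.3)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def evaluate_recall_pipeline(cfg):
    """NER recall of the full extraction pipeline on a generated gold corpus.

    Generates the corpus for ``cfg``, runs section selection, sentence
    segmentation and NER, and scores the found mentions against the
    generator's gold standard.
    """
    from .extraction import evaluate_recall, ner, segment_sentences, select_sections
    from .fixtures import generate_corpus

    corpus = generate_corpus(cfg)
    found = []
    for p in select_sections(corpus.passages):
        segment_sentences(p)
        for si, (_, sentence) in enumerate(p.sentences):
            key = (p.pmid, p.section.value, si)
            found.extend((key, m) for m in ner(sentence, corpus.dictionaries))
    return evaluate_recall(found, corpus.gold_mentions)


def curation_metrics(log: CurationLog) -> CurationMetrics:
    """Minutes per statement and per statement+annotation, 1-decimal half-up."""
    if log.statements <= 0:
        raise ValueError("curation metrics need at least one statement")
    return CurationMetrics(
        arm=log.arm,
        minutes=log.minutes,
        statements=log.statements,
        annotations=log.annotations,
        time_per_statement=_round1(log.minutes / log.statements),
        time_per_statement_and_annotation=_round1(
            log.minutes / (log.statements + log.annotations)
        ),
    )
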