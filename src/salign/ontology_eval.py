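"""GO-based evaluation of an alignment: Wang similarity, BMA, AFS.

An alignment is judged by how functionally similar its aligned protein pairs
are.  Each protein carries Gene Ontology annotations in the Molecular
Function (MF) and Biological Process (BP) namespaces.  Term-level similarity
uses Wang's graph-based measure: a term's semantics are encoded by S-values
propagated up its ancestor DAG (S_a(a) = 1, S_a(t) = max over children c of
w_e * S_a(c), with edge contribution factors 0.8 for is_a and 0.6 for
part_of), and two terms are compared by how much semantic mass their common
ancestors carry relative to their total semantic values.  Protein-level
similarity combines the two term sets by Best-Match Average (BMA): the mean
of the row-wise and column-wise best-match averages.  The Average Functional
Similarity (AFS) of an alignment is the arithmetic mean of the per-pair BMA
scores over all pairs where both proteins are annotated in the namespace,
reported together with the percentage of annotated smaller-network nodes
that contributed a scored pair.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

from .network_io import Alignment

logger = logging.getLogger(__name__)

#: Wang semantic contribution factor per parent relation
RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

_NAMESPACE_CODE = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
_ASPECT_CODE = {"F": "MF", "P": "BP"}  # GAF aspect column; C (CC) is dropped

NAMESPACES = ("MF", "BP")


class OntologyError(ValueError):
    """Raised for malformed ontology or annotation input."""


@dataclass
class GoDag:
    """GO term DAG restricted to typed (is_a / part_of) parent edges."""

    terms: set[str]
    parents: dict[str, set[tuple[str, str]]]  # term -> {(parent, relation)}
    namespace: dict[str, str]  # term -> MF | BP | CC
    _svalues: dict[str, dict[str, float]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, links in self.parents.items():
            for parent, _ in links:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]}")


@dataclass
class AnnotationSet:
    """Protein -> per-namespace GO term sets."""

    annotations: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def terms(self, protein: str, namespace: str) -> set[str]:
        return self.annotations.get(protein, {}).get(namespace, set())

    def annotated(self, namespace: str) -> set[str]:
        return {p for p, by_ns in self.annotations.items() if by_ns.get(namespace)}


@dataclass
class AfsReport:
    """AFS and aligned-node coverage for one namespace."""

    namespace: str
    afs: float | None  # None when no pair could be scored
    pct_aligned_nodes: float
    n_pairs_scored: int
    per_pair: list[tuple[str, str, float]] = field(default_factory=list)


def parse_obo(path: str | Path) -> GoDag:
    """Load an OBO 1.2 flat file into a :class:`GoDag`.

    Keeps is_a and ``relationship: part_of`` edges, drops obsolete terms and
    (with a log message) cross-namespace parent links.  Raises
    :class:`OntologyError` on a cyclic ontology, naming a cycle member.
    """
    graph = obonet.read_obo(str(path))
    terms: set[str] = set()
    parents: dict[str, set[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        terms.add(term)
        namespace[term] = _NAMESPACE_CODE.get(data.get("namespace", ""), "CC")
    n_cross = 0
    for child, parent, relation in graph.edges(keys=True):
        if relation not in RELATION_WEIGHTS:
            continue
        if parent not in terms:
            continue
        if namespace[child] != namespace[parent]:
            n_cross += 1
            continue
        parents.setdefault(child, set()).add((parent, relation))
    if n_cross:
        logger.info("%s: dropped %d cross-namespace parent edge(s)", path, n_cross)
    dag = GoDag(terms=terms, parents=parents, namespace=namespace)
    dag.validate()
    return dag


def parse_gaf(path: str | Path, dag: GoDag) -> AnnotationSet:
    """Load GAF 2.x annotations: protein (col 2) -> GO term (col 5) by aspect.

    Rows with a NOT qualifier, aspect C, or terms absent from the DAG are
    dropped (the latter with a log message); malformed rows are logged and
    skipped.  Raises :class:`OntologyError` when no usable row remains.
    """
    ann: dict[str, dict[str, set[str]]] = {}
    n_unknown = n_bad = n_used = 0
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                n_bad += 1
                logger.warning("%s: malformed GAF row at line %d", path, lineno)
                continue
            protein, qualifier, term, aspect = fields[1], fields[3], fields[4], fields[8]
            if "NOT" in qualifier.split("|"):
                continue
            ns = _ASPECT_CODE.get(aspect)
            if ns is None:
                continue
            if term not in dag.terms:
                n_unknown += 1
                continue
            ann.setdefault(protein, {"MF": set(), "BP": set()})[ns].add(term)
            n_used += 1
    if n_unknown:
        logger.info("%s: dropped %d annotation(s) with unknown terms", path, n_unknown)
    if n_used == 0:
        raise OntologyError(f"{path}: no usable annotation rows")
    return AnnotationSet(annotations=ann)


def _svalues(dag: GoDag, term: str) -> dict[str, float]:
    """Wang S-values of ``term`` over its ancestor closure (term included).

    Max-product propagation up the DAG; since every contribution factor is
    < 1, a best-first (Dijkstra-style) traversal finalizes each ancestor the
    first time it is popped.
    """
    cached = dag._svalues.get(term)
    if cached is not None:
        return cached
    if term not in dag.terms:
        raise OntologyError(f"term {term} not in ontology")
    sv: dict[str, float] = {}
    heap: list[tuple[float, str]] = [(-1.0, term)]
    while heap:
        neg, t = heapq.heappop(heap)
        s = -neg
        if t in sv:
            continue
        sv[t] = s
        for parent, relation in dag.parents.get(t, ()):
            if parent not in sv:
                heapq.heappush(heap, (-(s * RELATION_WEIGHTS[relation]), parent))
    dag._svalues[term] = sv
    return sv


def wang_term_similarity(dag: GoDag, a: str, b: str) -> float:
    """Wang similarity of two terms in the same namespace.

    sim = sum over common ancestors t of (S_a(t) + S_b(t)) / (SV(a) + SV(b)).
    1.0 for identical terms, 0.0 for terms sharing no ancestor.
    """
    for t in (a, b):
        if t not in dag.terms:
            raise OntologyError(f"term {t} not in ontology")
    if dag.namespace[a] != dag.namespace[b]:
        raise OntologyError(
            f"namespace mismatch: {a} is {dag.namespace[a]}, {b} is {dag.namespace[b]}"
        )
    sa = _svalues(dag, a)
    sb = _svalues(dag, b)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def bma_similarity(dag: GoDag, terms_a: set[str], terms_b: set[str]) -> float:
    """Best-Match Average similarity of two non-empty same-namespace term sets.

    Mean of (average over a of max_b sim) and (average over b of max_a sim).
    """
    if not terms_a or not terms_b:
        raise OntologyError("bma_similarity requires non-empty term sets")
    la, lb = sorted(terms_a), sorted(terms_b)
    sims = [[wang_term_similarity(dag, a, b) for b in lb] for a in la]
    row = sum(max(r) for r in sims) / len(la)
    col = sum(max(sims[i][j] for i in range(len(la))) for j in range(len(lb))) / len(lb)
    return (row + col) / 2.0


def afs(
    alignment: Alignment,
    ann1: AnnotationSet,
    ann2: AnnotationSet,
    dag: GoDag,
    namespace: str,
) -> AfsReport:
    """Average Functional Similarity of an alignment in one namespace.

    Each aligned pair where both proteins carry at least one annotation in
    the namespace contributes its BMA score; AFS is the mean of those scores
    (undefined — reported as None — when nothing is scorable, never 0).
    ``pct_aligned_nodes`` is 100 x scored pairs / annotated smaller-network
    nodes, the per-namespace coverage of the alignment.
    """
    if namespace not in NAMESPACES:
        raise OntologyError(f"namespace must be one of {NAMESPACES}, got {namespace!r}")
    per_pair: list[tuple[str, str, float]] = []
    for u, v, _ in alignment.pairs:
        ta = ann1.terms(u, namespace)
        tb = ann2.terms(v, namespace)
        if ta and tb:
            per_pair.append((u, v, bma_similarity(dag, ta, tb)))
    n_annotated = len(ann1.annotated(namespace))
    pct = 100.0 * len(per_pair) / n_annotated if n_annotated else 0.0
    value = sum(s for _, _, s in per_pair) / len(per_pair) if per_pair else None
    return AfsReport(
        namespace=namespace,
        afs=value,
        pct_aligned_nodes=pct,
        n_pairs_scored=len(per_pair),
        per_pair=per_pair,
    )
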