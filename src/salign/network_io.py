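"""Reading, writing and validating PPI networks and alignments.

Networks are plain :class:`networkx.Graph` objects whose nodes are opaque
protein identifier strings.  Edges are undirected, unweighted presence
indicators (an interaction was reported or it was not); duplicate lines and
self-interactions in input files are collapsed or dropped at ingestion so the
rest of the pipeline only ever sees a simple graph.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

_HEADER_FIELD = re.compile(r"^[A-Za-z_]+$")


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass
class Alignment:
    """An injective mapping from the smaller network into the larger one.

    ``pairs`` holds ``(node_g1, node_g2, score)`` triples in the order the
    aligner produced them; ``mapping`` is the induced one-to-one dict.
    """

    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def mapping(self) -> dict[str, str]:
        return {u: v for u, v, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, net1: nx.Graph | None = None, net2: nx.Graph | None = None) -> None:
        """Check injectivity and (optionally) node membership.

        Raises ``ValueError`` on the first violated invariant.
        """
        lhs = [u for u, _, _ in self.pairs]
        rhs = [v for _, v, _ in self.pairs]
        if len(set(lhs)) != len(lhs) or len(set(rhs)) != len(rhs):
            raise ValueError("alignment is not one-to-one")
        if net1 is not None:
            missing = set(lhs) - set(net1.nodes)
            if missing:
                raise ValueError(f"aligned nodes absent from network 1: {sorted(missing)[:5]}")
        if net2 is not None:
            missing = set(rhs) - set(net2.nodes)
            if missing:
                raise ValueError(f"aligned nodes absent from network 2: {sorted(missing)[:5]}")
        if net1 is not None and net2 is not None:
            cap = min(net1.number_of_nodes(), net2.number_of_nodes())
            if len(self.pairs) > cap:
                raise ValueError(f"{len(self.pairs)} pairs exceeds min network size {cap}")


def network_sort_key(net: nx.Graph) -> tuple[int, int, str]:
    """Ordering used to decide which network is 'smaller' (the mapping domain)."""
    return (net.number_of_nodes(), net.number_of_edges(), str(net.graph.get("name", "")))


def smaller_first(net1: nx.Graph, net2: nx.Graph) -> tuple[nx.Graph, nx.Graph, bool]:
    """Return ``(smaller, larger, swapped)``; ties broken by edge count then name."""
    if network_sort_key(net1) <= network_sort_key(net2):
        return net1, net2, False
    return net2, net1, True


def _looks_like_header(fields: list[str], rest: Iterable[tuple[str, str]]) -> bool:
    # A header line such as "Uniprot_A\tUniprot_B": both lead fields are pure
    # word tokens and neither ever recurs as an edge endpoint.
    a, b = fields[0], fields[1]
    if not (_HEADER_FIELD.match(a) and _HEADER_FIELD.match(b)):
        return False
    endpoints = {n for pair in rest for n in pair}
    return a not in endpoints and b not in endpoints


def read_edgelist(path: str | Path, comment_prefix: str = "#") -> nx.Graph:
    """Read a 2+ column tab-separated edge list into an undirected graph.

    Duplicate edges collapse to one, self-loops are dropped (and counted in a
    log message), and a single leading header line is auto-detected and
    skipped.  Raises :class:`EdgeListError` on empty input or a line with
    fewer than two tab-separated fields (named by line number).
    """
    path = Path(path)
    rows: list[tuple[int, str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(comment_prefix):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListError(f"{path}: malformed edge line {lineno}: {line!r}")
            rows.append((lineno, fields[0].strip(), fields[1].strip()))

    if not rows:
        raise EdgeListError(f"{path}: no edges")
    if len(rows) > 1 and _looks_like_header(
        [rows[0][1], rows[0][2]], [(a, b) for _, a, b in rows[1:]]
    ):
        logger.info("%s: skipping header line %r", path, rows[0])
        rows = rows[1:]

    net = nx.Graph(name=path.stem)
    n_self = 0
    for _, a, b in rows:
        if a == b:
            n_self += 1
            net.add_node(a)
            continue
        net.add_edge(a, b, weight=1.0)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    if net.number_of_edges() == 0:
        raise EdgeListError(f"{path}: no edges")
    return net


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a sorted 2-column TSV (deterministic row order)."""
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as ``node_g1<TAB>node_g2<TAB>score`` rows.

    Rows are ordered by the smaller-network node ID so identical alignments
    serialize byte-identically.  An empty alignment yields an empty file.
    """
    alignment.validate()
    with Path(path).open("w") as fh:
        for u, v, score in sorted(alignment.pairs):
            fh.write(f"{u}\t{v}\t{score:.10g}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an alignment TSV written by :func:`write_alignment`."""
    pairs: list[tuple[str, str, float]] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeListError(f"{path}: malformed alignment line {lineno}: {line!r}")
            pairs.append((fields[0], fields[1], float(fields[2])))
    aln = Alignment(pairs=pairs)
    aln.validate()
    return aln
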