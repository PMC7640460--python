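"""Self-contained synthetic fixtures with a planted ground truth.

Real inputs to the aligner — two PPI networks, BLAST/TM-align similarity
matrices and GO annotations — are large downloads.  This module emulates all
of them at desk scale with a known answer:

* paired networks: an Erdős–Rényi draw and a relabeled copy with a chosen
  fraction of edges rewired, plus the true node correspondence;
* similarity matrices: true pairs draw from a high-mean truncated normal,
  non-pairs from a low-mean one, with a controllable fraction of proteins
  lacking structure entirely (missing entries, not zeros);
* a toy GO DAG (one rooted tree per namespace with a minority of part_of
  cross-links) and annotations in which true pairs share a chosen fraction
  of their terms.

Everything is deterministic given a seed, and every artifact can be written
in the same plain-text formats the readers consume (edge-list TSV,
similarity TSV, OBO, GAF), so generator output doubles as an end-to-end
round-trip oracle for the parsers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .biosim import SimMatrix, write_similarity_tsv
from .network_io import write_edgelist
from .ontology_eval import AnnotationSet, GoDag

#: non-pair similarity scores center here; true pairs at BASELINE + signal_mean.
#: Chosen so the non-pair/true-pair score ratio (~1:3 at the defaults) echoes
#: how unrelated-protein BLAST bit scores sit far below homolog scores, while
#: staying 2 sd above the clip at 0.
BASELINE_SCORE = 0.5


@dataclass
class SyntheticBundle:
    """One complete synthetic study: networks, similarities, ontology, truth."""

    net1: nx.Graph
    net2: nx.Graph
    true_mapping: dict[str, str]
    seq_sim: SimMatrix
    struct_sim: SimMatrix
    dag: GoDag
    ann1: AnnotationSet
    ann2: AnnotationSet
    params: dict = field(default_factory=dict)


def make_paired_networks(
    n_nodes: int, edge_p: float, rewire_fraction: float, seed: int
) -> tuple[nx.Graph, nx.Graph, dict[str, str]]:
    """An Erdős–Rényi network and a rewired relabeled copy with known truth.

    ``rewire_fraction`` of the copy's edges are replaced by uniformly random
    new node pairs; at 0 the copy is isomorphic to the original under the
    returned mapping, at 1 it shares only chance edge overlap.
    """
    if n_nodes < 3:
        raise ValueError(f"n_nodes must be >= 3, got {n_nodes}")
    if not 0.0 < edge_p < 1.0:
        raise ValueError(f"edge_p must be in (0, 1), got {edge_p}")
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError(f"rewire_fraction must be in [0, 1], got {rewire_fraction}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_nodes - 1)))

    base = nx.gnp_random_graph(n_nodes, edge_p, seed=int(rng.integers(2**31)))
    nodes1 = [f"a{i:0{width}d}" for i in range(n_nodes)]
    net1 = nx.Graph(name="net1")
    net1.add_nodes_from(nodes1)
    net1.add_edges_from((nodes1[i], nodes1[j]) for i, j in base.edges)

    perm = rng.permutation(n_nodes)
    nodes2 = [f"b{i:0{width}d}" for i in range(n_nodes)]
    true_mapping = {nodes1[i]: nodes2[perm[i]] for i in range(n_nodes)}
    net2 = nx.Graph(name="net2")
    net2.add_nodes_from(nodes2)
    net2.add_edges_from((true_mapping[a], true_mapping[b]) for a, b in net1.edges)

    edges = sorted(tuple(sorted(e)) for e in net2.edges)
    n_rewire = round(rewire_fraction * len(edges))
    if n_rewire:
        chosen = rng.choice(len(edges), size=n_rewire, replace=False)
        for idx in chosen:
            net2.remove_edge(*edges[idx])
        for _ in chosen:
            while True:
                a, b = rng.choice(n_nodes, size=2, replace=False)
                u, v = nodes2[a], nodes2[b]
                if not net2.has_edge(u, v):
                    net2.add_edge(u, v)
                    break
    return net1, net2, true_mapping


def make_similarity(
    true_mapping: dict[str, str],
    nodes1: list[str],
    nodes2: list[str],
    signal_mean: float,
    noise_sd: float,
    missing_struct_fraction: float,
    seed: int,
) -> tuple[SimMatrix, SimMatrix]:
    """Dense sequence and structure score matrices favoring the true pairs.

    True pairs draw from Normal(BASELINE + signal_mean, noise_sd), non-pairs
    from Normal(BASELINE, noise_sd); draws are clipped at 0.  A
    ``missing_struct_fraction`` of proteins on each side has no structure:
    every pair involving one of them is absent from the structure matrix.
    """
    if not 0.0 <= missing_struct_fraction <= 1.0:
        raise ValueError(
            f"missing_struct_fraction must be in [0, 1], got {missing_struct_fraction}"
        )
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    nodes1 = sorted(nodes1)
    nodes2 = sorted(nodes2)
    true_pairs = {(u, true_mapping[u]) for u in nodes1 if u in true_mapping}

    def draw_matrix(gen: np.random.Generator) -> dict[tuple[str, str], float]:
        raw = gen.normal(BASELINE_SCORE, noise_sd, size=(len(nodes1), len(nodes2)))
        entries: dict[tuple[str, str], float] = {}
        for i, u in enumerate(nodes1):
            for j, v in enumerate(nodes2):
                score = raw[i, j] + (signal_mean if (u, v) in true_pairs else 0.0)
                entries[(u, v)] = max(0.0, score)
        return entries

    seq = SimMatrix(role="sequence", entries=draw_matrix(rng))
    struct_entries = draw_matrix(rng)
    n_miss1 = math.ceil(missing_struct_fraction * len(nodes1))
    n_miss2 = math.ceil(missing_struct_fraction * len(nodes2))
    missing1 = set(rng.choice(nodes1, size=n_miss1, replace=False)) if n_miss1 else set()
    missing2 = set(rng.choice(nodes2, size=n_miss2, replace=False)) if n_miss2 else set()
    struct_entries = {
        (u, v): s
        for (u, v), s in struct_entries.items()
        if u not in missing1 and v not in missing2
    }
    struct = SimMatrix(role="structure", entries=struct_entries)
    return seq, struct


def make_toy_ontology(
    n_terms: int,
    branching: int,
    n_proteins: int,
    shared_fraction: float,
    seed: int,
    pairs: list[tuple[str, str]] | None = None,
    terms_per_protein: int = 3,
) -> tuple[GoDag, AnnotationSet, AnnotationSet]:
    """A toy GO DAG (MF + BP) and annotations for paired proteins.

    Each namespace is a rooted ``branching``-ary tree of ``n_terms`` is_a
    edges plus a minority of part_of cross-links.  Protein i on side 1 gets
    ``terms_per_protein`` random non-root terms per namespace; its partner
    shares ``round(shared_fraction * k)`` of them and draws the rest
    elsewhere.  ``pairs`` supplies the (protein1, protein2) identifier pairs;
    by default ``p000/q000``-style names are generated.
    """
    if n_terms < 3:
        raise ValueError(f"n_terms must be >= 3, got {n_terms}")
    if branching < 1:
        raise ValueError(f"branching must be >= 1, got {branching}")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = [(f"p{i:03d}", f"q{i:03d}") for i in range(n_proteins)]

    terms: set[str] = set()
    parents: dict[str, set[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    ns_terms: dict[str, list[str]] = {}
    for ns, prefix in (("MF", 1), ("BP", 2)):
        ids = [f"GO:{prefix}{i:06d}" for i in range(n_terms)]
        ns_terms[ns] = ids
        for i, t in enumerate(ids):
            terms.add(t)
            namespace[t] = ns
            if i > 0:
                parents.setdefault(t, set()).add((ids[(i - 1) // branching], "is_a"))
                # sparse part_of cross-links toward lower-index terms keep the DAG acyclic
                if i >= 5 and i % 5 == 0:
                    extra = ids[int(rng.integers(0, (i - 1) // branching + 1))]
                    if all(p != extra for p, _ in parents[t]):
                        parents[t].add((extra, "part_of"))
    dag = GoDag(terms=terms, parents=parents, namespace=namespace)
    dag.validate()

    ann1: dict[str, dict[str, set[str]]] = {}
    ann2: dict[str, dict[str, set[str]]] = {}
    k = min(terms_per_protein, n_terms - 1)
    n_shared = round(shared_fraction * k)
    for p1, p2 in pairs:
        ann1.setdefault(p1, {"MF": set(), "BP": set()})
        ann2.setdefault(p2, {"MF": set(), "BP": set()})
        for ns in ("MF", "BP"):
            non_root = ns_terms[ns][1:]
            mine = set(rng.choice(non_root, size=k, replace=False))
            shared = set(rng.choice(sorted(mine), size=n_shared, replace=False))
            other = shared | set(
                rng.choice(sorted(set(non_root) - mine), size=k - n_shared, replace=False)
            )
            ann1[p1][ns] = mine
            ann2[p2][ns] = other
    return dag, AnnotationSet(annotations=ann1), AnnotationSet(annotations=ann2)


def make_bundle(
    n_nodes: int = 200,
    edge_p: float = 0.05,
    rewire_fraction: float = 0.1,
    signal_mean: float = 1.0,
    noise_sd: float = 0.25,
    missing_struct_fraction: float = 0.3,
    n_terms: int = 40,
    branching: int = 3,
    shared_fraction: float = 0.8,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate a complete synthetic study with consistent ground truth."""
    net1, net2, true_mapping = make_paired_networks(n_nodes, edge_p, rewire_fraction, seed)
    seq, struct = make_similarity(
        true_mapping,
        sorted(net1.nodes),
        sorted(net2.nodes),
        signal_mean,
        noise_sd,
        missing_struct_fraction,
        seed + 1,
    )
    dag, ann1, ann2 = make_toy_ontology(
        n_terms,
        branching,
        n_nodes,
        shared_fraction,
        seed + 2,
        pairs=sorted(true_mapping.items()),
    )
    return SyntheticBundle(
        net1=net1,
        net2=net2,
        true_mapping=true_mapping,
        seq_sim=seq,
        struct_sim=struct,
        dag=dag,
        ann1=ann1,
        ann2=ann2,
        params=dict(
            n_nodes=n_nodes,
            edge_p=edge_p,
            rewire_fraction=rewire_fraction,
            signal_mean=signal_mean,
            noise_sd=noise_sd,
            missing_struct_fraction=missing_struct_fraction,
            n_terms=n_terms,
            branching=branching,
            shared_fraction=shared_fraction,
            seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# writers (plain-text formats matching the package's readers)
# ---------------------------------------------------------------------------


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a GoDag as an OBO 1.2 flat file."""
    ns_name = {"MF": "molecular_function", "BP": "biological_process", "CC": "cellular_component"}
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term.replace(':', '_')}\n")
            fh.write(f"namespace: {ns_name[dag.namespace[term]]}\n")
            for parent, relation in sorted(dag.parents.get(term, ())):
                if relation == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {relation} {parent}\n")


def write_gaf(ann: AnnotationSet, path: str | Path, db: str = "SYN") -> None:
    """Serialize an AnnotationSet as a GAF 2.1 file (evidence code IEA)."""
    aspect = {"MF": "F", "BP": "P"}
    with Path(path).open("w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for protein in sorted(ann.annotations):
            for ns in ("MF", "BP"):
                for term in sorted(ann.annotations[protein].get(ns, ())):
                    row = [
                        db, protein, protein, "", term, "SYN:0000001", "IEA", "",
                        aspect[ns], protein, "", "protein", "taxon:0000", "20200101",
                        db, "", "",
                    ]
                    fh.write("\t".join(row) + "\n")


def write_truth(true_mapping: dict[str, str], path: str | Path) -> None:
    """Write the planted correspondence as a 2-column TSV."""
    with Path(path).open("w") as fh:
        for u, v in sorted(true_mapping.items()):
            fh.write(f"{u}\t{v}\n")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> list[Path]:
    """Write all eight fixture files into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "net1.tsv": lambda p: write_edgelist(bundle.net1, p),
        "net2.tsv": lambda p: write_edgelist(bundle.net2, p),
        "truth.tsv": lambda p: write_truth(bundle.true_mapping, p),
        "seqsim.tsv": lambda p: write_similarity_tsv(bundle.seq_sim, p),
        "structsim.tsv": lambda p: write_similarity_tsv(bundle.struct_sim, p),
        "toy.obo": lambda p: write_obo(bundle.dag, p),
        "ann1.gaf": lambda p: write_gaf(bundle.ann1, p),
        "ann2.gaf": lambda p: write_gaf(bundle.ann2, p),
    }
    written = []
    for name, writer in paths.items():
        target = outdir / name
        writer(target)
        written.append(target)
    return written
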