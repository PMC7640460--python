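"""salign: structure-aware global pairwise alignment of PPI networks.

Pipeline: per-network topological importances via minimum-degree reduction
(topology), a biological matrix fusing normalized BLAST and TM-align scores
(biosim), convex combination into the final score matrix and greedy or
Monte Carlo one-to-one alignment (aligner), and GO-based evaluation with
Wang/BMA Average Functional Similarity (ontology_eval).  The synthetic
module generates complete desk-scale studies with a planted ground truth.
"""

from __future__ import annotations

import networkx as nx

from . import aligner, biosim, network_io, ontology_eval, synthetic, topology
from .aligner import Params
from .biosim import SimMatrix
from .network_io import Alignment

__version__ = "0.1.0"

__all__ = [
    "Params",
    "SimMatrix",
    "Alignment",
    "align_networks",
    "aligner",
    "biosim",
    "network_io",
    "ontology_eval",
    "synthetic",
    "topology",
]


def align_networks(
    net1: nx.Graph,
    net2: nx.Graph,
    seq_sim: SimMatrix,
    struct_sim: SimMatrix | None = None,
    params: Params | None = None,
    method: str = "greedy",
) -> Alignment:
    """Run the full pipeline: topology + biology -> score fusion -> alignment.

    ``seq_sim``/``struct_sim`` are raw (un-normalized) similarity matrices
    keyed (node-of-net1, node-of-net2); ``struct_sim`` may be None or empty
    when no structural data exists, in which case the biological score is
    the normalized sequence score alone.
    """
    params = params or Params()
    if method not in ("greedy", "mc"):
        raise ValueError(f"method must be 'greedy' or 'mc', got {method!r}")

    tw1 = topology.min_degree_reduce(net1, d=params.d)
    tw2 = topology.min_degree_reduce(net2, d=params.d)
    T = topology.topo_similarity(tw1, tw2)

    seq_n = biosim.normalize(seq_sim) if seq_sim.entries else SimMatrix("sequence", {}, True)
    if struct_sim is not None and struct_sim.entries:
        struct_n = biosim.normalize(struct_sim)
    else:
        struct_n = SimMatrix(role="structure", entries={}, normalized=True)
    B = biosim.combine_bio(seq_n, struct_n, params.beta)

    A = aligner.alignment_scores(T, B, params.alpha)
    if method == "greedy":
        return aligner.greedy_align(A, net1, net2)
    return aligner.mc_align(A, net1, net2, params)
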