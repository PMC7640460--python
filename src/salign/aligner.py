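"""Final score fusion and one-to-one network alignment.

The final alignment score of a cross-network node pair is a convex
combination of topological and biological similarity::

    A = alpha * T + (1 - alpha) * B

With the default alpha = 0.1 the biological score contributes 90% of the
final score.  Alignment proceeds seed-and-extend: the globally best-scoring
pair seeds the mapping, then neighbors of already-aligned nodes are
prioritized — the frontier holds pairs (u, v) where u neighbors an aligned
node u' in the smaller network and v neighbors g(u') in the larger — which
keeps the alignment topologically consistent.  When the frontier empties the
loop re-seeds from the best remaining pair, so all of the smaller network is
aligned whenever scored candidates remain.

The greedy aligner always takes the best frontier pair.  The Monte Carlo
variant visits nodes in the same order but draws the partner from the top-n
candidates with Boltzmann probabilities

    NS_i   = n_i / s                      (scores normalized over the top n)
    Prob_i = exp(-(best - NS_i)/KT) / sum_i exp(-(best - NS_i)/KT)

where best is the maximum normalized score and K*T = 0.1 by default.
Distinct seeds give alternative alignments of similar quality; n_top = 1
reproduces the greedy alignment exactly.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import networkx as nx
import numpy as np

from .biosim import SimMatrix
from .network_io import Alignment, smaller_first

logger = logging.getLogger(__name__)


@dataclass
class Params:
    """Tunable parameters of the full pipeline.

    alpha  weight of topology in the final score (default 0.1);
    beta   weight of sequence within the biological score (default 0.7;
           use 0.9 when few proteins have solved structures);
    d      degree threshold of the minimum-degree reduction (default 10);
    n_top  Monte Carlo candidate pool size (default 10);
    kT     Boltzmann temperature product (default 0.1);
    seed   random seed for the Monte Carlo aligner.
    """

    alpha: float = 0.1
    beta: float = 0.7
    d: int = 10
    n_top: int = 10
    kT: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.n_top < 1:
            raise ValueError(f"n_top must be >= 1, got {self.n_top}")
        if self.kT <= 0:
            raise ValueError(f"kT must be > 0, got {self.kT}")

    #: preset for species pairs with sparse structural coverage
    @classmethod
    def low_structure(cls, **kwargs) -> "Params":
        kwargs.setdefault("beta", 0.9)
        return cls(**kwargs)


@dataclass
class CandidateSet:
    """Top-n partner candidates of one smaller-network node."""

    candidates: list[tuple[str, float]]  # (node-of-G2, raw alignment score), sorted
    normalized: list[float] | None = None
    probabilities: list[float] | None = None

    @property
    def sum_s(self) -> float:
        return sum(s for _, s in self.candidates)

    @property
    def best(self) -> float:
        if self.normalized is None:
            raise ValueError("normalize_topn has not been applied")
        return max(self.normalized)

    def __len__(self) -> int:
        return len(self.candidates)


def alignment_scores(T: SimMatrix, B: SimMatrix, alpha: float) -> SimMatrix:
    """Fuse topological and biological matrices: A = alpha*T + (1-alpha)*B.

    Defined on the union of pairs present in either matrix; a missing
    component contributes 0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    entries: dict[tuple[str, str], float] = {}
    for key in T.entries.keys() | B.entries.keys():
        entries[key] = alpha * T.entries.get(key, 0.0) + (1.0 - alpha) * B.entries.get(key, 0.0)
    return SimMatrix(role="alignment", entries=entries, normalized=True)


def topn_candidates(
    A: SimMatrix, u: str, unaligned: set[str], n_top: int
) -> CandidateSet:
    """The up-to-n_top best-scoring unaligned partners of ``u``.

    Sorted by score descending, ties by lexicographic partner ID.  Empty when
    ``u`` has no scored unaligned candidate.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    scored = [
        (v, A.entries[(u, v)]) for v in unaligned if (u, v) in A.entries
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return CandidateSet(candidates=scored[:n_top])


def normalize_topn(cands: CandidateSet) -> CandidateSet:
    """Normalize candidate scores to proportions: NS_i = n_i / s.

    ``s`` is the score sum over the candidate list.  All-zero scores fall
    back to the uniform distribution (logged), the symmetric completion of a
    0/0 division.
    """
    if not cands.candidates:
        raise ValueError("cannot normalize an empty candidate set")
    s = cands.sum_s
    if s <= 0:
        logger.info("all-zero candidate scores: using uniform normalized scores")
        ns = [1.0 / len(cands)] * len(cands)
    else:
        ns = [score / s for _, score in cands.candidates]
    return replace(cands, normalized=ns)


def mc_probabilities(cands: CandidateSet, kT: float) -> CandidateSet:
    """Boltzmann selection probabilities referenced to the best candidate.

    Prob_i = exp(-(best - NS_i)/kT) / sum_j exp(-(best - NS_j)/kT).  The
    probabilities sum to 1 and the best candidate is always the mode; as
    kT -> 0 the distribution collapses onto the best candidate (greedy limit).
    """
    if kT <= 0:
        raise ValueError(f"kT must be > 0, got {kT}")
    if cands.normalized is None:
        raise ValueError("normalize_topn must run before mc_probabilities")
    best = max(cands.normalized)
    weights = [math.exp(-(best - ns) / kT) for ns in cands.normalized]
    total = sum(weights)
    return replace(cands, probabilities=[w / total for w in weights])


# ---------------------------------------------------------------------------
# alignment loops
# ---------------------------------------------------------------------------


def _transpose(A: SimMatrix) -> SimMatrix:
    return SimMatrix(
        role=A.role,
        entries={(v, u): s for (u, v), s in A.entries.items()},
        normalized=A.normalized,
    )


def _align_loop(
    A: SimMatrix,
    net1: nx.Graph,
    net2: nx.Graph,
    select: Callable[[str, list[tuple[str, float]]], str],
) -> Alignment:
    """Shared seed-and-extend loop; ``select(u, sorted_candidates) -> v``.

    ``sorted_candidates`` is the eligible (unaligned, scored) partner list of
    ``u``, sorted by score descending then partner ID.  The greedy aligner
    selects the head; the Monte Carlo aligner samples.
    """
    small, large, swapped = smaller_first(net1, net2)
    if swapped:
        A = _transpose(A)
    # similarity files may score proteins the edge lists never mention;
    # only network members are alignable
    entries = {
        (u, v): s for (u, v), s in A.entries.items() if u in small and v in large
    }
    if len(entries) != len(A.entries):
        logger.info(
            "ignoring %d scored pair(s) outside the networks", len(A.entries) - len(entries)
        )
    A = SimMatrix(role=A.role, entries=entries, normalized=A.normalized)

    by_u: dict[str, dict[str, float]] = {}
    for (u, v), s in A.entries.items():
        by_u.setdefault(u, {})[v] = s

    # global heap for seeding, frontier heap for extension; both lazy
    global_heap = [(-s, u, v) for (u, v), s in A.entries.items()]
    heapq.heapify(global_heap)
    frontier_heap: list[tuple[float, str, str]] = []
    frontier_partners: dict[str, set[str]] = {}

    aligned1: dict[str, str] = {}
    aligned2: set[str] = set()
    pairs: list[tuple[str, str, float]] = []

    def eligible(u: str, pool: set[str] | None) -> list[tuple[str, float]]:
        scores = by_u.get(u, {})
        if pool is None:
            cand = [(v, s) for v, s in scores.items() if v not in aligned2]
        else:
            cand = [(v, scores[v]) for v in pool if v not in aligned2 and v in scores]
        cand.sort(key=lambda t: (-t[1], t[0]))
        return cand

    def commit(u: str, v: str) -> None:
        aligned1[u] = v
        aligned2.add(v)
        pairs.append((u, v, by_u[u][v]))
        for up in small.adj[u]:
            if up in aligned1:
                continue
            for vp in large.adj[v]:
                if vp in aligned2 or (up, vp) not in A.entries:
                    continue
                heapq.heappush(frontier_heap, (-A.entries[(up, vp)], up, vp))
                frontier_partners.setdefault(up, set()).add(vp)

    n_target = small.number_of_nodes()
    while len(aligned1) < n_target:
        u = None
        pool: set[str] | None = None
        while frontier_heap:
            _, fu, fv = heapq.heappop(frontier_heap)
            if fu not in aligned1 and fv not in aligned2:
                u, pool = fu, frontier_partners.get(fu, set())
                break
        if u is None:
            while global_heap:
                _, gu, gv = heapq.heappop(global_heap)
                if gu not in aligned1 and gv not in aligned2:
                    u, pool = gu, None
                    break
        if u is None:
            break  # no scored pairs remain
        cand = eligible(u, pool)
        if not cand:
            continue
        commit(u, select(u, cand))

    aln = Alignment(pairs=pairs)
    aln.validate(small, large)
    return aln


def greedy_align(A: SimMatrix, net1: nx.Graph, net2: nx.Graph) -> Alignment:
    """Deterministic greedy alignment: always take the best eligible pair.

    Ties break by larger score, then lexicographic node IDs; identical inputs
    always give the identical alignment.
    """
    return _align_loop(A, net1, net2, select=lambda u, cand: cand[0][0])


def mc_align(A: SimMatrix, net1: nx.Graph, net2: nx.Graph, params: Params) -> Alignment:
    """Monte Carlo (semi-greedy) alignment.

    Same node-visit order as :func:`greedy_align`, but each partner is drawn
    from the Boltzmann probabilities over the top ``params.n_top`` eligible
    candidates.  Fixed ``params.seed`` gives a fixed alignment; different
    seeds generally give alternative alignments.
    """
    rng = np.random.default_rng(params.seed)

    def select(u: str, cand: list[tuple[str, float]]) -> str:
        cset = CandidateSet(candidates=cand[: params.n_top])
        if len(cset) == 1:
            return cset.candidates[0][0]
        cset = mc_probabilities(normalize_topn(cset), params.kT)
        idx = int(rng.choice(len(cset), p=cset.probabilities))
        return cset.candidates[idx][0]

    return _align_loop(A, net1, net2, select=select)
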