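"""Biological similarity: fusing sequence and structure scores.

The biological score of a cross-network protein pair blends a normalized
sequence-similarity score SQ (BLAST bit scores) with a normalized structure
similarity score SS (TM-align TM-scores)::

    B = (1 - beta) * SS + beta * SQ

``beta`` weights sequence against structure: beta=0.7 gives sequence 70% of
the biological score.  Pairs for which no structure comparison exists fall
back to the sequence score alone rather than being penalized with SS=0 —
structural coverage of proteomes is sparse and absence of a solved structure
is missing knowledge, not evidence of dissimilarity.

Raw scores come from external tools (blastp, TM-align), either via the thin
wrappers here or as precomputed 3-column TSVs.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path

logger = logging.getLogger(__name__)

#: valid roles for a similarity matrix
ROLES = ("sequence", "structure", "biological", "topological", "alignment")


@dataclass
class SimMatrix:
    """A sparse (node-of-G1, node-of-G2) -> score map with a role tag.

    Missing entries mean 0 for every role except ``structure``, where a
    missing entry means "no structure available for at least one member" and
    is distinct from an explicit 0.
    """

    role: str
    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")

    def get(self, u: str, v: str, default: float = 0.0) -> float:
        return self.entries.get((u, v), default)

    def max_entry(self) -> float:
        return max(self.entries.values(), default=0.0)

    def __len__(self) -> int:
        return len(self.entries)


class SimilarityError(ValueError):
    """Raised for malformed similarity input."""


def read_similarity_tsv(path: str | Path, role: str) -> SimMatrix:
    """Read an ``id1<TAB>id2<TAB>score`` file into an un-normalized SimMatrix.

    Duplicate (id1, id2) rows keep the maximum score (logged).  Negative
    scores and malformed rows raise :class:`SimilarityError` naming the line.
    """
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SimilarityError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise SimilarityError(
                    f"{path}: unparseable score at line {lineno}: {fields[2]!r}"
                ) from exc
            if score < 0:
                raise SimilarityError(f"{path}: negative score at line {lineno}: {score}")
            key = (fields[0], fields[1])
            if key in entries:
                n_dup += 1
                entries[key] = max(entries[key], score)
            else:
                entries[key] = score
    if n_dup:
        logger.info("%s: %d duplicate pair(s), kept the maximum score", path, n_dup)
    return SimMatrix(role=role, entries=entries, normalized=False)


def write_similarity_tsv(sim: SimMatrix, path: str | Path) -> None:
    """Write a SimMatrix as a sorted 3-column TSV."""
    with Path(path).open("w") as fh:
        for (u, v), score in sorted(sim.entries.items()):
            fh.write(f"{u}\t{v}\t{score:.10g}\n")


def normalize(sim: SimMatrix) -> SimMatrix:
    """Scale all entries into [0, 1] by dividing by the global maximum.

    Max-division is monotone (rank-preserving) and parameter-free.  An
    all-zero matrix is returned unchanged with a logged warning so that the
    downstream convex combinations remain well defined.
    """
    if not sim.entries:
        raise SimilarityError(f"cannot normalize empty {sim.role} matrix")
    top = sim.max_entry()
    if top <= 0:
        logger.warning("all-zero %s matrix: normalization is a no-op", sim.role)
        return replace(sim, entries=dict(sim.entries), normalized=True)
    return replace(
        sim,
        entries={k: v / top for k, v in sim.entries.items()},
        normalized=True,
    )


def combine_bio(seq: SimMatrix, struct: SimMatrix, beta: float) -> SimMatrix:
    """Blend normalized sequence and structure scores into the biological matrix.

    For pairs with both scores ``B = (1-beta)*SS + beta*SQ``; for pairs with
    no structure comparison ``B = SQ`` (full weight to sequence).  ``beta``
    must lie in [0, 1] and both inputs must already be normalized.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if not (seq.normalized and struct.normalized) and (seq.entries or struct.entries):
        raise ValueError("combine_bio requires normalized inputs")
    if seq.role != "sequence" or struct.role != "structure":
        raise ValueError("combine_bio expects (sequence, structure) matrices")

    entries: dict[tuple[str, str], float] = {}
    for key in seq.entries.keys() | struct.entries.keys():
        sq = seq.entries.get(key, 0.0)
        if key in struct.entries:
            entries[key] = (1.0 - beta) * struct.entries[key] + beta * sq
        else:
            entries[key] = sq
    return SimMatrix(role="biological", entries=entries, normalized=True)


# ---------------------------------------------------------------------------
# external-tool wrappers (optional; precomputed TSVs are always accepted)
# ---------------------------------------------------------------------------


def parse_blast_tab(text: str) -> SimMatrix:
    """Parse blastp tabular output (``qseqid sseqid bitscore`` columns)."""
    entries: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise SimilarityError(f"malformed blastp tabular row: {line!r}")
        key = (fields[0], fields[1])
        score = float(fields[2])
        entries[key] = max(entries.get(key, 0.0), score)
    return SimMatrix(role="sequence", entries=entries, normalized=False)


def run_blastp_pairs(
    fasta1: str | Path, fasta2: str | Path, blastp_exe: str = "blastp"
) -> SimMatrix:
    """All-vs-all blastp bit scores between two FASTA files.

    FASTA record IDs must match network node IDs.  Absent hits are absent
    entries.  If the executable is missing, the error directs the user to
    supply a precomputed similarity TSV instead.
    """
    fasta1, fasta2 = Path(fasta1), Path(fasta2)
    for fa in (fasta1, fasta2):
        if not fa.exists() or fa.stat().st_size == 0:
            raise SimilarityError(f"empty or missing FASTA: {fa}")
    if shutil.which(blastp_exe) is None:
        raise SimilarityError(
            f"{blastp_exe!r} not found on PATH; run blastp elsewhere and provide "
            "a precomputed 3-column similarity TSV via read_similarity_tsv"
        )
    proc = subprocess.run(
        [blastp_exe, "-query", str(fasta1), "-subject", str(fasta2),
         "-outfmt", "6 qseqid sseqid bitscore"],
        capture_output=True, text=True, check=True,
    )
    return parse_blast_tab(proc.stdout)


_TM_SCORE = re.compile(r"TM-score=\s*([0-9.]+)")
_TM_CHAIN = re.compile(r"Name of Chain_([12]):\s*(\S+)")


def parse_tmalign_output(text: str) -> tuple[tuple[str, str], float] | None:
    """Extract ``((id1, id2), tm_score)`` from one TM-align stdout transcript.

    When TM-align prints two TM-scores (normalized by each chain length) the
    larger — i.e. the one normalized by the shorter chain — is kept.  Chain
    names are reduced to their file stem.  Returns ``None`` if no score is
    present.
    """
    chains = dict(_TM_CHAIN.findall(text))
    scores = [float(s) for s in _TM_SCORE.findall(text)]
    if not scores or "1" not in chains or "2" not in chains:
        return None
    id1 = Path(chains["1"]).stem
    id2 = Path(chains["2"]).stem
    return (id1, id2), max(scores)


def run_tmalign_pairs(
    pdb_dir1: str | Path, pdb_dir2: str | Path, tmalign_exe: str = "TMalign"
) -> SimMatrix:
    """All-vs-all TM-align TM-scores between two directories of PDB files.

    PDB files are named ``<node_id>.pdb``.  Proteins without a structure file
    simply contribute no entries (missing, not zero).  Multiple structures per
    protein keep the maximum TM-score.
    """
    pdb_dir1, pdb_dir2 = Path(pdb_dir1), Path(pdb_dir2)
    if shutil.which(tmalign_exe) is None:
        raise SimilarityError(
            f"{tmalign_exe!r} not found on PATH; run TM-align elsewhere and provide "
            "a precomputed 3-column similarity TSV via read_similarity_tsv"
        )
    entries: dict[tuple[str, str], float] = {}
    for p1 in sorted(pdb_dir1.glob("*.pdb")):
        for p2 in sorted(pdb_dir2.glob("*.pdb")):
            proc = subprocess.run(
                [tmalign_exe, str(p1), str(p2)], capture_output=True, text=True, check=True
            )
            parsed = parse_tmalign_output(proc.stdout)
            if parsed is None:
                continue
            key = (p1.stem, p2.stem)
            entries[key] = max(entries.get(key, 0.0), parsed[1])
    return SimMatrix(role="structure", entries=entries, normalized=False)
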