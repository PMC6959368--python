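"""Sequence-level tools for solubility-tag comparisons and NT phylogenetics.

Covers the sequence side of spidroin N-terminal-domain (NT) tag design:
charge profiles (charged-residue count and net charge, the properties that
drive tag solubility), pairwise percent identity from a global alignment,
Poisson-corrected evolutionary distances d = -ln(1 - p), and classical
Neighbor-Joining tree reconstruction with deterministic tie-breaking.

Charge convention: charged residues are D, E, K, R; net charge counts
K, R as +1 and D, E as -1; histidine is treated as neutral (appropriate
near pH 7) and termini are ignored.  The residue sets are arguments, so
other conventions are one call away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "DistanceMatrix",
    "charge_profile",
    "pairwise_identity",
    "p_distance",
    "poisson_distance",
    "poisson_distance_matrix",
    "nj_tree",
    "read_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NEGATIVE = frozenset("DE")
POSITIVE = frozenset("KR")
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence (uppercase one-letter code, X allowed)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        for pos, aa in enumerate(self.residues):
            if aa not in AMINO_ACIDS and aa not in GAP_CHARS:
                raise ValueError(
                    f"invalid character {aa!r} at position {pos + 1} "
                    f"in sequence {self.id!r}"
                )

    def ungapped(self) -> str:
        return "".join(aa for aa in self.residues if aa not in GAP_CHARS)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered taxon labels."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(np.diag(d) != 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(d < 0.0):
            raise ValueError("distances must be non-negative")


def charge_profile(
    seq: SequenceRecord,
    *,
    charged: frozenset = NEGATIVE | POSITIVE,
    positive: frozenset = POSITIVE,
    negative: frozenset = NEGATIVE,
) -> tuple[int, int]:
    """(number of charged residues, net charge) of a sequence.

    Defaults: charged = {D,E,K,R}; net = #{K,R} - #{D,E}; H neutral.
    """
    residues = seq.ungapped()
    n_charged = sum(aa in charged for aa in residues)
    net = sum(aa in positive for aa in residues) - \
        sum(aa in negative for aa in residues)
    return n_charged, net


_ALIGNER = None


def _get_aligner():
    """Global BLOSUM62 aligner, gap open 10 / extend 0.5 (conventional)."""
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _ALIGNER = aligner
    return _ALIGNER


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Percent identity from a global BLOSUM62 alignment.

    identity = identical columns / alignment length * 100.  The alignment
    settings (BLOSUM62, gap open 10, extend 0.5) matter for borderline
    comparisons and are fixed and documented here.
    """
    sa, sb = a.ungapped(), b.ungapped()
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aligner = _get_aligner()
    alignment = aligner.align(sa, sb)[0]
    matches = 0
    length = alignment.length
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matches += sum(x == y for x, y in zip(sa[a0:a1], sb[b0:b1]))
    return 100.0 * matches / length


def p_distance(
    a: SequenceRecord, b: SequenceRecord, *, complete_deletion_mask=None
) -> float:
    """Proportion of differing sites between two *aligned* sequences.

    Pairwise deletion: columns with a gap in either sequence are ignored.
    Pass a boolean ``complete_deletion_mask`` (True = keep column) to use
    complete deletion computed over a whole alignment instead.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError("aligned sequences must have equal length")
    used = diffs = 0
    for i, (x, y) in enumerate(zip(a.residues, b.residues)):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        if complete_deletion_mask is not None and not complete_deletion_mask[i]:
            continue
        used += 1
        diffs += x != y
    if used == 0:
        raise ValueError("no comparable columns")
    return diffs / used


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p) for p in [0, 1)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p}")
    return -math.log1p(-p)


def poisson_distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances from an aligned sequence set."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(
                p_distance(records[i], records[j])
            )
    return DistanceMatrix(labels=tuple(r.id for r in records), d=d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Classical Neighbor-Joining; returns an unrooted Newick string.

    Saitou–Nei Q-criterion, deterministic lowest-index tie-breaking,
    branch lengths clamped at 0.  Exact on additive (tree-metric) inputs.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [f"{label}" for label in dm.labels]
    active = list(range(n))

    def fmt(node: str, length: float) -> str:
        return f"{node}:{max(length, 0.0):.10g}"

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on flattened row-major array
        flat = int(np.argmin(q))
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        merged = f"({fmt(nodes[ai], li)},{fmt(nodes[aj], lj)})"
        # distances from the new node to every remaining taxon
        new_idx = ai  # reuse slot ai
        for m in active:
            if m in (ai, aj):
                continue
            d[new_idx, m] = d[m, new_idx] = 0.5 * (d[ai, m] + d[aj, m] - dij)
        d[new_idx, new_idx] = 0.0
        nodes[ai] = merged
        active.remove(aj)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return f"({fmt(nodes[a], la)},{fmt(nodes[b], lb)},{fmt(nodes[c], lc)});"


def read_fasta(path) -> list[SequenceRecord]:
    """Read sequences (optionally aligned) from a FASTA file."""
    from Bio import SeqIO

    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records
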