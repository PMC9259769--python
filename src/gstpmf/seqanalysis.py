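"""Pairwise alignment, MSA conservation, distance matrices and NJ trees.

Global (and optionally local) affine-gap alignment uses BLOSUM62 with the
unknown residue ``X`` scoring zero against everything; percent identity is
identical columns over all aligned columns (gaps included in the
denominator, the convention recorded on the result), and percent positives
counts residue pairs with a positive substitution score. Distances are
1 - fractional identity; trees are built with the classical neighbor-joining
agglomeration with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "ConservationSummary",
    "DistanceMatrix",
    "TreeNode",
    "STRONG_GROUPS",
    "global_align",
    "msa_conservation",
    "distance_matrix",
    "neighbor_joining",
]

GAP = "-"

# Clustal "strong" conservation groups (the ':' mark in alignment output).
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")


def _blosum62_with_neutral_x():
    mat = substitution_matrices.load("BLOSUM62")
    for a in mat.alphabet:
        mat["X", a] = 0.0
        mat[a, "X"] = 0.0
    return mat


_MATRIX = _blosum62_with_neutral_x()


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float          # percent, denominator = aligned columns incl. gaps
    positives: float         # percent of columns with positive substitution score
    mode: str = "global"
    identity_denominator: str = "alignment_length_including_gaps"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _aligner(open_gap: float, extend_gap: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    return aligner


def global_align(
    a: str,
    b: str,
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
    mode: str = "global",
) -> AlignmentResult:
    """Optimal affine-gap alignment of two protein sequences.

    ``mode`` may be 'global' (Needleman-Wunsch style) or 'local'
    (Smith-Waterman style); percent identity/positives are computed over the
    returned alignment's columns either way.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(open_gap, extend_gap, mode)
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    n_cols = len(ga)
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    pos = sum(
        1
        for x, y in zip(ga, gb)
        if x != GAP and y != GAP and _MATRIX[x, y] > 0
    )
    # identical columns always score positively under BLOSUM62 except X/X,
    # which is neutral by construction; count identities as positive too.
    pos = max(pos, ident)
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity=100.0 * ident / n_cols,
        positives=100.0 * pos / n_cols,
        mode=mode,
    )


@dataclass(frozen=True)
class ConservationSummary:
    region: tuple[int, int]
    mode: str
    count: int
    fraction: float


def msa_conservation(
    msa: list[str],
    region: tuple[int, int] | None = None,
    mode: str = "identical",
) -> ConservationSummary:
    """Count fully conserved columns of an aligned set of sequences.

    ``mode='identical'`` counts columns where every row carries the same
    residue (no gaps); ``'identical_or_strong'`` additionally counts columns
    whose residues all fall in one Clustal strong group. ``region`` is
    1-based inclusive over alignment columns (default: whole alignment).
    """
    if not msa:
        raise ValueError("empty MSA")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("MSA rows differ in length")
    if region is None:
        region = (1, width)
    lo, hi = region
    if not (1 <= lo <= hi <= width):
        raise ValueError(f"region {region} outside alignment 1-{width}")
    if mode not in ("identical", "identical_or_strong"):
        raise ValueError(f"unknown mode {mode!r}")
    count = 0
    for col in range(lo - 1, hi):
        residues = {row[col] for row in msa}
        if GAP in residues:
            continue
        if len(residues) == 1:
            count += 1
        elif mode == "identical_or_strong" and any(
            residues <= set(group) for group in STRONG_GROUPS
        ):
            count += 1
    return ConservationSummary(
        region=region, mode=mode, count=count, fraction=count / (hi - lo + 1)
    )


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def distance_matrix(sequences: list[tuple[str, str]] | dict[str, str]) -> DistanceMatrix:
    """Pairwise 1 - fractional-identity distances from global alignments."""
    if isinstance(sequences, dict):
        sequences = list(sequences.items())
    labels = [lab for lab, _ in sequences]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(sequences[i][1], sequences[j][1])
            m[i, j] = m[j, i] = 1.0 - res.identity / 100.0
    return DistanceMatrix(labels=tuple(labels), matrix=m)


@dataclass
class TreeNode:
    """A node of an unrooted tree, stored with an arbitrary trifurcating root."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name
        inner = ",".join(f"{c._newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> tuple[TreeNode, float]:
    """Classic neighbor joining.

    Returns (tree, clamped_deficit): the agglomeration picks the smallest Q
    criterion, breaking ties by the lexicographically smallest pair of
    subtree labels; negative branch lengths are clamped to zero and the total
    clamped magnitude returned so callers can log it.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    canon: list[str] = list(labels)  # smallest leaf label under each node
    d = dm.matrix.astype(float).copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0.0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair_labels = tuple(sorted((canon[i], canon[j])))
                key = (q, pair_labels)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_canon = min(canon[i], canon[j])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        canon = [canon[k] for k in keep] + [new_canon]
        d = d2

    # final trifurcation
    l0 = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    l1 = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    l2 = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return root, deficit
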