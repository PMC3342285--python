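"""Comparative analysis: pairwise global alignment and identity, p-distance
matrices, neighbor-joining with bootstrap, and the taxon-diagnostic residue
scanner.

The scanner formalizes the comparison behind clade-specific channel
residues: a column of a grouped alignment is diagnostic for the focal clade
when every focal sequence carries one residue X (no gaps allowed) and all
other sequences share a single different residue Y, with at most
``max_exceptions`` non-focal sequences deviating (deviant sequences are
reported by id; non-focal gaps count as deviations).

Neighbor joining follows Saitou & Nei with explicit determinism: Q-matrix
ties are broken by the lexicographically smallest (row, col) label pair, and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch.  Bootstrap supports are the fraction of column-resampled
replicate trees containing each internal bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


# ---------------------------------------------------------------------------
# Pairwise alignment & identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseAlignment:
    a: str  # unaligned inputs
    b: str
    aligned_a: str  # with '-' gaps
    aligned_b: str
    score: float


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment with affine gap penalties
    (a gap of length k costs gap_open + gap_extend*(k-1))."""
    for name, s in (("first", a), ("second", b)):
        if not s:
            raise ValueError(f"{name} sequence is empty")
        bad = sorted(set(s) - set(AA20))
        if bad:
            raise ValueError(f"{name} sequence contains non-amino-acid letters {bad}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(a, b, str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(alignment: PairwiseAlignment) -> int:
    """100 * identical aligned pairs / length of the shorter input sequence,
    rounded half-up to an integer."""
    from .codons import round_half_up

    ident = sum(
        1
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
        if x == y and x != GAP
    )
    return round_half_up(100.0 * ident / min(len(alignment.a), len(alignment.b)))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrix must be symmetric with a zero diagonal")


def p_distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise proportion of differing columns (pairwise gap deletion)."""
    labels = tuple(sequences)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(sequences[l]) for l in labels])
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arr[i] != GAP) & (arr[j] != GAP)
            nv = int(valid.sum())
            d = float((arr[i][valid] != arr[j][valid]).sum() / nv) if nv else 0.0
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    label: str | None = None  # leaf name (None for internal nodes)
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c, _ in self.children))

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{ln:.6g}" for c, ln in self.children)
        sup = "" if self.support is None else f"{self.support:.3g}"
        return f"({inner}){sup}"


@dataclass
class PhyloTree:
    root: TreeNode  # unrooted tree held at the final join (3+ children)
    star: bool = False  # degenerate all-zero-distance input

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        return self.root.newick() + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the alphabetically first taxon."""
        all_leaves = self.leaf_names
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side if anchor not in side else all_leaves - side)
                walk(child)

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie handling."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if np.allclose(dm.matrix, 0):
        root = TreeNode(children=[(TreeNode(label=l), 0.0) for l in sorted(dm.labels)])
        return PhyloTree(root, star=True)

    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    tags: list[str] = list(dm.labels)  # min leaf label per subtree, for tie-breaks
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_tag = tuple(sorted((tags[active[ai]], tags[active[aj]])))
                key = (q, pair_tag)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            lj, li = 0.0, dij
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining ones
        newD = np.zeros(len(nodes) + 1)
        for k in active:
            if k not in (i, j):
                newD[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newD)] = newD
        D[: len(newD), -1] = newD
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = max(0.0, 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = max(0.0, 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = max(0.0, 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root)


def bootstrap_support(
    sequences: Mapping[str, str], replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree of the p-distance matrix, with internal-edge supports from
    column resampling with replacement.

    Each replicate uses its own replicate-indexed RNG stream derived from
    the single seed, so results are stable regardless of evaluation order.
    Alignments of identical sequences collapse to a flagged zero-branch star.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    dm = p_distance_matrix(sequences)
    tree = nj_tree(dm)
    if tree.star:
        return tree

    labels = list(sequences)
    arr = np.array([list(sequences[l]) for l in labels])
    L = arr.shape[1]
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, L, size=L)
        res = {l: "".join(arr[k][cols]) for k, l in enumerate(labels)}
        rep_tree = nj_tree(p_distance_matrix(res))
        if rep_tree.star:
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    anchor = min(tree.leaf_names)
    all_leaves = tree.leaf_names

    def attach(node: TreeNode) -> None:
        for child, _ in node.children:
            side = child.leaves()
            if 1 < len(side) < len(all_leaves) - 1:
                key = side if anchor not in side else all_leaves - side
                child.support = counts[key] / replicates
            attach(child)

    attach(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Taxon-diagnostic residue scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupedAlignment:
    sequences: Mapping[str, str]  # id -> aligned sequence ('-' gaps)
    groups: Mapping[str, str]  # id -> group label
    focal_group: str

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        missing = sorted(set(self.sequences) - set(self.groups))
        if missing:
            raise ValueError(f"sequences without a group label: {missing}")
        if not any(g == self.focal_group for g in self.groups.values()):
            raise ValueError(f"focal group {self.focal_group!r} is empty")

    @property
    def focal_ids(self) -> list[str]:
        return [i for i in self.sequences if self.groups[i] == self.focal_group]

    @property
    def nonfocal_ids(self) -> list[str]:
        return [i for i in self.sequences if self.groups[i] != self.focal_group]


@dataclass(frozen=True)
class DiagnosticSite:
    column: int  # 1-based alignment coordinate
    focal_residue: str
    background_residue: str
    n_exceptions: int
    exception_ids: tuple[str, ...]


def find_diagnostic_sites(
    ga: GroupedAlignment, max_exceptions: int = 0
) -> list[DiagnosticSite]:
    """Columns where the focal group is monomorphic for X (gap-free) and all
    other sequences share one residue Y != X, allowing up to
    ``max_exceptions`` deviating non-focal sequences (gaps deviate)."""
    focal, nonfocal = ga.focal_ids, ga.nonfocal_ids
    length = len(next(iter(ga.sequences.values())))
    sites = []
    for col in range(length):
        fres = {ga.sequences[i][col] for i in focal}
        if len(fres) != 1 or GAP in fres:
            continue
        x = next(iter(fres))
        # best background residue: minimizes deviations, alphabetical on ties
        candidates = sorted(
            {ga.sequences[i][col] for i in nonfocal} - {x, GAP}
        )
        best = None
        for y in candidates:
            deviants = tuple(i for i in nonfocal if ga.sequences[i][col] != y)
            if best is None or (len(deviants), y) < (len(best[1]), best[0]):
                best = (y, deviants)
        if best is None:
            continue
        y, deviants = best
        if len(deviants) <= max_exceptions:
            sites.append(DiagnosticSite(col + 1, x, y, len(deviants), deviants))
    return sites
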