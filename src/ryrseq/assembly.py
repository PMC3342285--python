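"""Greedy overlap assembly of clone sequences into a single contig.

Clone libraries of the kind produced by RT-PCR/RACE walking form a simple
linear path of suffix-prefix overlaps, so a greedy maximal-overlap merger is
sufficient (and verifiable): repeatedly merge the pair of contigs with the
largest acceptable overlap until one contig remains.  An overlap of length k
is acceptable when the suffix/prefix mismatch count is at most
``max_overlap_mismatch``; mismatches within accepted overlaps are exactly how
inter-clone polymorphisms (different alleles, or PCR errors) surface, and
they are collected as :class:`RawConflict` records.

Consensus policy: at a conflicting column the base of the clone whose id
sorts first wins; all observed alleles are retained in the conflict record.
``N`` matches any base during overlap scoring but never becomes consensus
when a concrete base is available.  Coordinates are 0-based half-open
internally; reports are rendered 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_BASE_ORD = {b: ord(b) for b in "ACGTN"}
_N = ord("N")


class AssemblyError(ValueError):
    """Raised when clones cannot be assembled into a single unambiguous contig."""


@dataclass(frozen=True)
class RawConflict:
    """One contig column at which overlapping clones disagree."""

    contig_position: int  # 0-based
    alleles: dict[str, tuple[str, ...]]  # base -> clone ids carrying it


@dataclass
class Contig:
    seq: str
    layout: list[tuple[str, int]]  # (clone id, 0-based offset), non-decreasing
    conflicts: list[RawConflict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


def _encode(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    bad = ~np.isin(a, list(_BASE_ORD.values()))
    if bad.any():
        raise ValueError(f"non-IUPAC base {chr(a[bad.argmax()])!r} in sequence")
    return a


def _best_overlap(a: np.ndarray, b: np.ndarray, min_overlap: int, max_mm: int) -> int:
    """Largest k such that the length-k suffix of `a` matches the length-k
    prefix of `b` with at most `max_mm` mismatches (N matches anything).
    Returns 0 if none."""
    cap = min(len(a), len(b))
    if cap < min_overlap:
        return 0
    asuf, bpre = a[len(a) - cap :], b[:cap]
    if _N not in asuf and _N not in bpre:
        # match counts for every k at once: matches(k) is a convolution of
        # per-base indicators of the reversed suffix with the prefix
        from scipy.signal import fftconvolve

        ar = asuf[::-1]
        matches = np.zeros(2 * cap - 1)
        for base in (65, 67, 71, 84):  # A C G T
            matches += fftconvolve((ar == base).astype(float), (bpre == base).astype(float))
        k_arr = np.arange(1, cap + 1)
        mism = k_arr - np.rint(matches[:cap]).astype(int)
        ok = (k_arr >= min_overlap) & (mism <= max_mm)
        return int(k_arr[ok][-1]) if ok.any() else 0
    for k in range(cap, min_overlap - 1, -1):
        sa, sb = asuf[cap - k :], bpre[:k]
        mm = np.count_nonzero((sa != sb) & (sa != _N) & (sb != _N))
        if mm <= max_mm:
            return k
    return 0


def assemble_clones(
    clones: Sequence,
    min_overlap: int = 20,
    max_overlap_mismatch: int = 5,
) -> Contig:
    """Merge clones into the unique consensus contig.

    Raises :class:`AssemblyError` when no overlap chain covers all clones
    (listing the orphans) or when the maximal overlap at a greedy step is
    ambiguous (two tied candidates competing for the same clone end).
    """
    if not clones:
        raise AssemblyError("no clones supplied")
    ids = [c.id for c in clones]
    if len(set(ids)) != len(ids):
        raise AssemblyError("duplicate clone ids")

    # each working contig: (sequence array, [(clone id, offset within contig)])
    contigs: dict[int, tuple[np.ndarray, list[tuple[str, int]]]] = {
        i: (_encode(c.seq), [(c.id, 0)]) for i, c in enumerate(clones)
    }
    overlaps: dict[tuple[int, int], int] = {}

    def scan(i: int, j: int) -> None:
        k = _best_overlap(contigs[i][0], contigs[j][0], min_overlap, max_overlap_mismatch)
        if k:
            overlaps[(i, j)] = k

    keys = list(contigs)
    for i in keys:
        for j in keys:
            if i != j:
                scan(i, j)

    next_id = len(clones)
    while len(contigs) > 1:
        if not overlaps:
            orphans = sorted(cid for _, members in contigs.values() for cid, _ in members)
            raise AssemblyError(f"unassemblable: no overlap chain covers clones {orphans}")
        best_k = max(overlaps.values())
        cands = sorted(
            (pair for pair, k in overlaps.items() if k == best_k),
            key=lambda p: (contigs[p[0]][1][0][0], contigs[p[1]][1][0][0]),
        )
        if len(cands) > 1:
            # ties competing for the same contig end are genuinely ambiguous
            lefts = [i for i, _ in cands]
            rights = [j for _, j in cands]
            if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
                names = [(contigs[i][1][0][0], contigs[j][1][0][0]) for i, j in cands]
                raise AssemblyError(f"ambiguous tiling: tied maximal overlaps {names}")
        i, j = cands[0]
        a, la = contigs[i]
        b, lb = contigs[j]
        shift = len(a) - best_k
        merged = np.concatenate([a, b[best_k:]])
        # within the overlap keep a's bases unless a has N and b does not
        ov = merged[shift : shift + best_k]
        bn = b[:best_k]
        fix = (ov == _N) & (bn != _N)
        ov[fix] = bn[fix]
        layout = la + [(cid, off + shift) for cid, off in lb]
        del contigs[i], contigs[j]
        overlaps = {p: k for p, k in overlaps.items() if i not in p and j not in p}
        contigs[next_id] = (merged, layout)
        for other in list(contigs):
            if other != next_id:
                scan(next_id, other)
                scan(other, next_id)
        next_id += 1

    arr, layout = contigs.popitem()[1]
    layout.sort(key=lambda t: (t[1], t[0]))
    clone_by_id = {c.id: _encode(c.seq) for c in clones}

    # column-wise consensus: paint clones in descending id order so that the
    # lexicographically first clone wins at conflicting columns
    consensus = arr.copy()
    for cid, off in sorted(layout, key=lambda t: t[0], reverse=True):
        cs = clone_by_id[cid]
        concrete = cs != _N
        consensus[off : off + len(cs)][concrete] = cs[concrete]
    # never let N stand where any clone has a concrete base
    for cid, off in layout:
        cs = clone_by_id[cid]
        seg = consensus[off : off + len(cs)]
        fix = (seg == _N) & (cs != _N)
        seg[fix] = cs[fix]

    contig = Contig(seq=consensus.tobytes().decode(), layout=layout)
    contig.conflicts = detect_conflicts(contig, {c.id: c.seq for c in clones})
    return contig


def detect_conflicts(contig: Contig, clone_seqs: dict[str, str]) -> list[RawConflict]:
    """One record per contig column where >= 2 covering clones carry distinct
    concrete bases.  Positions are 0-based contig coordinates (rendered in
    ORF convention downstream, once the ORF is known)."""
    cons = _encode(contig.seq)
    suspects: set[int] = set()
    arrays = {}
    for cid, off in contig.layout:
        cs = _encode(clone_seqs[cid])
        arrays[cid] = (off, cs)
        mism = np.flatnonzero((cs != cons[off : off + len(cs)]) & (cs != _N))
        suspects.update((mism + off).tolist())

    conflicts = []
    for pos in sorted(suspects):
        alleles: dict[str, list[str]] = {}
        for cid, (off, cs) in arrays.items():
            if off <= pos < off + len(cs):
                base = chr(cs[pos - off])
                if base != "N":
                    alleles.setdefault(base, []).append(cid)
        if len(alleles) >= 2:
            conflicts.append(
                RawConflict(pos, {b: tuple(sorted(v)) for b, v in sorted(alleles.items())})
            )
    return conflicts
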