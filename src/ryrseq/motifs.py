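"""Protein sequence hallmarks: pattern scanning (P-loop, pore motif),
EF-hand detection, hydropathy-based transmembrane prediction, and domain
interval bookkeeping.

Patterns use the compact convention common in channel literature: residue
letters, ``X`` for any residue, ``[..]`` for alternatives and ``{..}`` for
exclusions (PROSITE-style).  TM segments are predicted with a Kyte-Doolittle
sliding window — a deliberately simple, fully declared stand-in for HMM
predictors: maximal runs of window-centered means above a cutoff, kept when
at least ``min_len`` long.  Domain locations (MIR, RIH, SD, SPRY, RyR
repeats, RIH-associated) come from homology and are carried as a validated
annotation track, not re-detected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: PROSITE PS00018-style EF-hand Ca2+-binding loop consensus
EF_HAND_PATTERN = (
    "D-X-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-X-X-[DE]-[LIVMFYW]"
)


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str  # letters, X, [..], {..}; optional '-' separators

    def elements(self) -> list[str]:
        pat = self.pattern.replace("-", "")
        if not pat:
            raise ValueError("empty pattern")
        out = re.findall(r"\[[A-Z]+\]|\{[A-Z]+\}|[A-Z]", pat)
        if "".join(out) != pat:
            raise ValueError(f"malformed pattern {self.pattern!r}")
        return out

    def to_regex(self) -> re.Pattern:
        parts = []
        for el in self.elements():
            if el == "X":
                parts.append(f"[{AA20}]")
            elif el.startswith("["):
                if len(el) == 2:
                    raise ValueError("empty alternative set")
                parts.append(el)
            elif el.startswith("{"):
                allowed = "".join(sorted(set(AA20) - set(el[1:-1])))
                parts.append(f"[{allowed}]")
            else:
                parts.append(el)
        return re.compile("".join(parts))

    def __len__(self) -> int:
        return len(self.elements())


@dataclass(frozen=True)
class MotifHit:
    name: str
    start: int  # 1-based inclusive
    end: int
    matched: str


@dataclass(frozen=True)
class TmSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float


def scan_motif(protein: str, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) pattern matches, ascending by start."""
    rx = pattern.to_regex()
    m = len(pattern)
    hits = []
    for match in re.finditer(f"(?=({rx.pattern}))", protein):
        s = match.start()
        hits.append(MotifHit(pattern.name, s + 1, s + m, protein[s : s + m]))
    return hits


def find_ef_hands(protein: str) -> list[MotifHit]:
    """Matches of the canonical EF-hand loop consensus, ascending."""
    return scan_motif(protein, MotifPattern("EF-hand", EF_HAND_PATTERN))


def predict_tm_segments(
    protein: str, window: int = 19, cutoff: float = 1.6, min_len: int = 18
) -> list[TmSegment]:
    """Hydropathy-window transmembrane prediction.

    A residue qualifies when the mean Kyte-Doolittle hydropathy of the
    length-``window`` window centered on it is >= ``cutoff``; maximal runs of
    qualifying residues at least ``min_len`` long are reported with their
    mean hydropathy.  Windows are only defined where they fit entirely
    within the sequence.
    """
    n = len(protein)
    if n < window:
        raise ValueError(f"sequence shorter than the window ({n} < {window})")
    vals = np.array([KYTE_DOOLITTLE[aa] for aa in protein])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    half = window // 2
    ok = means >= cutoff  # ok[i] corresponds to center position i + half (0-based)
    segments = []
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                s, e = i + half, j + half  # 0-based residue positions
                segments.append(
                    TmSegment(s + 1, e + 1, float(np.mean(vals[s : e + 1])))
                )
            i = j + 1
        else:
            i += 1
    return segments


@dataclass(frozen=True)
class DomainInterval:
    name: str
    start: int  # 1-based inclusive
    end: int
    overlaps: tuple[str, ...] = ()


def annotate_domains(
    protein_length: int, intervals: Sequence[tuple[str, int, int]]
) -> list[DomainInterval]:
    """Validate and sort a homology-derived domain table; intervals that
    overlap another are flagged (not rejected)."""
    for name, s, e in intervals:
        if not (1 <= s <= e <= protein_length):
            raise ValueError(f"domain {name}: interval ({s}, {e}) outside [1, {protein_length}]")
    ordered = sorted(intervals, key=lambda t: (t[1], t[2], t[0]))
    out = []
    for name, s, e in ordered:
        partners = tuple(
            n2 for n2, s2, e2 in ordered if n2 != name and s <= e2 and s2 <= e
        )
        out.append(DomainInterval(name, s, e, partners))
    return out
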