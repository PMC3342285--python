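"""Synthetic-data generation for every stage of the pipeline.

The generator emulates the CmRyR study material: a full-length transcript
(5'UTR + ORF + 3'UTR) with motifs planted at known coordinates, a second
haplotype carrying a planned set of nucleotide substitutions, an overlapping
clone library tiling the transcript, per-developmental-stage splice pools
with mutually exclusive / optional exons, and a grouped protein MSA with
planted taxon-diagnostic columns.  Every product comes with a machine-
readable truth record so downstream operations can be checked against what
was planted.

Background composition is uniform over A/C/G/T (codons drawn uniformly from
the 61 sense codons inside the ORF); UTR composition is scaled exactly to a
GC/AT target by fixing base counts before shuffling.  All randomness flows
from explicit integer seeds and identical seeds give byte-identical output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import studydata
from .codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    round_half_up,
    revcomp,
    smallest_codon,
    translate_nt,
)

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptSpec:
    """Blueprint for a reference transcript.

    ``planted_motifs`` are peptide instances written into the translation at
    1-based protein positions; ``planted_nt`` are codon-aligned nucleotide
    blocks written at 1-based ORF coordinates (used to plant primer binding
    sites and exon contexts).
    """

    utr5_len: int = 0
    orf_codons: int = 2  # includes the stop codon
    utr3_len: int = 0
    gc_target_utr5: float | None = None
    at_target_utr3: float | None = None
    planted_motifs: tuple[tuple[str, int], ...] = ()
    planted_nt: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError("UTR lengths must be non-negative")
        if self.orf_codons < 2:
            raise ValueError("ORF needs at least a start and a stop codon")


@dataclass(frozen=True)
class SplicePoolSpec:
    """Clone counts for one developmental pool (Fig 6 style)."""

    pool_name: str
    n_clones: int
    n_exon_a: int
    n_exon_b: int
    n_exon_c_present: int
    seed: int = 0

    def validate(self) -> None:
        if self.n_exon_a + self.n_exon_b != self.n_clones:
            raise ValueError(
                f"pool {self.pool_name}: exon a + exon b counts "
                f"({self.n_exon_a}+{self.n_exon_b}) must equal n_clones ({self.n_clones})"
            )
        if not 0 <= self.n_exon_c_present <= self.n_clones:
            raise ValueError(f"pool {self.pool_name}: exon c count out of range")
        if min(self.n_clones, self.n_exon_a, self.n_exon_b) < 0:
            raise ValueError(f"pool {self.pool_name}: negative count")


@dataclass(frozen=True)
class GroupedMsaSpec:
    """Blueprint for a grouped alignment with planted diagnostic columns."""

    group_ids: Mapping[str, Sequence[str]]
    focal_group: str
    n_columns: int
    n_clean_diagnostic: int
    n_exception_diagnostic: int
    max_planted_exceptions_per_site: int = 1
    exception_ids: tuple[str, ...] = ()  # optional fixed choice, one per exception column
    seed: int = 0

    def validate(self) -> None:
        if self.focal_group not in self.group_ids:
            raise ValueError(f"focal group {self.focal_group!r} missing")
        if any(len(ids) < 1 for ids in self.group_ids.values()):
            raise ValueError("every group needs at least one sequence")
        if self.n_clean_diagnostic + self.n_exception_diagnostic > self.n_columns:
            raise ValueError("more diagnostic columns than columns")
        n_nonfocal = sum(
            len(ids) for g, ids in self.group_ids.items() if g != self.focal_group
        )
        if self.n_exception_diagnostic > 0 and n_nonfocal < 2:
            raise ValueError("non-focal set too small to express an exception")


# ---------------------------------------------------------------------------
# Reference transcript
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """A generated transcript plus the truth record of what was planted."""

    seq: str
    utr5_len: int
    orf_len: int
    utr3_len: int
    truth: dict = field(default_factory=dict)

    @property
    def orf_seq(self) -> str:
        return self.seq[self.utr5_len : self.utr5_len + self.orf_len]

    @property
    def protein(self) -> str:
        return translate_nt(self.orf_seq)[:-1]


def _scaled_composition(n: int, frac: float, pair: str, other: str, rng) -> list[str]:
    """n bases whose `pair` content hits round(frac*n) exactly, shuffled."""
    n_pair = round_half_up(frac * n)
    bases = [pair[0]] * (n_pair // 2 + n_pair % 2) + [pair[1]] * (n_pair // 2)
    n_other = n - n_pair
    bases += [other[0]] * (n_other // 2 + n_other % 2) + [other[1]] * (n_other // 2)
    return list(rng.permutation(bases))


def _repair_forbidden(bases: list[str], forbidden: Sequence[str], rng) -> list[str]:
    """Swap bases (composition-preserving) until no forbidden motif remains."""
    s = "".join(bases)
    for _ in range(10_000):
        hit = None
        for motif in forbidden:
            i = s.find(motif)
            if i >= 0:
                hit = (i, len(motif))
                break
        if hit is None:
            return list(s)
        i, m = hit
        j = i + int(rng.integers(m))  # a position inside the motif
        k = int(rng.integers(len(s)))
        if s[j] != s[k]:
            lst = list(s)
            lst[j], lst[k] = lst[k], lst[j]
            s = "".join(lst)
    raise RuntimeError("could not purge forbidden motifs from UTR")


def _random_utr(n: int, target: float | None, pair: str, rng,
                forbidden: Sequence[str]) -> str:
    if n == 0:
        return ""
    other = "".join(sorted(set("ACGT") - set(pair)))
    if target is None:
        bases = list(rng.choice(list("ACGT"), size=n))
    else:
        bases = _scaled_composition(n, target, pair, other, rng)
    return "".join(_repair_forbidden(bases, forbidden, rng))


def make_reference_transcript(spec: TranscriptSpec) -> Transcript:
    """Build a transcript: ATG-initiated stop-terminated ORF with planted
    features, an ATG-free 5'UTR and a poly(A)-signal-free 3'UTR.

    Raises ``ValueError`` when a planted feature collides with the start or
    stop codon or with another planted feature.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_codons = spec.orf_codons

    codons = ["ATG"] + list(rng.choice(SENSE_CODONS, size=n_codons - 2)) + ["TGA"]

    occupied: list[tuple[int, int, str]] = []  # 0-based codon intervals [a, b)

    def _claim(a: int, b: int, what: str) -> None:
        if a < 1 or b > n_codons - 1:
            raise ValueError(f"{what} clashes with the start or stop codon")
        for x, y, other in occupied:
            if a < y and x < b:
                raise ValueError(f"{what} overlaps planted feature {other}")
        occupied.append((a, b, what))

    motif_truth = []
    for peptide, pos in spec.planted_motifs:
        a = pos - 1  # codon index of first residue (codon 0 = Met)
        _claim(a, a + len(peptide), f"motif {peptide!r}@{pos}")
        for k, aa in enumerate(peptide):
            codons[a + k] = smallest_codon(aa)
        motif_truth.append({"peptide": peptide, "start": pos, "end": pos + len(peptide) - 1})

    nt_truth = []
    for block, nt_pos in spec.planted_nt:
        if (nt_pos - 1) % 3 or len(block) % 3:
            raise ValueError("planted nucleotide blocks must be codon-aligned")
        a = (nt_pos - 1) // 3
        _claim(a, a + len(block) // 3, f"nt block @{nt_pos}")
        for k in range(0, len(block), 3):
            cod = block[k : k + 3]
            if CODON_TO_AA[cod] == "*":
                raise ValueError(f"nt block @{nt_pos} introduces a stop codon ({cod})")
            codons[a + k // 3] = cod
        nt_truth.append({"seq": block, "nt_start": nt_pos, "nt_end": nt_pos + len(block) - 1})

    orf = "".join(codons)
    utr5 = _random_utr(spec.utr5_len, spec.gc_target_utr5, "GC", rng,
                       forbidden=("ATG", "TATAAA"))
    utr3 = _random_utr(spec.utr3_len, spec.at_target_utr3, "AT", rng,
                       forbidden=("AATAAA",))

    seq = utr5 + orf + utr3
    protein = translate_nt(orf)[:-1]
    for rec in motif_truth:
        planted = protein[rec["start"] - 1 : rec["end"]]
        assert planted == rec["peptide"], "planted motif failed to round-trip"

    truth = {
        "utr5": (1, spec.utr5_len),
        "orf": (spec.utr5_len + 1, spec.utr5_len + len(orf)),
        "utr3": (spec.utr5_len + len(orf) + 1, len(seq)),
        "protein_length": n_codons - 1,
        "planted_motifs": motif_truth,
        "planted_nt": nt_truth,
    }
    return Transcript(seq, spec.utr5_len, len(orf), spec.utr3_len, truth)


# ---------------------------------------------------------------------------
# Substitution planting (Table-2-style haplotypes)
# ---------------------------------------------------------------------------


def _solve_codon(rows: Sequence[studydata.SubstitutionRow]) -> tuple[str, str]:
    """Find the lexicographically smallest reference codon realizing a group
    of same-codon substitution rows, returning (ref_codon, alt_codon)."""
    offsets = [(r.nt_position - 1) % 3 for r in rows]
    exchanges = {r.aa_exchange for r in rows if r.aa_exchange is not None}
    if len(exchanges) > 1:
        raise ValueError(f"inconsistent amino-acid exchanges within one codon: {rows}")
    exchange = exchanges.pop() if exchanges else None

    for ref in SENSE_CODONS:
        if any(ref[o] != r.ref_base for o, r in zip(offsets, rows)):
            continue
        alt = list(ref)
        for o, r in zip(offsets, rows):
            alt[o] = r.alt_base
        alt = "".join(alt)
        if CODON_TO_AA[alt] == "*":
            continue
        ref_aa, alt_aa = CODON_TO_AA[ref], CODON_TO_AA[alt]
        if exchange is not None:
            want_ref, _, want_alt = exchange
            if (ref_aa, alt_aa) != (want_ref, want_alt) or ref_aa == alt_aa:
                continue
        else:  # all rows silent
            if ref_aa != alt_aa:
                continue
        return ref, alt
    raise ValueError(
        "no sense codon realizes the planned substitution(s): "
        + ", ".join(f"{r.nt_position}{r.ref_base}>{r.alt_base}" for r in rows)
    )


def plant_substitutions(
    transcript: Transcript, plan: Sequence[studydata.SubstitutionRow]
) -> tuple[Transcript, str, list[dict]]:
    """Rewrite the reference so every planned row is realizable, and build the
    variant haplotype differing from it at exactly the planned positions.

    Same-codon rows are solved jointly against the genetic code (e.g. two
    adjacent substitutions jointly producing K->L).  Returns the adjusted
    reference transcript, the variant haplotype sequence, and per-row truth.
    """
    rows = sorted(plan, key=lambda r: r.nt_position)
    if any(a.nt_position == b.nt_position for a, b in zip(rows, rows[1:])):
        raise ValueError("duplicate substitution positions")
    orf_len = transcript.orf_len
    for r in rows:
        if not 1 <= r.nt_position <= orf_len:
            raise ValueError(f"position {r.nt_position} outside the ORF")
        if r.ref_base == r.alt_base:
            raise ValueError(f"position {r.nt_position}: ref equals alt")

    planted_codons = set()
    for rec in transcript.truth.get("planted_motifs", []):
        planted_codons.update(range(rec["start"], rec["end"] + 1))
    for rec in transcript.truth.get("planted_nt", []):
        planted_codons.update(
            range((rec["nt_start"] - 1) // 3 + 1, (rec["nt_end"] - 1) // 3 + 2)
        )

    by_codon: dict[int, list[studydata.SubstitutionRow]] = {}
    for r in rows:
        by_codon.setdefault((r.nt_position - 1) // 3, []).append(r)

    ref_seq = list(transcript.seq)
    var_seq = list(transcript.seq)
    off = transcript.utr5_len
    truth = []
    for codon_idx0, group in sorted(by_codon.items()):
        if codon_idx0 + 1 in planted_codons:
            raise ValueError(
                f"substitution codon {codon_idx0 + 1} collides with a planted feature"
            )
        ref_codon, alt_codon = _solve_codon(group)
        a = off + 3 * codon_idx0
        ref_seq[a : a + 3] = ref_codon
        var_seq[a : a + 3] = alt_codon
        for r in group:
            truth.append(
                {
                    "nt_position": r.nt_position,
                    "ref_base": r.ref_base,
                    "alt_base": r.alt_base,
                    "codon_index": codon_idx0 + 1,
                    "ref_codon": ref_codon,
                    "alt_codon": alt_codon,
                    "effect": r.effect,
                    "aa_exchange": r.aa_exchange,
                }
            )

    new_ref = Transcript(
        "".join(ref_seq),
        transcript.utr5_len,
        transcript.orf_len,
        transcript.utr3_len,
        dict(transcript.truth, substitutions=truth),
    )
    variant = "".join(var_seq)
    diff = [i for i, (x, y) in enumerate(zip(new_ref.seq, variant)) if x != y]
    assert diff == [off + r.nt_position - 1 for r in rows], "variant differs off-plan"
    return new_ref, variant, truth


# ---------------------------------------------------------------------------
# Clone libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Clone:
    id: str
    seq: str
    pool: str | None = None


def _tiling(L: int, cuts: Sequence[int], overlaps: Sequence[int]) -> list[tuple[int, int]]:
    """Fragment intervals [start, end) around interior cut points, splitting
    each requested overlap across the cut."""
    assert len(overlaps) == len(cuts)
    bounds = []
    starts = [0] + [c - (o + 1) // 2 for c, o in zip(cuts, overlaps)]
    ends = [c + o // 2 for c, o in zip(cuts, overlaps)] + [L]
    for i, (s, e) in enumerate(zip(starts, ends)):
        if s < 0 or e > L or e - s <= 0:
            raise ValueError("overlap_range incompatible with fragment count and length")
        bounds.append((s, e))
    for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
        if not (s1 < s2 < e1 < e2):
            raise ValueError("overlap_range incompatible with fragment count and length")
    return bounds


def _draw_overlaps(rng, n: int, overlap_range: tuple[int, int]) -> list[int]:
    lo, hi = overlap_range
    pool = np.arange(lo, hi + 1)
    if len(pool) < n:
        raise ValueError("overlap_range too narrow to draw distinct overlaps")
    return [int(x) for x in rng.choice(pool, size=n, replace=False)]


def make_clone_library(
    transcript: Transcript | str,
    n_fragments: int,
    overlap_range: tuple[int, int] = (50, 150),
    seed: int = 0,
    variant: str | None = None,
) -> tuple[list[Clone], list[dict]]:
    """Fragment a transcript into an overlapping clone library.

    With ``variant`` supplied, a second, half-grid-staggered tiling of the
    variant haplotype is added (ids ``hapB_*``), so that every position - in
    particular every planted substitution - is covered by clones of both
    haplotypes and shows up as an overlap conflict during assembly.  Distinct
    overlap lengths are drawn so greedy assembly never faces an ambiguous tie.
    """
    seq = transcript.seq if isinstance(transcript, Transcript) else transcript
    L = len(seq)
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    if n_fragments == 1 and variant is None:
        return [Clone("P01", seq)], [{"id": "P01", "start": 0, "end": L, "haplotype": "A"}]

    rng = np.random.default_rng(seed)
    cuts_a = [round(i * L / n_fragments) for i in range(1, n_fragments)]
    ov_a = _draw_overlaps(rng, len(cuts_a), overlap_range)
    bounds_a = _tiling(L, cuts_a, ov_a)

    prefix = "hapA" if variant is not None else "P"
    clones, layout = [], []
    for i, (s, e) in enumerate(bounds_a, 1):
        cid = f"{prefix}{i:02d}"
        clones.append(Clone(cid, seq[s:e]))
        layout.append({"id": cid, "start": s, "end": e, "haplotype": "A"})

    if variant is not None:
        if len(variant) != L:
            raise ValueError("variant haplotype length differs from reference")
        cuts_b = [round((i - 0.5) * L / n_fragments) for i in range(1, n_fragments + 1)]
        ov_b = _draw_overlaps(rng, len(cuts_b), overlap_range)
        bounds_b = _tiling(L, cuts_b, ov_b)
        for i, (s, e) in enumerate(bounds_b, 1):
            cid = f"hapB{i:02d}"
            clones.append(Clone(cid, variant[s:e]))
            layout.append({"id": cid, "start": s, "end": e, "haplotype": "B"})
        diffs = np.flatnonzero(
            np.frombuffer(seq.encode(), np.uint8) != np.frombuffer(variant.encode(), np.uint8)
        )
        # postcondition: every substituted position is covered by both haplotypes
        for hap, bb in (("A", bounds_a), ("B", bounds_b)):
            for p in diffs:
                if not any(s <= p < e for s, e in bb):
                    raise AssertionError(f"position {p} uncovered by haplotype {hap}")
    return clones, layout


def cross_overlap_mismatch_bound(layout: Sequence[dict], diff_positions: Iterable[int]) -> int:
    """Largest number of haplotype-difference positions falling inside any
    pairwise overlap between clones of different haplotypes (the minimum
    ``max_overlap_mismatch`` the assembler needs for such a library)."""
    diffs = sorted(diff_positions)
    worst = 0
    a_side = [r for r in layout if r["haplotype"] == "A"]
    b_side = [r for r in layout if r["haplotype"] == "B"]
    for ra in a_side:
        for rb in b_side:
            s, e = max(ra["start"], rb["start"]), min(ra["end"], rb["end"])
            if e > s:
                worst = max(worst, sum(1 for p in diffs if s <= p < e))
    return worst


# ---------------------------------------------------------------------------
# Splice pools
# ---------------------------------------------------------------------------


def make_splice_pools(
    specs: Sequence[SplicePoolSpec],
    exon_a: str,
    exon_b: str,
    exon_c: str,
    reference: Transcript | str,
    margin: int = 300,
) -> tuple[dict[str, list[Clone]], list[dict]]:
    """Build per-pool clone sets spanning both alternative-splice loci.

    The reference must carry exon a and exon c (each locatable as a unique
    substring).  Each clone gets exon a or b at the mutually exclusive locus
    and keeps or loses exon c, per the pool spec counts.
    """
    if len(exon_a) != len(exon_b):
        raise ValueError("mutually exclusive exons must have equal length")
    if len(exon_a) % 3 or len(exon_c) % 3:
        raise ValueError("exon lengths must be divisible by 3")
    ref = reference.seq if isinstance(reference, Transcript) else reference

    def _locate(exon: str, name: str) -> int:
        i = ref.find(exon)
        if i < 0 or ref.find(exon, i + 1) >= 0:
            raise ValueError(f"{name} must occur exactly once in the reference")
        return i

    a0 = _locate(exon_a, "exon a")
    c0 = _locate(exon_c, "exon c")
    w0 = max(0, min(a0, c0) - margin)
    w1 = min(len(ref), max(a0 + len(exon_a), c0 + len(exon_c)) + margin)
    window = ref[w0:w1]
    a_off, c_off = a0 - w0, c0 - w0

    pools: dict[str, list[Clone]] = {}
    truth = []
    for spec in specs:
        spec.validate()
        rng = np.random.default_rng(spec.seed)
        ab = ["a"] * spec.n_exon_a + ["b"] * spec.n_exon_b
        cc = [True] * spec.n_exon_c_present + [False] * (spec.n_clones - spec.n_exon_c_present)
        ab = list(rng.permutation(ab))
        cc = [bool(x) for x in rng.permutation(cc)]
        clones = []
        for i, (which, has_c) in enumerate(zip(ab, cc), 1):
            s = window
            if not has_c:  # delete the optional exon (right locus first)
                s = s[:c_off] + s[c_off + len(exon_c):]
            if which == "b":
                s = s[:a_off] + exon_b + s[a_off + len(exon_a):]
            cid = f"{spec.pool_name}_{i:02d}"
            clones.append(Clone(cid, s, pool=spec.pool_name))
            truth.append(
                {"pool": spec.pool_name, "id": cid, "iasi": which,
                 "iasii": "present" if has_c else "absent"}
            )
        pools[spec.pool_name] = clones
    return pools, truth


# ---------------------------------------------------------------------------
# Grouped MSA with planted diagnostic columns
# ---------------------------------------------------------------------------


def make_grouped_msa(spec: GroupedMsaSpec) -> tuple[dict[str, str], dict[str, str], list[dict]]:
    """Generate an aligned protein set with exactly the requested number of
    clean and single-exception diagnostic columns.

    Non-diagnostic columns are either fully conserved or polymorphic within
    the focal group, so a scanner with exception allowance 0 finds exactly
    the clean columns and allowance >= 1 adds the exception columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = {sid: g for g, ids in spec.group_ids.items() for sid in ids}
    ids = [sid for g in spec.group_ids for sid in spec.group_ids[g]]
    focal = list(spec.group_ids[spec.focal_group])
    nonfocal = [sid for sid in ids if sid not in focal]

    n_diag = spec.n_clean_diagnostic + spec.n_exception_diagnostic
    diag_cols = sorted(int(c) for c in rng.choice(spec.n_columns, size=n_diag, replace=False))
    clean_cols = set(diag_cols[: spec.n_clean_diagnostic])
    exc_cols = [c for c in diag_cols if c not in clean_cols]
    if spec.exception_ids and len(spec.exception_ids) != len(exc_cols):
        raise ValueError("exception_ids must name one sequence per exception column")

    columns: dict[str, list[str]] = {sid: [] for sid in ids}
    truth = []
    exc_iter = iter(spec.exception_ids) if spec.exception_ids else None
    alpha = list(AMINO_ALPHABET)
    for col in range(spec.n_columns):
        if col in clean_cols or col in exc_cols:
            x, y = rng.choice(alpha, size=2, replace=False)
            exceptions: list[str] = []
            if col in exc_cols:
                sid = next(exc_iter) if exc_iter else str(rng.choice(nonfocal))
                if sid in focal:
                    raise ValueError(f"exception id {sid} is in the focal group")
                exceptions = [sid]
            for sid in ids:
                if sid in focal or sid in exceptions:
                    columns[sid].append(str(x))
                else:
                    columns[sid].append(str(y))
            truth.append(
                {"column": col + 1, "focal_residue": str(x), "background_residue": str(y),
                 "exception_ids": exceptions}
            )
        elif len(focal) >= 2 and rng.random() < 0.3:  # focal-polymorphic, non-diagnostic
            x, y = rng.choice(alpha, size=2, replace=False)
            for k, sid in enumerate(ids):
                if sid == focal[0]:
                    columns[sid].append(str(y))
                else:
                    columns[sid].append(str(x))
        else:  # fully conserved
            x = str(rng.choice(alpha))
            for sid in ids:
                columns[sid].append(x)

    seqs = {sid: "".join(columns[sid]) for sid in ids}
    return seqs, groups, truth


# ---------------------------------------------------------------------------
# CmRyR study fixtures
# ---------------------------------------------------------------------------

_TM_PEPTIDE = ("ILFV" * 6)[:23]  # strongly hydrophobic 23-mer
_EF_LOOP = "DKDGDGYISAAEF"  # canonical Ca2+-binding loop + exiting hydrophobic
_SHARED_EXON_PEPTIDE = "LNTIDRSWKQHFMVGPYCEA"  # exon a/b invariant core


def cmryr_exon_sequences() -> dict[str, str]:
    """Synthetic stand-ins for the three alternative exons.

    The real exon sequences are only published as a figure; these synthetic
    versions satisfy every text-anchored constraint: exons a/b are 99 nt,
    translate without stops, differ at exactly 13 of 33 residues with the
    divergence spread over the whole exon (as in the real pair - no long
    identical interior run), and carry the exon-specific diagnostic primer
    sites (371/373) at their 5' ends; exon c is 18 nt, in frame, and forms
    the printed junction-spanning primer sites (375/377) with its flanks.
    """
    p = {k.split(".")[0]: v.sequence for k, v in studydata.DIAGNOSTIC_PRIMERS.items()}
    # codons 1-7 come from the exon-specific primers (7 residue differences);
    # 6 more differing codons (E vs K) are interleaved at positions chosen so
    # identical stretches stay below the detection anchor length
    diff_codons = {13, 19, 25, 28, 31, 33}
    shared_iter = iter(_SHARED_EXON_PEPTIDE)
    a_codons, b_codons = [p["371"] + "C"], [p["373"] + "T"]
    for idx in range(8, 34):
        if idx in diff_codons:
            a_codons.append("GAA")  # E
            b_codons.append("AAG")  # K, first and last base differing
        else:
            a_codons.append(smallest_codon(next(shared_iter)))
            b_codons.append(a_codons[-1])
    exon_a, exon_b = "".join(a_codons), "".join(b_codons)
    exon_c = p["377"][12:] + "ACCTGGAAGC"
    assert len(exon_a) == len(exon_b) == 99 and len(exon_c) == 18
    assert sum(
        a != b for a, b in zip(translate_nt(exon_a), translate_nt(exon_b))
    ) == studydata.EXON_AB_DIVERGENT_RESIDUES
    return {"a": exon_a, "b": exon_b, "c": exon_c}


def _cmryr_nt_plants() -> tuple[tuple[str, int], ...]:
    """Codon-aligned nucleotide blocks: exon a, exon c, their primer-bearing
    flanks, and the reverse-primer sites downstream of each locus."""
    p = {k.split(".")[0]: v.sequence for k, v in studydata.DIAGNOSTIC_PRIMERS.items()}
    exons = cmryr_exon_sequences()

    def nt(codon_index: int) -> int:
        return (codon_index - 1) * 3 + 1

    flank_l = p["377"][:12]  # last 4 codons before exon c
    flank_r = p["375"][1:] + "AC"  # first 7 codons after exon c
    assert flank_l.endswith(p["375"][0])
    return (
        (exons["a"], nt(studydata.IASI_RESIDUES[0])),  # codons 1136-1168
        (revcomp(p["372"]) + "C", nt(1172)),
        (revcomp(p["374"]) + "G", nt(1182)),
        (flank_l, nt(2911)),
        (exons["c"], nt(studydata.IASII_RESIDUES[0])),  # codons 2915-2920
        (flank_r, nt(2921)),
        (revcomp(p["376"]) + "A", nt(2931)),
        (revcomp(p["378"]) + "C", nt(2941)),
    )


def cmryr_transcript_spec(seed: int = 0) -> TranscriptSpec:
    """The full-length study fixture: 289 + 15,264 + 220 nt with the P-loop,
    tandem EF-hands, pore motif, six TM stretches and both splice-locus
    contexts planted at their published coordinates."""
    motifs = [("GPPPPGKS", studydata.PLOOP_SITE[0])]
    motifs += [(_EF_LOOP, 4187), (_EF_LOOP, 4222)]  # inside the EF-hand intervals
    motifs += [("GIRTGGGIGD", studydata.PORE_SITE[0])]
    motifs += [(_TM_PEPTIDE, s) for s, _ in studydata.TM_SEGMENTS]
    return TranscriptSpec(
        utr5_len=studydata.UTR5_LEN,
        orf_codons=studydata.ORF_CODONS,
        utr3_len=studydata.UTR3_LEN,
        gc_target_utr5=studydata.UTR5_GC_FRACTION,
        at_target_utr3=studydata.UTR3_AT_FRACTION,
        planted_motifs=tuple(motifs),
        planted_nt=_cmryr_nt_plants(),
        seed=seed,
    )


def cmryr_reference(seed: int = 0) -> Transcript:
    """Build the study-fixture transcript and verify primer-site uniqueness."""
    t = make_reference_transcript(cmryr_transcript_spec(seed))
    p = {k.split(".")[0]: v.sequence for k, v in studydata.DIAGNOSTIC_PRIMERS.items()}
    expected = {  # occurrences of each primer's binding site on the reference
        p["371"]: 1, p["373"]: 0, revcomp(p["372"]): 1, revcomp(p["374"]): 1,
        p["375"]: 0, p["377"]: 1, revcomp(p["376"]): 1, revcomp(p["378"]): 1,
    }
    for site, n in expected.items():
        found = len(re.findall(f"(?={site})", t.seq))
        if found != n:
            raise RuntimeError(
                f"primer site {site} occurs {found}x (expected {n}); re-seed the fixture"
            )
    return t


def cmryr_splice_pool_specs(seed: int = 0) -> list[SplicePoolSpec]:
    """Developmental pools at the published clone counts."""
    return [
        SplicePoolSpec(name, n, a, n - a, c, seed=seed * 1000 + k)
        for k, (name, (n, a, c)) in enumerate(studydata.POOL_COUNTS.items())
    ]


def cmryr_msa_spec(seed: int = 0) -> GroupedMsaSpec:
    """31-sequence grouped MSA with 5 clean + 2 single-exception diagnostic
    columns; the exceptions sit in the mite and nematode sequences, matching
    the published pattern."""
    return GroupedMsaSpec(
        group_ids=studydata.MSA_GROUPS,
        focal_group=studydata.FOCAL_GROUP,
        n_columns=180,
        n_clean_diagnostic=5,
        n_exception_diagnostic=2,
        exception_ids=("TuRyR", "CeRyR"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Plain-text output
# ---------------------------------------------------------------------------


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(path, rows: Sequence[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
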