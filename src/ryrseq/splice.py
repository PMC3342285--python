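"""Alternative-exon detection, degenerate primer design, in-silico
diagnostic PCR and exon-usage quantification.

The workflow mirrors how splice variants are scored from cDNA clone pools:
clones are aligned to the reference transcript; a same-length divergent
block shared by a clone subset is a mutually exclusive exon pair, a clean
presence/absence block whose length is divisible by three is an optional
(cassette) exon.  Each clone is then genotyped purely from the amplicon
pattern of exon-specific primer pairs, and per-pool usage frequencies are
reported with exact (Clopper-Pearson) binomial confidence intervals.

Primer-template matching is IUPAC-class based: a primer position matches a
template base when its ambiguity class covers the base.  The 3'-terminal
primer base must match unconditionally (the standard PCR specificity rule);
elsewhere up to ``max_mismatch`` violations are tolerated (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy.stats import beta

from .annotation import find_orf
from .codons import IUPAC_MASK, degenerate_codon, revcomp, round_half_up, translate_nt

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Primer:
    name: str
    iupac_seq: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        if len(self.iupac_seq) < 3:
            raise ValueError("primer too short")
        bad = sorted(set(self.iupac_seq) - set(IUPAC_MASK))
        if bad:
            raise ValueError(f"invalid IUPAC letters {bad}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation {self.orientation!r}")


@dataclass(frozen=True)
class BindingSite:
    start: int  # 0-based template coordinates of the covered window
    end: int  # half-open
    strand: str  # '+' | '-'
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    start: int  # 0-based, 5' end of the forward site
    end: int  # half-open, 3' side of the reverse site
    fwd: str
    rev: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceEvent:
    kind: str  # "mutually_exclusive" | "optional" | "flagged"
    ref_interval: tuple[int, int]  # 0-based half-open on the reference
    protein_interval: tuple[int, int] | None  # 1-based inclusive residues
    variants: dict[str, str]  # exon label -> nucleotide sequence

    def __post_init__(self):
        if self.kind == "mutually_exclusive":
            if len(self.variants) != 2:
                raise ValueError("mutually exclusive event needs exactly 2 variants")
            la, lb = (len(v) for v in self.variants.values())
            if la != lb:
                raise ValueError("mutually exclusive variants must have equal length")
        if self.kind == "optional" and any(len(v) % 3 for v in self.variants.values()):
            raise ValueError("optional exon length must be divisible by 3")


@dataclass
class ExonUsageRow:
    pool: str
    exon: str
    n_clones: int
    count: int
    frequency: int  # integer percent
    ci_low: float  # percent
    ci_high: float


# ---------------------------------------------------------------------------
# Degenerate primer design
# ---------------------------------------------------------------------------


def design_degenerate_primer(
    peptide: str, orientation: str, primer_length: int, name: str | None = None
) -> Primer:
    """Back-translate a conserved peptide into an IUPAC-degenerate primer.

    Each residue becomes the minimal IUPAC codon covering all of its codons.
    The back-translated sense sequence is truncated at its 3' end to
    ``primer_length``; forward primers are that sequence, reverse primers its
    reverse complement.
    """
    if 3 * len(peptide) < primer_length:
        raise ValueError("peptide too short for the requested primer length")
    sense = "".join(degenerate_codon(aa) for aa in peptide)[:primer_length]
    seq = sense if orientation == "forward" else revcomp(sense)
    return Primer(name or f"{peptide}_{orientation[0]}", seq, orientation)


# ---------------------------------------------------------------------------
# IUPAC matching and in-silico PCR
# ---------------------------------------------------------------------------


def _mask_array(seq: str) -> np.ndarray:
    try:
        return np.array([IUPAC_MASK[b] for b in seq], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"invalid IUPAC letter {e.args[0]!r}") from None


def _scan(primer_seq: str, template: np.ndarray, max_mismatch: int, anchor: int):
    """Window starts where the primer covers the template with <= max_mismatch
    violations and position `anchor` (primer 3' base) covered exactly."""
    p = _mask_array(primer_seq)
    m = len(p)
    if len(template) < m:
        return []
    win = np.lib.stride_tricks.sliding_window_view(template, m)
    covered = (win & p) != 0
    ok = (m - covered.sum(axis=1) <= max_mismatch) & covered[:, anchor]
    return np.flatnonzero(ok)


def iupac_match(primer: Primer, template: str, max_mismatch: int = 0) -> list[BindingSite]:
    """All binding sites of the primer on both template strands.

    A '+' site means the primer sequence reads along the template sense
    strand (it primes leftward-to-rightward synthesis); a '-' site means the
    primer anneals to the sense strand (its reverse complement appears in
    the template) and primes rightward-to-leftward synthesis.
    """
    t = _mask_array(template.upper())
    m = len(primer.iupac_seq)
    sites = []
    for start in _scan(primer.iupac_seq, t, max_mismatch, anchor=m - 1):
        sites.append(BindingSite(int(start), int(start) + m, "+", 0))
    for start in _scan(revcomp(primer.iupac_seq), t, max_mismatch, anchor=0):
        sites.append(BindingSite(int(start), int(start) + m, "-", 0))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def in_silico_pcr(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_product: int = 3000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predicted products: every forward '+' site paired with every reverse
    '-' site downstream of it within ``max_product``."""
    fwd_sites = [s for s in iupac_match(fwd, template, max_mismatch) if s.strand == "+"]
    rev_sites = [s for s in iupac_match(rev, template, max_mismatch) if s.strand == "-"]
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start >= f.start and r.end - f.start <= max_product:
                out.append(Amplicon(f.start, r.end, fwd.name, rev.name))
    return out


# ---------------------------------------------------------------------------
# Splice-event detection
# ---------------------------------------------------------------------------


def _variant_blocks(clone: str, reference: str, min_anchor: int = 20):
    """Locate divergent blocks of a clone against the reference by edit-
    distance alignment (infix mode), merging variant operations separated by
    fewer than ``min_anchor`` matching bases.

    Returns (ref_start, ref_end, clone_segment) triples, ref coords 0-based.
    """
    res = edlib.align(clone, reference, mode="HW", task="path")
    ref_pos = res["locations"][0][0]
    cig = res["cigar"]
    blocks: list[tuple[int, int, int, int]] = []  # (ref_s, ref_e, q_s, q_e)
    q_pos = 0
    cur: list[int] | None = None
    import re as _re

    for num, op in _re.findall(r"(\d+)([=XIDM])", cig):
        n = int(num)
        if op in ("=", "M"):
            ref_pos += n
            q_pos += n
            if cur is not None:
                if n < min_anchor:
                    cur[1], cur[3] = ref_pos, q_pos  # absorb short match run
                else:
                    blocks.append(tuple(cur))
                    cur = None
        else:
            dr = n if op in ("X", "D") else 0  # D consumes the reference only
            dq = n if op in ("X", "I") else 0
            if cur is None:
                cur = [ref_pos, ref_pos + dr, q_pos, q_pos + dq]
            else:
                cur[1] = ref_pos + dr
                cur[3] = q_pos + dq
            ref_pos += dr
            q_pos += dq
    if cur is not None:
        blocks.append(tuple(cur))

    out = []
    for rs, re_, qs, qe in blocks:
        # strip flanking agreement absorbed by sub-anchor merges
        while re_ > rs and qe > qs and clone[qe - 1] == reference[re_ - 1]:
            re_ -= 1
            qe -= 1
        while re_ > rs and qe > qs and clone[qs] == reference[rs]:
            rs += 1
            qs += 1
        # canonicalize pure deletions to their leftmost equivalent placement
        if qs == qe:
            while rs > 0 and reference[rs - 1] == reference[re_ - 1]:
                rs -= 1
                re_ -= 1
        out.append((rs, re_, clone[qs:qe]))
    return out


def detect_splice_events(
    pools: Mapping[str, Sequence], reference, min_anchor: int = 20
) -> list[SpliceEvent]:
    """Infer alternative-splice events from clone pools against a reference.

    A locus where part of the clones carry a same-length divergent block is
    reported as a mutually exclusive exon pair (labels in first-observed
    order: 'a' is the variant of the first clone encountered); a locus where
    part of the clones lack a reference segment whose length is divisible by
    three is an optional exon; frame-breaking indels are flagged.
    """
    ref_seq = reference.seq if hasattr(reference, "seq") else reference
    try:
        orf = find_orf(ref_seq)
    except ValueError:
        orf = None

    # first pass: per-clone variant blocks
    clones = [c for pool in pools.values() for c in pool]
    per_clone: list[dict[tuple[int, int], str]] = []
    for clone in clones:
        seq = clone.seq if hasattr(clone, "seq") else clone
        per_clone.append(
            {(rs, re_): seg for rs, re_, seg in _variant_blocks(seq, ref_seq, min_anchor)}
        )
    loci_keys = sorted({k for blocks in per_clone for k in blocks})

    # second pass: variant alleles per locus in first-observed clone order
    events = []
    for rs, re_ in loci_keys:
        ref_allele = ref_seq[rs:re_]
        variants: dict[str, int] = {}
        for idx, blocks in enumerate(per_clone):
            allele = blocks.get((rs, re_), ref_allele)
            variants.setdefault(allele, idx)
        ordered = [v for v, _ in sorted(variants.items(), key=lambda kv: kv[1])]
        if any(len(self_v) != len(ref_allele) for self_v in ordered):
            # presence/absence: one allele empty (or shorter) => optional exon
            present = max(ordered, key=len)
            absent_ok = all(v in ("", present) for v in ordered)
            if absent_ok and len(present) % 3 == 0:
                kind = "optional"
                labelled = {"c": present}
            else:
                kind = "flagged"
                labelled = {f"v{i}": v for i, v in enumerate(ordered)}
        elif len(ordered) == 2:
            kind = "mutually_exclusive"
            labelled = {"a": ordered[0], "b": ordered[1]}
        else:
            kind = "flagged"
            labelled = {f"v{i}": v for i, v in enumerate(ordered)}

        protein_iv = None
        if orf is not None and kind != "flagged":
            nt0 = rs - orf.start  # 0-based ORF offset of the locus
            span = len(max(labelled.values(), key=len))
            if nt0 >= 0 and nt0 % 3 == 0 and nt0 + span <= 3 * len(orf.protein):
                protein_iv = (nt0 // 3 + 1, (nt0 + span) // 3)
        events.append(SpliceEvent(kind, (rs, re_), protein_iv, labelled))
    return events


def exon_divergence(event: SpliceEvent) -> tuple[int, int]:
    """Differing amino-acid positions between the translations of a mutually
    exclusive exon pair -> (n_differing, n_total)."""
    if event.kind != "mutually_exclusive":
        raise ValueError("exon divergence is defined for mutually exclusive events")
    a, b = (event.variants[k] for k in sorted(event.variants))
    if len(a) != len(b):
        raise ValueError("variants of unequal length")
    pa, pb = translate_nt(a), translate_nt(b)
    return sum(x != y for x, y in zip(pa, pb)), len(pa)


# ---------------------------------------------------------------------------
# Clone genotyping and usage tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticPanel:
    """Primer pairs keyed by the call they support.

    ``mutually_exclusive``: exon label -> (fwd, rev); an amplicon means the
    clone carries that exon.  ``optional``: {"present"/"absent" -> (fwd, rev)}.
    """

    mutually_exclusive: Mapping[str, tuple[Primer, Primer]]
    optional: Mapping[str, tuple[Primer, Primer]]


def classify_clone(
    clone, panel: DiagnosticPanel, max_product: int = 3000
) -> dict[str, str]:
    """Genotype one clone from its diagnostic amplicon pattern.

    Exactly one positive reaction per event gives the call; zero or
    contradictory positives give "ambiguous"."""
    seq = clone.seq if hasattr(clone, "seq") else clone
    calls = {}
    for event_name, pairs in (("iasi", panel.mutually_exclusive), ("iasii", panel.optional)):
        positives = [
            label
            for label, (fwd, rev) in pairs.items()
            if in_silico_pcr(seq, fwd, rev, max_product)
        ]
        calls[event_name] = positives[0] if len(positives) == 1 else "ambiguous"
    return calls


def clopper_pearson(count: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion (as fractions)."""
    if not 0 <= count <= n or n == 0:
        raise ValueError("invalid counts")
    alpha = 1 - conf
    lo = 0.0 if count == 0 else float(beta.ppf(alpha / 2, count, n - count + 1))
    hi = 1.0 if count == n else float(beta.ppf(1 - alpha / 2, count + 1, n - count))
    return lo, hi


def exon_usage(classified: Mapping[str, Sequence[Mapping[str, str]]]) -> list[ExonUsageRow]:
    """Per-pool usage table from clone genotypes.

    Mutually exclusive frequencies are complementary by construction: exon a
    is rounded half-up to integer percent and exon b reported as the
    complement, so a+b is always 100%.  Ambiguous calls are excluded from
    the denominators.  Clopper-Pearson 95% CIs are reported in percent.
    """
    rows: list[ExonUsageRow] = []
    for pool, calls in classified.items():
        if not calls:
            raise ValueError(f"pool {pool!r} is empty")
        ab = [c["iasi"] for c in calls if c.get("iasi", "ambiguous") != "ambiguous"]
        cc = [c["iasii"] for c in calls if c.get("iasii", "ambiguous") != "ambiguous"]
        if ab:
            n = len(ab)
            na = sum(1 for x in ab if x == "a")
            fa = round_half_up(100.0 * na / n)
            for exon, cnt, freq in (("a", na, fa), ("b", n - na, 100 - fa)):
                lo, hi = clopper_pearson(cnt, n)
                rows.append(ExonUsageRow(pool, exon, n, cnt, freq, 100 * lo, 100 * hi))
        if cc:
            n = len(cc)
            nc = sum(1 for x in cc if x == "present")
            lo, hi = clopper_pearson(nc, n)
            rows.append(
                ExonUsageRow(pool, "c", n, nc, round_half_up(100.0 * nc / n), 100 * lo, 100 * hi)
            )
    return rows


def cmryr_panel() -> DiagnosticPanel:
    """The published exon-diagnostic primer panel (Table-style rows 371-378)."""
    from .studydata import DIAGNOSTIC_PRIMERS as P

    def pr(num: str) -> Primer:
        row = next(v for k, v in P.items() if k.startswith(num))
        return Primer(row.name, row.sequence, row.orientation)

    return DiagnosticPanel(
        mutually_exclusive={"a": (pr("371"), pr("372")), "b": (pr("373"), pr("374"))},
        optional={"absent": (pr("375"), pr("376")), "present": (pr("377"), pr("378"))},
    )
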