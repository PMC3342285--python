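"""ORF location, translation, protein mass, UTR characterization and
silent/missense classification of inter-clone conflicts.

The ORF rule is "longest ATG-initiated, stop-terminated reading frame, ties
broken leftmost".  Conflict classification mirrors the polymorphism table
convention of cDNA studies: nucleotide positions are 1-based with the A of
the initiator ATG as position 1; substitutions sharing a codon are grouped
and the jointly mutated codon determines a single amino-acid exchange, while
each site still counts individually toward the silent/missense tallies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight

from .assembly import Contig, RawConflict
from .codons import CODON_TO_AA, round_half_up, translate_nt


@dataclass
class OrfAnnotation:
    seq: str  # the full source sequence
    start: int  # 0-based half-open ORF coordinates (incl. stop codon)
    end: int
    protein: str  # stop excluded

    @property
    def utr5(self) -> str:
        return self.seq[: self.start]

    @property
    def utr3(self) -> str:
        return self.seq[self.end :]

    @property
    def orf_seq(self) -> str:
        return self.seq[self.start : self.end]


@dataclass(frozen=True)
class Polymorphism:
    nt_position: int  # 1-based ORF coordinate (A of the start codon = 1)
    ref_base: str
    alt_base: str
    codon_index: int  # 1-based
    effect: str  # "silent" | "missense" | "noncoding"
    aa_exchange: tuple[str, int, str] | None  # (ref_aa, residue index, alt_aa)
    mnv_group: int | None = None  # shared by same-codon sites


def find_orf(seq: str) -> OrfAnnotation:
    """Longest ATG-to-stop ORF (stop required, leftmost on ties)."""
    seq = seq.upper()
    best: tuple[int, int] | None = None  # (start, end) 0-based half-open
    for frame in range(3):
        prev_stop_end = frame  # ORFs cannot cross an in-frame stop
        pending_atg: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if pending_atg is None and codon == "ATG":
                pending_atg = i
            if CODON_TO_AA.get(codon) == "*":
                if pending_atg is not None:
                    cand = (pending_atg, i + 3)
                    if best is None or (cand[1] - cand[0], -cand[0]) > (
                        best[1] - best[0],
                        -best[0],
                    ):
                        best = cand
                    pending_atg = None
                prev_stop_end = i + 3
    if best is None:
        raise ValueError("no ATG-initiated, stop-terminated ORF found")
    start, end = best
    return OrfAnnotation(seq, start, end, translate(seq[start:end]))


def translate(orf_nt: str) -> str:
    """Translate an ORF (standard code); the terminal stop is stripped, an
    internal stop is an error naming its codon index."""
    if len(orf_nt) % 3:
        raise ValueError("ORF length not divisible by 3")
    aa = translate_nt(orf_nt.upper())
    internal = aa[:-1].find("*")
    if internal >= 0:
        raise ValueError(f"internal stop codon at codon index {internal + 1}")
    return aa[:-1] if aa.endswith("*") else aa


def molecular_mass(protein: str) -> int:
    """Average molecular mass in Da (sum of residue masses plus one water),
    rounded half-up to an integer, initiator methionine included."""
    if not protein:
        raise ValueError("empty protein")
    if not set(protein) <= set("ACDEFGHIKLMNPQRSTVWY"):
        bad = sorted(set(protein) - set("ACDEFGHIKLMNPQRSTVWY"))
        raise ValueError(f"unknown residue(s): {bad}")
    return round_half_up(molecular_weight(protein, seq_type="protein", monoisotopic=False))


def utr_stats(ann: OrfAnnotation) -> dict:
    """UTR composition and regulatory-motif report: 5'UTR GC%, 3'UTR AT%
    (integer-rounded), literal TATAAA (TATA box) and AATAAA (poly(A) signal)
    searches on the DNA sense strand.  Empty UTRs are flagged."""
    utr5, utr3 = ann.utr5, ann.utr3
    out: dict = {"utr5_len": len(utr5), "utr3_len": len(utr3)}
    out["utr5_gc_percent"] = (
        round_half_up(100 * (utr5.count("G") + utr5.count("C")) / len(utr5)) if utr5 else None
    )
    out["utr3_at_percent"] = (
        round_half_up(100 * (utr3.count("A") + utr3.count("T")) / len(utr3)) if utr3 else None
    )
    out["tata_box"] = "TATAAA" in utr5 if utr5 else None
    out["polya_signal"] = "AATAAA" in utr3 if utr3 else None
    out["flags"] = [u for u, s in (("utr5", utr5), ("utr3", utr3)) if not s]
    return out


def classify_conflicts(
    conflicts: list[RawConflict], ann: OrfAnnotation
) -> list[Polymorphism]:
    """Classify assembly conflicts as silent or missense.

    The consensus base is the reference allele.  Conflicts outside the ORF
    are passed through unclassified (effect "noncoding", position in 1-based
    source coordinates).  Same-codon sites are grouped (``mnv_group``) and
    the joint mutated codon determines the exchange assigned to each member.
    """
    in_orf: dict[int, list[tuple[int, str, str]]] = {}  # codon_idx0 -> sites
    out: list[Polymorphism] = []
    for c in conflicts:
        ref_base = ann.seq[c.contig_position]
        alts = [b for b in c.alleles if b != ref_base]
        if ref_base not in c.alleles:
            raise ValueError(
                f"conflict at {c.contig_position}: no allele matches the consensus base"
            )
        if len(alts) != 1:
            raise ValueError(f"conflict at {c.contig_position}: expected biallelic site")
        alt_base = alts[0]
        if ann.start <= c.contig_position < ann.end - 3:
            orf_pos = c.contig_position - ann.start + 1  # 1-based
            in_orf.setdefault((orf_pos - 1) // 3, []).append((orf_pos, ref_base, alt_base))
        else:
            out.append(
                Polymorphism(c.contig_position + 1, ref_base, alt_base,
                             codon_index=0, effect="noncoding", aa_exchange=None)
            )

    orf = ann.orf_seq
    group_no = 0
    for codon_idx0, sites in sorted(in_orf.items()):
        ref_codon = orf[3 * codon_idx0 : 3 * codon_idx0 + 3]
        alt_codon = list(ref_codon)
        for orf_pos, ref_base, _alt in sites:
            if ref_codon[(orf_pos - 1) % 3] != ref_base:
                raise ValueError(f"conflict ref base at {orf_pos} disagrees with the contig")
        for orf_pos, _ref, alt_base in sites:
            alt_codon[(orf_pos - 1) % 3] = alt_base
        alt_codon = "".join(alt_codon)
        ref_aa, alt_aa = CODON_TO_AA[ref_codon], CODON_TO_AA[alt_codon]
        effect = "silent" if ref_aa == alt_aa else "missense"
        exchange = None if effect == "silent" else (ref_aa, codon_idx0 + 1, alt_aa)
        mnv = None
        if len(sites) > 1:
            group_no += 1
            mnv = group_no
        for orf_pos, ref_base, alt_base in sites:
            out.append(
                Polymorphism(orf_pos, ref_base, alt_base, codon_idx0 + 1,
                             effect, exchange, mnv)
            )
    out.sort(key=lambda p: p.nt_position)
    return out


def annotate_contig(contig: Contig) -> tuple[OrfAnnotation, list[Polymorphism]]:
    """Convenience: ORF-annotate a contig and classify its conflicts."""
    ann = find_orf(contig.seq)
    return ann, classify_conflicts(contig.conflicts, ann)


def effect_tally(polys: list[Polymorphism]) -> dict[str, int]:
    tally = {"total": 0, "missense": 0, "silent": 0, "noncoding": 0}
    for p in polys:
        tally["total"] += 1
        tally[p.effect] += 1
    return tally
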