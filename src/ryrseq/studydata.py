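"""Published characterization values for the CmRyR cDNA (GenBank JQ799046).

The rice leaffolder (*Cnaphalocrocis medinalis*) ryanodine receptor cDNA was
compiled from 16 overlapping RT-PCR/RACE clones into a 15,773-bp contig:
289 nt of 5'UTR, a 15,264-nt ORF (5,087 residues plus the TGA stop) and
220 nt of 3'UTR.  This module records the printed results of that study as
plain data: the 35 inter-clone nucleotide substitutions with their codon
effects, the degenerate and diagnostic PCR primers, the domain/motif
coordinate table, the alternative-splice loci, and the per-pool clone counts
behind the exon-usage figures.  The synthetic-data generator consumes these
tables to build fixtures whose downstream analysis reproduces the printed
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

# ---------------------------------------------------------------------------
# Transcript architecture
# ---------------------------------------------------------------------------

UTR5_LEN = 289
ORF_CODONS = 5088  # 5087 residues + stop => 15,264 nt
UTR3_LEN = 220
TRANSCRIPT_LEN = UTR5_LEN + 3 * ORF_CODONS + UTR3_LEN  # 15,773
PROTEIN_LEN = ORF_CODONS - 1  # 5,087

UTR5_GC_FRACTION = 0.41  # 5'UTR is 41% GC, no TATA box
UTR3_AT_FRACTION = 0.65  # 3'UTR is 65% AT, no AATAAA
N_CLONES = 16  # overlapping cDNA fragments (P1-P14 + R5 + R3)

# ---------------------------------------------------------------------------
# Inter-clone nucleotide substitutions (ORF coordinates, A of the start
# codon = 1).  35 sites: 20 missense, 15 silent.  Positions 14326/14327 fall
# in the same codon and jointly produce K4776L.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionRow:
    nt_position: int  # 1-based ORF coordinate
    ref_base: str
    alt_base: str
    effect: str  # "silent" | "missense"
    aa_exchange: tuple[str, int, str] | None  # (ref_aa, residue, alt_aa)


SUBSTITUTIONS: tuple[SubstitutionRow, ...] = tuple(
    SubstitutionRow(*row)
    for row in [
        (486, "A", "G", "silent", None),
        (837, "C", "T", "silent", None),
        (1021, "A", "G", "missense", ("K", 341, "E")),
        (3006, "A", "T", "missense", ("E", 1002, "D")),
        (3042, "A", "G", "silent", None),
        (3051, "C", "T", "silent", None),
        (3060, "C", "G", "silent", None),
        (3105, "A", "G", "silent", None),
        (3582, "T", "C", "silent", None),
        (6409, "A", "G", "missense", ("K", 2137, "E")),
        (6424, "A", "G", "missense", ("T", 2142, "A")),
        (6452, "G", "A", "missense", ("R", 2151, "Q")),
        (6843, "T", "C", "silent", None),
        (6868, "T", "G", "missense", ("C", 2290, "G")),
        (6964, "C", "T", "silent", None),
        (10252, "A", "G", "missense", ("T", 3418, "A")),
        (10351, "G", "A", "missense", ("A", 3451, "T")),
        (10521, "C", "T", "silent", None),
        (10524, "G", "T", "missense", ("W", 3508, "C")),
        (10554, "A", "G", "silent", None),
        (10559, "A", "T", "missense", ("Y", 3520, "F")),
        (10638, "G", "T", "silent", None),
        (11076, "G", "C", "silent", None),
        (11079, "C", "A", "silent", None),
        (11127, "C", "G", "silent", None),
        (11189, "T", "G", "missense", ("I", 3730, "S")),
        (11705, "T", "C", "missense", ("V", 3902, "A")),
        (11762, "A", "G", "missense", ("Q", 3921, "R")),
        (11863, "T", "C", "missense", ("F", 3955, "L")),
        (11915, "T", "C", "missense", ("V", 3972, "A")),
        (11947, "A", "G", "missense", ("T", 3983, "A")),
        (12724, "G", "A", "missense", ("G", 4242, "S")),
        (14326, "A", "C", "missense", ("K", 4776, "L")),
        (14327, "A", "T", "missense", ("K", 4776, "L")),
        (15124, "A", "T", "missense", ("M", 5042, "L")),
    ]
)

# ---------------------------------------------------------------------------
# Domain / motif coordinates (1-based inclusive protein positions)
# ---------------------------------------------------------------------------

PLOOP_PATTERN = "[GA]XXXXGK[ST]"  # Walker-A ATP/GTP-binding motif
PLOOP_SITE = (1088, 1095)
PORE_PATTERN = "GXRXGGGXGD"  # pore-forming selectivity-filter motif
PORE_SITE = (4939, 4948)
EF_HAND_SITES = ((4175, 4202), (4210, 4237))  # tandem EF-hands (Results)
TM_SEGMENTS = (
    (4434, 4456),
    (4615, 4637),
    (4697, 4719),
    (4839, 4861),
    (4887, 4909),
    (4967, 4986),
)

#: conserved structural domains plus the P-loop: 12 intervals in total
DOMAIN_INTERVALS: tuple[tuple[str, int, int], ...] = (
    ("SD", 12, 201),
    ("MIR", 212, 393),
    ("RIH", 440, 649),
    ("SPRY1", 666, 803),
    ("P-loop", 1088, 1095),
    ("SPRY2", 1092, 1213),
    ("SPRY3", 1518, 1659),
    ("RyR1", 854, 948),
    ("RyR2", 967, 1061),
    ("RyR3", 2802, 2895),
    ("RyR4", 2928, 3016),
    ("RIH-assoc", 3975, 4098),
)

# ---------------------------------------------------------------------------
# Alternative splicing: IASI (mutually exclusive 99-nt exons a/b inside the
# second SPRY domain) and IASII (optional in-frame 18-nt exon c between the
# third and fourth RyR domains)
# ---------------------------------------------------------------------------

IASI_RESIDUES = (1136, 1168)  # 33 codons, exons a/b
IASII_RESIDUES = (2915, 2920)  # 6 codons, exon c
EXON_AB_DIVERGENT_RESIDUES = 13  # exon a vs b translations differ at 13/33

# ---------------------------------------------------------------------------
# Oligonucleotide primers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerRow:
    name: str
    sequence: str
    peptide: str | None  # degenerate primers carry their source peptide
    orientation: str  # "forward" | "reverse"
    description: str


#: degenerate RT-PCR primers with the conserved peptides they were designed
#: against; these double as worked examples for the back-translation rules
DEGENERATE_PRIMERS: tuple[PrimerRow, ...] = (
    PrimerRow("258.RYRF13", "TGGTGGACNGTNCAYCCNGC", "WWTVHPA", "forward", "RT-PCR product P1"),
    PrimerRow("127.RYRR1", "TCCATYTTNCCYTCYTCRTG", "HEEGKMD", "reverse", "RT-PCR product P1"),
    PrimerRow("139.RYRF7", "GARAAYACNCAYAAYYTNTGG", "ENTHNLW", "forward", "RT-PCR product P3"),
    PrimerRow("141.RYRR7", "TCCCARTTNGCYTTYTCCAT", "MEKANWE", "reverse", "RT-PCR product P3"),
    PrimerRow("143.RYRR8", "TCRTTYTTRCANACYTCCAT", "MEVCKNE", "reverse", "RT-PCR product P4"),
    PrimerRow("290.RYRF14", "GCNATGTTYGAYCAYTTYGA", "AMFDHFD", "forward", "RT-PCR product P6"),
    PrimerRow("257.RYRR13", "TCNCCRTTNACCCANACRCA", "CVWVNGE", "reverse", "RT-PCR product P6"),
    PrimerRow("146.RYRF10", "GARCAYTAYCAYGAYGCNTGG", "EHYHDAW", "forward", "RT-PCR product P8"),
    PrimerRow("147.RYRR10", "GCNACCATYTCYTTYTCYTT", "KEKEMVA", "reverse", "RT-PCR product P8"),
    PrimerRow("148.RYRF11", "CCNTGGATGACNMGNATHGC", "PWMTRIA", "forward", "RT-PCR product P10"),
    PrimerRow("149.RYRR11", "TGYTGNGGRTGRTCDATCAT", "MIDHPQQ", "reverse", "RT-PCR product P10"),
    PrimerRow("132.RYRF4", "ATGGAYTTYTAYTGGCAYTA", "MDFYWHY", "forward", "RT-PCR product P12"),
    PrimerRow("133.RYRR4", "GGYTCRTTNGGCATRTGYTC", "EHMPNEP", "reverse", "RT-PCR product P12"),
    PrimerRow("134.RYRF5", "GTNAAYTAYTGGGAYAARTT", "VNYWDKF", "forward", "RT-PCR product P14"),
    PrimerRow("136.RYRR5", "CATRTTCCANACRTANGTYTC", "ETYVWNM", "reverse", "RT-PCR product P14"),
)

#: exon-diagnostic PCR primers (concrete sequences)
DIAGNOSTIC_PRIMERS: dict[str, PrimerRow] = {
    row.name: row
    for row in (
        PrimerRow("371.CmRyRF1", "GTCAGTTCCGGGAAATGGTA", None, "forward", "diagnostic PCR for exon a"),
        PrimerRow("372.CmRyRR1", "CCCACTGCTTGCCAAACGAC", None, "reverse", "diagnostic PCR for exon a"),
        PrimerRow("373.CmRyRF2", "CAGTTTCGGGCAGCAGTTCA", None, "forward", "diagnostic PCR for exon b"),
        PrimerRow("374.CmRyRR2", "ATCCTGGTATCTGGCATTTC", None, "reverse", "diagnostic PCR for exon b"),
        PrimerRow("375.CmRyRF3", "AACAACGACCTCAACACCAT", None, "forward", "diagnostic PCR for the absence of exon c"),
        PrimerRow("376.CmRyRR3", "GTGGCTGAATCCGTACCACC", None, "reverse", "diagnostic PCR for the absence of exon c"),
        PrimerRow("377.CmRyRF4", "TCGACCACCAGATGTCGTGA", None, "forward", "diagnostic PCR for the presence of exon c"),
        PrimerRow("378.CmRyRR4", "TATCGGTGAGGAGGTCGTAG", None, "reverse", "diagnostic PCR for the presence of exon c"),
    )
}

# ---------------------------------------------------------------------------
# Exon-usage clone pools (E eggs, L1/L3/L5 larval instars, P pupae,
# AH adult heads, AB adult bodies).  Counts printed in the text: exon a in
# all egg and adult-head clones, 16/23 pupal and 11/21 adult-body clones;
# exon c at 0%, 55%, 17%, 10% and ~70% in E, L1, L3, L5 and P.  Totals other
# than 23/21 fall in the reported 18-27 range; the AH/AB exon-c counts are
# not printed and are fixture choices.
# ---------------------------------------------------------------------------

POOL_COUNTS: dict[str, tuple[int, int, int]] = {
    # pool -> (n_clones, n_exon_a, n_exon_c_present)
    "E": (18, 18, 0),
    "L1": (20, 20, 11),
    "L3": (24, 24, 4),
    "L5": (20, 20, 2),
    "P": (23, 16, 16),
    "AH": (25, 25, 5),
    "AB": (21, 11, 8),
}

# ---------------------------------------------------------------------------
# Grouped MSA (C-terminal comparison): 31 RyR isoforms from 26 species.
# 7 residues are lepidopteran-diagnostic; at two of them a single
# non-lepidopteran sequence (the spider mite, resp. C. elegans) carries the
# lepidopteran residue.
# ---------------------------------------------------------------------------

MSA_GROUPS: dict[str, tuple[str, ...]] = {
    "lepidoptera": ("CmRyR", "sRyR", "PxRyR", "HvRyR", "DpRyR"),
    "other_insects": (
        "HsRyR", "DmRyR", "AaRyR", "PhcRyR", "TcRyR", "PaRyR", "AgRyR",
        "AmRyR", "BiRyR", "BtRyR", "CfRyR", "CqRyR", "ApRyR",
    ),
    "other_invertebrates": ("TuRyR", "SmRyR", "SjRyR", "HpRyR", "CeRyR"),
    "non_mammalian_vertebrates": ("RcRyRa", "RcRyRb"),
    "mammals": ("hRyR1", "hRyR2", "hRyR3", "OcRyR1", "OcRyR2", "OcRyR3"),
}
FOCAL_GROUP = "lepidoptera"
N_DIAGNOSTIC_RESIDUES = 7  # 5 clean + 2 single-exception columns
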