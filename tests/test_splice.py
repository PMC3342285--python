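"""Degenerate primer design, IUPAC PCR, splice-event detection, exon usage."""

import itertools

import numpy as np
import pytest

from ryrseq import studydata as S
from ryrseq.codons import AA_TO_CODONS, IUPAC_BASES, revcomp, translate_nt
from ryrseq.splice import (
    Primer,
    classify_clone,
    clopper_pearson,
    cmryr_panel,
    design_degenerate_primer,
    detect_splice_events,
    exon_divergence,
    exon_usage,
    in_silico_pcr,
    iupac_match,
)
from ryrseq.synthetic import Clone


class TestDegeneratePrimerDesign:
    @pytest.mark.parametrize(
        "row", S.DEGENERATE_PRIMERS, ids=[r.name for r in S.DEGENERATE_PRIMERS]
    )
    def test_published_primer_rows_byte_identical(self, row):
        got = design_degenerate_primer(row.peptide, row.orientation, len(row.sequence))
        assert got.iupac_seq == row.sequence

    def test_single_codon_residue(self):
        assert design_degenerate_primer("M", "forward", 3).iupac_seq == "ATG"

    def test_peptide_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            design_degenerate_primer("MK", "forward", 12)

    def test_stop_residue_rejected(self):
        with pytest.raises(ValueError, match="back-translate"):
            design_degenerate_primer("M*K", "forward", 9)

    def test_roundtrip_every_expansion_encodes_the_peptide(self):
        """Each concrete expansion of the degenerate primer is a codon
        sequence encoding the source peptide prefix."""
        pep = "WCM"  # small degeneracy so the expansion set stays tiny
        primer = design_degenerate_primer(pep, "forward", 9)
        pools = [sorted(IUPAC_BASES[c]) for c in primer.iupac_seq]
        for combo in itertools.product(*pools):
            assert translate_nt("".join(combo)) == pep

    def test_reverse_roundtrip_via_complement(self):
        pep = "MKW"
        primer = design_degenerate_primer(pep, "reverse", 9)
        sense_pools = [sorted(IUPAC_BASES[c]) for c in revcomp(primer.iupac_seq)]
        for combo in itertools.product(*sense_pools):
            assert translate_nt("".join(combo)) == pep


def _oracle_iupac_sites(primer_seq, template, max_mm, anchor_last):
    """Brute-force window checker for one strand."""
    m = len(primer_seq)
    out = []
    for s in range(len(template) - m + 1):
        ok = [template[s + k] in IUPAC_BASES[primer_seq[k]] for k in range(m)]
        anchor = ok[-1] if anchor_last else ok[0]
        if anchor and (m - sum(ok)) <= max_mm:
            out.append(s)
    return out


class TestIupacMatch:
    def test_ambiguity_class_semantics(self):
        primer = Primer("p", "CAY", "forward")
        assert any(s.strand == "+" for s in iupac_match(primer, "GGCATGG"))
        assert not [s for s in iupac_match(primer, "GGCAGGG") if s.strand == "+"]

    def test_equals_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(17)
        iupac = list("ACGTRYSWKMN")
        for _ in range(25):
            primer_seq = "".join(rng.choice(iupac, size=8))
            template = "".join(rng.choice(list("ACGT"), size=120))
            for mm in (0, 1, 2):
                got = iupac_match(Primer("p", primer_seq, "forward"), template, mm)
                plus = [s.start for s in got if s.strand == "+"]
                minus = [s.start for s in got if s.strand == "-"]
                assert plus == _oracle_iupac_sites(primer_seq, template, mm, True)
                assert minus == _oracle_iupac_sites(revcomp(primer_seq), template, mm, False)

    def test_three_prime_anchor_is_strict(self):
        # one mismatch allowed, but never at the 3'-terminal base
        primer = Primer("p", "AAAA", "forward")
        sites = iupac_match(primer, "AAAT", max_mismatch=1)
        assert not [s for s in sites if s.strand == "+"]
        sites = iupac_match(primer, "ATAA", max_mismatch=1)
        assert [s.start for s in sites if s.strand == "+"] == [0]


class TestInSilicoPcr:
    def test_exon_specific_pairs_discriminate(self, splice_fixture):
        pools, truth, _ = splice_fixture
        panel = cmryr_panel()
        by_id = {r["id"]: r for r in truth}
        fa, ra = panel.mutually_exclusive["a"]
        fb, rb = panel.mutually_exclusive["b"]
        for clone in pools["P"]:
            a_amp = in_silico_pcr(clone.seq, fa, ra)
            b_amp = in_silico_pcr(clone.seq, fb, rb)
            if by_id[clone.id]["iasi"] == "a":
                assert len(a_amp) == 1 and b_amp == []
            else:
                assert a_amp == [] and len(b_amp) == 1

    def test_junction_primers_discriminate_exon_c(self, splice_fixture):
        pools, truth, _ = splice_fixture
        panel = cmryr_panel()
        by_id = {r["id"]: r for r in truth}
        fp, rp = panel.optional["present"]
        fa, ra = panel.optional["absent"]
        for clone in pools["L1"]:
            present = bool(in_silico_pcr(clone.seq, fp, rp))
            absent = bool(in_silico_pcr(clone.seq, fa, ra))
            assert present != absent
            assert present == (by_id[clone.id]["iasii"] == "present")

    def test_no_binding_sites_empty(self):
        f = Primer("f", "ACGTACGTACGT", "forward")
        r = Primer("r", "TTTTGGGGCCCC", "reverse")
        assert in_silico_pcr("A" * 200, f, r) == []


class TestSpliceEventDetection:
    def test_fixture_events(self, splice_fixture, reference):
        pools, _, exons = splice_fixture
        events = detect_splice_events(pools, reference)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["mutually_exclusive", "optional"]
        me = next(e for e in events if e.kind == "mutually_exclusive")
        opt = next(e for e in events if e.kind == "optional")
        assert me.protein_interval == S.IASI_RESIDUES
        assert opt.protein_interval == S.IASII_RESIDUES
        assert sorted(me.variants.values()) == sorted([exons["a"], exons["b"]])
        assert opt.variants == {"c": exons["c"]}

    def test_first_observed_variant_is_labelled_a(self, splice_fixture, reference):
        pools, truth, exons = splice_fixture
        events = detect_splice_events(pools, reference)
        me = next(e for e in events if e.kind == "mutually_exclusive")
        first_clone_variant = truth[0]["iasi"]  # composition of the first clone
        expected_a = exons[first_clone_variant]
        assert me.variants["a"] == expected_a

    def test_identical_clones_no_events(self, reference):
        window = reference.seq[3000:5000]
        pools = {"x": [Clone(f"c{i}", window) for i in range(4)]}
        assert detect_splice_events(pools, reference) == []

    def test_frame_breaking_indel_flagged(self, reference):
        window = reference.seq[8900:9600]
        broken = window[:300] + window[317:]  # 17-nt deletion
        pools = {"x": [Clone("ok", window), Clone("bad", broken)]}
        events = detect_splice_events(pools, reference)
        assert [e.kind for e in events] == ["flagged"]

    def test_planted_optional_block_is_six_codons(self, splice_fixture, reference):
        pools, _, _ = splice_fixture
        opt = next(
            e for e in detect_splice_events(pools, reference) if e.kind == "optional"
        )
        assert len(opt.variants["c"]) == 18
        assert opt.protein_interval[1] - opt.protein_interval[0] + 1 == 6


class TestExonDivergence:
    def test_fixture_pair_differs_at_13_of_33(self, splice_fixture, reference):
        pools, _, _ = splice_fixture
        me = next(
            e
            for e in detect_splice_events(pools, reference)
            if e.kind == "mutually_exclusive"
        )
        assert exon_divergence(me) == (13, 33)

    def test_identical_variants(self):
        from ryrseq.splice import SpliceEvent

        ev = SpliceEvent("mutually_exclusive", (0, 9), None, {"a": "ATGAAATTT", "b": "ATGAAATTT"})
        assert exon_divergence(ev) == (0, 3)

    def test_random_pair_matches_hand_hamming(self):
        from ryrseq.splice import SpliceEvent

        rng = np.random.default_rng(8)
        codons = [c for cs in AA_TO_CODONS.values() for c in cs]
        a = "".join(rng.choice(codons, 10))
        b = "".join(rng.choice(codons, 10))
        ev = SpliceEvent("mutually_exclusive", (0, 30), None, {"a": a, "b": b})
        hand = sum(
            translate_nt(a)[i] != translate_nt(b)[i] for i in range(10)
        )
        assert exon_divergence(ev) == (hand, 10)


class TestClassifyAndUsage:
    def test_end_to_end_recovery_no_ambiguity(self, splice_fixture):
        pools, truth, _ = splice_fixture
        panel = cmryr_panel()
        by_id = {r["id"]: r for r in truth}
        for name, clones in pools.items():
            for clone in clones:
                call = classify_clone(clone, panel)
                assert call["iasi"] == by_id[clone.id]["iasi"]
                assert call["iasii"] == by_id[clone.id]["iasii"]

    def test_contradictory_pattern_is_ambiguous(self, splice_fixture, reference):
        pools, _, exons = splice_fixture
        # a chimeric template carrying both exon a and exon b primer sites
        a_clone = next(c for c in pools["P"] if exons["a"] in c.seq)
        b_clone = next(c for c in pools["P"] if exons["b"] in c.seq)
        chimera = Clone("chimera", a_clone.seq + b_clone.seq)
        assert classify_clone(chimera, cmryr_panel())["iasi"] == "ambiguous"

    def test_usage_frequencies_match_printed_values(self, splice_fixture):
        pools, _, _ = splice_fixture
        panel = cmryr_panel()
        classified = {
            n: [classify_clone(c, panel) for c in cl] for n, cl in pools.items()
        }
        rows = exon_usage(classified)
        freq = {(r.pool, r.exon): r.frequency for r in rows}
        assert freq[("P", "b")] == 30 and freq[("AB", "b")] == 48
        assert freq[("E", "a")] == 100 and freq[("AH", "a")] == 100
        # complementarity invariant in every pool
        for pool in pools:
            assert freq[(pool, "a")] + freq[(pool, "b")] == 100
        # CI contains the point estimate
        for r in rows:
            assert r.ci_low - 1e-9 <= 100 * r.count / r.n_clones <= r.ci_high + 1e-9

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            exon_usage({"E": []})

    def test_clopper_pearson_coverage(self):
        """95% exact intervals cover the true proportion in >= 93% of
        seeded binomial replicates."""
        rng = np.random.default_rng(123)
        p, n, reps = 0.3, 23, 400
        covered = 0
        for _ in range(reps):
            k = rng.binomial(n, p)
            lo, hi = clopper_pearson(k, n)
            covered += lo <= p <= hi
        assert covered / reps >= 0.93
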