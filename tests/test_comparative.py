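"""Alignment/identity, p-distance, NJ + bootstrap, diagnostic-site scan."""

import numpy as np
import pytest

from ryrseq.comparative import (
    DistanceMatrix,
    GroupedAlignment,
    bootstrap_support,
    find_diagnostic_sites,
    global_align,
    nj_tree,
    p_distance_matrix,
    percent_identity,
)

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def _nw_affine_oracle(a, b, gap_open=10.0, gap_extend=0.5):
    """Independent affine-gap global alignment score (Gotoh three-state DP)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    NEG = -1e9
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("MKE", "MKE")
        assert aln.aligned_a == aln.aligned_b == "MKE"

    def test_single_residue_gap(self):
        aln = global_align("MKE", "ME")
        assert aln.aligned_a == "MKE"
        assert aln.aligned_b.count("-") == 1

    def test_score_matches_independent_dp(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            a = "".join(rng.choice(AAS, size=int(rng.integers(3, 12))))
            b = "".join(rng.choice(AAS, size=int(rng.integers(3, 12))))
            assert global_align(a, b).score == pytest.approx(_nw_affine_oracle(a, b))

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            global_align("MKE", "MXE-")


class TestPercentIdentity:
    def test_boundaries(self):
        assert percent_identity(global_align("MKTE", "MKTE")) == 100
        assert percent_identity(global_align("MK", "ME")) == 50

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join(rng.choice(AAS, size=20))
            b = "".join(rng.choice(AAS, size=25))
            pid = percent_identity(global_align(a, b))
            assert pid == percent_identity(global_align(b, a))
            assert 0 <= pid <= 100


class TestPDistance:
    def test_trivial_cases(self):
        dm = p_distance_matrix({"a": "MKE", "b": "MKE"})
        assert dm.matrix[0, 1] == 0
        dm = p_distance_matrix({"a": "MKE", "b": "WRT"})
        assert dm.matrix[0, 1] == 1.0

    def test_hand_count_with_gaps(self):
        dm = p_distance_matrix({"a": "MK-E", "b": "MATE", "c": "M-TE"})
        lbl = dm.labels
        # a vs b: columns 1,2,4 comparable, 1 differs
        assert dm.matrix[lbl.index("a"), lbl.index("b")] == pytest.approx(1 / 3)
        # a vs c: columns 1,4 comparable, none differ
        assert dm.matrix[lbl.index("a"), lbl.index("c")] == 0


def _tree_distance_matrix(newick_like):
    """Additive distances for a fixed 4-taxon tree ((A:1,B:2):1,(C:3,D:4))."""
    d = {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
        ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
    }
    labels = ("A", "B", "C", "D")
    m = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(labels, m)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery_vs_exhaustive_fit(self):
        dm = _tree_distance_matrix(None)
        # oracle: least-squares fit over all three unrooted quartet topologies
        def quartet_fit(split):
            (a, b), (c, d) = split
            lbl = dm.labels
            D = lambda x, y: dm.matrix[lbl.index(x), lbl.index(y)]
            # four-point condition residual for the split ab|cd
            return abs((D(a, c) + D(b, d)) - (D(a, d) + D(b, c)))

        splits = [(("A", "B"), ("C", "D")), (("A", "C"), ("B", "D")), (("A", "D"), ("B", "C"))]
        best = min(splits, key=quartet_fit)
        assert best == (("A", "B"), ("C", "D"))
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), m))
        lengths = {c.label: l for c, l in tree.root.children}
        assert lengths == {"a": 1.0, "b": 3.0, "c": 5.0}

    def test_ultrametric_five_taxon_clades(self):
        labels = ("u", "v", "w", "x", "y")
        # clades (u,v) and (x,y), w outgroupish
        m = np.array(
            [
                [0, 2, 8, 10, 10],
                [2, 0, 8, 10, 10],
                [8, 8, 0, 10, 10],
                [10, 10, 10, 0, 2],
                [10, 10, 10, 2, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(labels, m))
        assert frozenset({"x", "y"}) in tree.bipartitions()
        assert frozenset({"u", "v"}) in tree.bipartitions() or frozenset(
            {"w", "x", "y"}
        ) in tree.bipartitions()

    @pytest.mark.parametrize("seed", range(4))
    def test_random_additive_matrices_recover_topology(self, seed):
        """NJ on exact additive path-length distances from random binary
        trees (n <= 8) recovers every generating bipartition."""
        import random

        import dendropy

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
        dtree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            taxon_namespace=tns, rng=random.Random(seed),
        )
        for e in dtree.preorder_edge_iter():
            e.length = float(rng.uniform(0.5, 3))
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = list(tns)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
        tree = nj_tree(DistanceMatrix(tuple(t.label for t in taxa), m))

        all_lab = frozenset(t.label for t in taxa)
        anchor = min(all_lab)
        true_bips = set()
        for node in dtree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(side) < n - 1:
                true_bips.add(side if anchor not in side else all_lab - side)
        assert tree.bipartitions() == true_bips


class TestBootstrap:
    def test_clade_support_on_structured_alignment(self):
        rng = np.random.default_rng(3)
        base = {g: "".join(rng.choice(AAS, size=150)) for g in "XYZ"}
        seqs = {f"{g}{i}": base[g] for g in "XYZ" for i in range(4)}
        # no within-clade divergence, strong between-clade divergence
        tree = bootstrap_support(seqs, replicates=200, seed=9)
        supports = {}

        def collect(node):
            for child, _ in node.children:
                if child.children and child.support is not None:
                    supports[child.leaves()] = child.support
                collect(child)

        collect(tree.root)
        clades = [frozenset(f"{g}{i}" for i in range(4)) for g in "XYZ"]
        found = [s for ls, s in supports.items() if ls in clades]
        assert found and all(s >= 0.95 for s in found)

    def test_identical_sequences_star_flagged(self):
        seqs = {f"s{i}": "MKTE" * 10 for i in range(5)}
        tree = bootstrap_support(seqs, replicates=10, seed=0)
        assert tree.star
        assert all(not c.children for c, _ in tree.root.children)


def _oracle_diagnostic(seqs, groups, focal, max_exc):
    """Independent per-column re-implementation of the diagnosticity rule."""
    focal_ids = [i for i in seqs if groups[i] == focal]
    other_ids = [i for i in seqs if groups[i] != focal]
    L = len(next(iter(seqs.values())))
    cols = []
    for c in range(L):
        fr = {seqs[i][c] for i in focal_ids}
        if len(fr) != 1 or fr == {"-"}:
            continue
        x = fr.pop()
        if x == "-":
            continue
        best = None
        for y in sorted(set("ACDEFGHIKLMNPQRSTVWY") - {x}):
            exc = [i for i in other_ids if seqs[i][c] != y]
            if any(seqs[i][c] == y for i in other_ids) and (
                best is None or len(exc) < len(best)
            ):
                best = exc
        if best is not None and len(best) <= max_exc:
            cols.append(c + 1)
    return cols


class TestDiagnosticSites:
    def test_fixture_counts_at_both_allowances(self, grouped_msa):
        seqs, groups, truth = grouped_msa
        ga = GroupedAlignment(seqs, groups, "lepidoptera")
        sites1 = find_diagnostic_sites(ga, max_exceptions=1)
        sites0 = find_diagnostic_sites(ga, max_exceptions=0)
        assert len(sites1) == 7 and len(sites0) == 5
        assert [s.column for s in sites1] == [r["column"] for r in truth]
        exc = {s.column: s.exception_ids for s in sites1 if s.n_exceptions}
        assert sorted(i for ids in exc.values() for i in ids) == ["CeRyR", "TuRyR"]

    def test_equals_per_column_oracle_on_random_alignments(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            ids = [f"s{i}" for i in range(8)]
            groups = {i: ("f" if k < 3 else "o") for k, i in enumerate(ids)}
            seqs = {
                i: "".join(rng.choice(list("AC-"), size=40, p=[0.45, 0.45, 0.1]))
                for i in ids
            }
            ga = GroupedAlignment(seqs, groups, "f")
            for allow in (0, 1, 2):
                got = [s.column for s in find_diagnostic_sites(ga, allow)]
                assert got == _oracle_diagnostic(seqs, groups, "f", allow)

    def test_monotone_in_allowance(self, grouped_msa):
        seqs, groups, _ = grouped_msa
        ga = GroupedAlignment(seqs, groups, "lepidoptera")
        counts = [len(find_diagnostic_sites(ga, k)) for k in range(4)]
        assert counts == sorted(counts)

    def test_fully_conserved_alignment_empty(self):
        seqs = {f"s{i}": "MMMM" for i in range(6)}
        groups = {f"s{i}": "f" if i < 2 else "o" for i in range(6)}
        assert find_diagnostic_sites(GroupedAlignment(seqs, groups, "f"), 2) == []

    def test_focal_gap_disqualifies_nonfocal_gap_counts(self):
        seqs = {"f1": "K", "f2": "-", "o1": "R", "o2": "R"}
        groups = {"f1": "f", "f2": "f", "o1": "o", "o2": "o"}
        assert find_diagnostic_sites(GroupedAlignment(seqs, groups, "f"), 2) == []
        seqs2 = {"f1": "K", "f2": "K", "o1": "R", "o2": "-"}
        sites = find_diagnostic_sites(GroupedAlignment(seqs2, groups, "f"), 1)
        assert len(sites) == 1 and sites[0].exception_ids == ("o2",)
        assert find_diagnostic_sites(GroupedAlignment(seqs2, groups, "f"), 0) == []

    def test_missing_focal_group_error(self):
        with pytest.raises(ValueError, match="focal"):
            GroupedAlignment({"a": "M"}, {"a": "o"}, "f")
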