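"""Alignment, codon back-translation, outliers, NJ trees, duplication
detection, the 5% prune-vs-split rule, and physical annotations."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from pannlrome.models import CodonAlignment, GeneModel, Orthogroup
from pannlrome.refinement import (GeneTree, align_og, annotate_og,
                                  build_tree, classify_og_type,
                                  detect_duplications, detect_outliers,
                                  detect_pairs, detect_physical_clusters,
                                  protein_to_codon, refine_og)

_B62 = substitution_matrices.load("BLOSUM62")


def global_alignment_oracle(a: str, b: str, open_=-11.0, ext=-1.0) -> float:
    """Exhaustive enumeration of global alignments for tiny sequences."""
    best = -np.inf

    def rec(i, j, score, gap_state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _B62[a[i]][b[j]], None)
        if i < len(a):
            cost = ext if gap_state == "a" else open_
            rec(i + 1, j, score + cost, "a")
        if j < len(b):
            cost = ext if gap_state == "b" else open_
            rec(i, j + 1, score + cost, "b")

    rec(0, 0, 0.0, None)
    return best


class TestAlignOG:
    def test_identical_sequences_align_gap_free(self):
        msa = align_og({"a": "MKVLLAG", "b": "MKVLLAG", "c": "MKVLLAG"})
        assert all("-" not in row for row in msa.values())

    def test_pairwise_score_is_global_optimum(self):
        from pannlrome.refinement import _align_profiles
        for a, b in [("MKV", "MV"), ("MKWL", "MWL"), ("ACDEF", "ADF")]:
            ra, rb, score = _align_profiles([a], [b])
            assert score == pytest.approx(global_alignment_oracle(a, b))
            assert ra[0].replace("-", "") == a
            assert rb[0].replace("-", "") == b

    def test_one_gap_in_shorter_row(self):
        msa = align_og({"a": "MKV", "b": "MV"})
        assert msa["a"] == "MKV"
        assert msa["b"].count("-") == 1

    def test_row_order_preserved(self):
        msa = align_og({"z": "MKV", "a": "MKV", "m": "MKV"})
        assert list(msa) == ["z", "a", "m"]

    def test_residues_preserved_in_rows(self):
        seqs = {"a": "MKVLLAGWW", "b": "MKVAGWW", "c": "MKVLLGWW",
                "d": "MKVLLAGW"}
        msa = align_og(seqs)
        for name, row in msa.items():
            assert row.replace("-", "") == seqs[name]

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_og({"a": "MKV"})


class TestProteinToCodon:
    def test_gap_becomes_triple_dash(self):
        out = protein_to_codon({"a": "M-K", "b": "MAK"},
                               {"a": "ATGAAA", "b": "ATGGCTAAA"})
        assert out.row("a") == "ATG---AAA"

    def test_trailing_stop_excluded(self):
        out = protein_to_codon({"a": "MK", "b": "MK"},
                               {"a": "ATGAAATAA", "b": "ATGAAA"})
        assert out.row("a") == "ATGAAA"

    def test_mismatch_reported_with_gene_and_residue(self):
        with pytest.raises(ValueError, match="a.*residue 2"):
            protein_to_codon({"a": "MK"}, {"a": "ATGCCC"})


class TestDetectOutliers:
    def _family(self, n, seed=0):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 60))
        rows = {}
        for i in range(n):
            s = list(base)
            for p in rng.choice(60, size=3, replace=False):
                s[p] = rng.choice(list("ARNDCQEGHILKMFPSTWYV"))
            rows[f"g{i}"] = "".join(s)
        return rows

    def test_identical_rows_give_no_outliers(self):
        msa = {f"g{i}": "MKVLLAGWWQ" for i in range(10)}
        assert detect_outliers(msa, seed=1) == set()

    def test_random_intruder_is_flagged(self):
        rows = self._family(9, seed=2)
        rng = np.random.default_rng(3)
        rows["intruder"] = "".join(
            rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 60))
        assert detect_outliers(rows, seed=4) == {"intruder"}

    def test_deterministic_under_seed(self):
        rows = self._family(8, seed=5)
        assert detect_outliers(rows, seed=6) == detect_outliers(rows, seed=6)

    def test_small_families_are_skipped(self):
        assert detect_outliers({"a": "MK", "b": "MK", "c": "WW",
                                "d": "MK"}, seed=1) == set()


def _aln_from_rows(rows: dict[str, str]) -> CodonAlignment:
    return CodonAlignment(list(rows), list(rows.values()))


class TestBuildTree:
    def test_identical_rows_give_zero_branch_lengths(self):
        aln = _aln_from_rows({c: "ATGATGATG" for c in "abc"})
        gt = build_tree(aln, bootstrap_reps=0)
        assert gt.total_branch_length == 0.0

    def test_nj_recovers_topology_from_additive_matrix(self):
        # distances: d(a,b)=2, d(c,d)=4, cross = 6 -> ((a,b),(c,d)); verify
        # against brute force over the three quartet topologies
        D = {("a", "b"): 2, ("a", "c"): 6, ("a", "d"): 6,
             ("b", "c"): 6, ("b", "d"): 6, ("c", "d"): 4}

        def quartet_cost(split):
            (p, q), (r, s) = split
            # four-point: the true split minimizes d(p,q) + d(r,s)
            return D[tuple(sorted((p, q)))] + D[tuple(sorted((r, s)))]

        splits = [(("a", "b"), ("c", "d")), (("a", "c"), ("b", "d")),
                  (("a", "d"), ("b", "c"))]
        best = min(splits, key=quartet_cost)
        assert best == (("a", "b"), ("c", "d"))

        # build sequences realizing (a scaled version of) these distances
        L = 300
        base = "A" * L
        rows = {"a": base, "b": base, "c": base, "d": base}

        def mutate(row, positions):
            s = list(row)
            for p in positions:
                s[p] = "T"
            return "".join(s)

        # a-b differ at 20 sites; c-d at 40; cross pairs at 60
        rows["b"] = mutate(rows["b"], range(0, 20))
        rows["c"] = mutate(rows["c"], range(100, 150))
        rows["d"] = mutate(rows["d"], range(130, 190))
        gt = build_tree(_aln_from_rows(rows), bootstrap_reps=0)
        tips_under = [frozenset(t.name for t in n.tips())
                      for n in gt.tree.non_tips()]
        assert (frozenset({"a", "b"}) in tips_under
                or frozenset({"c", "d"}) in tips_under)

    def test_bootstrap_supports_in_range(self):
        rng = np.random.default_rng(8)
        rows = {}
        base = rng.choice(list("ACGT"), 90)
        for i in range(5):
            s = base.copy()
            s[rng.choice(90, size=6, replace=False)] = "T"
            rows[f"g{i}"] = "".join(s)
        gt = build_tree(_aln_from_rows(rows), bootstrap_reps=20, seed=9)
        sups = [n.support for n in gt.tree.non_tips()
                if getattr(n, "support", None) is not None]
        assert sups and all(0 <= s <= 100 for s in sups)

    def test_two_leaves_degenerate(self):
        aln = _aln_from_rows({"a": "ATGATG", "b": "ATGTTG"})
        gt = build_tree(aln, bootstrap_reps=0)
        assert sorted(gt.leaves) == ["a", "b"]


def _tree_from_newick(nwk: str, leaves: list[str]) -> GeneTree:
    from skbio import TreeNode
    return GeneTree(tree=TreeNode.read([nwk]), leaves=leaves)


class TestDetectDuplications:
    ACC = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}

    def test_sister_leaves_same_accession_is_simple(self):
        gt = _tree_from_newick("((a1:1,a2:1):1,(b1:1,c1:1):1);",
                               ["a1", "a2", "b1", "c1"])
        dups = detect_duplications(gt, self.ACC)
        assert len(dups) == 1
        assert dups[0].kind == "simple"
        assert dups[0].leaf_names == frozenset({"a1", "a2"})

    def test_spread_duplication_is_complex(self):
        gt = _tree_from_newick("((a1:1,b1:1):1,(a2:1,c1:1):1);",
                               ["a1", "a2", "b1", "c1"])
        dups = detect_duplications(gt, self.ACC)
        assert dups and all(d.kind == "complex" for d in dups)

    def test_all_distinct_accessions_no_duplications(self):
        gt = _tree_from_newick("((a1:1,b1:1):1,c1:2);", ["a1", "b1", "c1"])
        acc = {"a1": "A", "b1": "B", "c1": "C"}
        assert detect_duplications(gt, acc) == []


class TestRefineOG:
    def _setup(self, n_acc, dup_accs):
        """OG over n_acc accessions; accessions in dup_accs carry 2 copies
        placed as sister leaves."""
        members = []
        acc = {}
        for i in range(n_acc):
            a = f"A{i:02d}"
            members.append(f"{a}x")
            acc[f"{a}x"] = a
            if i in dup_accs:
                members.append(f"{a}y")
                acc[f"{a}y"] = a
        # caterpillar newick with duplicated copies as cherries
        tips = []
        for i in range(n_acc):
            a = f"A{i:02d}"
            if i in dup_accs:
                tips.append(f"({a}x:0.01,{a}y:0.05):0.1")
            else:
                tips.append(f"{a}x:0.1")
        # balanced topology via iterative pairing
        nodes = tips[:]
        while len(nodes) > 1:
            nodes = [f"({nodes[i]},{nodes[i+1]}):0.1"
                     if i + 1 < len(nodes) else nodes[i]
                     for i in range(0, len(nodes), 2)]
        gt = _tree_from_newick(nodes[0] + ";", members)
        og = Orthogroup("OGx", sorted(members))
        dups = detect_duplications(gt, acc)
        return og, gt, dups, acc

    def test_one_duplicated_of_forty_is_pruned(self):
        og, gt, dups, acc = self._setup(40, {3})
        out, status = refine_og(og, gt, dups, acc)
        assert len(out) == 1
        assert len(out[0].members) == 40
        pruned = [g for g, s in status.items() if s == "pruned_paralog"]
        assert len(pruned) == 1 and acc[pruned[0]] == "A03"
        # survivor is the copy with the shorter root-to-leaf path
        assert "A03x" in out[0].members

    def test_five_duplicated_of_forty_triggers_split(self):
        og, gt, dups, acc = self._setup(40, {1, 5, 9, 13, 17})
        out, status = refine_og(og, gt, dups, acc)
        # split, not pruned: the duplicated cherries are cut off the tree
        assert not any(s == "pruned_paralog" for s in status.values())
        assert any(s.startswith("split_to:") for s in status.values())
        # after splitting no OG carries two copies from one accession
        for o in out:
            accs = [acc[g] for g in o.members]
            assert len(accs) == len(set(accs))
        # no member appears in two OGs; none lost silently
        all_members = [g for o in out for g in o.members]
        singles = [g for g, s in status.items() if s == "singleton"]
        assert sorted(all_members + singles) == og.members

    def test_root_duplication_splits_into_two_ogs(self):
        # every accession has two copies, x and y, in two clean clades:
        # the root is a complex duplication and splitting yields two OGs
        n = 8
        acc = {}
        for i in range(n):
            a = f"A{i:02d}"
            acc[f"{a}x"] = a
            acc[f"{a}y"] = a

        def clade(suffix):
            nodes = [f"A{i:02d}{suffix}:0.1" for i in range(n)]
            while len(nodes) > 1:
                nodes = [f"({nodes[i]},{nodes[i+1]}):0.1"
                         if i + 1 < len(nodes) else nodes[i]
                         for i in range(0, len(nodes), 2)]
            return nodes[0]

        gt = _tree_from_newick(f"({clade('x')}:0.5,{clade('y')}:0.5);",
                               sorted(acc))
        og = Orthogroup("OGx", sorted(acc))
        dups = detect_duplications(gt, acc)
        assert any(d.kind == "complex" for d in dups)
        out, status = refine_og(og, gt, dups, acc)
        assert len(out) == 2
        groups = sorted(sorted(o.members) for o in out)
        assert groups == [sorted(g for g in acc if g.endswith("x")),
                          sorted(g for g in acc if g.endswith("y"))]

    def test_no_duplications_unchanged(self):
        og, gt, dups, acc = self._setup(10, set())
        out, status = refine_og(og, gt, dups, acc)
        assert out == [og]
        assert set(status.values()) == {"kept"}


class TestClassifyOGType:
    @pytest.mark.parametrize("size,expected", [
        (2, "cloud"), (12, "cloud"), (13, "shell"), (30, "shell"),
        (51, "shell"), (52, "core"), (200, "core")])
    def test_boundaries(self, size, expected):
        assert classify_og_type(size) == expected

    def test_partition_over_sizes(self):
        counts = {"cloud": 0, "shell": 0, "core": 0}
        for size in range(2, 120):
            counts[classify_og_type(size)] += 1
        assert sum(counts.values()) == 118


def _gene(gid, contig, start, end, strand="+", acc="A"):
    return GeneModel(gene_id=gid, accession=acc, contig=contig,
                     start=start, end=end, strand=strand)


class TestPhysicalClusters:
    def test_within_window_clustered(self):
        genes = [_gene("a", "c1", 1000, 2000), _gene("b", "c1", 150000, 151000)]
        flag, clusters = detect_physical_clusters(genes)
        assert flag == {"a": True, "b": True}
        assert clusters == [{"a", "b"}]

    def test_beyond_window_unclustered(self):
        genes = [_gene("a", "c1", 1000, 2000), _gene("b", "c1", 250000, 251000)]
        flag, clusters = detect_physical_clusters(genes)
        assert not any(flag.values()) and clusters == []

    def test_single_linkage_chains_transitively(self):
        genes = [_gene("a", "c1", 1, 500), _gene("b", "c1", 150001, 150500),
                 _gene("c", "c1", 300001, 300500)]
        _, clusters = detect_physical_clusters(genes)
        assert clusters == [{"a", "b", "c"}]


class TestDetectPairs:
    def test_divergent_adjacent_paired(self):
        genes = [_gene("a", "c1", 1000, 3000, "-"),
                 _gene("b", "c1", 3500, 6000, "+")]
        assert detect_pairs(genes) == [("a", "b")]

    def test_convergent_not_paired(self):
        genes = [_gene("a", "c1", 1000, 3000, "+"),
                 _gene("b", "c1", 3500, 6000, "-")]
        assert detect_pairs(genes) == []

    def test_separation_beyond_limit_not_paired(self):
        genes = [_gene("a", "c1", 1000, 3000, "-"),
                 _gene("b", "c1", 53001, 56000, "+")]
        assert detect_pairs(genes) == []


class TestAnnotateOG:
    def test_majority_class_vote(self):
        og = Orthogroup("OG1", [f"g{i}" for i in range(12)])
        classes = {f"g{i}": ("TNL" if i < 10 else "NL") for i in range(12)}
        out = annotate_og(og, classes, {}, {}, {})
        assert out.class_label == "TNL"

    def test_any_member_with_id_sets_flag(self):
        og = Orthogroup("OG1", [f"g{i}" for i in range(20)])
        has_id = {f"g{i}": i == 7 for i in range(20)}
        out = annotate_og(og, {g: "NL" for g in og.members}, {}, {}, has_id)
        assert out.id_flag

    def test_star_tree_zero_mean_branch_length(self):
        og = Orthogroup("OG1", ["a", "b", "c"])
        gt = _tree_from_newick("(a:0,b:0,c:0);", ["a", "b", "c"])
        out = annotate_og(og, {g: "NL" for g in og.members}, {}, {}, {},
                          gene_tree=gt)
        assert out.mean_branch_length == 0.0
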