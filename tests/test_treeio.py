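"""Tree parsing, pruning, posterior-sample reading and clade location."""

import numpy as np
import pytest

from conftest import random_tree
from mkasr import treeio
from mkasr.treeio import (
    CladeDefinition,
    TreeError,
    clade_nodes,
    parse_newick,
    read_tree_sample,
    relabel_and_prune,
    write_newick,
)

NEXUS_FIXTURE = """#NEXUS
BEGIN TAXA;
  DIMENSIONS NTAX=2;
  TAXLABELS A B;
END;
BEGIN TREES;
  TRANSLATE
    1 A,
    2 B;
  TREE t1 = (1:1.0,2:2.0);
  TREE t2 = (1:1.5,2:2.5);
END;
"""


class TestParse:
    def test_two_tips_with_lengths(self):
        t = parse_newick("(A:1,B:2);")
        assert t.n_tips == 2 and t.n_nodes == 3
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.blen[t.tip_index("A")] == 1.0
        assert t.blen[t.tip_index("B")] == 2.0

    def test_polytomy_preserved(self):
        t = parse_newick("(A:1,B:1,C:1);")
        assert len(t.children[0]) == 3

    def test_missing_lengths_default_zero(self):
        t = parse_newick("(A,B);")
        assert t.blen[t.tip_index("A")] == 0.0

    def test_malformed_raises(self):
        with pytest.raises(TreeError, match="malformed"):
            parse_newick("((A:1,B:2;")

    def test_duplicate_tip_labels_raise(self):
        with pytest.raises(TreeError):
            parse_newick("(A:1,A:2);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeError, match="negative"):
            parse_newick("(A:1,B:-2);")

    def test_roundtrip_identity_random_trees(self, rng):
        # writing quantises branch lengths to 10 significant digits; after
        # one write/parse cycle the representation is an exact fixed point
        for _ in range(100):
            t = parse_newick(write_newick(random_tree(rng, int(rng.integers(3, 15)))))
            assert parse_newick(write_newick(t)) == t


class TestTreeSample:
    def _write_sample(self, path, n, n_tips=4):
        rng = np.random.default_rng(7)
        trees = [random_tree(rng, n_tips) for _ in range(1)]
        # same topology repeated: shared tip universe guaranteed
        with open(path, "w") as fh:
            for _ in range(n):
                fh.write(trees[0].to_newick() + "\n")

    def test_burnin_removes_first_quarter(self, tmp_path):
        p = tmp_path / "trees.nwk"
        self._write_sample(p, 400)
        sample = read_tree_sample(p, burnin=0.25)
        assert len(sample) == 300
        assert sample.provenance["burnin"] == 0.25

    def test_zero_burnin_keeps_all(self, tmp_path):
        p = tmp_path / "trees.nwk"
        self._write_sample(p, 10)
        assert len(read_tree_sample(p, burnin=0.0)) == 10

    def test_nexus_translate_table(self, tmp_path):
        p = tmp_path / "trees.nex"
        p.write_text(NEXUS_FIXTURE)
        sample = read_tree_sample(p, schema="nexus")
        assert len(sample) == 2
        assert sorted(sample[0].tip_labels) == ["A", "B"]
        assert sample[0].blen[sample[0].tip_index("B")] == 2.0

    def test_inconsistent_tip_sets_error_names_difference(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("(A:1,B:1);\n(A:1,C:1);\n")
        with pytest.raises(TreeError, match="symmetric difference.*'B'.*'C'"):
            read_tree_sample(p)

    def test_burnin_applied_per_file(self, tmp_path):
        p1, p2 = tmp_path / "run1.nwk", tmp_path / "run2.nwk"
        self._write_sample(p1, 8)
        self._write_sample(p2, 8)
        sample = read_tree_sample([p1, p2], burnin=0.25)
        assert len(sample) == 12  # 6 per run


class TestRelabelPrune:
    def test_keep_all_is_identity_up_to_ids(self, rng):
        t = random_tree(rng, 8)
        p = relabel_and_prune(t, keep=set(t.tip_labels))
        assert sorted(p.tip_labels) == sorted(t.tip_labels)
        for a, b in [("t001", "t002"), ("t003", "t008")]:
            assert p.patristic_distance(a, b) == pytest.approx(
                t.patristic_distance(a, b)
            )

    def test_suppressed_path_lengths_sum(self):
        t = parse_newick("((A:1,B:1):2,C:3);")
        p = relabel_and_prune(t, keep={"A", "C"})
        assert p.n_tips == 2 and p.n_nodes == 3
        assert p.blen[p.tip_index("A")] == 3.0
        assert p.blen[p.tip_index("C")] == 3.0

    def test_patristic_distances_preserved_random(self, rng):
        for _ in range(50):
            t = random_tree(rng, int(rng.integers(5, 12)))
            labs = list(t.tip_labels)
            keep = list(rng.choice(labs, size=int(rng.integers(2, len(labs))), replace=False))
            p = relabel_and_prune(t, keep=set(keep))
            for i in range(len(keep)):
                for j in range(i + 1, len(keep)):
                    assert p.patristic_distance(keep[i], keep[j]) == pytest.approx(
                        t.patristic_distance(keep[i], keep[j]), abs=1e-9
                    )

    def test_patristic_against_dendropy(self, rng):
        import dendropy

        t = random_tree(rng, 10)
        dt = dendropy.Tree.get(data=t.to_newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in dt.taxon_namespace}
        for a, b in [("t001", "t005"), ("t002", "t009"), ("t003", "t010")]:
            assert t.patristic_distance(a, b) == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9
            )

    def test_relabel_mapping_applies_and_collides(self):
        t = parse_newick("((A:1,B:1):2,C:3);")
        p = relabel_and_prune(t, keep={"X", "C"}, mapping={"A": "X"})
        assert "X" in p.tip_labels
        with pytest.raises(TreeError, match="collides"):
            relabel_and_prune(t, keep={"B", "C"}, mapping={"A": "B"})

    def test_too_few_kept_raises(self):
        t = parse_newick("((A:1,B:1):2,C:3);")
        with pytest.raises(TreeError, match="2 tips"):
            relabel_and_prune(t, keep={"A"})


class TestCladeNodes:
    def test_whole_tree_clade_is_root(self, balanced_tree):
        cn = clade_nodes(balanced_tree, CladeDefinition("all", frozenset("ABCD")))
        assert cn.crown == 0 and cn.stem is None and cn.monophyletic

    def test_cherry_clade(self, balanced_tree):
        cn = clade_nodes(balanced_tree, CladeDefinition("ab", frozenset("AB")))
        assert cn.stem == 0
        assert cn.monophyletic
        assert balanced_tree.subtree_tips(cn.crown) == {"A", "B"}

    def test_non_monophyletic_group(self):
        t = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        cn = clade_nodes(t, CladeDefinition("ab", frozenset("AB")))
        assert cn.crown == 0 and not cn.monophyletic

    def test_absent_clade_raises(self, balanced_tree):
        with pytest.raises(TreeError, match="ghost"):
            clade_nodes(balanced_tree, CladeDefinition("ghost", frozenset({"Z"})))

    def test_single_member_degenerate(self, balanced_tree):
        cn = clade_nodes(balanced_tree, CladeDefinition("a", frozenset({"A"})))
        assert cn.degenerate and cn.n_members_present == 1

    def test_monophyly_matches_subtree_enumeration(self, rng):
        for _ in range(30):
            t = random_tree(rng, int(rng.integers(4, 12)))
            labs = list(t.tip_labels)
            members = set(
                rng.choice(labs, size=int(rng.integers(2, len(labs))), replace=False)
            )
            cn = clade_nodes(t, CladeDefinition("x", frozenset(members)))
            subtree_sets = {frozenset(t.subtree_tips(v)) for v in range(t.n_nodes)}
            assert cn.monophyletic == (frozenset(members) in subtree_sets)


def test_sample_write_read_idempotent(tmp_path, rng):
    trees = [random_tree(rng, 6) for _ in range(5)]
    # shared tip universe: relabel all to the first tree's labels by size
    sample = treeio.TreeSample([trees[0]] * 3 + [trees[0]])
    p = tmp_path / "s.nwk"
    treeio.write_tree_sample(sample, p)
    again = read_tree_sample(p)
    assert [t.to_newick() for t in again] == [t.to_newick() for t in sample]
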