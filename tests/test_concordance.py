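"""Gene-tree/species-tree concordance: split extraction, per-node
classification, and agreement with a brute-force graph oracle."""

import numpy as np
import pytest

from _oracles import oracle_classify, oracle_splits, random_binary_newick
from hybcap.concordance import (
    Bipartition,
    TreeFileError,
    classify_gene_tree,
    informative_bipartitions,
    node_concordance,
    pie_fractions,
    read_trees,
)


def bip(side, taxa):
    return Bipartition.of(set(side), set(taxa))


class TestReadTrees:
    def test_four_leaf_tree(self):
        (t,) = read_trees("((A,B),(C,D));")
        assert len(t.leaf_nodes()) == 4

    def test_multi_tree_file(self, tmp_path):
        p = tmp_path / "genetrees.nwk"
        p.write_text("\n".join("((A,B),(C,D));" for _ in range(10)) + "\n")
        assert len(read_trees(p)) == 10

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(TreeFileError, match="duplicate"):
            read_trees("((A,A),(C,D));")

    def test_parse_error_has_tree_number(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A,B),(C,D));\n((A,B,;\n")
        with pytest.raises(TreeFileError, match="tree 2"):
            read_trees(p)


class TestBipartitions:
    def test_single_internal_edge(self):
        (t,) = read_trees("((A,B),(C,D));")
        assert informative_bipartitions(t) == {bip({"A", "B"}, "ABCD")}

    def test_caterpillar_five_taxa(self):
        (t,) = read_trees("((((A,B),C),D),E);")
        assert informative_bipartitions(t) == {
            bip({"A", "B"}, "ABCDE"),
            bip({"A", "B", "C"}, "ABCDE"),
        }

    def test_star_polytomy_empty(self):
        (t,) = read_trees("(A,B,C,D);")
        assert informative_bipartitions(t) == set()

    def test_canonical_side_contains_smallest_taxon(self):
        b = bip({"C", "D"}, "ABCD")
        assert b.side_a == ("A", "B")

    def test_conflict_rule(self):
        taxa = "ABCD"
        assert bip({"A", "B"}, taxa).conflicts_with(bip({"A", "C"}, taxa))
        assert not bip({"A", "B"}, taxa).conflicts_with(bip({"A", "B"}, taxa))


class TestClassify:
    def test_identical_tree_concordant_everywhere(self):
        (sp,) = read_trees("((((A,B),C),D),E);")
        (gt,) = read_trees("((((A,B),C),D),E);")
        for b in informative_bipartitions(sp):
            assert classify_gene_tree(b, gt) == ("concordant", None)

    def test_four_taxon_conflict_reports_observed_split(self):
        (gt,) = read_trees("((A,C),(B,D));")
        status, obs = classify_gene_tree(bip({"A", "B"}, "ABCD"), gt)
        assert status == "conflict"
        assert obs == bip({"A", "C"}, "ABCD")

    def test_missing_taxon_uninformative(self):
        (gt,) = read_trees("((A,C),D);")  # taxon B absent
        status, _ = classify_gene_tree(bip({"A", "B"}, "ABCD"), gt)
        assert status == "uninformative"

    def test_polytomy_uninformative(self):
        (gt,) = read_trees("(A,B,C,D);")
        status, _ = classify_gene_tree(bip({"A", "B"}, "ABCD"), gt)
        assert status == "uninformative"

    def test_rooting_invariance(self):
        """Re-rooting a gene tree never changes its classification."""
        (sp,) = read_trees("(((A,B),(C,D)),(E,F));")
        newick = "(((A,C),(B,D)),(E,F));"
        (base,) = read_trees(newick)
        expected = {
            b: classify_gene_tree(b, base) for b in informative_bipartitions(sp)
        }
        (gt,) = read_trees(newick)
        for leaf in list(gt.leaf_node_iter()):
            (rerooted,) = read_trees(newick)
            node = [
                l
                for l in rerooted.leaf_node_iter()
                if l.taxon.label == leaf.taxon.label
            ][0]
            rerooted.reroot_at_edge(node.edge, update_bipartitions=False)
            for b, exp in expected.items():
                assert classify_gene_tree(b, rerooted) == exp


class TestNodeConcordance:
    def test_all_identical_gene_trees(self):
        (sp,) = read_trees("((((A,B),C),D),E);")
        gts = read_trees("\n".join("((((A,B),C),D),E);" for _ in range(10)))
        for rec in node_concordance(sp, gts):
            assert (
                rec.n_concordant,
                rec.n_top_alternative,
                rec.n_other_conflict,
                rec.n_uninformative,
            ) == (10, 0, 0, 0)

    def test_exhaustive_four_taxon_tally(self):
        (sp,) = read_trees("((A,B),(C,D));")
        gts = read_trees(
            "\n".join(
                ["((A,B),(C,D));"] * 6 + ["((A,C),(B,D));"] * 3 + ["((A,D),(B,C));"]
            )
        )
        (rec,) = node_concordance(sp, gts)
        assert (
            rec.n_concordant,
            rec.n_top_alternative,
            rec.n_other_conflict,
            rec.n_uninformative,
        ) == (6, 3, 1, 0)
        assert rec.top_alternative == bip({"A", "C"}, "ABCD")

    def test_star_gene_trees_all_uninformative(self):
        (sp,) = read_trees("((A,B),(C,D));")
        gts = read_trees("\n".join("(A,B,C,D);" for _ in range(10)))
        (rec,) = node_concordance(sp, gts)
        assert rec.n_uninformative == 10 and rec.total == 10

    def test_counts_sum_to_n_gene_trees(self, rng):
        taxa = list("ABCDEF")
        sp = read_trees(random_binary_newick(rng, taxa))[0]
        newicks = []
        for _ in range(30):
            sub = [t for t in taxa if rng.random() > 0.3]
            if len(sub) < 2:
                sub = taxa[:2]
            newicks.append(random_binary_newick(rng, sub))
        gts = read_trees("\n".join(newicks))
        for rec in node_concordance(sp, gts):
            assert rec.total == 30

    def test_label_permutation_invariance(self, rng):
        taxa = list("ABCDEF")
        perm = dict(zip(taxa, ["W", "X", "Y", "Z", "U", "V"]))

        def rename(newick):
            return "".join(perm.get(c, c) for c in newick)

        sp_n = random_binary_newick(rng, taxa)
        gt_ns = [random_binary_newick(rng, taxa) for _ in range(12)]
        recs = node_concordance(read_trees(sp_n)[0], read_trees("\n".join(gt_ns)))
        recs_p = node_concordance(
            read_trees(rename(sp_n))[0],
            read_trees("\n".join(rename(n) for n in gt_ns)),
        )

        def key(b, mapper=None):
            sides = (b.side_a, b.side_b)
            if mapper:
                sides = tuple(tuple(mapper[t] for t in s) for s in sides)
            return frozenset(frozenset(s) for s in sides)

        by_split = {key(r.species_bipartition, perm): r for r in recs}
        assert len(by_split) == len(recs_p)
        for rp in recs_p:
            r = by_split[key(rp.species_bipartition)]
            assert (
                r.n_concordant,
                r.n_top_alternative,
                r.n_other_conflict,
                r.n_uninformative,
            ) == (
                rp.n_concordant,
                rp.n_top_alternative,
                rp.n_other_conflict,
                rp.n_uninformative,
            )


class TestOracleAgreement:
    def test_splits_match_graph_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 7))
            taxa = [chr(65 + i) for i in range(n)]
            newick = random_binary_newick(rng, taxa)
            (t,) = read_trees(newick)
            impl = {
                frozenset({frozenset(b.side_a), frozenset(b.side_b)})
                for b in informative_bipartitions(t)
            }
            assert impl == oracle_splits(newick)

    def test_classification_matches_graph_oracle(self, rng):
        """Brute-force split-compatibility oracle over random species and
        gene trees on up to 6 taxa, including missing taxa."""
        checked = 0
        while checked < 120:
            n = int(rng.integers(4, 7))
            taxa = [chr(65 + i) for i in range(n)]
            sp_newick = random_binary_newick(rng, taxa)
            sub = [t for t in taxa if rng.random() > 0.25]
            if len(sub) < 3:
                continue
            gt_newick = random_binary_newick(rng, sub)
            (sp,) = read_trees(sp_newick)
            (gt,) = read_trees(gt_newick)
            for b in informative_bipartitions(sp):
                status, obs = classify_gene_tree(b, gt)
                o_status, o_obs = oracle_classify(
                    frozenset({frozenset(b.side_a), frozenset(b.side_b)}), gt_newick
                )
                assert status == o_status, (sp_newick, gt_newick, str(b))
                if status == "conflict":
                    assert (
                        frozenset({frozenset(obs.side_a), frozenset(obs.side_b)})
                        == o_obs
                    )
                checked += 1


class TestFractions:
    def test_division(self):
        from hybcap.concordance import ConcordanceRecord

        rec = ConcordanceRecord("n", bip({"A", "B"}, "ABCD"), 6, 3, 1, 0)
        assert pie_fractions(rec) == (0.6, 0.3, 0.1, 0.0)

    def test_all_concordant(self):
        from hybcap.concordance import ConcordanceRecord

        rec = ConcordanceRecord("n", bip({"A", "B"}, "ABCD"), 10, 0, 0, 0)
        assert pie_fractions(rec) == (1.0, 0.0, 0.0, 0.0)

    def test_empty_total_rejected(self):
        from hybcap.concordance import ConcordanceRecord

        rec = ConcordanceRecord("n", bip({"A", "B"}, "ABCD"), 0, 0, 0, 0)
        with pytest.raises(ValueError):
            pie_fractions(rec)
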