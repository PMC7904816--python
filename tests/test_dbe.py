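"""Dependency-based extraction: chunking, distance, prep/LCA/inherit rules."""

import numpy as np

from conftest import random_dep_tree
from mdrel import dbe
from mdrel.dbe import (chunk, enumerate_dep_pairs, filter_pairs, inherit, lca,
                       lca_relation, prep_relation, tree_distance)
from mdrel.ner import MICROBE, DISEASE, EntityMention
from mdrel.trees import DependencyTree


def _mentions(tokens):
    out = []
    for i, t in enumerate(tokens):
        if t.startswith("BAC00"):
            out.append(EntityMention(MICROBE, (i, i + 1), t[5:], t))
        elif t.startswith("DIS00"):
            out.append(EntityMention(DISEASE, (i, i + 1), t[5:], t))
    return out


class TestChunk:
    def test_common_cause_merge(self, streptococcus):
        ct = chunk(streptococcus.dtree, streptococcus.sentence.mentions)
        words = [n.word for n in ct.nodes]
        assert "common_cause" in words
        node = words.index("common_cause")
        # the merged node governs the disease entity
        children = [ct.nodes[c].word for c, _ in ct.children(node)]
        assert "DIS00sepsis" in children

    def test_no_merge_without_of_with_or_compound(self, vulnificus):
        before = len(vulnificus.dtree.tokens)
        # 'wound'-'infection' compound edge DOES merge (entity + parent)
        ct = chunk(vulnificus.dtree, vulnificus.sentence.mentions)
        merged = [n for n in ct.nodes if len(n.indices) > 1]
        assert len(merged) == 1
        assert merged[0].combined_word == "wound"
        assert sum(len(n.indices) for n in ct.nodes) == before

    def test_tree_with_no_patterns_is_unchanged(self):
        tokens = ["BAC00a", "harms", "DIS00b"]
        dt = DependencyTree(tokens, [1, -1, 1], ["nsubj", "root", "obj"])
        ct = chunk(dt, _mentions(tokens))
        assert all(len(n.indices) == 1 for n in ct.nodes)
        assert ct.heads == [1, -1, 1]

    def test_nested_merges_stay_single_headed_and_acyclic(self):
        # "resistant strain of BAC00x" + "DIS00y flare of ..." style nesting
        tokens = ["resistant", "strain", "of", "BAC00x", "worsens", "DIS00y"]
        heads = [1, 4, 3, 1, -1, 4]
        labels = ["amod", "nsubj", "case", "nmod:of", "root", "obj"]
        dt = DependencyTree(tokens, heads, labels)
        ct = chunk(dt, _mentions(tokens))
        # partition preserved
        covered = sorted(i for n in ct.nodes for i in n.indices)
        assert covered == list(range(len(tokens)))
        roots = [i for i, h in enumerate(ct.heads) if h == -1]
        assert len(roots) == 1
        for i in range(len(ct.nodes)):  # acyclic: every node reaches root
            seen, j = set(), i
            while ct.heads[j] != -1:
                assert j not in seen
                seen.add(j)
                j = ct.heads[j]
        assert "resistant_strain" in [n.word for n in ct.nodes]


class TestTreeDistance:
    def _pair_and_tree(self, tokens, heads, labels):
        dt = DependencyTree(tokens, heads, labels)
        ms = _mentions(tokens)
        ct = chunk(dt, ms)
        (pair,) = enumerate_dep_pairs("t", ct, ms)
        return pair, ct

    def test_plain_path_counts_all_edges(self):
        pair, ct = self._pair_and_tree(
            ["BAC00a", "b", "c", "DIS00d"],
            [1, 2, -1, 2],
            ["nsubj", "dep", "root", "obj"])
        assert tree_distance(pair, ct) == 3

    def test_free_edges_not_counted(self):
        # 2 plain + 3 conj:and edges -> distance 2
        pair, ct = self._pair_and_tree(
            ["BAC00a", "v", "x", "y", "z", "DIS00d"],
            [1, -1, 1, 2, 3, 4],
            ["nsubj", "root", "obj", "conj:and", "conj:and", "conj:and"])
        assert tree_distance(pair, ct) == 2

    def test_symmetric_and_zero_on_self(self):
        rng = np.random.Generator(np.random.PCG64(3))
        tree = random_dep_tree(rng, 9, ["dep", "conj", "obj"])
        ms = [EntityMention(MICROBE, (2, 3), "a", "BAC00a"),
              EntityMention(DISEASE, (7, 8), "b", "DIS00b")]
        ct = chunk(tree, ms)
        (pair,) = enumerate_dep_pairs("t", ct, ms)
        back = dbe.DepPair("t", pair.microbe, pair.disease,
                           pair.disease_node, pair.microbe_node)
        assert tree_distance(pair, ct) == tree_distance(back, ct)
        same = dbe.DepPair("t", pair.microbe, pair.disease,
                           pair.microbe_node, pair.microbe_node)
        assert tree_distance(same, ct) == 0

    def test_filter_keeps_boundary_distance(self, stenotrophomonas):
        ct = chunk(stenotrophomonas.dtree, stenotrophomonas.sentence.mentions)
        pairs = enumerate_dep_pairs("fig4", ct,
                                    stenotrophomonas.sentence.mentions)
        assert tree_distance(pairs[0], ct) == 4
        assert filter_pairs(pairs, ct, max_distance=4) == pairs
        assert filter_pairs(pairs, ct, max_distance=3) == []


class TestPrepRule:
    def _run(self, tokens, heads, labels):
        dt = DependencyTree(tokens, heads, labels)
        ms = _mentions(tokens)
        ct = chunk(dt, ms)
        (pair,) = enumerate_dep_pairs("t", ct, ms)
        return prep_relation(pair, ct)

    def test_due_to_connector(self):
        t = self._run(["DIS00d", "due", "to", "BAC00m"],
                      [-1, 3, 1, 0],
                      ["root", "case", "fixed", "nmod:due_to"])
        assert t is not None and t.relation == "due_to"
        assert t.pattern_ids == ("PREP_SIMPLE",)

    def test_between_connector(self):
        t = self._run(["BAC00m", "link", "DIS00d"],
                      [-1, 0, 0],
                      ["root", "dep", "nmod:between"])
        assert t is not None and t.relation == "between"

    def test_verb_link_is_not_a_connector(self):
        t = self._run(["BAC00m", "causes", "DIS00d"],
                      [1, -1, 1],
                      ["nsubj", "root", "obj"])
        assert t is None

    def test_induced_modifier(self):
        t = self._run(["BAC00m", "induced", "DIS00d"],
                      [2, 2, -1],
                      ["nsubj", "amod", "root"])
        assert t is not None and t.relation == "induced"


class TestLcaRule:
    def test_stenotrophomonas_implicated(self, stenotrophomonas):
        ct = chunk(stenotrophomonas.dtree, stenotrophomonas.sentence.mentions)
        (pair,) = enumerate_dep_pairs("fig4", ct,
                                      stenotrophomonas.sentence.mentions)
        t = lca_relation(pair, ct)
        assert t.relation == "implicated"
        assert t.pattern_ids == ("LCA_CHILD",)

    def test_fallback_to_lca_word(self):
        tokens = ["BAC00m", "causes", "DIS00d"]
        dt = DependencyTree(tokens, [1, -1, 1], ["nsubj", "root", "obj"])
        ms = _mentions(tokens)
        ct = chunk(dt, ms)
        (pair,) = enumerate_dep_pairs("t", ct, ms)
        assert lca_relation(pair, ct).relation == "causes"

    def test_child_priority_follows_edge_list_order(self):
        # acl outranks amod even when the amod child comes first in the
        # sentence (the Stenotrophomonas configuration, minimised)
        tokens = ["BAC00m", "emerging", "pathogen", "implicated", "DIS00d"]
        dt = DependencyTree(tokens, [2, 2, -1, 2, 3],
                            ["nsubj", "amod", "root", "acl", "obj"])
        ms = _mentions(tokens)
        ct = chunk(dt, ms)
        (pair,) = enumerate_dep_pairs("t", ct, ms)
        assert lca_relation(pair, ct).relation == "implicated"
        # with equal-priority labels the leftmost child wins
        dt2 = DependencyTree(tokens, [2, 2, -1, 2, 3],
                             ["nsubj", "acl", "root", "acl", "obj"])
        ct2 = chunk(dt2, ms)
        (pair2,) = enumerate_dep_pairs("t", ct2, ms)
        assert lca_relation(pair2, ct2).relation == "emerging"

    def test_entity_as_lca_emits_edge_label(self, fig3):
        ct = chunk(fig3.dtree, fig3.sentence.mentions)
        pairs = enumerate_dep_pairs("fig3", ct, fig3.sentence.mentions)
        pair = next(p for p in pairs if p.disease.canonical == "sepsis")
        t = lca_relation(pair, ct)
        assert t.pattern_ids == ("LCA_SELF_EDGE",)
        assert t.relation == "appos"

    def test_lca_matches_brute_force_ancestor_oracle(self):
        rng = np.random.Generator(np.random.PCG64(77))
        for _ in range(300):
            n = int(rng.integers(3, 13))
            tree = random_dep_tree(rng, n, ["dep", "obj", "conj:and"])
            a, b = (int(x) for x in rng.choice(n, size=2, replace=False))
            ms = [EntityMention(MICROBE, (a, a + 1), f"w{a}", f"w{a}"),
                  EntityMention(DISEASE, (b, b + 1), f"w{b}", f"w{b}")]
            ct = chunk(tree, ms)
            na, nb = ct.node_of_token[a], ct.node_of_token[b]
            # oracle: deepest node among the intersection of ancestor sets
            anc_a = {na}
            j = na
            while ct.heads[j] != -1:
                j = ct.heads[j]
                anc_a.add(j)
            anc_b = {nb}
            j = nb
            while ct.heads[j] != -1:
                j = ct.heads[j]
                anc_b.add(j)
            common = anc_a & anc_b

            def depth(x):
                d, j = 0, x
                while ct.heads[j] != -1:
                    j = ct.heads[j]
                    d += 1
                return d

            expected = max(common, key=depth)
            assert lca(ct, na, nb) == expected


class TestInherit:
    def test_streptococcus_both_diseases_get_common_cause(self, streptococcus):
        triplets = dbe.extract_triplets(streptococcus)
        got = {(t.microbe, t.disease, t.relation) for t in triplets}
        assert ("Streptococcus_pneumoniae", "sepsis", "common_cause") in got
        assert ("Streptococcus_pneumoniae", "meningitis", "common_cause") in got

    def test_no_same_class_chain_no_additions(self, stenotrophomonas):
        ct = chunk(stenotrophomonas.dtree, stenotrophomonas.sentence.mentions)
        pairs = enumerate_dep_pairs("fig4", ct,
                                    stenotrophomonas.sentence.mentions)
        base = [lca_relation(p, ct) for p in pairs]
        assert inherit(pairs, ct, base) == []

    def test_chain_of_three_coordinated_diseases_all_inherit(self):
        tokens = ["BAC00m", "is", "cause", "of", "DIS00a", "DIS00b", "DIS00c"]
        heads = [2, 2, -1, 4, 2, 4, 5]
        labels = ["nsubj", "cop", "root", "case", "nmod:of", "conj:and",
                  "conj:and"]
        dt = DependencyTree(tokens, heads, labels)
        ms = _mentions(tokens)
        ct = chunk(dt, ms)
        pairs = enumerate_dep_pairs("t", ct, ms)
        base = [lca_relation(pairs[0], ct)]
        added = inherit(pairs, ct, base)
        diseases = {t.disease for t in added}
        assert diseases == {"b", "c"}
        assert all(t.relation == base[0].relation for t in added)

    def test_disabling_inherit_preserves_other_triplets(self, streptococcus):
        with_inherit = dbe.extract_triplets(streptococcus, enable_inherit=True)
        without = dbe.extract_triplets(streptococcus, enable_inherit=False)
        # disabling inheritance removes exactly the pure-INHERIT triplets
        assert {t.key for t in without} == {
            t.key for t in with_inherit
            if any(p != "INHERIT" for p in t.pattern_ids)}
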