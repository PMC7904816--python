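"""TPE engine: grammar parsing, wildcard semantics, oracle equivalence."""

import re
from itertools import combinations, product

import numpy as np
import pytest

from mdrel.stem import stem
from mdrel.tpe import (Gap, InternalMatcher, LeafMatcher, Wildcard,
                       builtin_patterns, extract_triplets, match, parse_tpe)
from mdrel.trees import ConstituencyTree, CTreeNode, parse_bracketed


class TestParseTpe:
    def test_simple_pattern(self):
        p = parse_tpe("{NP <NN 1#BAC00.+>}")
        assert p.captures == {1}
        assert isinstance(p.root.items[0], LeafMatcher)

    def test_duplicate_capture_rejected(self):
        with pytest.raises(ValueError, match="duplicate capture"):
            parse_tpe("{NP <NN 1#BAC00.+> <NN 1#.+>}")

    def test_unbalanced_braces_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_tpe("{NP <NN x>")
        with pytest.raises(ValueError, match="unbalanced"):
            parse_tpe("{NP <NN x}")

    def test_invalid_regex_named(self):
        with pytest.raises(ValueError, match="invalid regex"):
            parse_tpe("{NP <NN [>}")

    def test_builtin_patterns_parse_with_all_captures(self):
        pats = builtin_patterns()
        assert len(pats) == 2
        for p in pats:
            assert p.captures == {1, 2, 3}


class TestWildcardSemantics:
    def test_star_requires_exactly_one_child(self):
        tree1 = parse_bracketed("(S (NP (NN a)))")
        tree2 = parse_bracketed("(S (NP (NN a)) (VP (VBZ b)))")
        one = parse_tpe("{S *}")
        any_ = parse_tpe("{S **}")
        assert len(match(tree1, one)) == 1
        assert len(match(tree2, one)) == 0
        assert len(match(tree1, any_)) == 1
        assert len(match(tree2, any_)) == 1

    def test_word_regex_without_matching_leaves(self):
        tree = parse_bracketed("(S (NP (NN dog)) (VP (VBZ runs)))")
        p = parse_tpe("{S ** {NP ** <N.+ 1#BAC00.+> **} **}")
        assert match(tree, p) == []


# ---------------------------------------------------------------------------
# brute-force embedding oracle: global enumeration of child alignments,
# written independently of the engine's left-to-right backtracking


def _oracle_node(matcher, node):
    if isinstance(matcher, Wildcard):
        return [frozenset()]
    if isinstance(matcher, LeafMatcher):
        if node.word is None:
            return []
        if not matcher.pos_re.fullmatch(node.label):
            return []
        if not matcher.word_re.fullmatch(node.word):
            return []
        return [frozenset({(matcher.capture, node.word)})] if matcher.capture \
            else [frozenset()]
    if node.word is not None or not matcher.label_re.fullmatch(node.label):
        return []
    return _oracle_seq(matcher.items, node.children)


def _oracle_seq(items, children):
    solid = [(i, it) for i, it in enumerate(items) if not isinstance(it, Gap)]
    gap_before = []  # is there a gap between consecutive solid items / ends?
    positions = [-1] + [i for i, _ in solid] + [len(items)]
    for a, b in zip(positions, positions[1:]):
        gap_before.append(any(isinstance(items[j], Gap) for j in range(a + 1, b)))
    k = len(solid)
    results = []
    for combo in combinations(range(len(children)), k):
        idxs = [-1] + list(combo) + [len(children)]
        ok = True
        for seg, (a, b) in enumerate(zip(idxs, idxs[1:])):
            if not gap_before[seg] and b - a != 1:
                ok = False
                break
        if not ok:
            continue
        per_item = [_oracle_node(it, children[ci])
                    for (_, it), ci in zip(solid, combo)]
        if any(not caps for caps in per_item):
            continue
        for picks in product(*per_item):
            merged = frozenset().union(*picks) if picks else frozenset()
            results.append(merged)
    return results


def _random_tree(rng, max_nodes):
    labels = ["S", "NP", "VP", "PP"]
    pos_tags = ["NN", "VBZ", "IN", ","]
    words = ["BAC00x", "DIS00y", "cause", "of", ","]
    budget = [int(rng.integers(2, max_nodes + 1))]

    def build(depth):
        budget[0] -= 1
        if depth >= 3 or budget[0] <= 0 or rng.random() < 0.4:
            return CTreeNode(label=pos_tags[rng.integers(len(pos_tags))],
                             word=words[rng.integers(len(words))])
        node = CTreeNode(label=labels[rng.integers(len(labels))])
        for _ in range(int(rng.integers(1, 4))):
            if budget[0] <= 0:
                break
            node.children.append(build(depth + 1))
        if not node.children:
            node.word = words[rng.integers(len(words))]
        return node

    root = CTreeNode(label="S")
    for _ in range(int(rng.integers(1, 4))):
        root.children.append(build(1))
    return ConstituencyTree(root=root)


def _random_matcher(rng, max_items, depth=0, caps=None):
    caps = caps if caps is not None else set()
    label_res = ["S", "NP", "VP", ".+", "N.+"]
    word_res = [".+", "BAC00.+", "cause", "of"]
    pos_res = ["NN", "N.+", ".+", ","]
    node = InternalMatcher(label_re=re.compile(label_res[rng.integers(len(label_res))]))
    for _ in range(int(rng.integers(0, max_items + 1))):
        r = rng.random()
        if r < 0.25:
            node.items.append(Gap())
        elif r < 0.4:
            node.items.append(Wildcard())
        elif r < 0.75 or depth >= 2:
            cap = None
            if rng.random() < 0.4:
                free = {1, 2, 3} - caps
                if free:
                    cap = sorted(free)[0]
                    caps.add(cap)
            node.items.append(LeafMatcher(
                pos_re=re.compile(pos_res[rng.integers(len(pos_res))]),
                word_re=re.compile(word_res[rng.integers(len(word_res))]),
                capture=cap))
        else:
            node.items.append(_random_matcher(rng, max_items - 1, depth + 1, caps))
    return node


def _count_nodes(node):
    return 1 + sum(_count_nodes(c) for c in node.children)


def _count_matchers(m):
    if not isinstance(m, InternalMatcher):
        return 1
    return 1 + sum(_count_matchers(i) for i in m.items)


def test_match_equals_brute_force_oracle():
    """Engine bindings == exhaustive alignment enumeration, 600 cases."""
    from mdrel.tpe import TPEPattern, _preorder

    rng = np.random.Generator(np.random.PCG64(2024))
    checked = 0
    while checked < 600:
        tree = _random_tree(rng, 12)
        if _count_nodes(tree.root) > 12:
            continue
        root = _random_matcher(rng, 3)
        if _count_matchers(root) > 6:
            continue
        pattern = TPEPattern(pattern_id="r", source="", root=root,
                             captures=frozenset())
        got = {(b.anchor, b.captured) for b in match(tree, pattern)}
        expected = set()
        for idx, node in enumerate(_preorder(tree)):
            for caps in _oracle_node(root, node):
                expected.add((idx, tuple(sorted(caps))))
        assert got == expected
        checked += 1


class TestExtractTriplets:
    def test_printed_patterns_on_appositive_passive_sentence(self, fig3):
        triplets = extract_triplets(fig3, builtin_patterns())
        got = {(t.microbe, t.disease, t.relation) for t in triplets}
        assert got == {
            ("Klebsiella_pneumoniae", "sepsis", "cause"),
            ("Klebsiella_pneumoniae", "pneumonia", "associate"),
        }
        assert len(triplets) == 2

    def test_empty_pattern_list(self, fig3):
        assert extract_triplets(fig3, []) == []

    def test_no_entity_leaves_no_triplets(self):
        from conftest import make_parsed
        parsed = make_parsed("plain", ["dogs", "run"], [1, -1],
                             ["nsubj", "root"], ["NNS", "VBP"],
                             "(S (NP (NNS dogs)) (VP (VBP run)))")
        assert extract_triplets(parsed, builtin_patterns()) == []

    def test_monotone_in_pattern_library(self, fig3):
        pats = builtin_patterns()
        smaller = {t.key for t in extract_triplets(fig3, pats[:1])}
        larger = {t.key for t in extract_triplets(fig3, pats)}
        assert smaller <= larger

    def test_incomplete_pattern_rejected(self, fig3):
        with pytest.raises(ValueError, match="complete extraction"):
            extract_triplets(fig3, [parse_tpe("{NP <NN 1#BAC00.+>}", "partial")])


class TestStemmer:
    @pytest.mark.parametrize("word,expected", [
        ("causes", "cause"), ("associated", "associate"),
        ("implicated", "implicate"), ("induces", "induce"),
        ("common_cause", "common_cause"), ("due_to", "due_to"),
    ])
    def test_paper_stems(self, word, expected):
        assert stem(word) == expected

    def test_idempotent(self):
        for w in ["causes", "associated", "implicated", "linked", "monitored",
                  "common_cause", "due_to", "infections", "is"]:
            assert stem(stem(w)) == stem(w)
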