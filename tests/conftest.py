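"""Shared fixtures: printed worked examples and random tree generators."""

from __future__ import annotations

import numpy as np
import pytest

from mdrel.ner import MICROBE, DISEASE, AnnotatedSentence, EntityMention
from mdrel.trees import DependencyTree, ParsedSentence, parse_bracketed


def make_parsed(sentence_id: str, tokens: list[str], heads: list[int],
                labels: list[str], pos: list[str],
                bracketed: str) -> ParsedSentence:
    """Assemble a ParsedSentence from tagged tokens and gold trees."""
    mentions = []
    for i, t in enumerate(tokens):
        if t.startswith("BAC00"):
            cls, canon = MICROBE, t[5:]
        elif t.startswith("DIS00"):
            cls, canon = DISEASE, t[5:]
        else:
            continue
        mentions.append(EntityMention(entity_class=cls, token_span=(i, i + 1),
                                      canonical=canon, tagged_token=t))
    sent = AnnotatedSentence(sentence_id=sentence_id, tokens=list(tokens),
                             mentions=mentions)
    ctree = parse_bracketed(bracketed)
    dtree = DependencyTree(tokens=list(tokens), heads=list(heads),
                           labels=list(labels), pos=list(pos))
    assert ctree.tokens() == tokens
    return ParsedSentence(sentence=sent, ctree=ctree, dtree=dtree)


@pytest.fixture(scope="session")
def vulnificus() -> ParsedSentence:
    """The vulnificus sentence: 1 microbe, 2 diseases, SDP 'causes wound'."""
    tokens = ["additionally", ",", "in", "otherwise", "healthy", "people", ",",
              "BAC00vulnificus", "causes", "wound", "DIS00infection", "that",
              "can", "require", "amputation", "or", "lead", "to", "DIS00sepsis"]
    heads = [8, 8, 5, 4, 5, 8, 8, 8, -1, 8, 9, 13, 13, 10, 13, 16, 13, 18, 16]
    labels = ["advmod", "punct", "case", "advmod", "amod", "nmod:in", "punct",
              "nsubj", "root", "obj", "compound", "nsubj", "aux", "acl:relcl",
              "obj", "cc", "conj:or", "case", "nmod:to"]
    pos = ["RB", ",", "IN", "RB", "JJ", "NNS", ",", "NN", "VBZ", "NN", "NN",
           "WDT", "MD", "VB", "NN", "CC", "VB", "IN", "NN"]
    bracketed = (
        "(S (ADVP (RB additionally)) (, ,)"
        " (PP (IN in) (NP (RB otherwise) (JJ healthy) (NNS people))) (, ,)"
        " (NP (NN BAC00vulnificus))"
        " (VP (VBZ causes) (NP (NP (NN wound) (NN DIS00infection))"
        " (SBAR (WHNP (WDT that)) (S (VP (MD can) (VP (VB require)"
        " (NP (NN amputation)) (CC or) (VP (VB lead) (PP (IN to)"
        " (NP (NN DIS00sepsis)))))))))))"
    )
    return make_parsed("vulnificus", tokens, heads, labels, pos, bracketed)


@pytest.fixture(scope="session")
def fig3() -> ParsedSentence:
    """Appositive + passive-participle sentence with three entities."""
    tokens = ["BAC00Klebsiella_pneumoniae", ",", "the", "most", "common",
              "cause", "of", "DIS00sepsis", ",", "is", "associated", "with",
              "DIS00pneumonia", "."]
    heads = [10, 5, 5, 4, 5, 0, 7, 5, 5, 10, -1, 12, 10, 10]
    labels = ["nsubj:pass", "punct", "det", "advmod", "amod", "appos", "case",
              "nmod:of", "punct", "aux:pass", "root", "case", "nmod:with",
              "punct"]
    pos = ["NN", ",", "DT", "RBS", "JJ", "NN", "IN", "NN", ",", "VBZ", "VBN",
           "IN", "NN", "."]
    bracketed = (
        "(S (NP (NN BAC00Klebsiella_pneumoniae)) (, ,)"
        " (NP (DT the) (RBS most) (JJ common) (NN cause)"
        " (PP (IN of) (NP (NN DIS00sepsis)))) (, ,)"
        " (VP (VBZ is) (VBN associated)"
        " (PP (IN with) (NP (NN DIS00pneumonia)))) (. .))"
    )
    return make_parsed("fig3", tokens, heads, labels, pos, bracketed)


@pytest.fixture(scope="session")
def stenotrophomonas() -> ParsedSentence:
    """Copular sentence whose LCA 'pathogen' has an acl child 'implicated'."""
    tokens = ["BAC00Stenotrophomonas_maltophilia", "is", "an", "emerging",
              "pathogen", "implicated", "in", "an", "increasing", "number",
              "of", "DIS00severe_pulmonary_infections", "."]
    heads = [4, 4, 4, 4, -1, 4, 9, 9, 9, 5, 11, 9, 4]
    labels = ["nsubj", "cop", "det", "amod", "root", "acl", "case", "det",
              "amod", "nmod:in", "case", "nmod:of", "punct"]
    pos = ["NN", "VBZ", "DT", "JJ", "NN", "VBN", "IN", "DT", "JJ", "NN", "IN",
           "NN", "."]
    bracketed = (
        "(S (NP (NN BAC00Stenotrophomonas_maltophilia))"
        " (VP (VBZ is) (NP (DT an) (JJ emerging) (NN pathogen)"
        " (VP (VBN implicated) (PP (IN in) (NP (DT an) (JJ increasing)"
        " (NN number) (PP (IN of) (NP (NN DIS00severe_pulmonary_infections))))))))"
        " (. .))"
    )
    return make_parsed("fig4", tokens, heads, labels, pos, bracketed)


@pytest.fixture(scope="session")
def streptococcus() -> ParsedSentence:
    """Chunked 'common cause of' with coordinated diseases (inheritance)."""
    tokens = ["BAC00Streptococcus_pneumoniae", ",", "the", "pneumococcus", ",",
              "is", "the", "most", "common", "cause", "of", "DIS00sepsis",
              "and", "DIS00meningitis", "."]
    heads = [9, 3, 3, 0, 3, 9, 9, 8, 9, -1, 11, 9, 13, 11, 9]
    labels = ["nsubj", "punct", "det", "appos", "punct", "cop", "det",
              "advmod", "amod", "root", "case", "nmod:of", "cc", "conj:and",
              "punct"]
    pos = ["NN", ",", "DT", "NN", ",", "VBZ", "DT", "RBS", "JJ", "NN", "IN",
           "NN", "CC", "NN", "."]
    bracketed = (
        "(S (NP (NP (NN BAC00Streptococcus_pneumoniae)) (, ,)"
        " (NP (DT the) (NN pneumococcus)) (, ,))"
        " (VP (VBZ is) (NP (DT the) (RBS most) (JJ common) (NN cause)"
        " (PP (IN of) (NP (NP (NN DIS00sepsis)) (CC and)"
        " (NP (NN DIS00meningitis)))))) (. .))"
    )
    return make_parsed("strep", tokens, heads, labels, pos, bracketed)


def random_dep_tree(rng: np.random.Generator, n: int,
                    labels: list[str]) -> DependencyTree:
    """Random rooted tree: token i>0 attaches to a random earlier token."""
    heads = [-1] + [int(rng.integers(i)) for i in range(1, n)]
    labs = ["root"] + [labels[rng.integers(len(labels))] for _ in range(n - 1)]
    tokens = [f"w{i}" for i in range(n)]
    return DependencyTree(tokens=tokens, heads=heads, labels=labs)
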