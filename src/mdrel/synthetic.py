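"""Synthetic annotated corpus with gold parse trees.

Every pipeline stage is testable without downloads: this module
generates, deterministically under a seed, sentences that co-mention a
microbe and a disease, together with the gold constituency and
dependency trees, pair labels and planted relation words.  The corpus
emulates the statistical shape of a hand-annotated microbe-disease
corpus (~1000 sentences, roughly 60% positive pairs) using the syntactic
construction families that matter to the extractors:

* ``active``            — "BAC00X frequently causes DIS00Y ."
* ``passive``           — "BAC00X is associated with DIS00Y ."
* ``appositive``        — "BAC00X , the most common cause of DIS00Y , is
                           widespread ." (comma-delimited appositive)
* ``copular_chunk``     — "BAC00X is the most common cause of DIS00Y ."
* ``coordination``      — the same with "DIS00Y and DIS00Z" (the second
                           disease inherits the relation)
* ``prep_connector``    — "DIS00Y due to BAC00X was reported ."
* ``compound_chunk``    — "BAC00X infection causes DIS00Y ."
* two negative families — coordinated and subordinate co-mentions with
                           no asserted relation.

Trees are written from per-template schemas, not parsed, so they are
exact; the generator shares no code with the extractors it is used to
test.  A noise knob replaces the planted relation verb of a fraction of
positive sentences with an out-of-inventory synonym while keeping the
gold word, making detector and extractor metrics non-degenerate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ner import MICROBE, DISEASE, AnnotatedSentence, EntityMention
from .trees import (ConstituencyTree, CTreeNode, DependencyTree, ParsedSentence,
                    write_conllu)
from .triplets import RelationTriplet, write_triplets

# builtin vocabularies (surface forms; canonical = underscored surface)
MICROBE_NAMES = [
    "Escherichia coli", "Pseudomonas aeruginosa", "Staphylococcus aureus",
    "Streptococcus pneumoniae", "Klebsiella pneumoniae", "Haemophilus influenzae",
    "Moraxella catarrhalis", "Helicobacter pylori", "Clostridium difficile",
    "Mycobacterium tuberculosis", "Listeria monocytogenes", "Salmonella enterica",
    "Vibrio vulnificus", "Bacteroides fragilis", "Enterococcus faecalis",
    "Neisseria meningitidis", "Campylobacter jejuni", "Legionella pneumophila",
    "Acinetobacter baumannii", "Stenotrophomonas maltophilia",
]
DISEASE_NAMES = [
    "sepsis", "meningitis", "pneumonia", "gastritis", "tuberculosis",
    "bacteremia", "endocarditis", "otitis media", "sinusitis",
    "cystic fibrosis", "periodontitis", "gastroenteritis", "peritonitis",
    "osteomyelitis", "cellulitis", "cholangitis", "colitis", "bronchitis",
    "pharyngitis", "empyema",
]

ACTIVE_VERBS = ("causes", "induces")
PARTICIPLES = (("associated", "with"), ("implicated", "in"))
#: out-of-inventory synonyms used by the noise knob
NOISE_ACTIVE = "provokes"
NOISE_PARTICIPLE = "correlated"
NOISE_NOUN = "source"  # replaces "cause" in the chunk templates


@dataclass
class GeneratorConfig:
    n_sentences: int = 200
    positive_fraction: float = 0.6
    n_microbes: int = 20
    n_diseases: int = 20
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        if self.n_microbes < 1 or self.n_microbes > len(MICROBE_NAMES):
            raise ValueError(f"n_microbes must be in [1, {len(MICROBE_NAMES)}]")
        if self.n_diseases < 2 or self.n_diseases > len(DISEASE_NAMES):
            # coordination templates need two distinct diseases
            raise ValueError(f"n_diseases must be in [2, {len(DISEASE_NAMES)}]")
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be positive")


@dataclass
class SynthSentence:
    sentence_id: str
    template: str
    tokens: list[str]  # tagged token stream
    pos: list[str]
    heads: list[int]
    labels: list[str]
    ctree: ConstituencyTree
    #: (e1 tagged token, e2 tagged token, label, gold relation stem or "")
    gold_pairs: list[tuple[str, str, int, str]]

    @property
    def text(self) -> str:
        """Raw surface text (tags stripped, underscores back to spaces)."""
        words = []
        for t in self.tokens:
            if t.startswith(("BAC00", "DIS00")):
                words.append(t[5:].replace("_", " "))
            else:
                words.append(t)
        return " ".join(words)

    def annotated(self) -> AnnotatedSentence:
        mentions = []
        for i, t in enumerate(self.tokens):
            if t.startswith("BAC00"):
                cls, canon = MICROBE, t[5:]
            elif t.startswith("DIS00"):
                cls, canon = DISEASE, t[5:]
            else:
                continue
            mentions.append(EntityMention(
                entity_class=cls, token_span=(i, i + 1), canonical=canon,
                tagged_token=t, surface_tokens=tuple(canon.split("_"))))
        return AnnotatedSentence(sentence_id=self.sentence_id,
                                 tokens=list(self.tokens), mentions=mentions,
                                 source_text=self.text)

    def parsed(self) -> ParsedSentence:
        dtree = DependencyTree(tokens=list(self.tokens), heads=list(self.heads),
                               labels=list(self.labels), pos=list(self.pos))
        return ParsedSentence(sentence=self.annotated(), ctree=self.ctree,
                              dtree=dtree)

    def gold_triplets(self) -> list[RelationTriplet]:
        out = []
        for e1, e2, label, rel in self.gold_pairs:
            if label != 1 or not rel:
                continue
            mic = e1[5:] if e1.startswith("BAC00") else e2[5:]
            dis = e2[5:] if e2.startswith("DIS00") else e1[5:]
            out.append(RelationTriplet(
                sentence_id=self.sentence_id, microbe=mic, disease=dis,
                relation=rel, extractor="GOLD"))
        return out


def _n(label: str, *children: CTreeNode) -> CTreeNode:
    return CTreeNode(label=label, children=list(children))


def _leaf(pos: str, word: str) -> CTreeNode:
    return CTreeNode(label=pos, word=word)


def _tree(root: CTreeNode) -> ConstituencyTree:
    return ConstituencyTree(root=root)


# ---------------------------------------------------------------------------
# templates: each returns (tokens, pos, heads, labels, ctree, gold_pairs)


def _t_active(m: str, d: str, verb: str, gold: str):
    tokens = [m, "frequently", verb, d, "."]
    pos = ["NN", "RB", "VBZ", "NN", "."]
    heads = [2, 2, -1, 2, 2]
    labels = ["nsubj", "advmod", "root", "obj", "punct"]
    ctree = _tree(_n("S", _n("NP", _leaf("NN", m)), _n("ADVP", _leaf("RB", "frequently")),
                     _n("VP", _leaf("VBZ", verb), _n("NP", _leaf("NN", d))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 1, gold)]


def _t_passive(m: str, d: str, participle: str, prep: str, gold: str):
    tokens = [m, "is", participle, prep, d, "."]
    pos = ["NN", "VBZ", "VBN", "IN", "NN", "."]
    heads = [2, 2, -1, 4, 2, 2]
    labels = ["nsubj:pass", "aux:pass", "root", "case", f"nmod:{prep}", "punct"]
    ctree = _tree(_n("S", _n("NP", _leaf("NN", m)),
                     _n("VP", _leaf("VBZ", "is"), _leaf("VBN", participle),
                        _n("PP", _leaf("IN", prep), _n("NP", _leaf("NN", d)))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 1, gold)]


def _t_appositive(m: str, d: str, noun: str, gold: str):
    tokens = [m, ",", "the", "most", "common", noun, "of", d, ",", "is",
              "widespread", "."]
    pos = ["NN", ",", "DT", "RBS", "JJ", "NN", "IN", "NN", ",", "VBZ", "JJ", "."]
    heads = [10, 5, 5, 4, 5, 0, 7, 5, 5, 10, -1, 10]
    labels = ["nsubj", "punct", "det", "advmod", "amod", "appos", "case",
              "nmod:of", "punct", "cop", "root", "punct"]
    ctree = _tree(_n("S",
                     _n("NP", _leaf("NN", m)),
                     _leaf(",", ","),
                     _n("NP", _leaf("DT", "the"), _leaf("RBS", "most"),
                        _leaf("JJ", "common"), _leaf("NN", noun),
                        _n("PP", _leaf("IN", "of"), _n("NP", _leaf("NN", d)))),
                     _leaf(",", ","),
                     _n("VP", _leaf("VBZ", "is"), _n("ADJP", _leaf("JJ", "widespread"))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 1, gold)]


def _t_copular_chunk(m: str, d: str, noun: str, gold: str):
    tokens = [m, "is", "the", "most", "common", noun, "of", d, "."]
    pos = ["NN", "VBZ", "DT", "RBS", "JJ", "NN", "IN", "NN", "."]
    heads = [5, 5, 5, 4, 5, -1, 7, 5, 5]
    labels = ["nsubj", "cop", "det", "advmod", "amod", "root", "case",
              "nmod:of", "punct"]
    ctree = _tree(_n("S", _n("NP", _leaf("NN", m)),
                     _n("VP", _leaf("VBZ", "is"),
                        _n("NP", _leaf("DT", "the"), _leaf("RBS", "most"),
                           _leaf("JJ", "common"), _leaf("NN", noun),
                           _n("PP", _leaf("IN", "of"), _n("NP", _leaf("NN", d))))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 1, gold)]


def _t_coordination(m: str, d1: str, d2: str, noun: str, gold: str):
    tokens = [m, "is", "the", "most", "common", noun, "of", d1, "and", d2, "."]
    pos = ["NN", "VBZ", "DT", "RBS", "JJ", "NN", "IN", "NN", "CC", "NN", "."]
    heads = [5, 5, 5, 4, 5, -1, 7, 5, 9, 7, 5]
    labels = ["nsubj", "cop", "det", "advmod", "amod", "root", "case",
              "nmod:of", "cc", "conj:and", "punct"]
    ctree = _tree(_n("S", _n("NP", _leaf("NN", m)),
                     _n("VP", _leaf("VBZ", "is"),
                        _n("NP", _leaf("DT", "the"), _leaf("RBS", "most"),
                           _leaf("JJ", "common"), _leaf("NN", noun),
                           _n("PP", _leaf("IN", "of"),
                              _n("NP", _n("NP", _leaf("NN", d1)),
                                 _leaf("CC", "and"),
                                 _n("NP", _leaf("NN", d2)))))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d1, 1, gold), (m, d2, 1, gold)]


def _t_prep_connector(m: str, d: str):
    tokens = [d, "due", "to", m, "was", "reported", "."]
    pos = ["NN", "IN", "IN", "NN", "VBD", "VBN", "."]
    heads = [5, 3, 1, 0, 5, -1, 5]
    labels = ["nsubj:pass", "case", "fixed", "nmod:due_to", "aux:pass",
              "root", "punct"]
    ctree = _tree(_n("S", _n("NP", _n("NP", _leaf("NN", d)),
                             _n("PP", _leaf("IN", "due"), _leaf("IN", "to"),
                                _n("NP", _leaf("NN", m)))),
                     _n("VP", _leaf("VBD", "was"), _leaf("VBN", "reported")),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 1, "due_to")]


def _t_compound_chunk(m: str, d: str, verb: str, gold: str):
    tokens = [m, "infection", verb, d, "."]
    pos = ["NN", "NN", "VBZ", "NN", "."]
    heads = [1, 2, -1, 2, 2]
    labels = ["compound", "nsubj", "root", "obj", "punct"]
    ctree = _tree(_n("S", _n("NP", _leaf("NN", m), _leaf("NN", "infection")),
                     _n("VP", _leaf("VBZ", verb), _n("NP", _leaf("NN", d))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 1, gold)]


def _t_neg_conj(m: str, d: str):
    tokens = [m, "was", "cultured", ",", "and", d, "was", "monitored", "."]
    pos = ["NN", "VBD", "VBN", ",", "CC", "NN", "VBD", "VBN", "."]
    heads = [2, 2, -1, 7, 7, 7, 7, 2, 2]
    labels = ["nsubj:pass", "aux:pass", "root", "punct", "cc", "nsubj:pass",
              "aux:pass", "conj:and", "punct"]
    ctree = _tree(_n("S",
                     _n("S", _n("NP", _leaf("NN", m)),
                        _n("VP", _leaf("VBD", "was"), _leaf("VBN", "cultured"))),
                     _leaf(",", ","), _leaf("CC", "and"),
                     _n("S", _n("NP", _leaf("NN", d)),
                        _n("VP", _leaf("VBD", "was"), _leaf("VBN", "monitored"))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 0, "")]


def _t_neg_advcl(m: str, d: str):
    tokens = ["the", "survey", "examined", m, "while", "clinicians",
              "documented", d, "."]
    pos = ["DT", "NN", "VBD", "NN", "IN", "NNS", "VBD", "NN", "."]
    heads = [1, 2, -1, 2, 6, 6, 2, 6, 2]
    labels = ["det", "nsubj", "root", "obj", "mark", "nsubj", "advcl",
              "obj", "punct"]
    ctree = _tree(_n("S", _n("NP", _leaf("DT", "the"), _leaf("NN", "survey")),
                     _n("VP", _leaf("VBD", "examined"), _n("NP", _leaf("NN", m)),
                        _n("SBAR", _leaf("IN", "while"),
                           _n("S", _n("NP", _leaf("NNS", "clinicians")),
                              _n("VP", _leaf("VBD", "documented"),
                                 _n("NP", _leaf("NN", d)))))),
                     _leaf(".", ".")))
    return tokens, pos, heads, labels, ctree, [(m, d, 0, "")]


POSITIVE_TEMPLATES = ("active", "passive", "appositive", "copular_chunk",
                      "coordination", "prep_connector", "compound_chunk")
NEGATIVE_TEMPLATES = ("neg_conj", "neg_advcl")


@dataclass
class CorpusBundle:
    config: GeneratorConfig
    sentences: list[SynthSentence]
    microbes: list[str]  # surface forms
    diseases: list[str]

    def parsed_sentences(self) -> list[ParsedSentence]:
        return [s.parsed() for s in self.sentences]

    def gold_pairs(self) -> list[tuple[str, str, str, int, str]]:
        out = []
        for s in self.sentences:
            for e1, e2, label, rel in s.gold_pairs:
                out.append((s.sentence_id, e1, e2, label, rel))
        return out

    def gold_triplets(self) -> list[RelationTriplet]:
        out: list[RelationTriplet] = []
        for s in self.sentences:
            out.extend(s.gold_triplets())
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "sentences.tsv", "w", encoding="utf-8") as fh:
            for s in self.sentences:
                fh.write(f"{s.sentence_id}\t{s.text}\n")
        for name, vocab in (("microbes.tsv", self.microbes),
                            ("diseases.tsv", self.diseases)):
            with open(out / name, "w", encoding="utf-8") as fh:
                for surface in vocab:
                    fh.write(surface + "\n")
        with open(out / "trees.mrg", "w", encoding="utf-8") as fh:
            for s in self.sentences:
                fh.write(f"# sent_id = {s.sentence_id}\n")
                fh.write(s.ctree.to_bracketed() + "\n")
        write_conllu(out / "trees.conllu",
                     [(s.sentence_id, s.parsed().dtree) for s in self.sentences])
        with open(out / "gold_pairs.tsv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sentence_id", "e1", "e2", "label", "relation_word"])
            for row in self.gold_pairs():
                writer.writerow(row)
        write_triplets(out / "gold_triplets.tsv", self.gold_triplets())


def _tag(prefix: str, surface: str) -> str:
    return prefix + "_".join(surface.split())


def generate(config: GeneratorConfig) -> CorpusBundle:
    """Generate the corpus bundle; identical seed, identical bundle."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    microbes = MICROBE_NAMES[: config.n_microbes]
    diseases = DISEASE_NAMES[: config.n_diseases]
    sentences: list[SynthSentence] = []
    for i in range(config.n_sentences):
        sid = f"s{i:05d}"
        positive = rng.random() < config.positive_fraction
        noisy = positive and rng.random() < config.noise
        m = _tag("BAC00", microbes[rng.integers(len(microbes))])
        d_idx = int(rng.integers(len(diseases)))
        d = _tag("DIS00", diseases[d_idx])
        if positive:
            template = POSITIVE_TEMPLATES[rng.integers(len(POSITIVE_TEMPLATES))]
        else:
            template = NEGATIVE_TEMPLATES[rng.integers(len(NEGATIVE_TEMPLATES))]
        if template == "active":
            verb = ACTIVE_VERBS[rng.integers(len(ACTIVE_VERBS))]
            surface = NOISE_ACTIVE if noisy else verb
            parts = _t_active(m, d, surface, _stem_gold(verb))
        elif template == "passive":
            participle, prep = PARTICIPLES[rng.integers(len(PARTICIPLES))]
            surface = NOISE_PARTICIPLE if noisy else participle
            parts = _t_passive(m, d, surface, prep, _stem_gold(participle))
        elif template == "appositive":
            surface = NOISE_NOUN if noisy else "cause"
            parts = _t_appositive(m, d, surface, "cause")
        elif template == "copular_chunk":
            surface = NOISE_NOUN if noisy else "cause"
            parts = _t_copular_chunk(m, d, surface, "common_cause")
        elif template == "coordination":
            d2_idx = int(rng.integers(len(diseases) - 1))
            if d2_idx >= d_idx:
                d2_idx += 1
            d2 = _tag("DIS00", diseases[d2_idx])
            surface = NOISE_NOUN if noisy else "cause"
            parts = _t_coordination(m, d, d2, surface, "common_cause")
        elif template == "prep_connector":
            parts = _t_prep_connector(m, d)
        elif template == "compound_chunk":
            verb = ACTIVE_VERBS[rng.integers(len(ACTIVE_VERBS))]
            surface = NOISE_ACTIVE if noisy else verb
            parts = _t_compound_chunk(m, d, surface, _stem_gold(verb))
        elif template == "neg_conj":
            parts = _t_neg_conj(m, d)
        else:
            parts = _t_neg_advcl(m, d)
        tokens, pos, heads, labels, ctree, gold_pairs = parts
        sentences.append(SynthSentence(
            sentence_id=sid, template=template, tokens=tokens, pos=pos,
            heads=heads, labels=labels, ctree=ctree, gold_pairs=gold_pairs))
    return CorpusBundle(config=config, sentences=sentences, microbes=microbes,
                        diseases=diseases)


def _stem_gold(word: str) -> str:
    # gold stems are declared, not computed, so generator and extractors
    # share no stemming code path
    table = {"causes": "cause", "induces": "induce", "associated": "associate",
             "implicated": "implicate"}
    return table[word]
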