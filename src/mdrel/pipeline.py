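"""End-to-end orchestration: cross-validated detection and extraction.

Ties the stages together on a corpus with gold annotations (in practice
the synthetic bundle): detector tenfold cross-validation at pair and
sentence level, and the extraction comparison of TPE-only, DBE-only and
the Bayes ensemble under a confidence threshold, also tenfold
cross-validated with pattern statistics fitted on the training folds
only.  Folds are sentence-level: all pairs of a sentence stay together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dbe, tpe
from .detector import (DetectorConfig, PairFeatures, Vocabulary, WordVectors,
                       enumerate_pairs, evaluate, featurize, train)
from .ensemble import fit_stats, macro_prf, merge, tenfold_splits
from .synthetic import CorpusBundle
from .trees import ParsedSentence
from .triplets import RelationTriplet


@dataclass
class LabelledCorpus:
    parsed: list[ParsedSentence]
    pairs: list  # CandidatePair, with labels attached
    sentence_ids: list[str]
    gold_triplets: list[RelationTriplet]

    @classmethod
    def from_bundle(cls, bundle: CorpusBundle) -> "LabelledCorpus":
        parsed = bundle.parsed_sentences()
        pairs, sids = [], []
        for sent, p in zip(bundle.sentences, parsed):
            gold = {(e1, e2): lab for e1, e2, lab, _ in sent.gold_pairs}
            for pair in enumerate_pairs(p):
                key = (pair.microbe.tagged_token, pair.disease.tagged_token)
                if key not in gold:
                    continue
                pair.label = gold[key]
                pairs.append(pair)
                sids.append(sent.sentence_id)
        return cls(parsed=parsed, pairs=pairs, sentence_ids=sids,
                   gold_triplets=bundle.gold_triplets())


@dataclass
class CVResult:
    fold_pair_prf: list[tuple[float, float, float]] = field(default_factory=list)
    fold_sentence_prf: list[tuple[float, float, float]] = field(default_factory=list)

    def _mean(self, rows: list[tuple[float, float, float]]) -> tuple[float, float, float]:
        arr = np.array(rows)
        return tuple(arr.mean(axis=0))

    @property
    def pair_mean(self) -> tuple[float, float, float]:
        return self._mean(self.fold_pair_prf)

    @property
    def sentence_mean(self) -> tuple[float, float, float]:
        return self._mean(self.fold_sentence_prf)


def detector_tenfold_cv(corpus: LabelledCorpus, config: DetectorConfig,
                        n_folds: int = 10) -> CVResult:
    """Sentence-level tenfold CV of the relation detector.

    Vocabularies and the model are refit per fold from the training
    sentences only; fold assignment is deterministic under
    ``config.seed``.
    """
    folds = tenfold_splits(corpus.sentence_ids, n_folds=n_folds, seed=config.seed)
    words = WordVectors(dim=config.word_dim, seed=config.seed)
    result = CVResult()
    for fold_ids in folds:
        held = set(fold_ids)
        pos_vocab, dep_vocab = Vocabulary(), Vocabulary()
        train_feats: list[PairFeatures] = []
        test_feats: list[PairFeatures] = []
        test_sids: list[str] = []
        for pair, sid in zip(corpus.pairs, corpus.sentence_ids):
            if sid in held:
                continue
            train_feats.append(featurize(pair, words, config, pos_vocab,
                                         dep_vocab, grow_vocab=True))
        for pair, sid in zip(corpus.pairs, corpus.sentence_ids):
            if sid not in held:
                continue
            test_feats.append(featurize(pair, words, config, pos_vocab, dep_vocab))
            test_sids.append(sid)
        model, _ = train(train_feats, config, pos_vocab, dep_vocab)
        result.fold_pair_prf.append(evaluate(model, test_feats))
        result.fold_sentence_prf.append(
            evaluate(model, test_feats, pair_sentences=test_sids, level="sentence"))
    return result


@dataclass
class ExtractionResult:
    """Mean macro P/R/F of each method over the folds."""

    tpe: tuple[float, float, float]
    dbe: tuple[float, float, float]
    ensemble: tuple[float, float, float]
    threshold: float


def _label_extractions(triplets: list[RelationTriplet],
                       gold: set) -> list[tuple[RelationTriplet, bool]]:
    return [(t, t.key in gold) for t in triplets]


def extraction_tenfold_cv(corpus: LabelledCorpus, threshold: float = 0.5,
                          alpha: float = 1.0, n_folds: int = 10,
                          seed: int = 0) -> ExtractionResult:
    """Compare TPE-only, DBE-only and the ensemble, tenfold CV.

    Pattern statistics are fitted on the training folds' extractions
    labelled against gold; each method's test-fold output is thresholded
    on the fitted confidences and scored with macro-averaged P/R/F over
    gold relation-word classes.
    """
    patterns = tpe.builtin_patterns()
    by_sid_tpe: dict[str, list[RelationTriplet]] = {}
    by_sid_dbe: dict[str, list[RelationTriplet]] = {}
    for parsed in corpus.parsed:
        sid = parsed.sentence.sentence_id
        by_sid_tpe[sid] = [t.stemmed() for t in tpe.extract_triplets(parsed, patterns)]
        by_sid_dbe[sid] = [t.stemmed() for t in dbe.extract_triplets(parsed)]
    gold_by_sid: dict[str, list[RelationTriplet]] = {}
    for t in corpus.gold_triplets:
        gold_by_sid.setdefault(t.sentence_id, []).append(t)
    gold_keys = {t.key for t in corpus.gold_triplets}

    folds = tenfold_splits(list(by_sid_tpe), n_folds=n_folds, seed=seed)
    scores = {"tpe": [], "dbe": [], "ensemble": []}
    for fold_ids in folds:
        held = set(fold_ids)
        train_extr = [
            t
            for sid in by_sid_tpe
            if sid not in held
            for t in by_sid_tpe[sid] + by_sid_dbe[sid]
        ]
        stats = fit_stats(_label_extractions(train_extr, gold_keys), alpha=alpha)
        test_tpe = [t for sid in held for t in by_sid_tpe.get(sid, [])]
        test_dbe = [t for sid in held for t in by_sid_dbe.get(sid, [])]
        test_gold = [t for sid in held for t in gold_by_sid.get(sid, [])]
        if not test_gold:
            continue
        for name, (a, b) in (("tpe", (test_tpe, [])), ("dbe", ([], test_dbe)),
                             ("ensemble", (test_tpe, test_dbe))):
            kept = [s.triplet for s in merge(a, b, stats, threshold=threshold)]
            scores[name].append(macro_prf(kept, test_gold))
    means = {k: tuple(np.array(v).mean(axis=0)) for k, v in scores.items()}
    return ExtractionResult(tpe=means["tpe"], dbe=means["dbe"],
                            ensemble=means["ensemble"], threshold=threshold)
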