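"""Bayes-confidence ensemble of the two relation-word extractors.

Every extraction pattern (a TPE pattern id or a DBE rule id) has an
empirical reliability.  From labelled extractions we estimate, with
add-alpha smoothing,

    Pr(p)       prior that pattern p extracts correctly (its precision)
    Pr(r | p)   frequency of relation word r among p's correct extractions
    Pr(r | ~p)  frequency of r among p's incorrect extractions

and score a triplet extracted by pattern p with relation word r by the
posterior

    Pr(p | r) = Pr(r|p) Pr(p) / (Pr(r|p) Pr(p) + Pr(r|~p) Pr(~p))

The confidence of a triplet is the maximum posterior over all patterns
(from either extractor) that produced it; merged triplets below a
confidence threshold (default 0.5, where the extraction F-score peaks)
are dropped.  Relation words are stemmed here, once, so the TPE stream
(already stemmed) and the DBE stream (surface forms) merge consistently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .stem import stem
from .triplets import RelationTriplet, dedupe

logger = logging.getLogger(__name__)


@dataclass
class PatternStats:
    """Per-pattern extraction counts with smoothing constant alpha."""

    alpha: float = 1.0
    n_extractions: dict[str, int] = field(default_factory=dict)
    n_correct: dict[str, int] = field(default_factory=dict)
    #: relation-word counts among correct / incorrect extractions per pattern
    word_correct: dict[str, dict[str, int]] = field(default_factory=dict)
    word_incorrect: dict[str, dict[str, int]] = field(default_factory=dict)
    vocab: set[str] = field(default_factory=set)

    def prior(self, pattern: str) -> float:
        n = self.n_extractions.get(pattern, 0)
        if n == 0:
            logger.warning("pattern %r has no recorded extractions; prior 0.5", pattern)
        k = self.n_correct.get(pattern, 0)
        return (k + self.alpha) / (n + 2 * self.alpha)

    def _likelihood(self, counts: dict[str, dict[str, int]], pattern: str,
                    word: str) -> float:
        per = counts.get(pattern, {})
        total = sum(per.values())
        v = len(self.vocab) + 1  # +1 unseen bucket
        return (per.get(word, 0) + self.alpha) / (total + self.alpha * v)

    def likelihood_correct(self, pattern: str, word: str) -> float:
        return self._likelihood(self.word_correct, pattern, word)

    def likelihood_incorrect(self, pattern: str, word: str) -> float:
        return self._likelihood(self.word_incorrect, pattern, word)

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "n_extractions": self.n_extractions,
                "n_correct": self.n_correct,
                "word_correct": self.word_correct,
                "word_incorrect": self.word_incorrect,
                "vocab": sorted(self.vocab),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PatternStats":
        d = json.loads(text)
        return cls(
            alpha=d["alpha"],
            n_extractions={k: int(v) for k, v in d["n_extractions"].items()},
            n_correct={k: int(v) for k, v in d["n_correct"].items()},
            word_correct={k: dict(v) for k, v in d["word_correct"].items()},
            word_incorrect={k: dict(v) for k, v in d["word_incorrect"].items()},
            vocab=set(d["vocab"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PatternStats":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def fit_stats(labelled: Iterable[tuple[RelationTriplet, bool]],
              alpha: float = 1.0) -> PatternStats:
    """Estimate pattern reliabilities from (triplet, is_correct) pairs.

    Correctness is exact-match of (microbe, disease, stemmed relation)
    against gold, decided by the caller.  Each pattern id in a triplet's
    provenance counts as one extraction of the stemmed relation word.
    """
    stats = PatternStats(alpha=alpha)
    for triplet, correct in labelled:
        word = stem(triplet.relation)
        stats.vocab.add(word)
        for pattern in triplet.pattern_ids:
            stats.n_extractions[pattern] = stats.n_extractions.get(pattern, 0) + 1
            target = stats.word_correct if correct else stats.word_incorrect
            if correct:
                stats.n_correct[pattern] = stats.n_correct.get(pattern, 0) + 1
            per = target.setdefault(pattern, {})
            per[word] = per.get(word, 0) + 1
    return stats


def pattern_posterior(stats: PatternStats, pattern: str, word: str) -> float:
    """Bayes posterior that ``pattern`` extracted ``word`` correctly."""
    prior = stats.prior(pattern)
    like_c = stats.likelihood_correct(pattern, word)
    like_i = stats.likelihood_incorrect(pattern, word)
    num = like_c * prior
    den = num + like_i * (1.0 - prior)
    return num / den if den > 0 else 0.0


@dataclass(frozen=True)
class ScoredTriplet:
    triplet: RelationTriplet
    confidence: float
    posteriors: tuple[tuple[str, float], ...]  # (pattern id, posterior)


def confidence(triplet: RelationTriplet, stats: PatternStats) -> ScoredTriplet:
    """Max-over-patterns posterior (the ensemble confidence)."""
    word = stem(triplet.relation)
    posts = tuple(
        (p, pattern_posterior(stats, p, word)) for p in triplet.pattern_ids
    )
    conf = max((v for _, v in posts), default=0.0)
    return ScoredTriplet(triplet=triplet, confidence=conf, posteriors=posts)


def merge(tpe_triplets: Sequence[RelationTriplet],
          dbe_triplets: Sequence[RelationTriplet],
          stats: PatternStats,
          threshold: float = 0.5) -> list[ScoredTriplet]:
    """Union the two extractor streams, score, and apply the threshold.

    Duplicates (same sentence, microbe, disease, stemmed word) merge
    their provenance; the confidence maximises over all contributing
    patterns from both extractors.
    """
    stemmed = [t.stemmed() for t in list(tpe_triplets) + list(dbe_triplets)]
    merged = dedupe(stemmed)
    scored = [confidence(t, stats) for t in merged]
    return [s for s in scored if s.confidence >= threshold]


# ---------------------------------------------------------------------------
# evaluation


def triplet_sets(predicted: Iterable[RelationTriplet],
                 gold: Iterable[RelationTriplet]) -> tuple[set, set]:
    pred = {t.key for t in predicted}
    gld = {t.key for t in gold}
    return pred, gld


def macro_prf(predicted: Sequence[RelationTriplet],
              gold: Sequence[RelationTriplet]) -> tuple[float, float, float]:
    """Macro-averaged P/R/F over relation-word classes present in gold."""
    classes = sorted({stem(t.relation) for t in gold})
    if not classes:
        raise ValueError("gold set has no relation classes")
    ps, rs, fs = [], [], []
    for cls in classes:
        pred = {t.key for t in predicted if stem(t.relation) == cls}
        gld = {t.key for t in gold if stem(t.relation) == cls}
        tp = len(pred & gld)
        p = tp / len(pred) if pred else 0.0
        r = tp / len(gld) if gld else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    n = len(classes)
    return sum(ps) / n, sum(rs) / n, sum(fs) / n


def micro_prf(predicted: Sequence[RelationTriplet],
              gold: Sequence[RelationTriplet]) -> tuple[float, float, float]:
    pred, gld = triplet_sets(predicted, gold)
    tp = len(pred & gld)
    p = tp / len(pred) if pred else 0.0
    r = tp / len(gld) if gld else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def tenfold_splits(sentence_ids: Sequence[str], n_folds: int = 10,
                   seed: int = 0) -> list[list[str]]:
    """Deterministic sentence-level folds (all pairs of a sentence stay
    together)."""
    import numpy as np

    ids = sorted(set(sentence_ids))
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(ids[idx])
    return folds
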