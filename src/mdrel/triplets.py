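"""Relation triplet records and their TSV serialisation.

A triplet is the unit of extraction: a microbe, a disease, and the word
describing their association, together with provenance (which extractor
and which pattern / rule produced it) and, after ensemble scoring, a
confidence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .stem import stem

#: canonical extractor names used in provenance
TPE = "TPE"
DBE = "DBE"


@dataclass(frozen=True)
class RelationTriplet:
    sentence_id: str
    microbe: str
    disease: str
    relation: str  # surface or stemmed relation word, see `stemmed`
    extractor: str  # TPE or DBE
    pattern_ids: tuple[str, ...] = field(default_factory=tuple)

    def stemmed(self) -> "RelationTriplet":
        return replace(self, relation=stem(self.relation))

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity for deduplication: sentence + entities + stemmed word."""
        return (self.sentence_id, self.microbe, self.disease, stem(self.relation))


_HEADER = ["sentence_id", "microbe", "disease", "relation", "extractor", "pattern_ids"]


def write_triplets(path: str | Path, triplets: Iterable[RelationTriplet]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for t in triplets:
            writer.writerow(
                [t.sentence_id, t.microbe, t.disease, t.relation, t.extractor,
                 ",".join(t.pattern_ids)]
            )


def read_triplets(path: str | Path) -> list[RelationTriplet]:
    out: list[RelationTriplet] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _HEADER:
            raise ValueError(f"{path}: unexpected triplet header {header!r}")
        for row in reader:
            if not row:
                continue
            sid, mic, dis, rel, ext, pats = row
            out.append(
                RelationTriplet(sid, mic, dis, rel, ext,
                                tuple(p for p in pats.split(",") if p))
            )
    return out


def dedupe(triplets: Iterable[RelationTriplet]) -> list[RelationTriplet]:
    """Collapse duplicates by (sentence, microbe, disease, stemmed word).

    Provenance pattern ids are merged in first-seen order; the surface
    relation of the first occurrence is kept.
    """
    merged: dict[tuple, RelationTriplet] = {}
    for t in triplets:
        k = t.key
        if k in merged:
            prev = merged[k]
            pats = prev.pattern_ids + tuple(
                p for p in t.pattern_ids if p not in prev.pattern_ids
            )
            ext = prev.extractor if prev.extractor == t.extractor else f"{prev.extractor}+{t.extractor}"
            merged[k] = replace(prev, pattern_ids=pats, extractor=ext)
        else:
            merged[k] = t
    return list(merged.values())
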