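"""Dictionary-based named entity recognition for microbes and diseases.

Sentences are tokenized (whitespace plus punctuation, punctuation kept as
separate tokens) and scanned against two lexicons — one of bacteria /
strains / viruses, one of diseases.  Matching is longest-match,
leftmost-first and case-insensitive, except that single-token
all-uppercase lexicon entries (acronyms) must match case-sensitively.
Each matched word sequence is collapsed into a single tagged token: the
canonical name prefixed with ``BAC00`` (microbe) or ``DIS00`` (disease),
e.g. ``BAC00Pseudomonas_aeruginosa``.  Downstream components (parsers,
the relation detector, the pattern extractors) all operate on this
collapsed token stream, so one entity is always one token.

When a microbe match and a disease match overlap, the microbe wins by
default (strain names are the more specific vocabulary); the order is
configurable through ``tag_entities(..., order=...)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

MICROBE = "MICROBE"
DISEASE = "DISEASE"

TAG_PREFIX = {MICROBE: "BAC00", DISEASE: "DIS00"}

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Split on whitespace, keeping punctuation as separate tokens."""
    return _TOKEN_RE.findall(text)


@dataclass
class Lexicon:
    """Surface-form -> canonical-name dictionary for one entity class."""

    entity_class: str
    entries: dict[str, str] = field(default_factory=dict)
    #: token-sequence index: tuple of lowercased tokens -> canonical
    _index: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)
    #: surfaces that must match case-sensitively (all-caps single tokens)
    _case_sensitive: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)

    def add(self, surface: str, canonical: str | None = None) -> None:
        surface = surface.strip()
        if not surface:
            raise ValueError("empty surface form in lexicon")
        if canonical is None or not canonical.strip():
            canonical = "_".join(surface.split())
        canonical = "_".join(canonical.split())
        key = surface.lower()
        if key in self.entries and self.entries[key] != canonical:
            raise ValueError(
                f"duplicate surface {surface!r} with conflicting canonical names "
                f"{self.entries[key]!r} vs {canonical!r}"
            )
        self.entries[key] = canonical
        toks = tokenize(surface)
        if len(toks) == 1 and toks[0].isupper() and len(toks[0]) > 1:
            self._case_sensitive[tuple(toks)] = canonical
        else:
            self._index[tuple(t.lower() for t in toks)] = canonical

    @property
    def max_len(self) -> int:
        lens = [len(k) for k in self._index] + [len(k) for k in self._case_sensitive]
        return max(lens, default=0)

    def lookup(self, tokens: list[str], start: int) -> tuple[int, str] | None:
        """Longest match beginning at ``start``; returns (length, canonical)."""
        best: tuple[int, str] | None = None
        for length in range(1, min(self.max_len, len(tokens) - start) + 1):
            window = tuple(tokens[start : start + length])
            if window in self._case_sensitive:
                best = (length, self._case_sensitive[window])
            lowered = tuple(t.lower() for t in window)
            if lowered in self._index:
                best = (length, self._index[lowered])
        return best


def load_lexicon(path: str | Path, entity_class: str) -> Lexicon:
    """Read a 1-2 column TSV lexicon (surface [, canonical]); '#' comments.

    Raises ``ValueError`` on an empty file or on the same surface mapping
    to two different canonical names.
    """
    if entity_class not in (MICROBE, DISEASE):
        raise ValueError(f"unknown entity class {entity_class!r}")
    lex = Lexicon(entity_class=entity_class)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            lex.add(cols[0], cols[1] if len(cols) > 1 else None)
    if not lex.entries:
        raise ValueError(f"{path}: empty lexicon")
    return lex


@dataclass(frozen=True)
class EntityMention:
    entity_class: str
    token_span: tuple[int, int]  # half-open, in the collapsed token stream
    canonical: str
    tagged_token: str
    surface_tokens: tuple[str, ...] = ()

    @property
    def index(self) -> int:
        """Position of the collapsed tagged token in the sentence."""
        return self.token_span[0]


@dataclass
class AnnotatedSentence:
    sentence_id: str
    tokens: list[str]  # after mention collapsing
    mentions: list[EntityMention]
    source_text: str = ""

    def mentions_of(self, entity_class: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_class == entity_class]

    def to_json(self) -> str:
        return json.dumps(
            {
                "sentence_id": self.sentence_id,
                "tokens": self.tokens,
                "source_text": self.source_text,
                "mentions": [
                    {
                        "entity_class": m.entity_class,
                        "token_span": list(m.token_span),
                        "canonical": m.canonical,
                        "tagged_token": m.tagged_token,
                        "surface_tokens": list(m.surface_tokens),
                    }
                    for m in self.mentions
                ],
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "AnnotatedSentence":
        d = json.loads(line)
        return cls(
            sentence_id=d["sentence_id"],
            tokens=list(d["tokens"]),
            mentions=[
                EntityMention(
                    entity_class=m["entity_class"],
                    token_span=tuple(m["token_span"]),
                    canonical=m["canonical"],
                    tagged_token=m["tagged_token"],
                    surface_tokens=tuple(m.get("surface_tokens", ())),
                )
                for m in d["mentions"]
            ],
            source_text=d.get("source_text", ""),
        )


def _scan(tokens: list[str], lex: Lexicon, occupied: set[int]) -> list[tuple[int, int, str]]:
    """Longest-match leftmost-first scan; spans avoiding occupied tokens."""
    found: list[tuple[int, int, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i in occupied:
            i += 1
            continue
        hit = lex.lookup(tokens, i)
        if hit is not None:
            length, canonical = hit
            span = range(i, i + length)
            if not any(j in occupied for j in span):
                found.append((i, i + length, canonical))
                i += length
                continue
        i += 1
    return found


def tag_entities(
    text: str,
    microbe_lex: Lexicon,
    disease_lex: Lexicon,
    sentence_id: str = "",
    order: tuple[str, str] = (MICROBE, DISEASE),
) -> AnnotatedSentence:
    """Tag microbe and disease mentions and collapse them to single tokens.

    The lexicon named first in ``order`` is applied first and wins any
    overlap.  A sentence with no matches is valid and returns an empty
    mentions list.
    """
    if not text.strip():
        raise ValueError("empty sentence text")
    tokens = tokenize(text)
    lex_by_class = {MICROBE: microbe_lex, DISEASE: disease_lex}
    occupied: set[int] = set()
    raw: list[tuple[int, int, str, str]] = []  # (start, end, class, canonical)
    for cls in order:
        for start, end, canonical in _scan(tokens, lex_by_class[cls], occupied):
            raw.append((start, end, cls, canonical))
            occupied.update(range(start, end))
    raw.sort()

    out_tokens: list[str] = []
    mentions: list[EntityMention] = []
    i = 0
    match_at = {start: (end, cls, canon) for start, end, cls, canon in raw}
    while i < len(tokens):
        if i in match_at:
            end, cls, canon = match_at[i]
            tagged = TAG_PREFIX[cls] + canon
            mentions.append(
                EntityMention(
                    entity_class=cls,
                    token_span=(len(out_tokens), len(out_tokens) + 1),
                    canonical=canon,
                    tagged_token=tagged,
                    surface_tokens=tuple(tokens[i:end]),
                )
            )
            out_tokens.append(tagged)
            i = end
        else:
            out_tokens.append(tokens[i])
            i += 1
    return AnnotatedSentence(
        sentence_id=sentence_id, tokens=out_tokens, mentions=mentions, source_text=text
    )


def read_sentences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (sentence_id, text) from plain text or 2-column TSV input."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line:
                sid, text = line.split("\t", 1)
            else:
                sid, text = f"s{lineno}", line
            yield sid, text


def write_jsonl(path: str | Path, sentences: Iterable[AnnotatedSentence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(s.to_json() + "\n")


def read_jsonl(path: str | Path) -> list[AnnotatedSentence]:
    with open(path, encoding="utf-8") as fh:
        return [AnnotatedSentence.from_json(line) for line in fh if line.strip()]
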