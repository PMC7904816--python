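"""Tree pattern expressions (TPE) over constituency parses.

A TPE is a search query over a bracketed parse tree.  The grammar:

    pattern   := internal
    internal  := "{" LABEL_RE item* "}"
    item      := internal | leaf | "*" | "**"
    leaf      := "<" POS_RE WORD_RE ">"

``LABEL_RE``, ``POS_RE`` and ``WORD_RE`` are ordinary regular expressions
(full-match semantics).  ``*`` matches exactly one arbitrary subtree;
``**`` is a gap matching zero or more consecutive subtrees.  A
``WORD_RE`` may carry a capture prefix ``k#`` with k in {1: microbe,
2: disease, 3: relation word}; a complete extraction pattern contains
each capture at most once and needs all three to emit a triplet.

Matching anchors the pattern at every tree node; child sequences are
aligned left-to-right with backtracking over gaps, and every distinct
captured triple is reported.  Example pattern matching an NP whose head
noun is a tagged microbe::

    {NP ** <N.+ 1#BAC00.+> **}

The package ships two curated patterns (appositive-with-commas and
passive past-participle clauses) in ``data/patterns.tsv``; users extend
the library through the same file format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .ner import MICROBE, DISEASE, TAG_PREFIX
from .stem import stem
from .trees import ConstituencyTree, CTreeNode, ParsedSentence
from .triplets import TPE, RelationTriplet, dedupe

CAPTURE_MICROBE, CAPTURE_DISEASE, CAPTURE_RELATION = 1, 2, 3


@dataclass
class LeafMatcher:
    pos_re: re.Pattern
    word_re: re.Pattern
    capture: int | None = None


@dataclass
class Wildcard:  # `*` — any one subtree
    pass


@dataclass
class Gap:  # `**` — any >=0 consecutive subtrees
    pass


@dataclass
class InternalMatcher:
    label_re: re.Pattern
    items: list[Union["InternalMatcher", LeafMatcher, Wildcard, Gap]] = field(
        default_factory=list
    )


Matcher = Union[InternalMatcher, LeafMatcher, Wildcard, Gap]


@dataclass
class TPEPattern:
    pattern_id: str
    source: str
    root: InternalMatcher
    captures: frozenset[int]


@dataclass(frozen=True)
class MatchBinding:
    pattern_id: str
    anchor: int  # preorder index of the anchor node in the tree
    captured: tuple[tuple[int, str], ...]  # sorted (capture_id, word) pairs

    def captured_map(self) -> dict[int, str]:
        return dict(self.captured)


# ---------------------------------------------------------------------------
# pattern parsing


def _compile(fragment: str, source: str) -> re.Pattern:
    try:
        return re.compile(fragment)
    except re.error as exc:
        raise ValueError(f"invalid regex {fragment!r} in pattern {source!r}: {exc}")


def parse_tpe(pattern_string: str, pattern_id: str = "") -> TPEPattern:
    """Parse a TPE string; errors carry the offending position/fragment."""
    toks: list[str] = []
    for raw in re.findall(r"[{}<>]|[^\s{}<>]+", pattern_string):
        toks.append(raw)
    pos = 0
    seen_captures: set[int] = set()

    def error(msg: str) -> ValueError:
        return ValueError(f"TPE pattern {pattern_id or pattern_string!r}: {msg} "
                          f"(at item {pos})")

    def parse_leaf() -> LeafMatcher:
        nonlocal pos
        pos += 1  # consume '<'
        parts: list[str] = []
        while pos < len(toks) and toks[pos] != ">":
            if toks[pos] in "{}<":
                raise error("unbalanced angle brackets in leaf matcher")
            parts.append(toks[pos])
            pos += 1
        if pos >= len(toks):
            raise error("unbalanced angle brackets (missing '>')")
        pos += 1  # consume '>'
        if len(parts) != 2:
            raise error(f"leaf matcher needs POS_RE and WORD_RE, got {parts!r}")
        pos_re, word = parts
        capture: int | None = None
        m = re.match(r"^([123])#(.+)$", word)
        if m:
            capture = int(m.group(1))
            word = m.group(2)
            if capture in seen_captures:
                raise error(f"duplicate capture id {capture}")
            seen_captures.add(capture)
        return LeafMatcher(
            pos_re=_compile(pos_re, pattern_string),
            word_re=_compile(word, pattern_string),
            capture=capture,
        )

    def parse_internal() -> InternalMatcher:
        nonlocal pos
        pos += 1  # consume '{'
        if pos >= len(toks) or toks[pos] in "{}<>":
            raise error("internal matcher missing label regex")
        node = InternalMatcher(label_re=_compile(toks[pos], pattern_string))
        pos += 1
        while pos < len(toks) and toks[pos] != "}":
            t = toks[pos]
            if t == "{":
                node.items.append(parse_internal())
            elif t == "<":
                node.items.append(parse_leaf())
            elif t == "**":
                node.items.append(Gap())
                pos += 1
            elif t == "*":
                node.items.append(Wildcard())
                pos += 1
            elif t == ">":
                raise error("unexpected '>'")
            else:
                raise error(f"unexpected bare token {t!r} inside internal matcher")
        if pos >= len(toks):
            raise error("unbalanced braces (missing '}')")
        pos += 1  # consume '}'
        return node

    if not toks or toks[0] != "{":
        raise ValueError(f"TPE pattern {pattern_id or pattern_string!r}: "
                         "must start with '{'")
    root = parse_internal()
    if pos != len(toks):
        raise ValueError(f"TPE pattern {pattern_id or pattern_string!r}: "
                         "unbalanced braces (trailing input)")
    return TPEPattern(pattern_id=pattern_id, source=pattern_string, root=root,
                      captures=frozenset(seen_captures))


# ---------------------------------------------------------------------------
# matching


def _node_matches(matcher: Matcher, node: CTreeNode) -> list[dict[int, str]]:
    """All capture maps under which ``matcher`` embeds at ``node``."""
    if isinstance(matcher, Wildcard):
        return [{}]
    if isinstance(matcher, LeafMatcher):
        if not node.is_leaf:
            return []
        if not matcher.pos_re.fullmatch(node.label):
            return []
        if not matcher.word_re.fullmatch(node.word or ""):
            return []
        return [{matcher.capture: node.word}] if matcher.capture else [{}]
    if isinstance(matcher, InternalMatcher):
        if node.is_leaf or not matcher.label_re.fullmatch(node.label):
            return []
        return _seq_matches(matcher.items, node.children)
    raise TypeError(f"gap wildcard outside a child sequence: {matcher!r}")


def _seq_matches(items: list[Matcher], children: list[CTreeNode]) -> list[dict[int, str]]:
    """Align a matcher item sequence against a child list (backtracking)."""
    results: list[dict[int, str]] = []

    def rec(ii: int, ci: int, captured: dict[int, str]) -> None:
        if ii == len(items):
            if ci == len(children):
                results.append(dict(captured))
            return
        item = items[ii]
        if isinstance(item, Gap):
            for skip in range(len(children) - ci + 1):
                rec(ii + 1, ci + skip, captured)
            return
        if ci >= len(children):
            return
        for sub in _node_matches(item, children[ci]):
            merged = {**captured, **sub}
            rec(ii + 1, ci + 1, merged)

    rec(0, 0, {})
    return results


def _preorder(tree: ConstituencyTree) -> list[CTreeNode]:
    out: list[CTreeNode] = []

    def walk(n: CTreeNode) -> None:
        out.append(n)
        for c in n.children:
            walk(c)

    walk(tree.root)
    return out


def match(tree: ConstituencyTree, pattern: TPEPattern) -> list[MatchBinding]:
    """Anchor the pattern at every node; distinct captured triples reported."""
    bindings: list[MatchBinding] = []
    seen: set[tuple[int, tuple[tuple[int, str], ...]]] = set()
    for idx, node in enumerate(_preorder(tree)):
        for captured in _node_matches(pattern.root, node):
            key = (idx, tuple(sorted(captured.items())))
            if key in seen:
                continue
            seen.add(key)
            bindings.append(
                MatchBinding(pattern_id=pattern.pattern_id, anchor=idx, captured=key[1])
            )
    return bindings


def _strip_tag(word: str, entity_class: str) -> str:
    prefix = TAG_PREFIX[entity_class]
    return word[len(prefix):] if word.startswith(prefix) else word


def extract_triplets(
    sentence: ParsedSentence, patterns: Iterable[TPEPattern]
) -> list[RelationTriplet]:
    """Run every pattern on the sentence's constituency tree.

    Each complete binding (captures 1, 2 and 3 present) yields one
    triplet with the relation word stemmed; duplicates within the
    sentence are collapsed with merged pattern provenance.
    """
    triplets: list[RelationTriplet] = []
    for pattern in patterns:
        if not {1, 2, 3} <= pattern.captures:
            raise ValueError(
                f"pattern {pattern.pattern_id!r} is not a complete extraction "
                f"pattern (captures {sorted(pattern.captures)})"
            )
        for binding in match(sentence.ctree, pattern):
            cap = binding.captured_map()
            if not {1, 2, 3} <= cap.keys():
                continue
            triplets.append(
                RelationTriplet(
                    sentence_id=sentence.sentence.sentence_id,
                    microbe=_strip_tag(cap[CAPTURE_MICROBE], MICROBE),
                    disease=_strip_tag(cap[CAPTURE_DISEASE], DISEASE),
                    relation=stem(cap[CAPTURE_RELATION]),
                    extractor=TPE,
                    pattern_ids=(pattern.pattern_id,),
                )
            )
    return dedupe(triplets)


# ---------------------------------------------------------------------------
# pattern files


def read_patterns(path: str | Path) -> list[TPEPattern]:
    """Read a pattern file: ``pattern_id <TAB> pattern_string``, '#' comments."""
    out: list[TPEPattern] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>pattern'")
            pid, pat = line.split("\t", 1)
            out.append(parse_tpe(pat.strip(), pattern_id=pid.strip()))
    return out


def builtin_patterns() -> list[TPEPattern]:
    """The curated patterns shipped with the package."""
    ref = resources.files("mdrel").joinpath("data/patterns.tsv")
    with resources.as_file(ref) as path:
        return read_patterns(path)
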