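"""Parse trees and their readers.

Each annotated sentence needs two parses: a constituency tree (Penn
Treebank bracketed format) used by the tree-pattern extractor, and a
dependency tree (CoNLL-U) used for shortest dependency paths and the
LCA-based extractor.  Trees are produced over the collapsed token stream
(entity mentions appear as single tagged tokens), so leaf/token alignment
is exact and is verified when a parse is attached to a sentence.

No parser is bundled: trees come from gold fixture files (the synthetic
corpus generator writes them) or from an external-parser adapter that the
caller supplies as a callable.

Token indices are 0-based internally; CoNLL-U's 1-based HEAD column is
converted at the reader boundary (head ``-1`` denotes the virtual root).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .ner import AnnotatedSentence

ROOT = -1


# ---------------------------------------------------------------------------
# constituency trees


@dataclass
class CTreeNode:
    label: str
    children: list["CTreeNode"] = field(default_factory=list)
    word: str | None = None  # set on leaves only; label is then the POS tag

    @property
    def is_leaf(self) -> bool:
        return self.word is not None


@dataclass
class ConstituencyTree:
    root: CTreeNode

    def leaves(self) -> list[tuple[str, str]]:
        """(pos_tag, token) pairs in sentence order."""
        out: list[tuple[str, str]] = []

        def walk(node: CTreeNode) -> None:
            if node.is_leaf:
                out.append((node.label, node.word))
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def tokens(self) -> list[str]:
        return [w for _, w in self.leaves()]

    def to_bracketed(self) -> str:
        def render(node: CTreeNode) -> str:
            if node.is_leaf:
                return f"({node.label} {node.word})"
            return "(" + node.label + " " + " ".join(render(c) for c in node.children) + ")"

        return render(self.root)


def _parse_sexpr(text: str, where: str) -> CTreeNode:
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse_node() -> CTreeNode:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos] != "(":
            raise ValueError(f"{where}: expected '(' at item {pos}")
        pos += 1
        if pos >= len(tokens) or tokens[pos] in "()":
            raise ValueError(f"{where}: empty node label")
        label = tokens[pos]
        pos += 1
        node = CTreeNode(label=label)
        words: list[str] = []
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                node.children.append(parse_node())
            else:
                words.append(tokens[pos])
                pos += 1
        if pos >= len(tokens):
            raise ValueError(f"{where}: unbalanced parentheses (missing ')')")
        pos += 1  # consume ')'
        if words:
            if node.children:
                raise ValueError(f"{where}: node {label!r} mixes words and subtrees")
            node.word = " ".join(words)
        elif not node.children:
            raise ValueError(f"{where}: internal node {label!r} has no children")
        return node

    root = parse_node()
    if pos != len(tokens):
        raise ValueError(f"{where}: unbalanced parentheses (trailing input)")
    return root


def parse_bracketed(line: str, where: str = "<string>") -> ConstituencyTree:
    return ConstituencyTree(root=_parse_sexpr(line, where))


def read_bracketed(path: str | Path) -> list[ConstituencyTree]:
    """Read bracketed trees, one per line (blank lines and '#' skipped)."""
    trees: list[ConstituencyTree] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(parse_bracketed(line, where=f"{path}:{lineno}"))
    return trees


def write_bracketed(path: str | Path, trees: Iterable[ConstituencyTree]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(t.to_bracketed() + "\n")


# ---------------------------------------------------------------------------
# dependency trees


@dataclass
class DependencyTree:
    tokens: list[str]
    heads: list[int]  # 0-based head index per token; ROOT (-1) for the root
    labels: list[str]  # dependency relation per token (label of edge to head)
    pos: list[str] = field(default_factory=list)  # UPOS/XPOS per token, optional

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (len(self.heads) == len(self.labels) == n):
            raise ValueError("tokens/heads/labels length mismatch")
        if not self.pos:
            self.pos = ["X"] * n
        roots = [i for i, h in enumerate(self.heads) if h == ROOT]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for i, h in enumerate(self.heads):
            if h != ROOT and not (0 <= h < n):
                raise ValueError(f"token {i}: head {h} out of range")
        # cycle check: follow heads from every node; must reach the root
        for i in range(n):
            seen = set()
            j = i
            while j != ROOT:
                if j in seen:
                    raise ValueError(f"cycle involving token {j}")
                seen.add(j)
                j = self.heads[j]

    @property
    def root(self) -> int:
        return self.heads.index(ROOT)

    def children(self, i: int) -> list[int]:
        return [j for j, h in enumerate(self.heads) if h == i]

    def adjacency(self) -> dict[int, list[tuple[int, str]]]:
        """Undirected adjacency with edge labels."""
        adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(self.tokens))}
        for i, h in enumerate(self.heads):
            if h != ROOT:
                adj[i].append((h, self.labels[i]))
                adj[h].append((i, self.labels[i]))
        return adj

    def path(self, a: int, b: int) -> list[int]:
        """The unique undirected path a..b inclusive (BFS)."""
        if a == b:
            return [a]
        adj = self.adjacency()
        prev: dict[int, int] = {a: a}
        frontier = [a]
        while frontier and b not in prev:
            nxt: list[int] = []
            for u in frontier:
                for v, _ in adj[u]:
                    if v not in prev:
                        prev[v] = u
                        nxt.append(v)
            frontier = nxt
        if b not in prev:
            raise ValueError(f"tokens {a} and {b} are not connected")
        out = [b]
        while out[-1] != a:
            out.append(prev[out[-1]])
        return out[::-1]


def _conllu_blocks(path: str | Path) -> Iterable[tuple[str | None, list[list[str]]]]:
    sent_id: str | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                if rows:
                    yield sent_id, rows
                sent_id, rows = None, []
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("sent_id"):
                    _, _, value = line.partition("=")
                    sent_id = value.strip()
                continue
            rows.append(line.split("\t"))
    if rows:
        yield sent_id, rows


def read_conllu(path: str | Path) -> list[DependencyTree]:
    """Read CoNLL-U sentence blocks into dependency trees.

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are
    skipped; labels (including subtypes like ``conj:and``) are preserved
    verbatim.  Multiple roots, cycles and out-of-range heads are errors.
    """
    return [t for _, t in read_conllu_indexed(path)]


def read_conllu_indexed(path: str | Path) -> list[tuple[str | None, DependencyTree]]:
    out: list[tuple[str | None, DependencyTree]] = []
    for sent_id, rows in _conllu_blocks(path):
        tokens: list[str] = []
        heads: list[int] = []
        labels: list[str] = []
        pos: list[str] = []
        for row in rows:
            if len(row) < 8:
                raise ValueError(f"{path}: short CoNLL-U row {row!r}")
            tid = row[0]
            if "-" in tid or "." in tid:
                continue
            tokens.append(row[1])
            pos.append(row[4] if row[4] != "_" else row[3])
            heads.append(int(row[6]) - 1)  # 1-based -> 0-based; 0 -> ROOT
            labels.append(row[7])
        out.append((sent_id, DependencyTree(tokens, heads, labels, pos)))
    return out


def write_conllu(path: str | Path, trees: Iterable[tuple[str, DependencyTree]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent_id, t in trees:
            fh.write(f"# sent_id = {sent_id}\n")
            for i, (tok, head, lab, pos) in enumerate(
                zip(t.tokens, t.heads, t.labels, t.pos)
            ):
                fh.write(
                    f"{i + 1}\t{tok}\t_\t{pos}\t{pos}\t_\t{head + 1}\t{lab}\t_\t_\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# provider


@dataclass
class ParsedSentence:
    sentence: AnnotatedSentence
    ctree: ConstituencyTree
    dtree: DependencyTree


def _check_alignment(sentence: AnnotatedSentence, ctree: ConstituencyTree,
                     dtree: DependencyTree) -> None:
    for name, toks in (("constituency", ctree.tokens()), ("dependency", dtree.tokens)):
        if toks != sentence.tokens:
            diverge = next(
                (i for i, (a, b) in enumerate(zip(toks, sentence.tokens)) if a != b),
                min(len(toks), len(sentence.tokens)),
            )
            raise ValueError(
                f"sentence {sentence.sentence_id!r}: {name} tree tokens diverge from "
                f"sentence tokens at index {diverge} "
                f"(tree has {len(toks)} tokens, sentence {len(sentence.tokens)})"
            )


class FixtureParseProvider:
    """Gold trees keyed by sentence_id, loaded from fixture files.

    ``trees.mrg`` holds one bracketed tree per line with ``# sent_id``
    comment lines above each tree; ``trees.conllu`` uses standard
    ``# sent_id =`` metadata.
    """

    def __init__(self, ctrees: dict[str, ConstituencyTree],
                 dtrees: dict[str, DependencyTree]):
        self.ctrees = ctrees
        self.dtrees = dtrees

    @classmethod
    def from_files(cls, mrg_path: str | Path, conllu_path: str | Path
                   ) -> "FixtureParseProvider":
        ctrees: dict[str, ConstituencyTree] = {}
        current_id: str | None = None
        with open(mrg_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "sent_id" in line:
                        _, _, value = line.partition("=")
                        current_id = value.strip()
                    continue
                if current_id is None:
                    raise ValueError(f"{mrg_path}:{lineno}: tree without sent_id")
                ctrees[current_id] = parse_bracketed(line, where=f"{mrg_path}:{lineno}")
                current_id = None
        dtrees: dict[str, DependencyTree] = {}
        for sent_id, tree in read_conllu_indexed(conllu_path):
            if sent_id is None:
                raise ValueError(f"{conllu_path}: CoNLL-U block without sent_id")
            dtrees[sent_id] = tree
        return cls(ctrees, dtrees)

    def provide(self, sentence: AnnotatedSentence) -> ParsedSentence:
        sid = sentence.sentence_id
        if sid not in self.ctrees or sid not in self.dtrees:
            raise KeyError(f"no fixture parse for sentence {sid!r}")
        ctree, dtree = self.ctrees[sid], self.dtrees[sid]
        _check_alignment(sentence, ctree, dtree)
        return ParsedSentence(sentence=sentence, ctree=ctree, dtree=dtree)


class AdapterParseProvider:
    """Parse provider backed by a caller-supplied parsing callable.

    The callable receives the token list and must return
    ``(ConstituencyTree, DependencyTree)``; alignment is verified here, a
    mismatch is an error rather than silent.
    """

    def __init__(self, parse_fn: Callable[[list[str]], tuple[ConstituencyTree, DependencyTree]]):
        self.parse_fn = parse_fn

    def provide(self, sentence: AnnotatedSentence) -> ParsedSentence:
        ctree, dtree = self.parse_fn(sentence.tokens)
        _check_alignment(sentence, ctree, dtree)
        return ParsedSentence(sentence=sentence, ctree=ctree, dtree=dtree)
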