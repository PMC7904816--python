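"""Dependency-tree relation-word extraction (DBE).

Relation words for a candidate microbe-disease pair are read off the
sentence's dependency tree in a fixed rule pipeline:

1. **chunk** — merge multiword relation units: for each ``word -(of|with)->
   entity`` preposition edge the governing word and its amod/compound
   modifiers collapse into one node (``common cause of DIS00sepsis`` ->
   node ``common_cause``); an entity linked to its parent by a
   ``compound`` edge is merged with the parent, the parent word kept as
   the chunk's relation candidate.
2. **filter** — drop pairs whose tree distance exceeds a threshold
   (default 4); edges labelled conj, conj:and, conj:or, compound or
   appos are free and do not count.
3. **prep rule** (PREP_SIMPLE) — entities directly linked through a
   listed connector (by, in, from, on, with, of, due_to, induced,
   between) yield the connector itself as the relation word.
4. **LCA rule** (LCA_CHILD / LCA_SELF_EDGE / NO_LCA_CHUNK) — the lowest
   common ancestor of the pair carries the relation: a child of the LCA
   attached by a descriptive edge (acl, acl:relcl, amod, xcomp, ccomp,
   appos, nmod:as, conj:and, conj:or, advcl, dep) if one exists, else
   the LCA's own word.  When an entity is itself the LCA the connecting
   edge label is emitted; when the chunked entity already carries a
   combined word, that word is used.
5. **inherit** (INHERIT) — entities of the same class chained by
   coordination/apposition/compound edges share relations: if sepsis and
   meningitis are conj:and-linked, a relation found for sepsis also
   holds for meningitis.

Relation words are emitted with their surface form; stemming happens
once, centrally, at the ensemble merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .ner import MICROBE, DISEASE, EntityMention
from .trees import DependencyTree, ParsedSentence, ROOT
from .triplets import DBE, RelationTriplet, dedupe

PREP_SIMPLE = "PREP_SIMPLE"
LCA_CHILD = "LCA_CHILD"
LCA_SELF_EDGE = "LCA_SELF_EDGE"
NO_LCA_CHUNK = "NO_LCA_CHUNK"
INHERIT = "INHERIT"

RULE_IDS = (PREP_SIMPLE, LCA_CHILD, LCA_SELF_EDGE, NO_LCA_CHUNK, INHERIT)

#: edges that do not count toward the pair distance
FREE_EDGES = frozenset({"conj", "conj:and", "conj:or", "compound", "appos"})

#: connectors of the simple effector-effected preposition rule
CONNECTORS = ("by", "in", "from", "on", "with", "of", "due_to", "induced", "between")

#: LCA child edges that carry a descriptive relation word, in priority order
LCA_CHILD_EDGES = (
    "acl", "acl:relcl", "amod", "xcomp", "ccomp", "appos",
    "nmod:as", "conj:and", "conj:or", "advcl", "dep",
)

#: edges along which same-class entities inherit relations
INHERIT_EDGES = frozenset({"conj", "conj:and", "conj:or", "appos", "compound"})

_CHUNK_PREPS = ("of", "with")
_MODIFIER_EDGES = frozenset({"amod", "compound"})


@dataclass
class ChunkNode:
    """A node of the chunked tree: one or more original token indices."""

    indices: tuple[int, ...]  # original token indices, sentence order
    word: str  # merged surface, underscore-joined
    entity_index: int | None = None  # original index of the entity token, if any
    combined_word: str | None = None  # non-entity words merged with an entity


@dataclass
class ChunkedTree:
    dtree: DependencyTree  # original tree (kept for reference)
    nodes: list[ChunkNode]
    heads: list[int]  # head chunk index per chunk; ROOT for the root chunk
    labels: list[str]
    node_of_token: dict[int, int] = field(default_factory=dict)

    @property
    def chunk_map(self) -> dict[int, tuple[int, ...]]:
        return {i: n.indices for i, n in enumerate(self.nodes)}

    def children(self, i: int) -> list[tuple[int, str]]:
        return [(j, self.labels[j]) for j, h in enumerate(self.heads) if h == i]

    def path(self, a: int, b: int) -> list[int]:
        if a == b:
            return [a]
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for i, h in enumerate(self.heads):
            if h != ROOT:
                adj[i].append(h)
                adj[h].append(i)
        prev = {a: a}
        frontier = [a]
        while frontier and b not in prev:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in prev:
                        prev[v] = u
                        nxt.append(v)
            frontier = nxt
        if b not in prev:
            raise ValueError("entities not connected in chunked tree")
        out = [b]
        while out[-1] != a:
            out.append(prev[out[-1]])
        return out[::-1]

    def edge_label(self, a: int, b: int) -> str:
        """Label of the edge between adjacent chunks a and b."""
        if self.heads[a] == b:
            return self.labels[a]
        if self.heads[b] == a:
            return self.labels[b]
        raise ValueError(f"chunks {a} and {b} are not adjacent")

    def ancestors(self, i: int) -> list[int]:
        out = []
        j = self.heads[i]
        while j != ROOT:
            out.append(j)
            j = self.heads[j]
        return out


def _is_entity_token(token: str) -> bool:
    return token.startswith("BAC00") or token.startswith("DIS00")


def chunk(dtree: DependencyTree, mentions: list[EntityMention]) -> ChunkedTree:
    """Apply the two chunk merges; merges are applied innermost-first.

    Group merging uses union-find over original token indices; contracting
    connected token groups of a tree preserves acyclicity and
    single-headedness by construction.
    """
    n = len(dtree.tokens)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    entity_tokens = {m.index for m in mentions}
    combined: dict[int, list[int]] = {}  # entity token -> merged word tokens

    # rule 1: word -(of|with)-> entity  =>  merge word with its modifiers
    # (innermost-first: deeper governors first)
    depth = [len(_token_ancestors(dtree, i)) for i in range(n)]
    governors = []
    for ent in sorted(entity_tokens):
        head = dtree.heads[ent]
        if head == ROOT:
            continue
        label = dtree.labels[ent]
        if any(label == f"nmod:{p}" or label == f"obl:{p}" for p in _CHUNK_PREPS):
            governors.append((depth[head], head))
    for _, gov in sorted(governors, reverse=True):
        for child in dtree.children(gov):
            if dtree.labels[child] in _MODIFIER_EDGES and child not in entity_tokens:
                union(gov, child)

    # rule 2: compound edge between an entity and its parent
    for ent in sorted(entity_tokens):
        head = dtree.heads[ent]
        if head != ROOT and dtree.labels[ent] == "compound" and head not in entity_tokens:
            union(ent, head)
            combined.setdefault(ent, []).append(head)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    ordered = sorted(groups.values(), key=min)
    node_of_token: dict[int, int] = {}
    nodes: list[ChunkNode] = []
    for gi, idxs in enumerate(ordered):
        idxs = sorted(idxs)
        ents = [i for i in idxs if i in entity_tokens]
        entity_index = ents[0] if ents else None
        non_entity = [i for i in idxs if i not in entity_tokens]
        if entity_index is not None:
            word = dtree.tokens[entity_index]
            comb = "_".join(dtree.tokens[i] for i in non_entity) or None
        else:
            word = "_".join(dtree.tokens[i] for i in idxs)
            comb = None
        nodes.append(ChunkNode(indices=tuple(idxs), word=word,
                               entity_index=entity_index, combined_word=comb))
        for i in idxs:
            node_of_token[i] = gi

    heads: list[int] = []
    labels: list[str] = []
    for gi, node in enumerate(nodes):
        head_chunk = ROOT
        label = "root"
        for i in node.indices:
            h = dtree.heads[i]
            if h == ROOT:
                head_chunk, label = ROOT, "root"
                break
            hc = node_of_token[h]
            if hc != gi:
                head_chunk, label = hc, dtree.labels[i]
                break
        heads.append(head_chunk)
        labels.append(label)

    return ChunkedTree(dtree=dtree, nodes=nodes, heads=heads, labels=labels,
                       node_of_token=node_of_token)


def _token_ancestors(dtree: DependencyTree, i: int) -> list[int]:
    out = []
    j = dtree.heads[i]
    while j != ROOT:
        out.append(j)
        j = dtree.heads[j]
    return out


@dataclass(frozen=True)
class DepPair:
    """A microbe-disease pair located in a chunked tree."""

    sentence_id: str
    microbe: EntityMention
    disease: EntityMention
    microbe_node: int
    disease_node: int


def enumerate_dep_pairs(sentence_id: str, ctree: ChunkedTree,
                        mentions: list[EntityMention]) -> list[DepPair]:
    microbes = [m for m in mentions if m.entity_class == MICROBE]
    diseases = [m for m in mentions if m.entity_class == DISEASE]
    return [
        DepPair(
            sentence_id=sentence_id,
            microbe=m,
            disease=d,
            microbe_node=ctree.node_of_token[m.index],
            disease_node=ctree.node_of_token[d.index],
        )
        for m, d in product(microbes, diseases)
    ]


def tree_distance(pair: DepPair, ctree: ChunkedTree) -> int:
    """Path length between the entity chunks, free edges not counted."""
    path = ctree.path(pair.microbe_node, pair.disease_node)
    dist = 0
    for a, b in zip(path, path[1:]):
        if ctree.edge_label(a, b) not in FREE_EDGES:
            dist += 1
    return dist


def filter_pairs(pairs: list[DepPair], ctree: ChunkedTree,
                 max_distance: int = 4) -> list[DepPair]:
    return [p for p in pairs if tree_distance(p, ctree) <= max_distance]


def _connector_of(label: str) -> str | None:
    """Connector encoded in an nmod/obl edge subtype, if listed."""
    if ":" not in label:
        return None
    base, _, sub = label.partition(":")
    if base not in ("nmod", "obl"):
        return None
    return sub if sub in CONNECTORS else None


def _make_triplet(pair: DepPair, relation: str, rule: str) -> RelationTriplet:
    return RelationTriplet(
        sentence_id=pair.sentence_id,
        microbe=pair.microbe.canonical,
        disease=pair.disease.canonical,
        relation=relation,
        extractor=DBE,
        pattern_ids=(rule,),
    )


def prep_relation(pair: DepPair, ctree: ChunkedTree) -> RelationTriplet | None:
    """Simple effector-effected rule: entities linked by a listed connector."""
    a, b = pair.microbe_node, pair.disease_node
    path = ctree.path(a, b)
    if len(path) == 2:
        conn = _connector_of(ctree.edge_label(path[0], path[1]))
        if conn is not None:
            return _make_triplet(pair, conn, PREP_SIMPLE)
    # "induced" as a modifier on either entity ("DIS00X induced by BAC00Y")
    for node in (a, b):
        for child, label in ctree.children(node):
            if label == "amod" and ctree.nodes[child].word.lower() == "induced":
                return _make_triplet(pair, "induced", PREP_SIMPLE)
    return None


def lca(ctree: ChunkedTree, a: int, b: int) -> int:
    """Lowest common ancestor of chunks a and b (a node may be its own)."""
    anc_a = [a] + ctree.ancestors(a)
    anc_b = set([b] + ctree.ancestors(b))
    for node in anc_a:
        if node in anc_b:
            return node
    raise ValueError("no common ancestor (forest input)")


def lca_relation(pair: DepPair, ctree: ChunkedTree,
                 child_edges: tuple[str, ...] = LCA_CHILD_EDGES) -> RelationTriplet:
    """Relation word from the LCA subtree of the pair.

    A descriptive child of the LCA wins if one exists; candidate children
    are ranked by the priority order of ``child_edges`` (then by token
    position), which keeps e.g. an acl participle ahead of an incidental
    amod on the same head.
    """
    node = lca(ctree, pair.microbe_node, pair.disease_node)
    entity_nodes = {pair.microbe_node, pair.disease_node}
    if node in entity_nodes:
        if ctree.nodes[node].combined_word:
            # the entity was chunk-combined with a word; that word is the relation
            return _make_triplet(pair, ctree.nodes[node].combined_word, NO_LCA_CHUNK)
        other = (entity_nodes - {node}).pop() if len(entity_nodes) == 2 else node
        path = ctree.path(node, other)
        label = ctree.edge_label(path[0], path[1]) if len(path) > 1 else "self"
        return _make_triplet(pair, label, LCA_SELF_EDGE)
    best: tuple[int, int, int] | None = None  # (priority, position, child)
    for child, label in ctree.children(node):
        if child in entity_nodes or label not in child_edges:
            continue
        rank = (child_edges.index(label), ctree.nodes[child].indices[0], child)
        if best is None or rank < best:
            best = rank
    if best is not None:
        return _make_triplet(pair, ctree.nodes[best[2]].word, LCA_CHILD)
    return _make_triplet(pair, ctree.nodes[node].word, LCA_CHILD)


def inherit(pairs: list[DepPair], ctree: ChunkedTree,
            extracted: list[RelationTriplet]) -> list[RelationTriplet]:
    """Propagate relations along same-class coordination chains.

    Entity chunks of the same class connected (in either direction,
    transitively) by conj/conj:and/conj:or/appos/compound edges form a
    component; a relation held by any member is inherited by all.
    """
    mention_by_node: dict[int, EntityMention] = {}
    for p in pairs:
        mention_by_node[p.microbe_node] = p.microbe
        mention_by_node[p.disease_node] = p.disease
    # components over entity nodes linked by inherit edges
    comp: dict[int, int] = {n: n for n in mention_by_node}

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for node, mention in mention_by_node.items():
        head = ctree.heads[node]
        if (
            head in mention_by_node
            and ctree.labels[node] in INHERIT_EDGES
            and mention_by_node[head].entity_class == mention.entity_class
        ):
            comp[find(node)] = find(head)

    members: dict[int, list[int]] = {}
    for n in mention_by_node:
        members.setdefault(find(n), []).append(n)

    by_canonical: dict[tuple[str, str], list[int]] = {}
    for n, m in mention_by_node.items():
        by_canonical.setdefault((m.entity_class, m.canonical), []).append(n)

    pair_index = {(p.microbe.canonical, p.disease.canonical): p for p in pairs}
    out: list[RelationTriplet] = []
    for t in extracted:
        for cls, canonical, other in (
            (MICROBE, t.microbe, t.disease),
            (DISEASE, t.disease, t.microbe),
        ):
            for node in by_canonical.get((cls, canonical), ()):
                for sibling in members.get(find(node), ()):
                    sib_mention = mention_by_node[sibling]
                    if sib_mention.entity_class != cls:
                        continue
                    if sib_mention.canonical == canonical:
                        continue
                    if cls == MICROBE:
                        key = (sib_mention.canonical, other)
                    else:
                        key = (other, sib_mention.canonical)
                    p = pair_index.get(key)
                    if p is not None:
                        out.append(_make_triplet(p, t.relation, INHERIT))
    return out


def extract_triplets(
    sentence: ParsedSentence,
    max_distance: int = 4,
    child_edges: tuple[str, ...] = LCA_CHILD_EDGES,
    enable_inherit: bool = True,
) -> list[RelationTriplet]:
    """Full DBE pipeline: chunk -> filter -> prep -> LCA -> inherit."""
    mentions = sentence.sentence.mentions
    ctree = chunk(sentence.dtree, mentions)
    pairs = enumerate_dep_pairs(sentence.sentence.sentence_id, ctree, mentions)
    pairs = filter_pairs(pairs, ctree, max_distance=max_distance)
    extracted: list[RelationTriplet] = []
    for pair in pairs:
        prep = prep_relation(pair, ctree)
        if prep is not None:
            extracted.append(prep)
        extracted.append(lca_relation(pair, ctree, child_edges=child_edges))
    if enable_inherit:
        extracted = extracted + inherit(pairs, ctree, extracted)
    return dedupe(extracted)
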