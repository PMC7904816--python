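"""Corpus-wide aggregation and the disease-similarity network.

Extracted triplets are aggregated into (microbe, disease) association
records with extraction counts and the bag of relation words.  Two
reliability filters follow: records whose disease is an excluded generic
term (by default "infection") are dropped, then records whose count
falls below the mean count of the remaining records are dropped — the
mean is always computed from the data at hand, never hard-coded.

From the filtered table each disease gets its set of associated
microbes; disease pairs sharing at least ``min_shared`` microbes
(default 2) receive a Jaccard similarity |A∩B| / |A∪B|, and pairs at or
above a threshold (default 0.6) form the disease-disease network, with
node size the number of associated microbes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .stem import stem
from .triplets import RelationTriplet


@dataclass
class AssociationRecord:
    microbe: str
    disease: str
    count: int
    relation_words: dict[str, int] = field(default_factory=dict)


@dataclass
class AssociationTable:
    records: list[AssociationRecord]
    category_map: dict[str, str] = field(default_factory=dict)

    def mean_count(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.count for r in self.records) / len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["microbe", "disease", "count", "relation_words", "category"])
            for r in sorted(self.records, key=lambda r: (-r.count, r.microbe, r.disease)):
                words = ",".join(f"{w}:{c}" for w, c in sorted(r.relation_words.items()))
                writer.writerow([r.microbe, r.disease, r.count, words,
                                 self.category_map.get(r.disease, "")])


def load_category_map(path: str | Path) -> dict[str, str]:
    """2-column TSV: disease canonical name -> top-level category label."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            disease, _, category = line.partition("\t")
            out[disease.strip()] = category.strip()
    return out


def aggregate(triplets: Iterable[RelationTriplet],
              category_map: dict[str, str] | None = None) -> AssociationTable:
    """Count extracted relations per (microbe, disease)."""
    counts: dict[tuple[str, str], AssociationRecord] = {}
    for t in triplets:
        key = (t.microbe, t.disease)
        rec = counts.get(key)
        if rec is None:
            rec = counts[key] = AssociationRecord(t.microbe, t.disease, 0)
        rec.count += 1
        word = stem(t.relation)
        rec.relation_words[word] = rec.relation_words.get(word, 0) + 1
    return AssociationTable(records=sorted(counts.values(),
                                           key=lambda r: (r.microbe, r.disease)),
                            category_map=dict(category_map or {}))


def apply_filters(table: AssociationTable,
                  exclude_terms: Iterable[str] = ("infection",),
                  min_count: float | None = None) -> AssociationTable:
    """Drop excluded-disease records, then below-mean-frequency records.

    Order is fixed: exclusion first, then the mean is computed over what
    remains.  ``min_count`` overrides the computed mean when given.
    Records with count strictly below the threshold are dropped.
    """
    excluded = {e.lower() for e in exclude_terms}
    kept = [r for r in table.records if r.disease.lower() not in excluded]
    threshold = min_count if min_count is not None else (
        sum(r.count for r in kept) / len(kept) if kept else 0.0)
    kept = [r for r in kept if r.count >= threshold]
    return AssociationTable(records=kept, category_map=table.category_map)


@dataclass(frozen=True)
class DiseaseSimilarityEdge:
    disease_a: str
    disease_b: str
    shared: frozenset[str]
    jaccard: float


def microbe_sets(table: AssociationTable) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in table.records:
        out.setdefault(r.disease, set()).add(r.microbe)
    return out


def jaccard(table: AssociationTable, min_shared: int = 2,
            min_microbes_per_disease: int | None = None
            ) -> list[DiseaseSimilarityEdge]:
    """Jaccard similarity for disease pairs sharing >= min_shared microbes.

    ``min_microbes_per_disease`` optionally also removes diseases with
    fewer associated microbes before pairing (the alternative reading of
    the single-common-bacterium exclusion); off by default.
    """
    sets = microbe_sets(table)
    if min_microbes_per_disease:
        sets = {d: s for d, s in sets.items() if len(s) >= min_microbes_per_disease}
    edges: list[DiseaseSimilarityEdge] = []
    for a, b in combinations(sorted(sets), 2):
        inter = sets[a] & sets[b]
        if len(inter) < min_shared:
            continue
        union = sets[a] | sets[b]
        edges.append(DiseaseSimilarityEdge(
            disease_a=a, disease_b=b, shared=frozenset(inter),
            jaccard=len(inter) / len(union)))
    return edges


def build_network(edges: Sequence[DiseaseSimilarityEdge],
                  table: AssociationTable | None = None,
                  threshold: float = 0.6) -> nx.Graph:
    """Graph of disease pairs with similarity >= threshold.

    Node attribute ``n_microbes`` (node size) is the number of microbes
    associated with the disease in the filtered table; edge weight is
    the Jaccard similarity.
    """
    graph = nx.Graph()
    sets = microbe_sets(table) if table is not None else {}
    for e in sorted(edges, key=lambda e: (e.disease_a, e.disease_b)):
        if e.jaccard < threshold:
            continue
        for d in (e.disease_a, e.disease_b):
            if d not in graph:
                graph.add_node(d, n_microbes=len(sets.get(d, e.shared)))
        graph.add_edge(e.disease_a, e.disease_b, weight=e.jaccard,
                       shared=",".join(sorted(e.shared)))
    return graph


def write_network(graph: nx.Graph, out_prefix: str | Path) -> None:
    """GraphML plus a deterministic edge-list TSV."""
    prefix = Path(out_prefix)
    nx.write_graphml(graph, prefix.with_suffix(".graphml"))
    with open(prefix.with_suffix(".edges.tsv"), "w", encoding="utf-8") as fh:
        fh.write("disease_a\tdisease_b\tjaccard\tshared_microbes\n")
        for a, b in sorted(graph.edges):
            d = graph.edges[a, b]
            fh.write(f"{a}\t{b}\t{d['weight']:.4f}\t{d['shared']}\n")
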