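"""Anatomy-ontology parsing, semantic similarity, and term dendrograms.

An anatomy ontology (OBO flat file) relates terms by typed edges such as
``is_a`` and ``part_of``.  Semantic similarity between two terms is measured
either by Jaccard overlap of their ancestor closures (edge-based) or by the
Resnik information content of their most informative common ancestor
(node-based, with the character-annotation table as the IC corpus).
Similarities are converted to distances and clustered (UPGMA by default)
into a dendrogram of terms; the same clustering applied to a pairwise
phylogenetic-dissonance matrix yields the dissonance dendrogram that is
contrasted with ontology structure to test for semantic signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .infotheory import dissonance
from .treeio import TreeSample

__all__ = [
    "TermGraph",
    "AnnotationTable",
    "SubsetSpec",
    "Dendrogram",
    "DEFAULT_RELATIONS",
    "parse_obo",
    "ancestors",
    "jaccard_sim",
    "resnik_sim",
    "similarity_matrix",
    "cluster_dendrogram",
    "dissonance_dendrogram",
    "terms_under",
]

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class TermGraph:
    """Ontology terms and typed child -> parent relations."""

    names: dict[str, str]
    edges: set[tuple[str, str, str]]  # (child, parent, relation)
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for child, parent, _rel in self.edges:
            for t in (child, parent):
                if t not in self.names:
                    raise ValueError(f"edge endpoint {t!r} is not a known term")

    @property
    def terms(self) -> set[str]:
        return set(self.names)

    def parents(self, term: str, relations: Iterable[str]) -> set[str]:
        rels = set(relations)
        return {p for c, p, r in self.edges
                if c == term and r in rels and p not in self.obsolete}

    def check_acyclic(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> None:
        g = nx.DiGraph((c, p) for c, p, r in self.edges if r in set(relations))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology relation graph contains a cycle")


def parse_obo(path_or_file) -> TermGraph:
    """Read an OBO 1.2/1.4 flat file into a TermGraph.

    ``is_a`` and ``relationship:`` edges are typed; obsolete terms are
    flagged and excluded from closures.
    """
    g = obonet.read_obo(path_or_file, ignore_obsolete=False)
    names: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    obsolete: set[str] = set()
    for node, data in g.nodes(data=True):
        names[node] = data.get("name", node)
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(node)
    for child, parent, rel in g.edges(keys=True):
        edges.add((child, parent, rel))
    tg = TermGraph(names=names, edges=edges, obsolete=obsolete)
    tg.check_acyclic()
    return tg


@dataclass
class AnnotationTable:
    """Character index (0-based matrix column) -> set of ontology term ids."""

    rows: dict[int, set[str]]

    def validate(self, graph: TermGraph, n_chars: int | None = None) -> None:
        for idx, terms in self.rows.items():
            if n_chars is not None and not 0 <= idx < n_chars:
                raise ValueError(f"character index {idx} out of matrix bounds")
            unknown = terms - graph.terms
            if unknown:
                raise ValueError(f"unknown terms for character {idx}: {sorted(unknown)}")

    def characters_of(self, term: str) -> set[int]:
        return {i for i, terms in self.rows.items() if term in terms}

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        """Read columns character_index, term_id[, term_label] (with header)."""
        rows: dict[int, set[str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ci, ti = header.index("character_index"), header.index("term_id")
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                rows.setdefault(int(fields[ci]), set()).add(fields[ti])
        return cls(rows)

    def to_tsv(self, path, graph: TermGraph | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("character_index\tterm_id\tterm_label\n")
            for idx in sorted(self.rows):
                for term in sorted(self.rows[idx]):
                    label = graph.names.get(term, "") if graph else ""
                    fh.write(f"{idx}\t{term}\t{label}\n")


@dataclass(frozen=True)
class SubsetSpec:
    """A named group of character columns (one analysis unit)."""

    subset_id: str
    label: str
    characters: tuple[int, ...]
    mode: str = "ALL"  # ALL | PROFILE | RESAMPLED
    group: str = ""    # profile group name, when mode == PROFILE

    def __post_init__(self) -> None:
        chars = tuple(sorted(set(self.characters)))
        if not chars:
            raise ValueError(f"subset {self.subset_id!r} has no characters")
        object.__setattr__(self, "characters", chars)


def ancestors(graph: TermGraph, term: str,
              relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
    """Reflexive transitive closure of ``term`` over the chosen relations."""
    if term not in graph.names:
        raise KeyError(f"unknown term {term!r}")
    rels = set(relations)
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in graph.parents(t, rels):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def jaccard_sim(graph: TermGraph, t1: str, t2: str,
                relations: Iterable[str] = DEFAULT_RELATIONS) -> float:
    """|anc(t1) & anc(t2)| / |anc(t1) | anc(t2)| over reflexive closures."""
    a1, a2 = ancestors(graph, t1, relations), ancestors(graph, t2, relations)
    return len(a1 & a2) / len(a1 | a2)


def _descendant_counts(graph: TermGraph, annotations: AnnotationTable,
                       relations: Iterable[str]) -> tuple[dict[str, int], int]:
    """Characters annotated to each term or any of its descendants."""
    chars_of: dict[str, set[int]] = {t: set() for t in graph.terms}
    all_chars: set[int] = set()
    for idx, terms in annotations.rows.items():
        all_chars.add(idx)
        for t in terms:
            for a in ancestors(graph, t, relations):
                chars_of[a].add(idx)
    return {t: len(cs) for t, cs in chars_of.items()}, len(all_chars)


def resnik_sim(graph: TermGraph, annotations: AnnotationTable,
               t1: str, t2: str,
               relations: Iterable[str] = DEFAULT_RELATIONS) -> float:
    """IC of the most informative common ancestor; IC(a) = -ln(n_a / N)
    with the annotation table as corpus.  0 when no common ancestor carries
    any annotation."""
    counts, N = _descendant_counts(graph, annotations, relations)
    if N == 0:
        raise ValueError("empty annotation corpus")
    common = ancestors(graph, t1, relations) & ancestors(graph, t2, relations)
    ics = [-math.log(counts[a] / N) for a in common if counts.get(a, 0) > 0]
    return max(ics, default=0.0)


def similarity_matrix(graph: TermGraph, terms: Sequence[str], *,
                      metric: str = "jaccard",
                      annotations: AnnotationTable | None = None,
                      relations: Iterable[str] = DEFAULT_RELATIONS,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise similarity and distance matrices for a list of terms.

    Distance is 1 - s/s_max with s_max = 1 for Jaccard and the maximum
    observed IC for Resnik.  Returns (similarity, distance).
    """
    if len(terms) < 2:
        raise ValueError("need at least two terms")
    m = len(terms)
    S = np.zeros((m, m))
    if metric == "jaccard":
        for i in range(m):
            for j in range(i, m):
                S[i, j] = S[j, i] = jaccard_sim(graph, terms[i], terms[j],
                                                relations)
        smax = 1.0
    elif metric == "resnik":
        if annotations is None:
            raise ValueError("resnik similarity needs an annotation corpus")
        counts, N = _descendant_counts(graph, annotations, relations)
        closures = {t: ancestors(graph, t, relations) for t in terms}
        for i in range(m):
            for j in range(i, m):
                common = closures[terms[i]] & closures[terms[j]]
                ics = [-math.log(counts[a] / N) for a in common
                       if counts.get(a, 0) > 0]
                S[i, j] = S[j, i] = max(ics, default=0.0)
        smax = float(S.max())
        if smax == 0.0:
            smax = 1.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    D = 1.0 - S / smax
    np.fill_diagonal(D, 0.0)
    return S, D


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labels, from a scipy linkage matrix."""

    labels: list[str]
    linkage: np.ndarray  # scipy (m-1, 4) linkage

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("non-monotone linkage heights")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def internal_nodes(self) -> list[tuple[float, frozenset[str]]]:
        """(height, subtended leaf labels) for each merge, leaf-most first."""
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        out = []
        m = self.n_leaves
        for k, (a, b, h, _cnt) in enumerate(self.linkage):
            mem = members[int(a)] | members[int(b)]
            members[m + k] = mem
            out.append((float(h), mem))
        return out

    def newick(self) -> str:
        node = hierarchy.to_tree(self.linkage)

        def quote(label: str) -> str:
            if any(c in label for c in "():,;[] '\t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(nd) -> str:
            if nd.is_leaf():
                return quote(self.labels[nd.id])
            h = nd.dist
            l, r = nd.left, nd.right
            return (f"({render(l)}:{h - l.dist:.6g},"
                    f"{render(r)}:{h - r.dist:.6g})")

        return render(node) + ";"


def cluster_dendrogram(distances: np.ndarray, labels: Sequence[str], *,
                       linkage: str = "average") -> Dendrogram:
    """UPGMA (default) or other agglomerative clustering of a symmetric
    zero-diagonal distance matrix.  Labels are sorted first so ties break
    deterministically by label order."""
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] != distances.shape[1] or len(labels) != distances.shape[0]:
        raise ValueError("distance matrix / labels shape mismatch")
    if np.isnan(distances).any():
        raise ValueError("NaN distances")
    if not np.allclose(distances, distances.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    order = np.argsort(np.asarray(labels, dtype=object))
    labs = [labels[i] for i in order]
    D = distances[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(labels=labs, linkage=Z)


def dissonance_dendrogram(dists: Mapping[str, TreeSample], *,
                          linkage: str = "average",
                          denominator: str = "merged",
                          ) -> tuple[Dendrogram, np.ndarray, list[str]]:
    """Cluster subsets by pairwise phylogenetic dissonance (percent scale).

    Returns the dendrogram plus the pairwise D% matrix and its label order.
    """
    labels = sorted(dists)
    if len(labels) < 2:
        raise ValueError("need at least two subsets")
    m = len(labels)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r = dissonance([dists[labels[i]], dists[labels[j]]],
                           denominator=denominator)
            D[i, j] = D[j, i] = r.dissonance_pct
    return cluster_dendrogram(D, labels, linkage=linkage), D, labels


def terms_under(graph: TermGraph, query: str,
                relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
    """All terms whose relation-closure contains ``query`` (query included)."""
    if query not in graph.names:
        raise KeyError(f"unknown term {query!r}")
    return {t for t in graph.terms - graph.obsolete
            if query in ancestors(graph, t, relations)}
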