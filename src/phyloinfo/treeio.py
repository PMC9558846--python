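"""Tree input/output and canonical unrooted topologies.

All downstream statistics (information content, coverage, dissonance) are
defined over *unrooted, fully resolved tree topologies*: branch lengths,
rootings, and rotation order are irrelevant.  A topology is therefore reduced
to its set of non-trivial bipartitions (splits), each encoded as a bitmask
over the canonical (sorted) taxon order, normalized to the side that contains
the first taxon.  The resulting split set gives a stable identity usable as a
dictionary key across samples, runs, and file formats.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "Topology",
    "TreeSample",
    "PolytomyError",
    "parse_newick",
    "parse_newick_list",
    "parse_mrbayes_t",
    "write_mrbayes_t",
    "count_topologies",
    "enumerate_topologies",
    "random_topology",
]


class PolytomyError(ValueError):
    """Raised when a multifurcating topology is rejected."""


@dataclass(frozen=True)
class TaxonSet:
    """Ordered set of unique taxon names; order is sorted label order."""

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        object.__setattr__(self, "labels", tuple(sorted(labels)))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index(lab)
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        return tuple(l for i, l in enumerate(self.labels) if mask >> i & 1)


def _normalize_split(mask: int, full: int) -> int:
    # store the side containing taxon 0 (bit 0)
    return mask if mask & 1 else full ^ mask


@dataclass(frozen=True)
class Topology:
    """Canonical unrooted topology: a compatible set of non-trivial splits.

    ``splits`` holds one bitmask per internal edge, always the side that
    contains the canonically first taxon.  A fully resolved topology on n
    taxa has exactly n - 3 splits; fewer indicates polytomies.
    """

    taxa: TaxonSet
    splits: frozenset[int]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def is_resolved(self) -> bool:
        return len(self.splits) == self.n_taxa - 3

    @property
    def id(self) -> str:
        key = (",".join(self.taxa.labels) + "|" +
               ",".join(str(s) for s in sorted(self.splits)))
        return hashlib.blake2b(key.encode(), digest_size=12).hexdigest()

    def clades(self) -> list[int]:
        """Clades of the tree rooted at the first taxon, largest first.

        Each split's taxon-0-free side is a clade; the root clade is the
        full set minus taxon 0.  Singletons are omitted.
        """
        full = self.taxa.full_mask
        out = {full ^ 1}
        for s in self.splits:
            out.add(full ^ s)
        return sorted(out, key=lambda m: (-m.bit_count(), m))

    def child_splits(self) -> dict[int, tuple[int, ...]]:
        """Map each clade (rooted at taxon 0) to its tuple of child clades.

        For resolved topologies every clade of size >= 2 has exactly two
        children (singletons included as children).
        """
        clades = self.clades()
        singles = [1 << i for i in range(1, self.n_taxa)]
        nodes = clades + singles
        out: dict[int, tuple[int, ...]] = {}
        for c in clades:
            rem = c
            kids = []
            for d in nodes:  # size-descending => maximal proper subsets first
                if d != c and d & rem == d:
                    kids.append(d)
                    rem ^= d
                    if rem == 0:
                        break
            out[c] = tuple(sorted(kids))
        return out

    def newick(self) -> str:
        """Unrooted Newick string with sorted-rotation (deterministic)."""
        kids = self.child_splits()

        def render(mask: int) -> str:
            if mask.bit_count() == 1:
                return self.taxa.labels[mask.bit_length() - 1]
            return "(" + ",".join(render(k) for k in kids[mask]) + ")"

        root = self.taxa.full_mask ^ 1
        parts = [self.taxa.labels[0]] + [render(k) for k in kids[root]]
        return "(" + ",".join(parts) + ");"


@dataclass
class TreeSample:
    """Ordered sample of topologies from one MCMC run (or synthetic draw)."""

    topologies: list[Topology]
    run_id: str = "run"
    subset_id: str = ""
    burnin_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.topologies:
            raise ValueError("empty tree sample")
        taxa = self.topologies[0].taxa
        if any(t.taxa != taxa for t in self.topologies):
            raise ValueError("mixed taxon sets in sample")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")

    def __len__(self) -> int:
        return len(self.topologies)

    @property
    def taxa(self) -> TaxonSet:
        return self.topologies[0].taxa

    def burned_in(self) -> "TreeSample":
        """Drop the first ceil(burnin * N) topologies."""
        drop = math.ceil(self.burnin_fraction * len(self.topologies))
        kept = self.topologies[drop:]
        if not kept:
            raise ValueError("no trees left after burn-in")
        return TreeSample(kept, run_id=self.run_id, subset_id=self.subset_id,
                          burnin_fraction=0.0)


def _topology_from_dendropy(tree: dendropy.Tree,
                            taxa: TaxonSet | None,
                            allow_polytomies: bool) -> Topology:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if taxa is None:
        taxa = TaxonSet(leaves)
    elif sorted(leaves) != list(taxa.labels):
        raise ValueError("tree leaf set does not match the given TaxonSet")
    full = taxa.full_mask
    masks: dict[int, int] = {}
    splits: set[int] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = 1 << taxa.index(node.taxon.label)
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[id(ch)]
            masks[id(node)] = m
            if node.parent_node is not None:
                if 2 <= m.bit_count() <= len(taxa) - 2:
                    splits.add(_normalize_split(m, full))
    topo = Topology(taxa, frozenset(splits))
    if not topo.is_resolved and not allow_polytomies:
        raise PolytomyError(
            f"topology has {len(splits)} splits, expected {len(taxa) - 3}; "
            "pass allow_polytomies=True to accept")
    return topo


def parse_newick(text: str, taxa: TaxonSet | None = None, *,
                 allow_polytomies: bool = False) -> Topology:
    """Parse a single Newick string into a canonical unrooted Topology.

    Branch lengths and internal labels are discarded; rooted inputs are
    unrooted (the degree-2 root is suppressed implicitly by the split
    encoding).
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except ValueError:
        raise
    except Exception as exc:  # dendropy parse errors are not ValueErrors
        raise ValueError(f"invalid Newick: {exc}") from exc
    return _topology_from_dendropy(tree, taxa, allow_polytomies)


def parse_newick_list(text: str, taxa: TaxonSet | None = None, *,
                      run_id: str = "run", subset_id: str = "",
                      burnin: float = 0.0,
                      allow_polytomies: bool = False) -> TreeSample:
    """Parse one-tree-per-line Newick text into a TreeSample (burn-in applied)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    topos = []
    for ln in lines:
        t = parse_newick(ln, taxa, allow_polytomies=allow_polytomies)
        taxa = t.taxa
        topos.append(t)
    sample = TreeSample(topos, run_id=run_id, subset_id=subset_id,
                        burnin_fraction=burnin)
    return sample.burned_in()


def parse_mrbayes_t(path, burnin: float = 0.25, *,
                    taxa: TaxonSet | None = None,
                    run_id: str | None = None, subset_id: str = "",
                    allow_polytomies: bool = False) -> TreeSample:
    """Read a NEXUS tree file (MrBayes ``.t`` dialect with translate table).

    The first ceil(burnin * N) trees are discarded; the remainder keep their
    sample order.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="nexus",
                                  preserve_underscores=True)
    if len(trees) == 0:
        raise ValueError(f"no trees in {path}")
    topos = [_topology_from_dendropy(t, taxa, allow_polytomies) for t in trees]
    taxa0 = topos[0].taxa
    if any(t.taxa != taxa0 for t in topos):
        raise ValueError("mixed taxon sets in tree file")
    if run_id is None:
        run_id = str(path)
    sample = TreeSample(topos, run_id=run_id, subset_id=subset_id,
                        burnin_fraction=burnin)
    return sample.burned_in()


def write_mrbayes_t(sample: TreeSample, path) -> None:
    """Write a TreeSample as a MrBayes-style NEXUS tree file with translate table."""
    taxa = sample.taxa
    buf = io.StringIO()
    buf.write("#NEXUS\n[ID: phyloinfo]\nbegin trees;\n   translate\n")
    for i, lab in enumerate(taxa.labels):
        sep = "," if i < len(taxa) - 1 else ";"
        buf.write(f"      {i + 1} {lab}{sep}\n")
    index = {lab: str(i + 1) for i, lab in enumerate(taxa.labels)}
    for g, topo in enumerate(sample.topologies):
        nwk = topo.newick()
        # leaf labels -> translate numbers (labels never contain (),;: here)
        out = []
        tok = ""
        for ch in nwk:
            if ch in "(),;":
                if tok:
                    out.append(index.get(tok, tok))
                    tok = ""
                out.append(ch)
            else:
                tok += ch
        buf.write(f"   tree gen.{g + 1} = [&U] {''.join(out)}\n")
    buf.write("end;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def count_topologies(n: int) -> int:
    """Number of unrooted fully resolved labeled topologies: (2n-5)!!."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    out = 1
    for k in range(1, 2 * n - 4, 2):
        out *= k
    return out


def _grow(edges: list[tuple[int, int]], new_leaf: int,
          next_internal: int) -> Iterator[list[tuple[int, int]]]:
    for i, (a, b) in enumerate(edges):
        yield (edges[:i] + edges[i + 1:] +
               [(a, next_internal), (next_internal, b),
                (next_internal, new_leaf)])


def _edges_to_topology(edges: list[tuple[int, int]], taxa: TaxonSet) -> Topology:
    n = len(taxa)
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    full = taxa.full_mask
    splits: set[int] = set()

    def below(u: int, parent: int) -> int:
        if u < n:
            return 1 << u
        m = 0
        for v in adj[u]:
            if v != parent:
                m |= below(v, u)
        if 2 <= m.bit_count() <= n - 2:
            splits.add(_normalize_split(m, full))
        return m

    below(n, -1)  # DFS from the first internal node covers every edge once
    return Topology(taxa, frozenset(splits))


def enumerate_topologies(taxa: TaxonSet | Sequence[str]) -> list[Topology]:
    """All (2n-5)!! resolved unrooted topologies, by sequential leaf addition."""
    if not isinstance(taxa, TaxonSet):
        taxa = TaxonSet(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # leaves are 0..n-1; internal nodes numbered from n upward
    trees: list[list[tuple[int, int]]] = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        nxt = n + leaf - 2
        trees = [g for t in trees for g in _grow(t, leaf, nxt)]
    return [_edges_to_topology(t, taxa) for t in trees]


def random_topology(taxa: TaxonSet | Sequence[str], rng) -> Topology:
    """Uniform random resolved topology via random sequential leaf addition."""
    if not isinstance(taxa, TaxonSet):
        taxa = TaxonSet(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    edges: list[tuple[int, int]] = [(0, n), (1, n), (2, n)]
    for leaf in range(3, n):
        nxt = n + leaf - 2
        i = int(rng.integers(len(edges)))
        a, b = edges.pop(i)
        edges += [(a, nxt), (nxt, b), (nxt, leaf)]
    return _edges_to_topology(edges, taxa)
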