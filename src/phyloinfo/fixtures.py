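"""Synthetic study generators: toy anatomy ontologies, Mk-simulated
character matrices with ontology annotations, and entropy-known synthetic
posteriors.

The default study emulates the concerted-convergence scenario: one group of
anatomical terms (jaw-region bones) whose characters evolve on the true
species tree, and a second group (fins) whose characters jointly evolve on
an alternative tree shared among unrelated lineages.  A pipeline with
semantic signal should cluster the fin subsets together with low
within-group dissonance, separate them from the jaw subsets, and place the
fin group's merged posterior on the alternative tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mksampler import CharacterMatrix, MkModel, simulate_matrix
from .ontosem import AnnotationTable, TermGraph
from .treeio import TaxonSet, Topology, TreeSample, parse_newick, random_topology

__all__ = [
    "FixtureSpec",
    "TermPlan",
    "make_toy_ontology",
    "write_obo",
    "make_fixture_study",
    "make_synthetic_posterior",
    "default_study_spec",
]


@dataclass(frozen=True)
class TermPlan:
    """Per-term block plan: how many characters, simulated on which tree."""

    n_chars: int
    tree: str = "species"       # "species" | "alternative" | "random"

    def __post_init__(self) -> None:
        if self.n_chars < 1:
            raise ValueError("per-term n_chars must be >= 1")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_taxa: int = 8
    species_tree: str | None = None       # Newick; generated when None
    alternative_tree: str | None = None
    subset_plan: dict[str, TermPlan] = field(default_factory=dict)
    n_noise_chars: int = 0                # characters on per-character random trees
    branch_length: float = 0.05           # conserved morphology: low homoplasy
    n_states: int = 2
    model: MkModel = field(default_factory=lambda: MkModel(coding="variable"))


# ---------------------------------------------------------------------------
# toy ontology

_FISH_GROUPS = {
    "dermatocranium": ["premaxilla", "maxilla", "dentary", "infraorbital"],
    "paired fin": ["pectoral fin", "pelvic fin", "dorsal fin"],
}


def make_toy_ontology(groups: Mapping[str, Sequence[str]] | None = None, *,
                      root: str = "anatomical structure") -> TermGraph:
    """Deterministic toy anatomy ontology.

    ``groups`` maps mid-level terms to their leaf parts; every group term is
    ``part_of`` the root and every leaf is ``part_of`` its group and
    ``is_a`` a generic sibling class ("bone" or "fin" style is collapsed to
    the root here to keep the graph small).
    """
    groups = dict(groups or _FISH_GROUPS)
    ids: dict[str, str] = {}

    def tid(name: str) -> str:
        if name not in ids:
            ids[name] = f"TOY:{len(ids):07d}"
        return ids[name]

    names = {tid(root): root}
    edges: set[tuple[str, str, str]] = set()
    for group, leaves in groups.items():
        names[tid(group)] = group
        edges.add((tid(group), tid(root), "part_of"))
        for leaf in leaves:
            names[tid(leaf)] = leaf
            edges.add((tid(leaf), tid(group), "part_of"))
            edges.add((tid(leaf), tid(root), "is_a"))
    return TermGraph(names=names, edges=edges)


def write_obo(graph: TermGraph, path) -> None:
    """Write a TermGraph as an OBO 1.2 flat file."""
    by_id = sorted(graph.names)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy-anatomy\n")
        for term in by_id:
            fh.write(f"\n[Term]\nid: {term}\nname: {graph.names[term]}\n")
            if term in graph.obsolete:
                fh.write("is_obsolete: true\n")
            for child, parent, rel in sorted(graph.edges):
                if child != term:
                    continue
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {graph.names[parent]}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} "
                             f"! {graph.names[parent]}\n")
        fh.write("\n[Typedef]\nid: part_of\nname: part of\n")


# ---------------------------------------------------------------------------
# simulated study

def default_study_spec(seed: int = 0, *, n_chars_per_term: int = 20,
                       n_taxa: int = 8) -> FixtureSpec:
    """The concerted-convergence default: jaw terms on the species tree,
    fin terms jointly on an alternative tree."""
    plan = {t: TermPlan(n_chars_per_term, "species")
            for t in _FISH_GROUPS["dermatocranium"]}
    plan |= {t: TermPlan(n_chars_per_term, "alternative")
             for t in _FISH_GROUPS["paired fin"]}
    return FixtureSpec(seed=seed, n_taxa=n_taxa, subset_plan=plan)


def make_fixture_study(spec: FixtureSpec | None = None,
                       ) -> tuple[CharacterMatrix, AnnotationTable,
                                  TermGraph, dict]:
    """Simulate a full study: matrix + annotations + ontology + truth manifest.

    The manifest records the generating tree of every term block (ground
    truth for assertions) and the Newick of both trees.
    """
    spec = spec or default_study_spec()
    rng = np.random.default_rng(spec.seed)
    taxa = TaxonSet([f"sp{i + 1:02d}" for i in range(spec.n_taxa)])
    species = (parse_newick(spec.species_tree, taxa) if spec.species_tree
               else random_topology(taxa, rng))
    alternative = (parse_newick(spec.alternative_tree, taxa)
                   if spec.alternative_tree else None)
    if alternative is None:
        while True:
            alternative = random_topology(taxa, rng)
            if alternative.id != species.id and not (species.splits
                                                     & alternative.splits):
                break

    graph = make_toy_ontology()
    name_to_id = {v: k for k, v in graph.names.items()}
    blocks: list[CharacterMatrix] = []
    ann_rows: dict[int, set[str]] = {}
    manifest: dict = {"seed": spec.seed,
                      "taxa": list(taxa.labels),
                      "species_tree": species.newick(),
                      "alternative_tree": alternative.newick(),
                      "terms": {}}
    col = 0
    for term, plan in spec.subset_plan.items():
        gen_tree = {"species": species, "alternative": alternative}.get(plan.tree)
        if gen_tree is None:
            gen_tree = random_topology(taxa, rng)
        block = simulate_matrix(gen_tree, spec.branch_length, plan.n_chars,
                                spec.model, seed=rng,
                                n_states=spec.n_states)
        blocks.append(block)
        term_id = name_to_id.get(term, term)
        for j in range(plan.n_chars):
            ann_rows[col + j] = {term_id}
        manifest["terms"][term] = {"term_id": term_id, "tree": plan.tree,
                                   "columns": list(range(col, col + plan.n_chars))}
        col += plan.n_chars
    for _ in range(spec.n_noise_chars):
        block = simulate_matrix(random_topology(taxa, rng),
                                spec.branch_length, 1, spec.model,
                                seed=rng, n_states=spec.n_states)
        blocks.append(block)
        col += 1
    states = np.concatenate([b.states for b in blocks], axis=1)
    n_states = np.concatenate([b.n_states for b in blocks])
    matrix = CharacterMatrix(taxa, states, n_states)
    annotations = AnnotationTable(ann_rows)
    annotations.validate(graph, matrix.n_chars)
    return matrix, annotations, graph, manifest


# ---------------------------------------------------------------------------
# synthetic posteriors with known entropy

def make_synthetic_posterior(probs: Mapping[Topology, float] | Sequence[tuple[Topology, float]],
                             n_draws: int, seed: int | np.random.Generator = 0,
                             *, run_id: str = "synthetic",
                             subset_id: str = "") -> TreeSample:
    """I.i.d. draws from an explicit topology distribution, as a TreeSample."""
    items = list(probs.items()) if isinstance(probs, Mapping) else list(probs)
    topos = [t for t, _ in items]
    p = np.array([w for _, w in items], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be non-negative and sum to 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.choice(len(topos), size=n_draws, p=p / p.sum())
    return TreeSample([topos[i] for i in idx], run_id=run_id,
                      subset_id=subset_id)
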