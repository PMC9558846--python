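"""Study-level analyses: subset construction, dendrogram-node information
maps, clade-support matrices against a reference tree, and resampling
comparisons.

Character subsets are built either from every annotated ontology term with
enough characters (ALL mode), from curated groups of preferred terms
(PROFILE mode, e.g. mouthparts / head / legs), or by random resampling of
matrix columns (RESAMPLED mode, the null against which ontology-based
subsets are compared).  Per-subset posteriors are then summarized with the
statistics from :mod:`phyloinfo.infotheory` and mapped onto dendrogram nodes
or onto the clades of a reference species tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .infotheory import (InfoSummary, among_run_dissonance, bpi, build_ccd,
                         ccd_entropy, clade_posterior, dissonance,
                         merge_ccds_by_pooling, summarize_sample,
                         DissonanceResult)
from .ontosem import (AnnotationTable, Dendrogram, SubsetSpec, TermGraph,
                      ancestors, DEFAULT_RELATIONS)
from .treeio import TaxonSet, Topology, TreeSample

__all__ = [
    "NodeInfoMap",
    "CladeSupportMatrix",
    "build_subsets_all",
    "build_subsets_profile",
    "node_info_map",
    "clade_support_matrix",
    "relative_information",
    "resample_subsets",
    "compare_standard_vs_resampled",
    "merged_information",
    "profile_info_table",
]


# ---------------------------------------------------------------------------
# subset construction

def build_subsets_all(annotations: AnnotationTable, *, min_chars: int = 3,
                      graph: TermGraph | None = None,
                      propagate: bool = False,
                      relations=DEFAULT_RELATIONS) -> list[SubsetSpec]:
    """One subset per annotated term with >= min_chars characters.

    With ``propagate=True`` characters annotated to a descendant term also
    count toward each ancestor (requires ``graph``).
    """
    chars_of: dict[str, set[int]] = {}
    for idx, terms in annotations.rows.items():
        for t in terms:
            targets = (ancestors(graph, t, relations)
                       if propagate and graph is not None else {t})
            for a in targets:
                chars_of.setdefault(a, set()).add(idx)
    out = [SubsetSpec(subset_id=t, label=t, characters=tuple(sorted(cs)),
                      mode="ALL")
           for t, cs in sorted(chars_of.items()) if len(cs) >= min_chars]
    if not out:
        raise ValueError(f"no term has >= {min_chars} annotated characters")
    return out


def build_subsets_profile(annotations: AnnotationTable,
                          profile: Mapping[str, Sequence[str]],
                          ) -> list[SubsetSpec]:
    """One subset per profile term, tagged with its group name.

    ``profile`` maps group name -> list of terms (e.g. "Mouthparts" ->
    [labrum, mandible, ...]).  Terms without characters are dropped with a
    warning.
    """
    out: list[SubsetSpec] = []
    for group, terms in profile.items():
        for term in terms:
            chars = annotations.characters_of(term)
            if not chars:
                warnings.warn(f"profile term {term!r} has no annotated "
                              "characters; dropped")
                continue
            out.append(SubsetSpec(subset_id=term, label=term,
                                  characters=tuple(sorted(chars)),
                                  mode="PROFILE", group=group))
    if not out:
        raise ValueError("no profile term has annotated characters")
    return out


def resample_subsets(n_chars: int, size: int, reps: int,
                     seed: int | np.random.Generator = 0, *,
                     label: str = "resample") -> list[SubsetSpec]:
    """``reps`` random subsets of ``size`` distinct character columns
    (without replacement within a replicate, independent across replicates)."""
    if size > n_chars:
        raise ValueError("resample size exceeds number of characters")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = []
    for r in range(reps):
        idx = rng.choice(n_chars, size=size, replace=False)
        out.append(SubsetSpec(subset_id=f"{label}_{r:03d}", label=label,
                              characters=tuple(sorted(int(i) for i in idx)),
                              mode="RESAMPLED"))
    return out


# ---------------------------------------------------------------------------
# merged information across subsets

def merged_information(samples: Sequence[TreeSample]) -> InfoSummary:
    """BPI of the equal-weight average posterior (pooled samples, CCD)."""
    merged = merge_ccds_by_pooling(samples)
    H = ccd_entropy(merged)
    return bpi(H, len(samples[0].taxa))


def profile_info_table(runs_by_subset: Mapping[str, Sequence[TreeSample]],
                       groups: Mapping[str, Sequence[str]], *,
                       denominator: str = "merged") -> pd.DataFrame:
    """Per-subset and per-group summary in the classic profile-table layout.

    For each subset: coverage %, information % (averaged over its runs) and
    among-run dissonance %.  For each group: one row per run with the merged
    information (BPI of the equal-weight average posterior across the
    group's subsets, within that run) and the among-subset dissonance within
    that run, then a Mean row averaging across runs.
    """
    rows = []
    for group, subset_ids in groups.items():
        per_run_merged: list[InfoSummary] = []
        per_run_diss: list[DissonanceResult] = []
        n_runs = min(len(runs_by_subset[s]) for s in subset_ids)
        for sid in subset_ids:
            runs = runs_by_subset[sid]
            summ = [summarize_sample(r) for r in runs]
            row = dict(group=group, subset=sid, row="subset",
                       coverage_pct=100 * float(np.mean([s.coverage_phi
                                                         for s in summ])),
                       information_pct=float(np.mean([s.information_pct
                                                      for s in summ])))
            if len(runs) >= 2:
                row["dissonance_pct"] = among_run_dissonance(
                    runs[0], runs[1], denominator=denominator).dissonance_pct
            rows.append(row)
        for r in range(n_runs):
            in_run = [runs_by_subset[s][r] for s in subset_ids]
            merged = merged_information(in_run)
            cov = float(np.mean([summarize_sample(s).coverage_phi
                                 for s in in_run]))
            diss = dissonance(in_run, denominator=denominator)
            per_run_merged.append(merged)
            per_run_diss.append(diss)
            rows.append(dict(group=group, subset=f"Run {r + 1}", row="run",
                             coverage_pct=100 * cov,
                             information_pct=merged.information_pct,
                             dissonance_pct=diss.dissonance_pct))
        if per_run_merged:
            rows.append(dict(
                group=group, subset="Mean", row="mean",
                coverage_pct=float(np.mean(
                    [r["coverage_pct"] for r in rows
                     if r["group"] == group and r["row"] == "run"])),
                information_pct=float(np.mean(
                    [m.information_pct for m in per_run_merged])),
                dissonance_pct=float(np.mean(
                    [d.dissonance_pct for d in per_run_diss]))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dendrogram node map

@dataclass
class NodeInfoMap:
    """Per-internal-node merged information and among-subset dissonance."""

    table: pd.DataFrame  # node_id, height, n_subsets, labels, info_*, diss_*

    def __post_init__(self) -> None:
        for col in ("rel_information", "rel_dissonance"):
            vals = self.table[col].dropna()
            if len(vals) and abs(vals.mean() - 1.0) > 1e-9 and vals.sum() > 0:
                raise ValueError(f"{col} does not average to 1")


def node_info_map(dendro: Dendrogram,
                  dists: Mapping[str, TreeSample],
                  *, denominator: str = "merged") -> NodeInfoMap:
    """For each internal dendrogram node, merged-posterior BPI and
    among-subset dissonance over the subtended subsets, plus values relative
    to the across-node mean."""
    rows = []
    for node_id, (height, members) in enumerate(dendro.internal_nodes()):
        have = sorted(m for m in members if m in dists)
        if len(have) < 2:
            warnings.warn(f"dendrogram node {node_id} subtends fewer than two "
                          "subsets with posteriors; skipped")
            continue
        samples = [dists[m] for m in have]
        info = merged_information(samples)
        diss = dissonance(samples, denominator=denominator)
        rows.append(dict(node_id=node_id, height=height, n_subsets=len(have),
                         labels=";".join(have),
                         information_nats=info.information_I,
                         information_pct=info.information_pct,
                         dissonance_nats=diss.dissonance_D,
                         dissonance_pct=diss.dissonance_pct))
    if not rows:
        raise ValueError("no dendrogram node with >= 2 posteriors")
    df = pd.DataFrame(rows)
    for src, dst in (("information_pct", "rel_information"),
                     ("dissonance_pct", "rel_dissonance")):
        mean = df[src].mean()
        df[dst] = df[src] / mean if mean > 0 else np.nan
    return NodeInfoMap(df)


# ---------------------------------------------------------------------------
# clade support against a reference tree

@dataclass
class CladeSupportMatrix:
    """Posterior probability of each reference-tree clade under each subset."""

    cells: pd.DataFrame          # rows: subset ids, cols: N1..Nk
    clades: dict[str, int]       # column name -> clade bitmask
    supporting: pd.Series        # per-clade fraction of subsets >= threshold
    threshold: float


def clade_support_matrix(dists: Mapping[str, TreeSample],
                         reference: Topology, *,
                         threshold: float = 0.95,
                         order: Sequence[str] | None = None,
                         ) -> CladeSupportMatrix:
    """Cell (s, c) = posterior probability of reference clade c in subset s;
    per-clade supporting proportion = share of subsets with cell >= threshold."""
    taxa = reference.taxa
    for lab, s in dists.items():
        if s.taxa != taxa:
            raise ValueError(f"subset {lab!r} is on a different taxon set")
    splits = sorted(reference.splits, key=lambda m: (m.bit_count(), m))
    names = {f"N{i + 1}": s for i, s in enumerate(splits)}
    subset_ids = list(order) if order is not None else sorted(dists)
    data = {col: [clade_posterior(dists[sid], mask) for sid in subset_ids]
            for col, mask in names.items()}
    cells = pd.DataFrame(data, index=subset_ids)
    supporting = (cells >= threshold).mean(axis=0)
    return CladeSupportMatrix(cells=cells, clades=names,
                              supporting=supporting, threshold=threshold)


# ---------------------------------------------------------------------------
# relative information and resampling comparison

def relative_information(summaries: Sequence[InfoSummary]) -> list[float]:
    """Each subset's I% divided by the mean I% (outputs average to 1)."""
    if not summaries:
        raise ValueError("no summaries")
    vals = np.array([s.information_pct for s in summaries], dtype=float)
    mean = vals.mean()
    if mean == 0:
        warnings.warn("all-zero information; relative values undefined")
        return [float("nan")] * len(vals)
    return list(vals / mean)


def compare_standard_vs_resampled(
        standard: Mapping[str, InfoSummary],
        resampled: Mapping[str, Sequence[InfoSummary]],
        *,
        standard_pair_diss: Mapping[str, float] | None = None,
        resampled_pair_diss: Mapping[str, Sequence[float]] | None = None,
        quantiles: Sequence[float] = (0.25, 0.5, 0.75),
        ) -> pd.DataFrame:
    """Per-term comparison of ontology-based ("standard") subsets with
    size-matched random resamples.

    Reports the standard BPI, resample quantiles, and the standard value
    relative to the resampled median (> 1 means the ontology-based subset is
    more informative than random same-size subsets); optionally the same
    framing for pairwise dissonance against a fixed reference term.
    """
    rows = []
    for term, summ in standard.items():
        res = resampled.get(term, ())
        vals = np.array([r.information_pct for r in res], dtype=float)
        row: dict = {"term": term, "standard_info_pct": summ.information_pct,
                     "n_resamples": len(vals)}
        qs = np.quantile(vals, quantiles) if len(vals) else [np.nan] * len(quantiles)
        for q, v in zip(quantiles, qs):
            row[f"resampled_info_q{int(100 * q)}"] = v
        med = row.get("resampled_info_q50", np.nan)
        row["info_vs_resampled_median"] = (summ.information_pct / med
                                           if med and med > 0 else np.nan)
        if standard_pair_diss is not None and term in standard_pair_diss:
            row["standard_pair_dissonance_pct"] = standard_pair_diss[term]
            rvals = np.array(list((resampled_pair_diss or {}).get(term, ())),
                             dtype=float)
            if len(rvals):
                rq = np.quantile(rvals, quantiles)
                for q, v in zip(quantiles, rq):
                    row[f"resampled_diss_q{int(100 * q)}"] = v
                med_d = float(np.quantile(rvals, 0.5))
                row["diss_vs_resampled_median"] = (
                    standard_pair_diss[term] / med_d if med_d > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
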