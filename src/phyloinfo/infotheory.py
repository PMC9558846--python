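"""Information-theoretic statistics on posterior tree-topology distributions.

Bayesian phylogenetic information (BPI) is the entropy difference between the
uniform prior over the (2n-5)!! resolved unrooted topologies and the
posterior inferred from data; posterior coverage is the share of total
posterior probability represented by the topologies actually present in an
MCMC sample; phylogenetic dissonance is the Jensen-Shannon-type divergence
among several posteriors (entropy of their average minus average entropy).

Two posterior estimators are provided:

* the plug-in estimator (relative topology frequencies) — simple, and the
  oracle baseline for tests;
* the conditional clade distribution (CCD) — trees are rooted at a reference
  taxon and each clade's observed child-split frequencies are treated as
  independent conditionals, extending probability mass to unsampled
  combinations of sampled splits.  Entropy is computed recursively over
  clades without enumerating topologies.

All entropies are in nats; reported summary statistics are percentages of
their respective maxima, so the log base cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .treeio import TaxonSet, Topology, TreeSample, count_topologies

__all__ = [
    "TopologyDistribution",
    "CladeDistribution",
    "InfoSummary",
    "DissonanceResult",
    "CladeInfoTable",
    "plugin_distribution",
    "build_ccd",
    "ccd_topology_prob",
    "ccd_entropy",
    "coverage",
    "prior_entropy",
    "bpi",
    "summarize_sample",
    "dissonance",
    "among_run_dissonance",
    "clade_info_components",
    "clade_posterior",
    "n_rooted_topologies",
    "prior_split_prob",
]

_REL_TOL = 1e-9  # tolerated relative entropy overshoot above the prior


# ---------------------------------------------------------------------------
# distributions

@dataclass
class TopologyDistribution:
    """Explicit distribution over topology ids (plug-in or enumerated)."""

    taxa: TaxonSet
    probs: dict[str, float]
    estimator: str = "plugin"
    topologies: dict[str, Topology] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("negative probability")
        total = sum(self.probs.values())
        if self.estimator == "plugin" and abs(total - 1.0) > 1e-9:
            raise ValueError(f"plugin probabilities sum to {total}, not 1")

    def entropy(self) -> float:
        return -sum(p * math.log(p) for p in self.probs.values() if p > 0)


def plugin_distribution(sample: TreeSample) -> TopologyDistribution:
    """Relative-frequency estimate of the topology posterior."""
    counts: dict[str, int] = {}
    topos: dict[str, Topology] = {}
    for t in sample.topologies:
        counts[t.id] = counts.get(t.id, 0) + 1
        topos.setdefault(t.id, t)
    n = len(sample.topologies)
    return TopologyDistribution(sample.taxa,
                                {k: c / n for k, c in counts.items()},
                                estimator="plugin", topologies=topos)


@dataclass
class CladeDistribution:
    """Conditional clade distribution built from a sample of rooted trees.

    Trees are rooted at the canonically first taxon; ``splits[c][(a, b)]`` is
    the number of sampled trees in which clade ``c`` (a bitmask over the
    remaining taxa) splits into child clades ``a`` and ``b``.
    """

    taxa: TaxonSet
    splits: dict[int, dict[tuple[int, int], float]]
    sample_size: int

    @property
    def root_clade(self) -> int:
        return self.taxa.full_mask ^ 1

    def conditional(self, clade: int) -> dict[tuple[int, int], float]:
        obs = self.splits[clade]
        total = sum(obs.values())
        return {s: c / total for s, c in obs.items()}


def build_ccd(sample: TreeSample) -> CladeDistribution:
    """Estimate the CCD from a sample of fully resolved topologies."""
    taxa = sample.taxa
    splits: dict[int, dict[tuple[int, int], float]] = {}
    for topo in sample.topologies:
        if not topo.is_resolved:
            raise ValueError("CCD requires fully resolved topologies")
        for clade, kids in topo.child_splits().items():
            splits.setdefault(clade, {})
            splits[clade][kids] = splits[clade].get(kids, 0) + 1
    return CladeDistribution(taxa, splits, sample_size=len(sample.topologies))


def merge_ccds_by_pooling(samples: Sequence[TreeSample]) -> CladeDistribution:
    """CCD of the pooled (concatenated) samples — the equal-weight merge when
    sample sizes are equal."""
    pooled = TreeSample([t for s in samples for t in s.topologies],
                        run_id="pooled")
    return build_ccd(pooled)


def ccd_topology_prob(ccd: CladeDistribution, t: Topology) -> float:
    """CCD probability of one topology: product of conditional split
    frequencies over its clades (0 if any clade or split is unobserved)."""
    if t.taxa != ccd.taxa:
        raise ValueError("topology and CCD are on different taxon sets")
    p = 1.0
    for clade, kids in t.child_splits().items():
        obs = ccd.splits.get(clade)
        if not obs or kids not in obs:
            return 0.0
        p *= obs[kids] / sum(obs.values())
    return p


def ccd_entropy(ccd: CladeDistribution) -> float:
    """Entropy of the CCD over its full support, without enumeration.

    H = sum over clades c of m(c) * H(q(.|c)), with clade marginals m(c)
    propagated top-down from the root clade.
    """
    marg: dict[int, float] = {ccd.root_clade: 1.0}
    H = 0.0
    for clade in sorted(ccd.splits, key=lambda m: -m.bit_count()):
        m = marg.get(clade, 0.0)
        if m == 0.0:
            continue
        q = ccd.conditional(clade)
        h = -sum(p * math.log(p) for p in q.values() if p > 0)
        H += m * h
        for (a, b), p in q.items():
            for kid in (a, b):
                if kid.bit_count() >= 2:
                    marg[kid] = marg.get(kid, 0.0) + m * p
    return H


def ccd_clade_marginals(ccd: CladeDistribution) -> dict[int, float]:
    """Marginal probability of each clade under the CCD (root clade = 1)."""
    marg: dict[int, float] = {ccd.root_clade: 1.0}
    for clade in sorted(ccd.splits, key=lambda m: -m.bit_count()):
        m = marg.get(clade, 0.0)
        if m == 0.0:
            continue
        for (a, b), p in ccd.conditional(clade).items():
            for kid in (a, b):
                if kid.bit_count() >= 2:
                    marg[kid] = marg.get(kid, 0.0) + m * p
    return marg


# ---------------------------------------------------------------------------
# scalar summaries

def prior_entropy(n: int) -> float:
    """ln (2n-5)!! — entropy of the uniform prior on resolved topologies."""
    if n < 4:
        raise ValueError("prior entropy needs at least 4 taxa")
    return math.log(count_topologies(n))


def coverage(sample: TreeSample, ccd: CladeDistribution | None = None) -> float:
    """Posterior coverage: total CCD probability of the distinct sampled
    topologies."""
    if ccd is None:
        ccd = build_ccd(sample)
    seen: dict[str, Topology] = {}
    for t in sample.topologies:
        seen.setdefault(t.id, t)
    return sum(ccd_topology_prob(ccd, t) for t in seen.values())


@dataclass
class InfoSummary:
    """Coverage, entropy, and information for one subset/run."""

    coverage_phi: float
    entropy_H: float
    information_I: float
    information_pct: float
    n_taxa: int
    subset_id: str = ""
    run_id: str = ""


def bpi(entropy_H: float, n: int, *, coverage_phi: float = float("nan"),
        subset_id: str = "", run_id: str = "") -> InfoSummary:
    """Bayesian phylogenetic information: prior entropy minus posterior
    entropy, also expressed as a percentage of the prior entropy."""
    H0 = prior_entropy(n)
    if entropy_H > H0 * (1 + _REL_TOL) + 1e-12:
        raise ValueError(
            f"posterior entropy {entropy_H} exceeds prior entropy {H0}")
    H = min(entropy_H, H0)
    I = H0 - H
    return InfoSummary(coverage_phi=coverage_phi, entropy_H=H,
                       information_I=I, information_pct=100.0 * I / H0,
                       n_taxa=n, subset_id=subset_id, run_id=run_id)


def summarize_sample(sample: TreeSample, *, estimator: str = "ccd") -> InfoSummary:
    """Coverage + entropy + BPI of one sample, via CCD (default) or plug-in."""
    n = len(sample.taxa)
    if estimator == "ccd":
        ccd = build_ccd(sample)
        H = ccd_entropy(ccd)
        phi = coverage(sample, ccd)
    elif estimator == "plugin":
        dist = plugin_distribution(sample)
        H = dist.entropy()
        phi = 1.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return bpi(H, n, coverage_phi=phi, subset_id=sample.subset_id,
               run_id=sample.run_id)


# ---------------------------------------------------------------------------
# dissonance

@dataclass
class DissonanceResult:
    entropies: list[float]
    mean_entropy: float
    merged_entropy: float
    dissonance_D: float
    dissonance_pct: float
    k: int
    denominator: str


def _mix_plugin(dists: Sequence[TopologyDistribution]) -> TopologyDistribution:
    taxa = dists[0].taxa
    mix: dict[str, float] = {}
    topos: dict[str, Topology] = {}
    for d in dists:
        for tid, p in d.probs.items():
            mix[tid] = mix.get(tid, 0.0) + p / len(dists)
        topos.update(d.topologies)
    return TopologyDistribution(taxa, mix, estimator="plugin", topologies=topos)


def dissonance(dists: Sequence[TreeSample | TopologyDistribution], *,
               denominator: str = "merged") -> DissonanceResult:
    """Phylogenetic dissonance D = H(merged) - mean(H) among K >= 2
    posteriors.

    TreeSample inputs are compared through their CCDs; the merged CCD is
    built by pooling the raw samples.  TopologyDistribution inputs use the
    explicit equal-weight mixture.  ``denominator`` in {"merged", "mean",
    "logk"} sets the scale of the reported percentage.
    """
    if len(dists) < 2:
        raise ValueError("dissonance needs at least two distributions")
    kinds = {type(d) for d in dists}
    if len(kinds) != 1:
        raise ValueError("cannot mix TreeSample and TopologyDistribution")
    taxa0 = dists[0].taxa
    if any(d.taxa != taxa0 for d in dists):
        raise ValueError("mismatched taxon sets")
    if isinstance(dists[0], TreeSample):
        entropies = [ccd_entropy(build_ccd(s)) for s in dists]
        merged_H = ccd_entropy(merge_ccds_by_pooling(dists))
    else:
        entropies = [d.entropy() for d in dists]
        merged_H = _mix_plugin(dists).entropy()
    mean_H = sum(entropies) / len(entropies)
    D = merged_H - mean_H
    k = len(dists)
    denom = {"merged": merged_H, "mean": mean_H,
             "logk": math.log(k)}.get(denominator)
    if denom is None:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct = 0.0 if denom <= 0 else max(0.0, min(100.0, 100.0 * D / denom))
    return DissonanceResult(entropies=entropies, mean_entropy=mean_H,
                            merged_entropy=merged_H, dissonance_D=D,
                            dissonance_pct=pct, k=k, denominator=denominator)


def among_run_dissonance(run1: TreeSample, run2: TreeSample, *,
                         denominator: str = "merged") -> DissonanceResult:
    """Dissonance between two MCMC runs of the same subset: a topology
    convergence diagnostic (near zero when runs sample the same posterior)."""
    return dissonance([run1, run2], denominator=denominator)


# ---------------------------------------------------------------------------
# clade-specific decomposition

def n_rooted_topologies(k: int) -> int:
    """(2k-3)!! rooted resolved topologies on k leaves (1 for k in {1, 2})."""
    if k < 1:
        raise ValueError("k must be positive")
    out = 1
    for j in range(1, 2 * k - 2, 2):
        out *= j
    return out


def prior_split_prob(size_a: int, size_b: int) -> float:
    """Uniform-prior conditional probability that a clade of a+b leaves
    splits into one given pair of child clades of sizes a and b:
    R(a) R(b) / R(a+b) with R(k) = (2k-3)!!."""
    return (n_rooted_topologies(size_a) * n_rooted_topologies(size_b)
            / n_rooted_topologies(size_a + size_b))


@dataclass
class CladeInfoTable:
    """Per-clade decomposition of total information (rows sum to total_I)."""

    rows: dict[int, tuple[float, float]]  # clade -> (posterior prob, nats)
    total_I: float
    taxa: TaxonSet


def clade_info_components(ccd: CladeDistribution) -> CladeInfoTable:
    """Decompose BPI over clades of the CCD.

    The information I = KL(posterior || uniform prior) factorizes over the
    conditional clade distributions: each clade c contributes
    m(c) * sum_s q(s|c) ln[ q(s|c) / q0(s|c) ], where q0 is the analytic
    prior conditional based on rooted-topology counts.  Components sum
    exactly to prior_entropy(n) - ccd_entropy(ccd).
    """
    marg = ccd_clade_marginals(ccd)
    rows: dict[int, tuple[float, float]] = {}
    total = 0.0
    for clade, obs in ccd.splits.items():
        m = marg.get(clade, 0.0)
        q = ccd.conditional(clade)
        comp = 0.0
        for (a, b), p in q.items():
            if p > 0:
                q0 = prior_split_prob(a.bit_count(), b.bit_count())
                comp += p * math.log(p / q0)
        comp *= m
        rows[clade] = (m, comp)
        total += comp
    return CladeInfoTable(rows=rows, total_I=total, taxa=ccd.taxa)


def analytic_prior_prob(topology: Topology) -> float:
    """Probability of any resolved topology under the analytic prior CCD:
    the product of prior conditional split probabilities, = 1/(2n-5)!!."""
    p = 1.0
    for clade, (a, b) in topology.child_splits().items():
        p *= prior_split_prob(a.bit_count(), b.bit_count())
    return p


# ---------------------------------------------------------------------------
# clade marginals of samples / distributions

def clade_posterior(dist: TreeSample | TopologyDistribution,
                    clade: int) -> float:
    """Marginal posterior probability that the (non-trivial) split induced
    by ``clade`` appears in a tree drawn from ``dist``."""
    taxa = dist.taxa
    n = len(taxa)
    size = clade.bit_count()
    if size < 2 or size > n - 2:
        raise ValueError("trivial clade")
    full = taxa.full_mask
    want = clade if clade & 1 else full ^ clade
    if isinstance(dist, TreeSample):
        hits = sum(1 for t in dist.topologies if want in t.splits)
        return hits / len(dist.topologies)
    return sum(p for tid, p in dist.probs.items()
               if want in dist.topologies[tid].splits)
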