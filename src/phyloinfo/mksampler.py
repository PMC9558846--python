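"""Mk+Gamma likelihood and a lightweight Bayesian MCMC over unrooted
topologies.

The Mk model (symmetric k-state Markov chain, rates normalized to one
expected change per unit branch length) gives the transition probabilities
P(same) = 1/k + (k-1)/k * exp(-k beta t) and P(diff) = 1/k * (1 - exp(-k
beta t)) with beta = 1/(k-1).  Among-character rate variation uses a
discrete gamma with equal-probability categories (mean of each quantile
slice).  The "variable" coding bias (Mkv) conditions each character's
likelihood on being variable by dividing by one minus the summed likelihood
of the constant patterns.

The sampler is a single-chain Metropolis-Hastings walk per run mixing NNI
topology moves, branch-length multipliers, and gamma-shape multipliers,
with an exponential prior on branch lengths and on the shape, and a uniform
prior on resolved topologies.  Clade constraints (bitmasks that must appear
as splits in every sampled topology) are enforced by auto-rejection, which
is how a reference tree with an enforced clade (e.g. a monophyletic group
of miniature taxa) is produced.  Posterior samples at the paper scale are
equally importable from MrBayes ``.t`` files via :mod:`phyloinfo.treeio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .treeio import TaxonSet, Topology, TreeSample, random_topology

__all__ = [
    "CharacterMatrix",
    "MkModel",
    "McmcConfig",
    "discrete_gamma_rates",
    "mk_log_likelihood",
    "run_mcmc",
    "simulate_matrix",
]

MISSING = -1


# ---------------------------------------------------------------------------
# data container

@dataclass
class CharacterMatrix:
    """Discrete character matrix with per-character state-space sizes.

    ``states[i, j]`` is the integer state of taxon i for character j, or -1
    for missing; polymorphic cells live in ``polymorphic[(i, j)]`` as a
    tuple of states (the ``states`` entry is then ignored).
    """

    taxa: TaxonSet
    states: np.ndarray            # (n_taxa, n_chars) int16
    n_states: np.ndarray          # (n_chars,) int16, k >= 2 per character
    polymorphic: dict[tuple[int, int], tuple[int, ...]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        self.n_states = np.asarray(self.n_states, dtype=np.int16)
        if self.states.shape != (len(self.taxa), len(self.n_states)):
            raise ValueError("states shape does not match taxa / n_states")
        if np.any(self.n_states < 2):
            raise ValueError("each character needs at least 2 states")
        for j in range(self.n_chars):
            col = self.states[:, j]
            ok = (col == MISSING) | ((col >= 0) & (col < self.n_states[j]))
            if not ok.all():
                raise ValueError(f"character {j} has states outside its alphabet")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def subset(self, characters: Sequence[int]) -> "CharacterMatrix":
        idx = list(characters)
        poly = {(i, new_j): v for new_j, old_j in enumerate(idx)
                for (i, jj), v in self.polymorphic.items() if jj == old_j}
        return CharacterMatrix(self.taxa, self.states[:, idx],
                               self.n_states[idx], poly)

    def tip_partials(self, j: int) -> np.ndarray:
        """(n_taxa, k) indicator partials for character j (missing -> all 1)."""
        k = int(self.n_states[j])
        out = np.zeros((self.n_taxa, k))
        for i in range(self.n_taxa):
            if (i, j) in self.polymorphic:
                for s in self.polymorphic[i, j]:
                    out[i, s] = 1.0
            elif self.states[i, j] == MISSING:
                out[i, :] = 1.0
            else:
                out[i, self.states[i, j]] = 1.0
        return out

    def is_variable(self, j: int) -> bool:
        col = self.states[:, j]
        obs = {int(s) for s in col if s != MISSING}
        obs |= {s for (i, jj), v in self.polymorphic.items()
                if jj == j for s in v}
        return len(obs) > 1

    def to_nexus(self, path) -> None:
        """Write a NEXUS data block (symbols line, '?' missing, '(01)' poly)."""
        kmax = int(self.n_states.max())
        symbols = "".join(str(d) for d in range(kmax))
        lines = ["#NEXUS", "begin data;",
                 f"   dimensions ntax={self.n_taxa} nchar={self.n_chars};",
                 f'   format datatype=standard symbols="{symbols}" missing=?;',
                 "   matrix"]
        width = max(len(l) for l in self.taxa.labels) + 2
        for i, lab in enumerate(self.taxa.labels):
            cells = []
            for j in range(self.n_chars):
                if (i, j) in self.polymorphic:
                    cells.append("(" + "".join(str(s) for s in
                                               self.polymorphic[i, j]) + ")")
                elif self.states[i, j] == MISSING:
                    cells.append("?")
                else:
                    cells.append(str(int(self.states[i, j])))
            lines.append(f"   {lab:<{width}}{''.join(cells)}")
        lines += ["   ;", "end;", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    @classmethod
    def from_nexus(cls, path) -> "CharacterMatrix":
        import dendropy
        mat = dendropy.StandardCharacterMatrix.get(path=str(path),
                                                   schema="nexus")
        labels = [t.label for t in mat.taxon_namespace]
        taxa = TaxonSet(labels)
        n_chars = max(len(mat[t]) for t in mat.taxon_namespace)
        states = np.full((len(taxa), n_chars), MISSING, dtype=np.int16)
        poly: dict[tuple[int, int], tuple[int, ...]] = {}
        from dendropy.datamodel.charstatemodel import StateAlphabet
        for t in mat.taxon_namespace:
            i = taxa.index(t.label)
            for j, cell in enumerate(mat[t]):
                if cell.state_denomination == StateAlphabet.FUNDAMENTAL_STATE:
                    states[i, j] = int(cell.symbol)
                elif cell.state_denomination == StateAlphabet.POLYMORPHIC_STATE:
                    poly[i, j] = tuple(sorted(int(m.symbol)
                                              for m in cell.member_states))
                # ambiguous ('?') stays MISSING
        n_states = np.zeros(n_chars, dtype=np.int16)
        for j in range(n_chars):
            observed = [int(s) for s in states[:, j] if s != MISSING]
            observed += [s for (i, jj), v in poly.items() if jj == j for s in v]
            n_states[j] = max(2, (max(observed) + 1) if observed else 2)
        return cls(taxa, states, n_states, poly)


# ---------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class MkModel:
    """Mk+Gamma model settings and priors."""

    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    coding: str = "variable"            # "all" | "variable"
    brlen_prior_rate: float = 10.0      # Exponential(10) on branch lengths
    shape_prior_rate: float = 1.0       # Exponential(1) on the gamma shape

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.coding not in ("all", "variable"):
            raise ValueError("coding must be 'all' or 'variable'")


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rate of each of ``ncat`` equal-probability gamma slices
    (shape alpha, mean 1)."""
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha,
                           scale=1.0 / alpha)
    # mean within [q_{i-1}, q_i]: ncat * [I(a+1, alpha*q_i) - I(a+1, alpha*q_{i-1})]
    cum = gammainc(alpha + 1, alpha * edges)
    cum[0], cum[-1] = 0.0, 1.0
    rates = ncat * np.diff(cum)
    return rates / rates.mean()


@dataclass
class McmcConfig:
    n_generations: int = 50_000
    sample_every: int = 50
    burnin_fraction: float = 0.25
    n_runs: int = 2
    seed: int = 0
    constraints: tuple[int, ...] = ()   # clade bitmasks required in every tree


# ---------------------------------------------------------------------------
# internal rooted representation (rooted at canonical taxon 0)

class _Node:
    __slots__ = ("children", "parent", "length", "taxon")

    def __init__(self, taxon: int = -1, length: float = 0.1):
        self.children: list["_Node"] = []
        self.parent: "_Node | None" = None
        self.taxon = taxon
        self.length = length


class _Tree:
    """Unrooted binary tree held rooted at leaf 0: ``root`` is the internal
    node adjacent to taxon 0, carrying the taxon-0 edge length in
    ``root.length``."""

    def __init__(self, root: _Node, taxa: TaxonSet):
        self.root = root
        self.taxa = taxa

    # -- construction -------------------------------------------------
    @classmethod
    def from_topology(cls, topo: Topology, lengths) -> "_Tree":
        kids = topo.child_splits()
        taxa = topo.taxa

        def getlen(mask: int) -> float:
            if callable(lengths):
                return float(lengths(mask))
            return float(lengths)

        def build(mask: int) -> _Node:
            if mask.bit_count() == 1:
                return _Node(taxon=mask.bit_length() - 1, length=getlen(mask))
            node = _Node(length=getlen(mask))
            for k in kids[mask]:
                ch = build(k)
                ch.parent = node
                node.children.append(ch)
            return node

        root = build(taxa.full_mask ^ 1)
        root.length = getlen(1)  # edge to taxon 0
        return cls(root, taxa)

    def copy(self) -> "_Tree":
        def cp(node: _Node) -> _Node:
            nn = _Node(taxon=node.taxon, length=node.length)
            for ch in node.children:
                cc = cp(ch)
                cc.parent = nn
                nn.children.append(cc)
            return nn
        return _Tree(cp(self.root), self.taxa)

    # -- views --------------------------------------------------------
    def nodes(self) -> list[_Node]:
        out: list[_Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return out

    def postorder(self) -> list[_Node]:
        return list(reversed(self.nodes()))

    def mask_below(self) -> dict[int, int]:
        masks: dict[int, int] = {}
        for nd in self.postorder():
            if nd.taxon >= 0:
                masks[id(nd)] = 1 << nd.taxon
            else:
                masks[id(nd)] = 0
                for ch in nd.children:
                    masks[id(nd)] |= masks[id(ch)]
        return masks

    def topology(self) -> Topology:
        full = self.taxa.full_mask
        masks = self.mask_below()
        splits = set()
        for nd in self.nodes():
            if nd.taxon < 0 and nd is not self.root:
                m = masks[id(nd)]
                if 2 <= m.bit_count() <= len(self.taxa) - 2:
                    splits.add(m if m & 1 else full ^ m)
        return Topology(self.taxa, frozenset(splits))

    def branch_nodes(self) -> list[_Node]:
        """Every node carries one branch (root's = the taxon-0 edge)."""
        return self.nodes()

    def log_brlen_prior(self, rate: float) -> float:
        lp = 0.0
        for nd in self.nodes():
            lp += math.log(rate) - rate * nd.length
        return lp

    # -- moves ----------------------------------------------------------
    def nni_candidates(self) -> list[_Node]:
        """Internal non-root nodes: each owns one internal edge (to parent)."""
        return [nd for nd in self.nodes()
                if nd.taxon < 0 and nd is not self.root]

    def nni(self, v: _Node, which: int) -> None:
        """Swap child ``which`` of v with v's sibling (in place)."""
        p = v.parent
        sib = p.children[0] if p.children[1] is v else p.children[1]
        a = v.children[which]
        i_sib = p.children.index(sib)
        i_a = v.children.index(a)
        p.children[i_sib], v.children[i_a] = a, sib
        a.parent, sib.parent = p, v


def _random_tree(taxa: TaxonSet, rng: np.random.Generator,
                 brlen_rate: float,
                 constraints: Sequence[int] = ()) -> _Tree:
    topo = _random_constrained_topology(taxa, rng, constraints)
    draw = lambda _mask: rng.exponential(1.0 / brlen_rate) + 1e-9
    return _Tree.from_topology(topo, draw)


def _random_constrained_topology(taxa: TaxonSet, rng: np.random.Generator,
                                 constraints: Sequence[int]) -> Topology:
    if not constraints:
        return random_topology(taxa, rng)
    for _ in range(10_000):
        t = random_topology(taxa, rng)
        if _satisfies(t, constraints):
            return t
    raise ValueError("could not find a topology satisfying the constraints")


def _satisfies(topo: Topology, constraints: Sequence[int]) -> bool:
    full = topo.taxa.full_mask
    for c in constraints:
        want = c if c & 1 else full ^ c
        if want not in topo.splits:
            return False
    return True


# ---------------------------------------------------------------------------
# likelihood

class _LikelihoodEngine:
    """Vectorized Felsenstein pruning over characters grouped by state count."""

    def __init__(self, matrix: CharacterMatrix, model: MkModel):
        self.model = model
        self.groups: list[tuple[int, np.ndarray]] = []  # (k, tips (C, n_taxa, k))
        for k in sorted(set(int(x) for x in matrix.n_states)):
            js = [j for j in range(matrix.n_chars)
                  if matrix.n_states[j] == k]
            if not js:
                continue
            if model.coding == "variable":
                bad = [j for j in js if not matrix.is_variable(j)]
                if bad:
                    raise ValueError(
                        f"coding='variable' but characters {bad} are constant")
            tips = np.stack([matrix.tip_partials(j) for j in js])
            self.groups.append((k, tips))
        self.n_chars = matrix.n_chars

    def log_likelihood(self, tree: _Tree, alpha: float) -> float:
        rates = discrete_gamma_rates(alpha, self.model.n_rate_categories)
        total = 0.0
        for k, tips in self.groups:
            total += self._group_loglik(tree, rates, k, tips)
        return total

    def _group_loglik(self, tree: _Tree, rates: np.ndarray, k: int,
                      tips: np.ndarray) -> float:
        # site likelihoods averaged over rate categories
        lik = self._site_liks(tree, rates, k, tips)       # (C,)
        if self.model.coding == "variable":
            const = self._constant_pattern_liks(tree, rates, k,
                                                tips.shape[1])
            lik = lik / (1.0 - const)
        return float(np.sum(np.log(lik)))

    def _site_liks(self, tree: _Tree, rates: np.ndarray, k: int,
                   tips: np.ndarray) -> np.ndarray:
        C = tips.shape[0]
        R = len(rates)
        beta = 1.0 / (k - 1)
        partials: dict[int, np.ndarray] = {}
        for nd in tree.postorder():
            if nd.taxon >= 0:
                partials[id(nd)] = np.broadcast_to(
                    tips[:, nd.taxon, None, :], (C, R, k))
            else:
                acc = np.ones((C, R, k))
                for ch in nd.children:
                    v = partials.pop(id(ch))
                    e = np.exp(-k * beta * ch.length * rates)  # (R,)
                    S = v.sum(axis=2, keepdims=True)
                    pd = (1.0 - e)[None, :, None] / k
                    acc = acc * (pd * S + e[None, :, None] * v)
                partials[id(nd)] = acc
        # final edge from the root node down to taxon 0
        v = partials[id(tree.root)]
        e = np.exp(-k * beta * tree.root.length * rates)
        S = v.sum(axis=2, keepdims=True)
        pd = (1.0 - e)[None, :, None] / k
        v = pd * S + e[None, :, None] * v
        tip0 = np.broadcast_to(tips[:, 0, None, :], (C, R, k))
        site = (tip0 * v).sum(axis=2) / k   # uniform root frequencies 1/k
        return site.mean(axis=1)            # average over rate categories

    def _constant_pattern_liks(self, tree: _Tree, rates: np.ndarray,
                               k: int, n_taxa: int) -> float:
        # k pseudo-characters, one per constant pattern: tips[c, i] = onehot(c)
        tips = np.transpose(np.broadcast_to(np.eye(k), (n_taxa, k, k)),
                            (1, 0, 2)).copy()

        lik = self._site_liks(tree, rates, k, tips)      # (k,)
        return float(lik.sum())


def mk_log_likelihood(matrix: CharacterMatrix, topology: Topology,
                      branch_lengths, model: MkModel | None = None,
                      *, gamma_shape: float | None = None) -> float:
    """Log-likelihood of a resolved topology under Mk+Gamma.

    ``branch_lengths`` is a scalar applied to every branch or a callable
    ``mask -> length`` (mask = taxon bitmask below the branch; the taxon-0
    edge has mask 1).  Non-positive lengths are rejected.
    """
    model = model or MkModel()
    if not topology.is_resolved:
        raise ValueError("topology must be fully resolved")
    tree = _Tree.from_topology(topology, branch_lengths)
    if any(nd.length <= 0 for nd in tree.nodes()):
        raise ValueError("branch lengths must be positive")
    engine = _LikelihoodEngine(matrix, model)
    return engine.log_likelihood(tree, gamma_shape or model.gamma_shape)


# ---------------------------------------------------------------------------
# MCMC

def _one_run(matrix: CharacterMatrix | None, model: MkModel,
             config: McmcConfig, taxa: TaxonSet, run_idx: int,
             rng: np.random.Generator, subset_id: str) -> TreeSample:
    engine = (None if matrix is None or matrix.n_chars == 0
              else _LikelihoodEngine(matrix, model))
    tree = _random_tree(taxa, rng, model.brlen_prior_rate, config.constraints)
    alpha = float(rng.exponential(1.0 / model.shape_prior_rate)) + 1e-6

    def loglik(tr: _Tree, a: float) -> float:
        return 0.0 if engine is None else engine.log_likelihood(tr, a)

    def logprior(tr: _Tree, a: float) -> float:
        return (tr.log_brlen_prior(model.brlen_prior_rate)
                + math.log(model.shape_prior_rate)
                - model.shape_prior_rate * a)

    cur_ll = loglik(tree, alpha)
    cur_lp = logprior(tree, alpha)
    samples: list[Topology] = []
    n_accept = 0
    n_moves = 0
    lam = 2.0 * math.log(1.6)   # multiplier tuning

    for gen in range(config.n_generations + 1):
        if gen % config.sample_every == 0:
            samples.append(tree.topology())
        if gen == config.n_generations:
            break
        u = rng.random()
        n_moves += 1
        if u < 0.5:
            # NNI on a uniformly chosen internal edge / direction
            cand = tree.nni_candidates()
            if not cand:
                continue
            v = cand[int(rng.integers(len(cand)))]
            which = int(rng.integers(2))
            prop = tree.copy()
            # find corresponding node in the copy by structural walk
            path = _path_to(tree.root, v)
            pv = _follow(prop.root, path)
            prop.nni(pv, which)
            if config.constraints and not _satisfies(prop.topology(),
                                                     config.constraints):
                continue
            new_ll = loglik(prop, alpha)
            new_lp = logprior(prop, alpha)
            if math.log(rng.random() + 1e-300) < (new_ll + new_lp
                                                  - cur_ll - cur_lp):
                tree, cur_ll, cur_lp = prop, new_ll, new_lp
                n_accept += 1
        elif u < 0.85 or engine is None:
            # branch-length multiplier on a random edge
            nodes = tree.branch_nodes()
            nd = nodes[int(rng.integers(len(nodes)))]
            old = nd.length
            factor = math.exp(lam * (rng.random() - 0.5))
            nd.length = old * factor
            new_ll = loglik(tree, alpha)
            new_lp = logprior(tree, alpha)
            if math.log(rng.random() + 1e-300) < (new_ll + new_lp - cur_ll
                                                  - cur_lp + math.log(factor)):
                cur_ll, cur_lp = new_ll, new_lp
                n_accept += 1
            else:
                nd.length = old
        else:
            # gamma-shape multiplier
            factor = math.exp(lam * (rng.random() - 0.5))
            new_alpha = alpha * factor
            new_ll = loglik(tree, new_alpha)
            new_lp = logprior(tree, new_alpha)
            if math.log(rng.random() + 1e-300) < (new_ll + new_lp - cur_ll
                                                  - cur_lp + math.log(factor)):
                alpha, cur_ll, cur_lp = new_alpha, new_ll, new_lp
                n_accept += 1

    return TreeSample(samples, run_id=f"run{run_idx + 1}",
                      subset_id=subset_id,
                      burnin_fraction=config.burnin_fraction)


def _path_to(root: _Node, target: _Node) -> list[int]:
    path: list[int] = []
    nd = target
    while nd is not root:
        path.append(nd.parent.children.index(nd))
        nd = nd.parent
    path.reverse()
    return path


def _follow(root: _Node, path: list[int]) -> _Node:
    nd = root
    for i in path:
        nd = nd.children[i]
    return nd


def run_mcmc(matrix: CharacterMatrix | None, model: MkModel,
             config: McmcConfig, *, taxa: TaxonSet | None = None,
             subset_id: str = "") -> list[TreeSample]:
    """Run ``config.n_runs`` independent MCMC chains; returns one TreeSample
    per run with burn-in retained but flagged (use ``.burned_in()``).

    With ``matrix=None`` (or zero characters) the chain samples from the
    prior, which is uniform over resolved topologies.
    """
    if matrix is not None:
        taxa = matrix.taxa
    if taxa is None:
        raise ValueError("need a taxon set when there is no data")
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    if config.constraints:
        _random_constrained_topology(taxa, np.random.default_rng(config.seed),
                                     config.constraints)  # feasibility check
    out = []
    for r in range(config.n_runs):
        rng = np.random.default_rng((config.seed, r))
        out.append(_one_run(matrix, model, config, taxa, r, rng, subset_id))
    return out


# ---------------------------------------------------------------------------
# simulation

def simulate_matrix(topology: Topology, branch_lengths, n_chars: int,
                    model: MkModel | None = None, seed: int | np.random.Generator = 0,
                    *, n_states: int = 2,
                    variable_only: bool | None = None) -> CharacterMatrix:
    """Simulate characters under Mk+Gamma on a fixed tree.

    ``variable_only`` defaults to True when the model codes for variable
    characters; invariant draws are then redrawn (ascertainment filtering to
    pair with coding='variable').
    """
    model = model or MkModel()
    if variable_only is None:
        variable_only = model.coding == "variable"
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    tree = _Tree.from_topology(topology, branch_lengths)
    taxa = topology.taxa
    k = n_states
    beta = 1.0 / (k - 1)
    rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    cols = []
    order = tree.postorder()[::-1]  # preorder
    max_tries = 10_000
    while len(cols) < n_chars:
        rate = rates[int(rng.integers(len(rates)))]
        states: dict[int, int] = {}
        # state at the root node (adjacent to taxon 0)
        root_state = int(rng.integers(k))
        col = np.zeros(len(taxa), dtype=np.int16)
        # taxon-0 edge
        e = math.exp(-k * beta * tree.root.length * rate)
        col[0] = (root_state if rng.random() < e + (1 - e) / k
                  else _other(rng, k, root_state))
        states[id(tree.root)] = root_state
        for nd in order:
            if nd is tree.root:
                continue
            p = states[id(nd.parent)]
            e = math.exp(-k * beta * nd.length * rate)
            s = p if rng.random() < e + (1 - e) / k else _other(rng, k, p)
            states[id(nd)] = s
            if nd.taxon >= 0:
                col[nd.taxon] = s
        if variable_only and len(set(col.tolist())) < 2:
            max_tries -= 1
            if max_tries <= 0:
                raise RuntimeError("could not draw enough variable characters")
            continue
        cols.append(col)
    states_arr = np.stack(cols, axis=1)
    return CharacterMatrix(taxa, states_arr,
                           np.full(n_chars, k, dtype=np.int16))


def _other(rng: np.random.Generator, k: int, s: int) -> int:
    x = int(rng.integers(k - 1))
    return x if x < s else x + 1
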