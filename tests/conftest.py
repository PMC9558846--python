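import itertools
import math

import numpy as np
import pytest

from phyloinfo import treeio as tio
from phyloinfo import mksampler as mk


@pytest.fixture(scope="session")
def taxa5():
    return tio.TaxonSet("ABCDE")


@pytest.fixture(scope="session")
def tops5(taxa5):
    return tio.enumerate_topologies(taxa5)


@pytest.fixture(scope="session")
def taxa6():
    return tio.TaxonSet("ABCDEF")


@pytest.fixture(scope="session")
def tops6(taxa6):
    return tio.enumerate_topologies(taxa6)


def brute_force_mk_loglik(matrix, topo, brlen, model):
    """Exhaustive sum over all internal-node state assignments (oracle)."""
    tree = mk._Tree.from_topology(topo, brlen)
    nodes = tree.nodes()
    internals = [nd for nd in nodes if nd.taxon < 0]
    rates = mk.discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    total = 0.0
    for j in range(matrix.n_chars):
        k = int(matrix.n_states[j])
        beta = 1.0 / (k - 1)
        tips = matrix.tip_partials(j)

        def psame(t, r):
            e = math.exp(-k * beta * t * r)
            return e + (1 - e) / k

        def pdiff(t, r):
            return (1 - math.exp(-k * beta * t * r)) / k

        site = 0.0
        for r in rates:
            for assign in itertools.product(range(k),
                                            repeat=len(internals) + 1):
                st = {id(nd): assign[i] for i, nd in enumerate(internals)}
                s0 = assign[-1]  # state of taxon 0
                if tips[0, s0] == 0:
                    continue
                rootst = st[id(tree.root)]
                p = (1.0 / k) * tips[0, s0] * (
                    psame(tree.root.length, r) if s0 == rootst
                    else pdiff(tree.root.length, r))
                for nd in nodes:
                    if nd is tree.root:
                        continue
                    pst = st[id(nd.parent)]
                    if nd.taxon >= 0:
                        sub = 0.0
                        for s in range(k):
                            if tips[nd.taxon, s] > 0:
                                sub += tips[nd.taxon, s] * (
                                    psame(nd.length, r) if s == pst
                                    else pdiff(nd.length, r))
                        p *= sub
                    else:
                        s = st[id(nd)]
                        p *= (psame(nd.length, r) if s == pst
                              else pdiff(nd.length, r))
                site += p / len(rates)
        total += math.log(site)
    return total
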