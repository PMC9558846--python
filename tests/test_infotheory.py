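import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloinfo import infotheory as it
from phyloinfo import treeio as tio
from phyloinfo.fixtures import make_synthetic_posterior


def _enumerated_entropy(ccd, tops):
    ps = [it.ccd_topology_prob(ccd, t) for t in tops]
    return -sum(p * math.log(p) for p in ps if p > 0), sum(ps)


class TestPluginDistribution:
    def test_point_mass(self, tops5):
        d = it.plugin_distribution(tio.TreeSample([tops5[0]] * 10))
        assert d.probs == {tops5[0].id: 1.0}

    def test_half_half(self, tops5):
        s = tio.TreeSample([tops5[0], tops5[0], tops5[1], tops5[1]])
        d = it.plugin_distribution(s)
        assert d.probs[tops5[0].id] == 0.5 and d.probs[tops5[1].id] == 0.5

    def test_frequencies_near_truth(self, tops5):
        probs = {tops5[0]: 0.6, tops5[1]: 0.3, tops5[2]: 0.1}
        s = make_synthetic_posterior(probs, 1000, seed=4)
        d = it.plugin_distribution(s)
        for topo, p in probs.items():
            se = math.sqrt(p * (1 - p) / 1000)
            assert abs(d.probs[topo.id] - p) < 2.6 * se  # 99% binomial CI


class TestCCD:
    def test_single_topology_conditionals(self, tops5):
        ccd = it.build_ccd(tio.TreeSample([tops5[0]] * 7))
        for clade, obs in ccd.splits.items():
            assert len(obs) == 1
            assert list(ccd.conditional(clade).values()) == [1.0]

    def test_disjoint_pair_root_split(self, tops5):
        t1, t2 = tops5[0], next(t for t in tops5
                                if not t.splits & tops5[0].splits)
        ccd = it.build_ccd(tio.TreeSample([t1, t2]))
        root = ccd.conditional(ccd.root_clade)
        assert sorted(root.values()) == [0.5, 0.5]

    def test_topology_prob_matches_product_oracle(self, tops5):
        rng = np.random.default_rng(2)
        sample = tio.TreeSample(
            [tio.random_topology(tops5[0].taxa, rng) for _ in range(100)])
        ccd = it.build_ccd(sample)
        for t in tops5:
            # independent brute-force product of conditional frequencies
            p = 1.0
            for clade, kids in t.child_splits().items():
                obs = ccd.splits.get(clade, {})
                tot = sum(obs.values())
                p = p * obs.get(kids, 0) / tot if tot else 0.0
            assert it.ccd_topology_prob(ccd, t) == pytest.approx(p, abs=1e-15)

    def test_unobserved_split_prob_zero(self, tops5):
        ccd = it.build_ccd(tio.TreeSample([tops5[0]] * 3))
        other = next(t for t in tops5 if t.id != tops5[0].id)
        assert it.ccd_topology_prob(ccd, other) == 0.0

    def test_ccd_converges_to_generating_distribution(self, tops6):
        # three topologies sharing splits
        base = tops6[0]
        shared = [t for t in tops6 if len(t.splits & base.splits) == 2]
        gen = {base: 0.5, shared[0]: 0.3, shared[1]: 0.2}
        errs = []
        for n in (200, 5000):
            s = make_synthetic_posterior(gen, n, seed=9)
            ccd = it.build_ccd(s)
            errs.append(max(abs(it.ccd_topology_prob(ccd, t) - p)
                            for t, p in gen.items()))
        assert errs[1] < errs[0] and errs[1] < 0.05


class TestEntropy:
    def test_point_mass_zero(self, tops5):
        ccd = it.build_ccd(tio.TreeSample([tops5[0]] * 5))
        assert it.ccd_entropy(ccd) == 0.0

    def test_two_equiprobable_one_split_apart(self, tops5):
        base = tops5[0]
        near = next(t for t in tops5 if len(t.splits & base.splits) == 1)
        ccd = it.build_ccd(tio.TreeSample([base, near]))
        assert it.ccd_entropy(ccd) == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_recursion_equals_enumeration(self, seed, tops5, tops6):
        rng = np.random.default_rng(seed)
        for tops in (tops5, tops6):
            taxa = tops[0].taxa
            sample = tio.TreeSample(
                [tio.random_topology(taxa, rng) for _ in range(60)])
            ccd = it.build_ccd(sample)
            H_enum, mass = _enumerated_entropy(ccd, tops)
            assert mass == pytest.approx(1.0, abs=1e-9)
            assert it.ccd_entropy(ccd) == pytest.approx(H_enum, abs=1e-9)


class TestPriorAndBPI:
    def test_prior_entropy_values(self):
        assert it.prior_entropy(4) == pytest.approx(math.log(3))
        assert it.prior_entropy(5) == pytest.approx(math.log(15))
        assert it.prior_entropy(10) == pytest.approx(
            math.log(tio.count_topologies(10)))

    def test_analytic_prior_is_uniform(self, tops5, tops6, taxa6):
        for tops, n in ((tops5, 5), (tops6, 6)):
            u = 1.0 / tio.count_topologies(n)
            for t in tops:
                assert it.analytic_prior_prob(t) == pytest.approx(u, rel=1e-12)

    def test_bpi_bounds(self, tops5):
        uniform = it.bpi(it.prior_entropy(5), 5)
        assert uniform.information_pct == pytest.approx(0.0)
        point = it.bpi(0.0, 5)
        assert point.information_pct == pytest.approx(100.0)

    def test_entropy_overshoot_rejected(self):
        with pytest.raises(ValueError):
            it.bpi(it.prior_entropy(5) + 0.1, 5)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=15))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_concentration_monotonicity(self, weights):
        # moving mass from a low- to a high-probability topology never
        # decreases information
        p = np.array(weights) / sum(weights)
        H0 = -np.sum(p * np.log(p))
        lo, hi = int(np.argmin(p)), int(np.argmax(p))
        if lo == hi:
            return
        q = p.copy()
        d = q[lo] * 0.5
        q[lo] -= d
        q[hi] += d
        H1 = -np.sum(q[q > 0] * np.log(q[q > 0]))
        assert H1 <= H0 + 1e-12


class TestCoverage:
    def test_point_mass_full_coverage(self, tops5):
        s = tio.TreeSample([tops5[0]] * 10)
        assert it.coverage(s) == pytest.approx(1.0)

    def test_support_equals_sample_gives_one(self, tops5):
        # two topologies sharing no splits: no unsampled recombinations
        t1 = tops5[0]
        t2 = next(t for t in tops5 if not t.splits & t1.splits)
        s = tio.TreeSample([t1, t1, t2])
        assert it.coverage(s) == pytest.approx(1.0)

    def test_recombination_leaks_probability(self, tops6):
        rng = np.random.default_rng(5)
        s = tio.TreeSample([tio.random_topology(tops6[0].taxa, rng)
                            for _ in range(20)])
        phi = it.coverage(s)
        assert 0 < phi <= 1.0


class TestDissonance:
    def test_identical_zero(self, tops5):
        s = tio.TreeSample([tops5[0], tops5[1], tops5[1]])
        r = it.dissonance([s, s])
        assert r.dissonance_D == pytest.approx(0.0, abs=1e-12)
        assert r.dissonance_pct == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_point_masses_max(self, tops5):
        d1 = it.plugin_distribution(tio.TreeSample([tops5[0]] * 3))
        d2 = it.plugin_distribution(tio.TreeSample([tops5[1]] * 3))
        r = it.dissonance([d1, d2], denominator="logk")
        assert r.dissonance_D == pytest.approx(math.log(2), abs=1e-12)
        assert r.dissonance_pct == pytest.approx(100.0)

    def test_mixture_value(self, tops5):
        d1 = it.plugin_distribution(tio.TreeSample([tops5[0]] * 2))
        s2 = tio.TreeSample([tops5[0], tops5[1]])
        d2 = it.plugin_distribution(s2)
        r = it.dissonance([d1, d2])
        expect = (-(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
                  - 0.5 * math.log(2))
        assert r.dissonance_D == pytest.approx(expect, abs=1e-12)

    def test_merged_identity_exact(self, tops5):
        rng = np.random.default_rng(11)
        ds = []
        for _ in range(4):
            s = tio.TreeSample([tops5[i] for i in rng.integers(0, 15, 30)])
            ds.append(it.plugin_distribution(s))
        r = it.dissonance(ds)
        assert r.merged_entropy == pytest.approx(
            r.mean_entropy + r.dissonance_D, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_jsd_bounds(self, tops5, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        ds = []
        for _ in range(k):
            w = rng.dirichlet(np.ones(15))
            probs = {t.id: float(p) for t, p in zip(tops5, w)}
            ds.append(it.TopologyDistribution(tops5[0].taxa, probs,
                                              topologies={t.id: t
                                                          for t in tops5}))
        r = it.dissonance(ds, denominator="logk")
        assert -1e-12 <= r.dissonance_D <= math.log(k) + 1e-12

    def test_among_run_near_zero_for_same_generator(self, tops6):
        gen = {tops6[0]: 0.5, tops6[1]: 0.3, tops6[2]: 0.2}
        r1 = make_synthetic_posterior(gen, 10_000, seed=1, run_id="run1")
        r2 = make_synthetic_posterior(gen, 10_000, seed=2, run_id="run2")
        res = it.among_run_dissonance(r1, r2)
        assert res.dissonance_pct < 1.0

    def test_needs_two(self, tops5):
        with pytest.raises(ValueError):
            it.dissonance([it.plugin_distribution(
                tio.TreeSample([tops5[0]]))])


class TestCladeComponents:
    def test_point_mass_sums_to_prior_entropy(self, tops5):
        ccd = it.build_ccd(tio.TreeSample([tops5[0]] * 4))
        table = it.clade_info_components(ccd)
        assert table.total_I == pytest.approx(math.log(15), rel=1e-12)

    def test_uniform_exhaustive_components_zero(self, tops5):
        ccd = it.build_ccd(tio.TreeSample(list(tops5)))
        table = it.clade_info_components(ccd)
        for _clade, (_prob, comp) in table.rows.items():
            assert comp == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation(self, seed, tops5):
        rng = np.random.default_rng(seed)
        s = tio.TreeSample([tio.random_topology(tops5[0].taxa, rng)
                            for _ in range(50)])
        ccd = it.build_ccd(s)
        table = it.clade_info_components(ccd)
        expect = it.prior_entropy(5) - it.ccd_entropy(ccd)
        assert table.total_I == pytest.approx(expect, abs=1e-9)


class TestCladePosterior:
    def test_counting(self, tops5, taxa5):
        t1 = tops5[0]
        split = sorted(t1.splits)[0]
        absent = next(t for t in tops5 if split not in t.splits)
        s = tio.TreeSample([t1] * 37 + [absent] * 63)
        assert it.clade_posterior(s, split) == pytest.approx(0.37)

    def test_always_and_never(self, tops5):
        t1 = tops5[0]
        split = sorted(t1.splits)[0]
        assert it.clade_posterior(tio.TreeSample([t1] * 5), split) == 1.0
        absent = next(t for t in tops5 if split not in t.splits)
        assert it.clade_posterior(tio.TreeSample([absent] * 5), split) == 0.0

    def test_trivial_clade_rejected(self, tops5):
        with pytest.raises(ValueError):
            it.clade_posterior(tio.TreeSample([tops5[0]]), 1)
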