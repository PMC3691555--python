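"""Diluted connectivity, associative storage, and attractor recall."""

import itertools

import numpy as np
import pytest

from hippomem.ca3 import (
    CA3Network,
    CA3Params,
    LearningRule,
    SynapticWeights,
    build_diluted_connectivity,
    build_duplicated_connectivity,
    make_partial_cue,
    recall,
)
from hippomem.patterns import completion_score, pattern_overlap
from hippomem.synth import PatternEnsembleSpec, generate_patterns


class TestDilutedConnectivity:
    def test_every_row_has_exactly_C_distinct_offdiagonal_contacts(self):
        conn = build_diluted_connectivity(N=5, C=2, seed=0)
        for i in range(5):
            row = conn.contacts[i]
            assert len(set(row)) == 2
            assert i not in row

    def test_max_multiplicity_one_without_duplicates(self):
        conn = build_diluted_connectivity(N=50, C=10, seed=1)
        assert conn.max_multiplicity() == 1

    def test_empirical_dilution_is_exact(self):
        # sampling without replacement gives exactly C/(N-1) per ordered pair
        for seed in range(20):
            conn = build_diluted_connectivity(N=200, C=40, seed=seed)
            counts = conn.count_matrix()
            assert counts.sum() == 200 * 40
            assert np.all(np.diag(counts) == 0)
            assert conn.dilution == pytest.approx(40 / 199)

    def test_C_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_diluted_connectivity(N=10, C=10)

    def test_reproducible_under_seed(self):
        a = build_diluted_connectivity(N=30, C=5, seed=7)
        b = build_diluted_connectivity(N=30, C=5, seed=7)
        assert np.array_equal(a.contacts, b.contacts)

    def test_symmetric_option_gives_symmetric_contacts_and_weights(self):
        from hippomem.ca3 import build_symmetric_connectivity

        conn = build_symmetric_connectivity(N=101, C=20, seed=4)
        counts = conn.count_matrix()
        assert np.array_equal(counts, counts.T)
        assert np.all(counts.sum(axis=1) == 20)
        w = SynapticWeights(conn)
        w.store_patterns(np.random.default_rng(0).random((3, 101)), LearningRule())
        assert np.allclose(w.w, w.w.T)

    def test_duplicated_connectivity_has_matched_C_and_multiplicity_two(self):
        conn = build_duplicated_connectivity(N=50, C=20, duplicate_fraction=0.5, seed=0)
        assert conn.contacts.shape == (50, 20)
        assert conn.max_multiplicity() == 2
        # half the contact slots belong to doubled pairs: 5 doubled partners/row
        for i in range(50):
            _, counts = np.unique(conn.contacts[i], return_counts=True)
            assert (counts == 2).sum() == 5


class TestStorePatterns:
    def _single_weight(self, pre_active, post_active, rule):
        # 2-unit network fragment embedded in N=3 so C=1 contacts exist
        conn = build_diluted_connectivity(N=2, C=1, seed=0)
        w = SynapticWeights(conn)
        pattern = np.array([1.0 if post_active else 0.0, 1.0 if pre_active else 0.0])
        w.store_patterns([pattern], rule)
        return w.w[0, 1]  # weight onto neuron 0 from neuron 1

    def test_no_patterns_leaves_weights_zero(self):
        conn = build_diluted_connectivity(N=10, C=3, seed=0)
        w = SynapticWeights(conn)
        w.store_patterns([], LearningRule())
        assert np.all(w.w == 0.0)

    def test_covariance_rule_ltp_when_both_active(self):
        # binary pattern with both units active, offsets a: dw = alpha (1-a)^2
        rule = LearningRule(alpha=2.0, rule="covariance", a_pre=0.1, a_post=0.1)
        assert self._single_weight(1, 1, rule) == pytest.approx(2.0 * 0.9 * 0.9)

    def test_covariance_rule_heterosynaptic_ltd(self):
        # active presynaptic, silent postsynaptic: dw = -alpha a (1 - a)
        rule = LearningRule(alpha=1.0, rule="covariance", a_pre=0.1, a_post=0.1)
        assert self._single_weight(1, 0, rule) == pytest.approx(-0.1 * 0.9)

    def test_hebb_rule_outer_product(self):
        rule = LearningRule(alpha=0.5, rule="hebb")
        assert self._single_weight(1, 1, rule) == pytest.approx(0.5)
        assert self._single_weight(1, 0, rule) == 0.0

    def test_storage_order_independent(self):
        rng = np.random.default_rng(3)
        conn = build_diluted_connectivity(N=40, C=10, seed=3)
        P = rng.random((6, 40))
        w1 = SynapticWeights(conn).store_patterns(P, LearningRule())
        w2 = SynapticWeights(conn).store_patterns(P[::-1].copy(), LearningRule())
        assert np.allclose(w1.w, w2.w)

    def test_weights_zero_off_contact_mask(self):
        conn = build_diluted_connectivity(N=30, C=4, seed=0)
        w = SynapticWeights(conn)
        w.store_patterns(np.random.default_rng(0).random((5, 30)), LearningRule())
        assert np.all(w.w[conn.count_matrix() == 0] == 0.0)

    def test_pattern_length_mismatch(self):
        conn = build_diluted_connectivity(N=10, C=3, seed=0)
        with pytest.raises(ValueError):
            SynapticWeights(conn).store_patterns(np.ones((1, 7)), LearningRule())


class TestRecall:
    def test_single_stored_pattern_is_recalled_exactly(self):
        params = CA3Params(N=100, C=30, a_target=0.1, seed=0)
        net = CA3Network(params)
        rng = np.random.default_rng(0)
        pattern = np.zeros(100)
        pattern[rng.choice(100, 10, replace=False)] = 1.0
        net.store([pattern])
        res = net.recall(pattern)
        assert res.converged
        assert pattern_overlap(res.final, pattern) == pytest.approx(1.0)

    def test_completion_from_half_cue_well_below_capacity(self):
        params = CA3Params(N=1000, C=200, a_target=0.05, seed=11)
        net = CA3Network(params)
        patterns = [
            p.rates for p in generate_patterns(PatternEnsembleSpec(N=1000, p=5, a=0.05, seed=11))
        ]
        net.store(np.array(patterns))
        rng = np.random.default_rng(5)
        for mu in range(5):
            cue, cued_idx = make_partial_cue(patterns[mu], 0.5, rng)
            res = net.recall(cue, reference=patterns[mu])
            assert completion_score(res.final, patterns[mu], cued_idx) >= 0.95

    def test_recall_sparseness_matches_target_every_step(self):
        params = CA3Params(N=200, C=50, a_target=0.1, seed=2)
        net = CA3Network(params)
        p = np.zeros(200)
        p[:20] = 1.0
        net.store([p])
        res = net.recall(p)
        assert (res.final > 0).sum() == round(0.1 * 200)

    def test_cue_orthogonal_to_stored_patterns_is_not_attributed(self):
        params = CA3Params(N=1000, C=200, a_target=0.05, seed=4)
        net = CA3Network(params)
        patterns = [
            p.rates for p in generate_patterns(PatternEnsembleSpec(N=1000, p=5, a=0.05, seed=4))
        ]
        net.store(np.array(patterns))
        # cue supported entirely on units silent in every stored pattern
        silent = np.flatnonzero(np.array(patterns).sum(axis=0) == 0)
        cue = np.zeros(1000)
        cue[silent[:50]] = 1.0
        res = net.recall(cue)
        assert max(pattern_overlap(res.final, p) for p in patterns) < 0.5

    def test_nonconvergence_is_flagged_not_raised(self):
        params = CA3Params(N=100, C=30, a_target=0.1, max_steps=1, seed=0, noise_sd=0.5)
        net = CA3Network(params)
        p = np.zeros(100)
        p[:10] = 1.0
        net.store([p])
        res = net.recall(np.roll(p, 13))
        assert isinstance(res.converged, bool)


class TestBruteForceEquivalence:
    """Synchronous recall agrees with exhaustive fixed-point enumeration at toy scale."""

    def _setup(self, N=10, k=2, n_patterns=2, seed=0):
        params = CA3Params(N=N, C=N - 1, a_target=k / N, cue_gain=0.0, seed=seed)
        net = CA3Network(params)
        rng = np.random.default_rng(seed)
        patterns = np.zeros((n_patterns, N))
        for mu in range(n_patterns):
            patterns[mu, rng.choice(N, k, replace=False)] = 1.0
        net.store(patterns)
        return net, patterns, k

    @staticmethod
    def _oracle_step(weights, state, k):
        """Independent one-step map: top-k drive, ties to the lowest index."""
        h = (weights.w @ state) / weights.connectivity.C
        order = sorted(range(len(state)), key=lambda i: (-h[i], i))
        nxt = np.zeros_like(state)
        for i in order[:k]:
            nxt[i] = 1.0
        return nxt

    def test_fixed_points_agree_with_enumeration(self):
        net, patterns, k = self._setup()
        N = net.params.N
        oracle_fixed = []
        for active in itertools.combinations(range(N), k):
            s = np.zeros(N)
            s[list(active)] = 1.0
            if np.array_equal(self._oracle_step(net.weights, s, k), s):
                oracle_fixed.append(s)
        assert oracle_fixed, "toy network should have at least one fixed point"
        # every oracle fixed point is invariant under the package dynamics
        for s in oracle_fixed:
            res = recall(net.weights, s, net.params)
            assert res.converged and res.n_steps == 1
            assert np.array_equal(res.final, s)
        # recall from every k-active state lands on an oracle fixed point or 2-cycle
        fixed_set = {tuple(s) for s in oracle_fixed}
        for active in itertools.combinations(range(N), k):
            s = np.zeros(N)
            s[list(active)] = 1.0
            res = recall(net.weights, s, net.params)
            if res.converged and res.n_steps == 1:
                assert tuple(res.final) in fixed_set
            elif res.converged:
                one = self._oracle_step(net.weights, res.final, k)
                two = self._oracle_step(net.weights, one, k)
                assert np.array_equal(two, res.final) or tuple(res.final) in fixed_set

    def test_stored_patterns_are_fixed_points(self):
        net, patterns, k = self._setup(N=12, k=3, n_patterns=2, seed=5)
        for mu in range(2):
            assert np.array_equal(self._oracle_step(net.weights, patterns[mu], k), patterns[mu])
            res = recall(net.weights, patterns[mu], net.params)
            assert np.array_equal(res.final, patterns[mu])
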