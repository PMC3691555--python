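"""Grid cells, dentate competitive learning, mossy-fiber and perforant-path routes."""

import numpy as np
import pytest

from hippomem.ca3 import CA3Network, CA3Params, make_partial_cue
from hippomem.dentate import (
    CompetitiveNet,
    CompetitiveNetParams,
    GridCellParams,
    MossyProjection,
    PerforantPath,
    grid_firing_map,
    grid_input_matrix,
    grid_population,
    linear_track_positions,
    mossy_projection,
    place_field_stats,
    train_competitive,
)
from hippomem.patterns import pattern_overlap, population_sparseness
from hippomem.synth import PatternEnsembleSpec, generate_patterns


class TestGridFiringMap:
    def test_peak_rate_at_lattice_vertex(self):
        cell = GridCellParams(spacing=30.0, orientation=0.3, phase=(5.0, -2.0), peak_rate=7.0)
        assert grid_firing_map(cell, np.array([[5.0, -2.0]]))[0] == pytest.approx(7.0)

    def test_periodic_under_lattice_translations(self):
        cell = GridCellParams(spacing=40.0, orientation=0.7, phase=(1.0, 2.0))
        rng = np.random.default_rng(0)
        pos = rng.uniform(-100, 100, size=(50, 2))
        v1, v2 = cell.lattice_vectors()
        base = grid_firing_map(cell, pos)
        for shift in (v1, v2, v1 + v2, 2 * v1 - v2):
            assert np.allclose(grid_firing_map(cell, pos + shift), base, atol=1e-9)

    def test_rates_nonnegative_and_mean_matches_quadrature_oracle(self):
        cell = GridCellParams(spacing=30.0, peak_rate=1.0)
        # independent oracle: direct evaluation of the three-cosine interference
        # pattern on a dense grid over one lattice period
        xs = np.linspace(0.0, 30.0, 301)
        ys = np.linspace(0.0, 30.0 * np.sqrt(3), 521)
        X, Y = np.meshgrid(xs, ys)
        kmag = 4 * np.pi / (np.sqrt(3) * 30.0)
        angles = np.pi / 6 + np.array([0.0, np.pi / 3, 2 * np.pi / 3])
        g = sum(np.cos(kmag * (X * np.cos(t) + Y * np.sin(t))) for t in angles)
        oracle_mean = np.maximum(0.0, (g + 1.5) / 4.5).mean()
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        rates = grid_firing_map(cell, pts)
        assert np.all(rates >= 0)
        assert rates.mean() == pytest.approx(oracle_mean, rel=1e-9)

    def test_invalid_positions_rejected(self):
        cell = GridCellParams(spacing=30.0)
        with pytest.raises(ValueError):
            grid_firing_map(cell, np.array([[np.inf, 0.0]]))


class TestCompetitiveNet:
    def _train(self, seed=0):
        cells = grid_population(seed=seed)
        X = grid_input_matrix(cells, linear_track_positions())
        params = CompetitiveNetParams(n_in=len(cells), n_out=200, a_out=0.05, seed=seed)
        net = CompetitiveNet(params)
        out_map = net.train(X)
        return net, X, out_map

    def test_weight_rows_unit_norm_after_training(self):
        net, _, _ = self._train()
        norms = np.linalg.norm(net.w, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_output_sparseness_is_exactly_a_out(self):
        _, _, out_map = self._train()
        for row in out_map:
            assert population_sparseness(row).a == pytest.approx(0.05)

    def test_zero_input_skipped_with_warning(self):
        params = CompetitiveNetParams(n_in=5, n_out=10, a_out=0.2, epochs=1, seed=0)
        net = CompetitiveNet(params)
        with pytest.warns(UserWarning):
            net.train(np.vstack([np.zeros(5), np.ones(5)]))

    def test_grid_to_place_separation(self):
        """Trained dentate outputs for distant positions are less correlated than
        the corresponding grid inputs (the pattern-separation claim)."""
        wins = 0
        for seed in range(5):
            _, X, out_map = self._train(seed=seed)
            i, j = 10, 35  # 50 cm apart on the 1 m track (50 samples)
            in_corr = pattern_overlap(X[i], X[j])
            out_corr = pattern_overlap(out_map[i], out_map[j])
            wins += out_corr < in_corr
        assert wins >= 4

    def test_trained_units_are_mostly_single_field(self):
        _, _, out_map = self._train(seed=1)
        stats = place_field_stats(out_map)
        counts = [s["n_fields"] for s in stats if s["n_fields"] > 0]
        assert len(counts) > 20
        assert np.mean(np.array(counts) == 1) > 0.5


class TestPlaceFieldStats:
    def test_single_gaussian_response_is_one_field(self):
        x = np.linspace(-3, 3, 60)
        out = np.exp(-(x**2))[:, None]
        stats = place_field_stats(out)
        assert stats[0]["n_fields"] == 1

    def test_raw_grid_input_has_multiple_fields(self):
        cell = GridCellParams(spacing=30.0)
        pos = linear_track_positions(length_cm=100.0, n=200)
        rates = grid_firing_map(cell, pos)[:, None]
        stats = place_field_stats(rates)
        assert stats[0]["n_fields"] >= 2  # track spans > 2 periods

    def test_silent_unit_has_zero_fields(self):
        stats = place_field_stats(np.zeros((10, 1)))
        assert stats[0]["n_fields"] == 0


class TestMossyProjection:
    def test_each_ca3_cell_receives_exactly_46_contacts_by_default(self):
        proj = MossyProjection(n_dg=1000, n_ca3=200, seed=0)
        assert proj.contacts.shape == (200, 46)
        for row in proj.contacts:
            assert len(set(row)) == 46

    def test_deterministic_given_projection(self):
        proj = MossyProjection(n_dg=500, n_ca3=300, seed=1)
        dg = generate_patterns(PatternEnsembleSpec(N=500, p=1, a=0.05, seed=2))[0]
        a = mossy_projection(dg, proj).rates
        b = mossy_projection(dg, proj).rates
        assert np.array_equal(a, b)

    def test_too_many_contacts_rejected(self):
        with pytest.raises(ValueError):
            MossyProjection(n_dg=10, n_ca3=5, n_contacts=46)

    @pytest.mark.parametrize("c_in", [0.4, 0.6, 0.8])
    def test_randomizing_effect_decorrelates(self, c_in):
        """Correlated dentate pairs drive less-correlated CA3 patterns."""
        out_corrs = []
        for seed in range(20):
            p1, p2 = generate_patterns(
                PatternEnsembleSpec(N=1000, p=2, a=0.05, pairwise_target_corr=c_in, seed=seed)
            )
            proj = MossyProjection(n_dg=1000, n_ca3=1000, seed=1000 + seed)
            out_corrs.append(
                pattern_overlap(mossy_projection(p1, proj), mossy_projection(p2, proj))
            )
        assert np.mean(out_corrs) < c_in


class TestPerforantPath:
    def test_full_cue_single_pattern_recovers_ca3_pattern_exactly(self):
        ec = generate_patterns(PatternEnsembleSpec(N=200, p=1, a=0.1, seed=0))[0].rates
        ca3 = generate_patterns(PatternEnsembleSpec(N=400, p=1, a=0.05, seed=1))[0].rates
        pp = PerforantPath(200, 400, a_ca3=0.05, seed=0).train(ec[None, :], ca3[None, :])
        assert pattern_overlap(pp.cue(ec), ca3) == pytest.approx(1.0)

    def test_half_cue_then_attractor_completion(self):
        rng = np.random.default_rng(7)
        EC = np.array(
            [p.rates for p in generate_patterns(PatternEnsembleSpec(N=400, p=5, a=0.1, seed=7))]
        )
        CA3 = np.array(
            [p.rates for p in generate_patterns(PatternEnsembleSpec(N=800, p=5, a=0.05, seed=8))]
        )
        pp = PerforantPath(400, 800, a_ca3=0.05, seed=0).train(EC, CA3)
        net = CA3Network(CA3Params(N=800, C=200, a_target=0.05, seed=9))
        net.store(CA3)
        for mu in range(5):
            half, _ = make_partial_cue(EC[mu], 0.5, rng)
            cue = pp.cue(half)
            res = net.recall(cue, reference=CA3[mu])
            assert pattern_overlap(res.final, CA3[mu]) >= 0.9

    def test_untrained_weights_give_chance_level_cue(self):
        # shared active fraction of two independent k-WTA patterns is ~a_ca3
        ec = generate_patterns(PatternEnsembleSpec(N=200, p=1, a=0.1, seed=3))[0].rates
        ca3 = generate_patterns(PatternEnsembleSpec(N=1000, p=1, a=0.05, seed=4))[0].rates
        pp = PerforantPath(200, 1000, a_ca3=0.05, seed=5)  # never trained
        cue = pp.cue(ec).rates
        shared = np.dot(cue, ca3) / cue.sum()
        assert shared == pytest.approx(0.05, abs=0.06)

    def test_mismatched_pair_counts(self):
        with pytest.raises(ValueError):
            PerforantPath(10, 20).train(np.ones((2, 10)), np.ones((3, 20)))
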