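"""Component maps, integration, winner-take-all, recognition, trial loop."""

import math

import numpy as np
import pytest

import refixate as rf
from refixate.model import (
    AttentionMapStack,
    Lattice,
    MemoryState,
    _crop_patch,
    cosine_distance,
    integrate_maps,
    normalize_map,
    recognition_map,
)


class StubBackend:
    """Backend returning pre-set feature stacks (for map arithmetic tests)."""

    def __init__(self, search_stack, template_stack=None, emb=None):
        self._search = np.asarray(search_stack, dtype=float)
        self._template = None if template_stack is None \
            else np.asarray(template_stack, dtype=float)
        self._emb = emb

    def modulation_features(self, image):
        return self._search

    def template_features(self, image):
        return self._template

    def embedding(self, image):
        return self._emb


class TestSimilarityMap:
    def test_matched_filter_peaks_at_template_location(self):
        search = np.zeros((2, 9, 9))
        tmpl = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3) + 1.0
        search[:, 3:6, 5:8] = tmpl  # exact copy centered at (4, 6)
        be = StubBackend(search, tmpl)
        m = rf.compute_similarity_map(be, None, None)
        assert np.unravel_index(np.argmax(m), m.shape) == (4, 6)

    def test_all_zero_search_features(self):
        be = StubBackend(np.zeros((3, 6, 6)), np.ones((3, 2, 2)))
        assert not rf.compute_similarity_map(be, None, None).any()

    def test_matches_nested_loop_convolution_oracle(self):
        rng = np.random.default_rng(8)
        search = rng.standard_normal((2, 5, 5))
        tmpl = rng.standard_normal((2, 3, 3))
        m = rf.compute_similarity_map(StubBackend(search, tmpl), None, None)
        # direct 'same'-mode cross-correlation with zero padding
        expected = np.zeros((5, 5))
        for y in range(5):
            for x in range(5):
                acc = 0.0
                for c in range(2):
                    for dy in range(3):
                        for dx in range(3):
                            sy, sx = y + dy - 1, x + dx - 1
                            if 0 <= sy < 5 and 0 <= sx < 5:
                                acc += tmpl[c, dy, dx] * search[c, sy, sx]
                expected[y, x] = acc
        np.testing.assert_allclose(m, expected, atol=1e-10)

    def test_template_larger_than_search_errors(self):
        be = StubBackend(np.ones((1, 3, 3)), np.ones((1, 5, 5)))
        with pytest.raises(ValueError, match="larger"):
            rf.compute_similarity_map(be, None, None)


class TestSaliencyMap:
    def test_identical_channels_equal_single_channel(self):
        ch = np.random.default_rng(0).uniform(size=(4, 6))
        m = rf.compute_saliency_map(StubBackend(np.stack([ch] * 5)), None)
        np.testing.assert_allclose(m, ch)

    def test_one_hot_channel_mean(self):
        stack = np.zeros((4, 3, 3))
        stack[1, 2, 2] = 0.8
        m = rf.compute_saliency_map(StubBackend(stack), None)
        assert m[2, 2] == pytest.approx(0.8 / 4)
        assert m.sum() == pytest.approx(0.8 / 4)

    def test_random_stack_mean_oracle(self):
        stack = np.random.default_rng(1).uniform(size=(7, 4, 5))
        np.testing.assert_allclose(
            rf.compute_saliency_map(StubBackend(stack), None), stack.mean(axis=0))


class TestSaccadePrior:
    lattice = Lattice(shape=(40, 40), extent=(20.0, 20.0))

    def test_point_mass_forms_ring(self):
        dist = rf.SaccadeSizeDistribution(
            bin_edges=np.array([4.5, 5.5]), probs=np.array([1.0]))
        m = rf.saccade_prior_map((10.0, 10.0), dist, self.lattice)
        X, Y = self.lattice.cell_centers()
        r = np.hypot(X - 10.0, Y - 10.0)
        on_ring = np.abs(r - 5.0) < 0.25
        assert m[on_ring].min() > 0.9
        assert m[np.abs(r - 5.0) > 2.0].max() < 0.2

    def test_uniform_distribution_constant_inside_support(self):
        dist = rf.SaccadeSizeDistribution(
            bin_edges=np.linspace(0, 40, 41), probs=np.full(40, 1 / 40))
        m = rf.saccade_prior_map((10.0, 10.0), dist, self.lattice)
        # flat density over the support -> constant map collapses to zeros
        assert np.allclose(m, 0.0)

    def test_values_match_radial_interpolator_along_ray(self):
        rng = np.random.default_rng(0)
        amps = rng.gamma(2.0, 2.0, size=5000)
        dist = rf.SaccadeSizeDistribution.from_samples(amps, bin_width=0.5)
        m = rf.saccade_prior_map((10.25, 10.25), dist, self.lattice)
        X, Y = self.lattice.cell_centers()
        row = 20  # a horizontal ray through the fixation
        r = np.hypot(X[row] - 10.25, Y[row] - 10.25)
        raw = dist.density(r)
        expected = (raw - m.min() * 0) / raw.max() if raw.max() > 0 else raw
        lo, hi = dist.density(np.hypot(X - 10.25, Y - 10.25)).min(), \
            dist.density(np.hypot(X - 10.25, Y - 10.25)).max()
        np.testing.assert_allclose(m[row], (raw - lo) / (hi - lo), atol=1e-12)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            rf.SaccadeSizeDistribution(bin_edges=np.array([0.0]), probs=np.array([]))


class TestMemory:
    def test_decay_values(self):
        assert rf.memory_value(10, 10) == pytest.approx(1.0)
        assert rf.memory_value(10, 9) == pytest.approx(0.92)
        # nine fixations back: 0.92**9 ~ 0.472 < 0.5, so the floor applies
        assert rf.memory_value(10, 1) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            rf.memory_value(5, 6)

    def test_decay_monotone_and_bounded(self):
        vals = [rf.memory_value(30, t) for t in range(1, 31)]
        assert all(0.5 <= v <= 1.0 for v in vals)
        assert vals == sorted(vals)

    def test_single_fixation_gaussian_bump(self):
        lat = Lattice(shape=(20, 20), extent=(10.0, 10.0))
        state = MemoryState(history=[(5.25, 5.25)])
        m = rf.memory_map(state, lat, sigma=0.05)
        r, c = np.unravel_index(np.argmax(m), m.shape)
        assert lat.to_dva(r, c) == (5.25, 5.25)
        assert m.max() == pytest.approx(1.0)  # a_t of the only fixation
        # radial decay
        assert m[r, c + 3] < m[r, c + 1] < m[r, c]

    def test_revisit_overwrites_decayed_value(self):
        lat = Lattice(shape=(20, 20), extent=(10.0, 10.0))
        old = MemoryState(history=[(5.25, 5.25)] + [(1.25, 1.25)] * 11)
        m_old = rf.memory_map(old, lat, sigma=0.03)
        r, c = lat.nearest_cell(5.25, 5.25)
        assert m_old[r, c] == pytest.approx(0.5)  # decayed to the floor
        revisit = MemoryState(history=old.history + [(5.25, 5.25)])
        m_new = rf.memory_map(revisit, lat, sigma=0.03)
        assert m_new[r, c] == pytest.approx(1.0)  # newest visit wins

    def test_two_distant_fixations_elementwise_max(self):
        lat = Lattice(shape=(24, 24), extent=(12.0, 12.0))
        a, b = (3.25, 3.25), (9.25, 9.25)
        X, Y = lat.cell_centers()
        sigma_dva = 0.04 * 12.0

        def bump(center, amp):
            return amp * np.exp(
                -((X - center[0]) ** 2 + (Y - center[1]) ** 2) / (2 * sigma_dva ** 2))

        m = rf.memory_map(MemoryState(history=[a, b]), lat, sigma=0.04)
        expected = np.maximum(bump(a, rf.memory_value(2, 1)), bump(b, 1.0))
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_empty_history_all_zero(self):
        lat = Lattice(shape=(4, 4), extent=(4.0, 4.0))
        assert not rf.memory_map(MemoryState(), lat).any()


class TestIntegrationAndSelection:
    def _stack(self, **maps):
        z = np.zeros((4, 4))
        return AttentionMapStack(
            m_sim=maps.get("m_sim"), m_sal=maps.get("m_sal"),
            m_sac=maps.get("m_sac", z), m_mem=maps.get("m_mem", z),
            m_f=z, step=1,
        )

    def test_free_viewing_reduces_to_saliency(self):
        sal = np.random.default_rng(0).uniform(size=(4, 4))
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=5, w_sac=0.0)
        out = integrate_maps(self._stack(m_sal=sal), cfg)
        np.testing.assert_allclose(out, sal)

    def test_memory_weight_subtracts(self):
        mem = np.zeros((4, 4))
        mem[2, 2] = 1.0
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=5, w_sac=0.0)
        out = integrate_maps(self._stack(m_sal=np.ones((4, 4)), m_mem=mem), cfg)
        assert out[2, 2] == pytest.approx(1.0 - 0.93)
        assert out[0, 0] == pytest.approx(1.0)

    def test_all_zero_maps(self):
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=5)
        assert not integrate_maps(self._stack(m_sal=np.zeros((4, 4))), cfg).any()

    def test_shape_mismatch_errors(self):
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=5)
        stack = self._stack(m_sal=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            integrate_maps(stack, cfg)

    def test_winner_take_all_and_tie_break(self):
        m = np.zeros((3, 4))
        m[1, 2] = 2.0
        assert rf.select_next_fixation(m) == (1, 2)
        tie = np.zeros((3, 4))
        tie[0, 3] = tie[2, 1] = 5.0
        assert rf.select_next_fixation(tie) == (0, 3)  # lowest row-major index
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(6, 7))
        best, where = -np.inf, None
        for r in range(6):
            for c in range(7):
                if m[r, c] > best:
                    best, where = m[r, c], (r, c)
        assert rf.select_next_fixation(m) == where
        with pytest.raises(ValueError):
            rf.select_next_fixation(np.full((2, 2), np.nan))

    def test_normalize_map_conventions(self):
        m = np.array([[1.0, 3.0], [2.0, 5.0]])
        out = normalize_map(m)
        assert out.min() == 0.0 and out.max() == 1.0
        assert not normalize_map(np.full((3, 3), 4.2)).any()

    def test_config_guards(self):
        with pytest.raises(ValueError):
            rf.ModelConfig(w_sim=1.0, w_sal=1.0)
        with pytest.raises(ValueError):
            rf.ModelConfig(alpha=1.5)


class TestRecognition:
    def test_identical_embedding_distance_zero(self):
        be = StubBackend(None, emb=np.array([1.0, 2.0, 3.0]))
        found, d = rf.recognize_at_fixation(
            be, np.ones((8, 8)), (1.0, 1.0), np.ones((8, 8)), (4.0, 4.0), 0.3)
        assert found and d == pytest.approx(0.0)

    def test_cosine_geometry(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1, 0], [1, math.sqrt(3)]) == pytest.approx(0.5)
        assert cosine_distance([0, 0], [1, 1]) is None

    def test_orthogonal_never_found(self):
        class TwoEmb:
            def __init__(self):
                self.calls = 0

            def modulation_features(self, image):
                return None

            def template_features(self, image):
                return None

            def embedding(self, image):
                self.calls += 1
                return np.array([1.0, 0.0]) if self.calls % 2 else np.array([0.0, 1.0])

        found, d = rf.recognize_at_fixation(
            TwoEmb(), np.ones((8, 8)), (1.0, 1.0), np.ones((8, 8)), (4.0, 4.0), 1.0)
        assert d == pytest.approx(1.0) and not found

    def test_zero_embedding_warns_not_found(self):
        be = StubBackend(None, emb=np.zeros(4))
        with pytest.warns(UserWarning, match="degenerate"):
            found, d = rf.recognize_at_fixation(
                be, np.ones((8, 8)), (1.0, 1.0), np.ones((8, 8)), (4.0, 4.0), 0.5)
        assert not found and d is None

    def test_border_patch_zero_padded(self):
        img = np.ones((8, 8))
        patch = _crop_patch(img, 0.0, 0.0, (4.0, 4.0), 1.0)
        assert patch.shape == (2, 2)
        assert patch.sum() == pytest.approx(1.0)  # 3 of 4 pixels padded

    def test_recognition_map_stride(self, backend):
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=1, kind="object_array"))
        lat = Lattice(shape=(8, 10), extent=scene.spec.extent)
        m = recognition_map(
            backend, scene.image, scene.template, scene.spec.extent, lat, stride=4)
        assert np.isfinite(m[0, 0]) or np.isinf(m[0, 0])
        assert np.isnan(m[1, 1])  # unsampled cell


class TestRunTrial:
    def test_free_viewing_budget_and_determinism(self, backend, saccade_dist):
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=2))
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=6)
        a = rf.run_trial(backend, cfg, scene.image, saccade_dist,
                         scene.spec.extent, mode="free_viewing", seed=0)
        b = rf.run_trial(backend, cfg, scene.image, saccade_dist,
                         scene.spec.extent, mode="free_viewing", seed=0)
        assert len(a) == 6
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_first_fixation_at_center(self, backend, saccade_dist):
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=3))
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=3)
        sp = rf.run_trial(backend, cfg, scene.image, saccade_dist,
                          scene.spec.extent, mode="free_viewing", seed=0)
        w, h = scene.spec.extent
        assert abs(sp.fixations[0].x - w / 2) <= w / 80
        assert abs(sp.fixations[0].y - h / 2) <= h / 64

    def test_fixations_stay_within_extent(self, backend, saccade_dist):
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=4))
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=12)
        sp = rf.run_trial(backend, cfg, scene.image, saccade_dist,
                          scene.spec.extent, mode="free_viewing", seed=1)
        w, h = scene.spec.extent
        assert np.all((sp.xy[:, 0] >= 0) & (sp.xy[:, 0] <= w))
        assert np.all((sp.xy[:, 1] >= 0) & (sp.xy[:, 1] <= h))

    def test_memory_suppresses_previous_fixation(self, backend, saccade_dist):
        """With w_mem < 0 the integrated value at the previous fixation is
        strictly below its value under w_mem = 0, for the same stack."""
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=5))
        cfg = rf.ModelConfig.for_free_viewing(n_fixations=5)
        sp, stacks = rf.run_trial(
            backend, cfg, scene.image, saccade_dist, scene.spec.extent,
            mode="free_viewing", seed=0, record_stacks=True)
        lat = Lattice(shape=stacks[0].m_sac.shape, extent=scene.spec.extent)
        from dataclasses import replace as dc_replace

        cfg0 = dc_replace(cfg, w_mem=0.0)
        for stack, fix in zip(stacks, sp.fixations):
            r, c = lat.nearest_cell(fix.x, fix.y)
            with_mem = integrate_maps(stack, cfg)[r, c]
            without = integrate_maps(stack, cfg0)[r, c]
            assert with_mem < without

    def test_search_stops_on_planted_match(self, backend, saccade_dist):
        """A verbatim template in the scene stops the search when fixated."""
        scene = rf.gen_scene(
            rf.SyntheticSceneSpec(seed=6, kind="object_array", target_index=0))
        cfg = rf.ModelConfig.for_search(
            recognition_threshold=0.05,
            recognition_patch=scene.spec.object_size_dva)
        sp = rf.run_trial(
            backend, cfg, scene.image, saccade_dist, scene.spec.extent,
            target_image=scene.template, mode="search", seed=0)
        assert len(sp) <= cfg.max_fixations

    def test_search_requires_target(self, backend, saccade_dist):
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=7))
        cfg = rf.ModelConfig.for_search()
        with pytest.raises(ValueError, match="target"):
            rf.run_trial(backend, cfg, scene.image, saccade_dist,
                         scene.spec.extent, mode="search", seed=0)

    def test_free_viewing_requires_budget(self, backend, saccade_dist):
        scene = rf.gen_scene(rf.SyntheticSceneSpec(seed=8))
        cfg = rf.ModelConfig(w_sal=1.0)
        with pytest.raises(ValueError, match="n_fixations"):
            rf.run_trial(backend, cfg, scene.image, saccade_dist,
                         scene.spec.extent, mode="free_viewing", seed=0)
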