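"""Texture dictionary, label/probability transforms and curve evolution."""

import numpy as np
import pytest

from wcbaseg import dictseg, metrics


def make_prob(e_in):
    e_in = np.asarray(e_in, dtype=float)
    return dictseg.ProbabilityMap(E=np.stack([e_in, 1 - e_in]),
                                  E_tilde=np.stack([e_in, 1 - e_in]))


class FakeRng:
    def __init__(self, values):
        self.values = list(values)

    def uniform(self, size=()):
        v = self.values.pop(0)
        return np.full(size, v) if size != () else v


class TestPatchesAndDictionary:
    def test_four_by_four_gives_four_patches(self, rng):
        img = rng.uniform(size=(4, 4))
        patches, origins = dictseg.extract_patches(img, 3)
        assert patches.shape == (4, 9)
        assert origins.tolist() == [[0, 0], [0, 1], [1, 0], [1, 1]]

    def test_constant_image_identical_patches(self):
        patches, _ = dictseg.extract_patches(np.full((6, 6), 0.3), 3)
        assert np.all(patches == 0.3)

    def test_matches_slicing_oracle(self, rng):
        img = rng.uniform(size=(8, 8))
        patches, origins = dictseg.extract_patches(img, 3)
        for (r, c), vec in zip(origins, patches):
            assert np.array_equal(vec, img[r : r + 3, c : c + 3].ravel())

    def test_invalid_patch_size_rejected(self, rng):
        img = rng.uniform(size=(8, 8))
        with pytest.raises(ValueError):
            dictseg.extract_patches(img, 4)
        with pytest.raises(ValueError):
            dictseg.extract_patches(img, 9)

    def test_two_point_kmeans_recovers_values(self):
        patches = np.vstack([np.full((10, 9), 0.2), np.full((12, 9), 0.8)])
        dic = dictseg.build_dictionary(patches, 2, seed=0)
        assert np.allclose(sorted(dic.centers[:, 0]), [0.2, 0.8], atol=1e-9)
        assert len(set(dic.assignments[:10])) == 1
        assert dic.assignments[0] != dic.assignments[-1]

    def test_single_atom_center_is_mean(self, rng):
        patches = rng.uniform(size=(30, 9))
        dic = dictseg.build_dictionary(patches, 1, seed=0)
        assert np.allclose(dic.centers[0], patches.mean(axis=0), atol=1e-9)

    def test_fixed_seed_reproducible(self, rng):
        patches = rng.uniform(size=(60, 9))
        a = dictseg.build_dictionary(patches, 5, seed=3)
        b = dictseg.build_dictionary(patches, 5, seed=3)
        assert np.array_equal(a.assignments, b.assignments)


class TestBiadjacency:
    def _single_atom_G(self, rng):
        img = rng.uniform(size=(4, 4))
        patches, origins = dictseg.extract_patches(img, 3)
        dic = dictseg.build_dictionary(patches, 1, seed=0)
        return dictseg.build_biadjacency(dic, origins, img.shape)

    def test_coverage_counts(self, rng):
        G = self._single_atom_G(rng)
        rowsums = G.row_sums().reshape(4, 4)
        assert rowsums[0, 0] == 1  # corner covered by one patch
        assert rowsums[1, 1] == 4  # center covered by all four patches
        assert G.matrix.nnz == 4 * 9  # conservation: patches x patch_len

    def test_row_sums_match_coverage_oracle(self, rng):
        img = rng.uniform(size=(8, 8))
        patches, origins = dictseg.extract_patches(img, 3)
        dic = dictseg.build_dictionary(patches, 4, seed=0)
        G = dictseg.build_biadjacency(dic, origins, img.shape)
        cover = np.zeros((8, 8))
        for r, c in origins:
            cover[r : r + 3, c : c + 3] += 1
        assert np.array_equal(G.row_sums().reshape(8, 8), cover)

    def test_out_of_range_origin_rejected(self, rng):
        img = rng.uniform(size=(4, 4))
        patches, origins = dictseg.extract_patches(img, 3)
        dic = dictseg.build_dictionary(patches, 1, seed=0)
        bad = origins.copy()
        bad[0] = [3, 3]
        with pytest.raises(ValueError):
            dictseg.build_biadjacency(dic, bad, img.shape)


class TestLabelTransforms:
    def _G(self, rng, size=8, n_atoms=4):
        img = rng.uniform(size=(size, size))
        patches, origins = dictseg.extract_patches(img, 3)
        dic = dictseg.build_dictionary(patches, n_atoms, seed=0)
        return dictseg.build_biadjacency(dic, origins, img.shape)

    def test_full_label_gives_unit_frequencies(self, rng):
        G = self._G(rng)
        ones = np.ones((8, 8))
        layers = np.stack([ones, 1 - ones])
        dl = dictseg.labels_to_dict(G, layers)
        covered = G.col_sums() > 0
        assert np.all(dl.g[0, covered] == 1.0)
        assert np.all(dl.g[1, covered] == 0.0)

    def test_counting_oracle_single_atom(self, rng):
        img = rng.uniform(size=(6, 6))
        patches, origins = dictseg.extract_patches(img, 3)
        dic = dictseg.build_dictionary(patches, 1, seed=0)
        G = dictseg.build_biadjacency(dic, origins, img.shape)
        inside = np.zeros((6, 6))
        inside[:, :3] = 1.0
        dl = dictseg.labels_to_dict(G, np.stack([inside, 1 - inside]))
        # oracle: per dictionary pixel, label hits / coverage
        hits = np.zeros(9)
        cov = np.zeros(9)
        for r, c in origins:
            hits += inside[r : r + 3, c : c + 3].ravel()
            cov += 1
        assert np.allclose(dl.g[0], hits / cov, atol=1e-12)

    def test_area_normalize_symmetry_and_hand_case(self):
        dl = dictseg.DictLabels(g=np.array([[0.5, 0.5], [0.5, 0.5]]))
        out = dictseg.area_normalize(dl, np.array([10.0, 10.0]))
        assert np.allclose(out.g_tilde[0], 0.5)
        out = dictseg.area_normalize(dl, np.array([10.0, 30.0]))
        assert np.allclose(out.g_tilde[0], 0.75)  # (0.05)/(0.05 + 0.05/3)

    def test_area_normalize_conserves_unit_sum(self, rng):
        g = rng.dirichlet(np.ones(3), size=20).T
        dl = dictseg.DictLabels(g=g)
        out = dictseg.area_normalize(dl, np.array([5.0, 17.0, 120.0]))
        assert np.allclose(out.g_tilde.sum(axis=0), 1.0, atol=1e-9)

    def test_area_normalize_rejects_all_zero_areas(self):
        dl = dictseg.DictLabels(g=np.array([[0.5], [0.5]]))
        with pytest.raises(ValueError):
            dictseg.area_normalize(dl, np.array([0.0, 0.0]))

    def test_dict_to_probabilities_constant_fields(self, rng):
        G = self._G(rng)
        for value in (1.0, 0.5):
            gt = np.stack([np.full(G.n_dict_pixels, value),
                           np.full(G.n_dict_pixels, 1 - value)])
            prob = dictseg.dict_to_probabilities(
                G, dictseg.DictLabels(g=gt, g_tilde=gt)
            )
            assert np.allclose(prob.E[0], value, atol=1e-12)

    def test_dict_to_probabilities_matches_averaging_oracle(self, rng):
        img = rng.uniform(size=(6, 6))
        patches, origins = dictseg.extract_patches(img, 3)
        dic = dictseg.build_dictionary(patches, 2, seed=0)
        G = dictseg.build_biadjacency(dic, origins, img.shape)
        gt0 = rng.uniform(size=G.n_dict_pixels)
        gt = np.stack([gt0, 1 - gt0])
        prob = dictseg.dict_to_probabilities(G, dictseg.DictLabels(g=gt, g_tilde=gt))
        expected = np.zeros((6, 6))
        cov = np.zeros((6, 6))
        for (r, c), a in zip(origins, dic.assignments):
            block = gt0[a * 9 : (a + 1) * 9].reshape(3, 3)
            expected[r : r + 3, c : c + 3] += block
            cov[r : r + 3, c : c + 3] += 1
        assert np.allclose(prob.E[0], expected / cov, atol=1e-12)

    def test_multi_label_transform_two_labels(self):
        prob = dictseg.ProbabilityMap(E=np.stack([np.full((2, 2), 0.7),
                                                  np.full((2, 2), 0.3)]))
        out = dictseg.multi_label_transform(prob)
        assert np.allclose(out.E_tilde[0], 0.7)

    def test_multi_label_transform_ties_and_argmax(self, rng):
        E = rng.dirichlet(np.ones(3), size=(5, 5)).transpose(2, 0, 1)
        out = dictseg.multi_label_transform(dictseg.ProbabilityMap(E=E))
        argmax = E.argmax(axis=0)
        for x in range(3):
            strict = (E[x] == E.max(axis=0)) & (np.sort(E, axis=0)[-1] > np.sort(E, axis=0)[-2])
            assert np.all((out.E_tilde[x] > 0.5) == (strict & (argmax == x)))
        equal = dictseg.multi_label_transform(
            dictseg.ProbabilityMap(E=np.full((3, 2, 2), 1 / 3))
        )
        assert np.allclose(equal.E_tilde, 0.5)


class TestLevelSetOperators:
    def test_curvature_flat_interface(self):
        rr, cc = np.mgrid[0:64, 0:64]
        phi = (rr - 30.0).astype(float)
        kappa = dictseg.curvature(dictseg.LevelSet(phi))
        assert np.all(np.abs(kappa[5:-5, 5:-5]) < 1e-6)

    def test_curvature_circle_value_and_sign(self, circle_sdf):
        kappa = dictseg.curvature(dictseg.LevelSet(circle_sdf))
        band = np.abs(circle_sdf) < 2
        assert abs(kappa[band].mean() - 1 / 20) < 0.1 * (1 / 20)
        assert kappa[band].min() > 0  # convex inside region, inside-negative

    def test_stationary_at_half_probability(self, circle_sdf):
        level = dictseg.LevelSet(circle_sdf.copy(), curvature_weight=0.0)
        out = dictseg.evolve_step(level, make_prob(np.full((128, 128), 0.5)), 0)
        assert np.array_equal(out.phi, level.phi)

    def test_inside_grows_under_unit_evidence(self, circle_sdf):
        rr, cc = np.mgrid[0:128, 0:128]
        disk = np.hypot(rr - 64, cc - 64) < 40
        level = dictseg.LevelSet(circle_sdf.copy(), dt=0.5, curvature_weight=0.0)
        areas = [int((level.phi < 0).sum())]
        for _ in range(40):
            level = dictseg.evolve_step(level, make_prob(disk.astype(float)), 0)
            areas.append(int((level.phi < 0).sum()))
        assert all(b >= a for a, b in zip(areas, areas[1:]))
        assert areas[-1] > areas[0]

    def test_inside_shrinks_under_zero_evidence(self, circle_sdf):
        level = dictseg.LevelSet(circle_sdf.copy(), dt=0.5, curvature_weight=0.0)
        for _ in range(40):
            level = dictseg.evolve_step(level, make_prob(np.zeros((128, 128))), 0)
        assert (level.phi < 0).sum() < (circle_sdf < 0).sum()

    def test_chan_vese_zero_force_on_uniform_image(self, circle_sdf):
        level = dictseg.LevelSet(circle_sdf.copy(), curvature_weight=0.0)
        out = dictseg.chan_vese_step(level, np.full((128, 128), 0.6))
        assert np.allclose(out.phi, level.phi)

    def test_chan_vese_recovers_disk(self):
        rr, cc = np.mgrid[0:128, 0:128]
        truth = np.hypot(rr - 64, cc - 64) < 24
        img = np.where(truth, 0.8, 0.2)
        init = np.hypot(rr - 60, cc - 60) < 6
        level = dictseg.LevelSet(
            dictseg.reinitialize(np.where(init, -1.0, 1.0)), dt=2.0, curvature_weight=0.2
        )
        level = dictseg.chan_vese_warmup(level, img, 200)
        assert metrics.jaccard((level.phi < 0).astype(np.uint8),
                               truth.astype(np.uint8)) >= 0.95

    def test_reinitialize_preserves_signs_and_slope(self, rng):
        rr, cc = np.mgrid[0:64, 0:64]
        phi = 3.7 * (np.hypot(rr - 32, cc - 32) - 14.0) + rng.normal(0, 0.05, (64, 64))
        out = dictseg.reinitialize(phi)
        away = np.abs(phi) > 3.7  # more than one pixel from the interface
        assert np.array_equal(np.sign(out[away]), np.sign(phi[away]))
        gr, gc = np.gradient(out)
        band = np.abs(out) < 3
        assert np.abs(np.hypot(gr, gc)[band] - 1).mean() < 0.1


class TestWcbaCurveUpdate:
    def test_plain_fallback_identity_at_zero_speed(self, circle_sdf):
        level = dictseg.LevelSet(circle_sdf.copy(), dt=0.1)
        # rand = 0, k = 0.01 -> D = 1 = l_b: singular guard, plain update
        new, vel = dictseg.wcba_curve_update(
            level, circle_sdf.copy(), np.zeros_like(circle_sdf),
            np.zeros_like(circle_sdf), FakeRng([0.0, 0.01]),
        )
        assert np.array_equal(new.phi, level.phi)
        assert np.all(vel == 0)

    def test_zero_rand_scalar_form(self, rng):
        phi = rng.normal(size=(16, 16))
        speed = rng.normal(size=(16, 16))
        level = dictseg.LevelSet(phi, dt=0.1)
        k = 0.5
        new, _ = dictseg.wcba_curve_update(
            level, rng.normal(size=(16, 16)), rng.normal(size=(16, 16)),
            speed, FakeRng([0.0, k]),
        )
        l_b = 100.0 * k
        assert np.allclose(new.phi, (1.0 / (1.0 - l_b)) * 0.1 * speed, atol=1e-12)

    @pytest.mark.parametrize("form", ["rearranged", "direct"])
    def test_field_update_matches_elementwise_formula(self, rng, form):
        phi, prev, vel, speed = rng.normal(size=(4, 12, 12))
        level = dictseg.LevelSet(phi, dt=0.1)
        r, k = 0.37, 0.81
        new, velocity = dictseg.wcba_curve_update(
            level, prev, vel, speed, FakeRng([r, k]), form=form
        )
        z, l_b = 2.0, 100.0 * k
        D = 1.0 - r * z * (2.0 - l_b)
        if form == "rearranged":
            expected = (D / (D - l_b)) * (0.1 * speed - r * z * l_b * (prev + vel) / D)
        else:
            expected = phi + (1.0 - r * z) * l_b * (prev + vel) / D + 0.1 * speed
        assert np.allclose(new.phi, expected, atol=1e-12)
        assert np.allclose(velocity, expected - phi, atol=1e-12)

    def test_sign_anchor_restores_orientation(self, circle_sdf):
        level = dictseg.LevelSet(circle_sdf.copy(), dt=0.1)
        # r=0.9, large l_b gives a negative coefficient on (prev + Q)
        args = (circle_sdf.copy(), np.zeros_like(circle_sdf), np.zeros_like(circle_sdf))
        raw, _ = dictseg.wcba_curve_update(level, *args, FakeRng([0.9, 0.9]),
                                           anchor_sign=False)
        anchored, _ = dictseg.wcba_curve_update(level, *args, FakeRng([0.9, 0.9]),
                                                anchor_sign=True)
        agree_raw = np.mean((raw.phi < 0) == (level.phi < 0))
        agree_anchored = np.mean((anchored.phi < 0) == (level.phi < 0))
        assert agree_anchored >= agree_raw
        assert agree_anchored > 0.5


class TestSegment:
    def test_degenerate_init_rejected(self, rng):
        img = rng.uniform(size=(32, 32))
        with pytest.raises(ValueError):
            dictseg.segment(img, np.zeros((32, 32), bool))
        with pytest.raises(ValueError):
            dictseg.segment(img, np.ones((32, 32), bool))

    def test_single_texture_shrinks_under_curvature(self, rng):
        img = np.clip(0.5 + rng.normal(0, 0.02, (48, 48)), 0, 1)
        rr, cc = np.mgrid[0:48, 0:48]
        init = np.hypot(rr - 24, cc - 24) < 10
        cfg = dictseg.SegmentConfig(
            patch_size=5, n_atoms=8, curvature_weight=0.5, max_iter=120, seed=0
        )
        out = dictseg.segment(img, init, cfg)
        assert out.inside_mask.sum() < init.sum()

    def test_masks_partition_image(self, rng):
        img = np.clip(0.5 + rng.normal(0, 0.02, (32, 32)), 0, 1)
        rr, cc = np.mgrid[0:32, 0:32]
        init = np.hypot(rr - 16, cc - 16) < 6
        cfg = dictseg.SegmentConfig(patch_size=5, n_atoms=4, max_iter=30, min_iter=10, seed=0)
        out = dictseg.segment(img, init, cfg)
        assert np.array_equal(out.masks.sum(axis=0), np.ones((32, 32), dtype=np.uint8))
        assert len(out.label_change_trace) == out.n_iter

    def test_plain_and_wcba_modes_agree_on_two_region_image(self, rng):
        h = w = 96
        rr, cc = np.mgrid[0:h, 0:w]
        truth = np.hypot(rr - 48, cc - 48) < 22
        img = np.clip(np.where(truth, 0.7, 0.3) + rng.normal(0, 0.02, (h, w)), 0, 1)
        init = np.hypot(rr - 44, cc - 46) < 9
        results = {}
        for mode in ("plain", "wcba"):
            cfg = dictseg.SegmentConfig(mode=mode, seed=3)
            results[mode] = dictseg.segment(img, init, cfg)
        cross = metrics.dice(results["plain"].inside_mask, results["wcba"].inside_mask)
        assert cross >= 0.98
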