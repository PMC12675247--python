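"""Texture matrices against brute-force enumeration oracles on tiny ROIs."""

import numpy as np
import pytest
from scipy import ndimage

from perisurv.radiomics.texture import (
    DIRECTIONS_13,
    OFFSETS_26,
    TEXTURE_NAMES,
    gldm_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_matrix,
    texture_features,
)

# ---------------------------------------------------------------------------
# brute-force oracles: plain loops over voxels, no shifts or transforms


def oracle_glcm(levels, ng, d):
    p = np.zeros((ng, ng))
    it = np.ndindex(levels.shape)
    for idx in it:
        a = levels[idx]
        if a == 0:
            continue
        for sgn in (+1, -1):
            j = tuple(i + sgn * o for i, o in zip(idx, d))
            if all(0 <= jj < s for jj, s in zip(j, levels.shape)) and levels[j] > 0:
                p[a - 1, levels[j] - 1] += 1
    return p


def oracle_glrlm(levels, ng, d):
    runs = {}
    seen = np.zeros(levels.shape, dtype=bool)
    for idx in np.ndindex(levels.shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        prev = tuple(i - o for i, o in zip(idx, d))
        inb = all(0 <= p < s for p, s in zip(prev, levels.shape))
        if inb and levels[prev] == levels[idx]:
            continue  # not a run start
        # walk the run
        length = 0
        cur = idx
        while all(0 <= c < s for c, s in zip(cur, levels.shape)) and levels[cur] == levels[idx]:
            seen[cur] = True
            length += 1
            cur = tuple(c + o for c, o in zip(cur, d))
        runs[(levels[idx], length)] = runs.get((levels[idx], length), 0) + 1
    max_l = max((l for (_, l) in runs), default=1)
    mat = np.zeros((ng, max_l))
    for (g, l), c in runs.items():
        mat[g - 1, l - 1] = c
    return mat


def oracle_glszm(levels, ng):
    zones = {}
    for g in range(1, ng + 1):
        lab, n = ndimage.label(levels == g, structure=np.ones((3, 3, 3)))
        for z in range(1, n + 1):
            s = int((lab == z).sum())
            zones[(g, s)] = zones.get((g, s), 0) + 1
    max_s = max((s for (_, s) in zones), default=1)
    mat = np.zeros((ng, max_s))
    for (g, s), c in zones.items():
        mat[g - 1, s - 1] = c
    return mat


def oracle_gldm(levels, ng, alpha=0):
    deps = {}
    for idx in np.ndindex(levels.shape):
        g = levels[idx]
        if g == 0:
            continue
        k = 0
        for off in OFFSETS_26:
            j = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= jj < s for jj, s in zip(j, levels.shape)) and levels[j] > 0:
                if abs(int(levels[j]) - int(g)) <= alpha:
                    k += 1
        deps[(g, k)] = deps.get((g, k), 0) + 1
    max_k = max((k for (_, k) in deps), default=0)
    mat = np.zeros((ng, max_k + 1))
    for (g, k), c in deps.items():
        mat[g - 1, k] = c
    return mat


def oracle_ngtdm(levels, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for idx in np.ndindex(levels.shape):
        g = levels[idx]
        if g == 0:
            continue
        nbrs = []
        for off in OFFSETS_26:
            j = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= jj < s for jj, s in zip(j, levels.shape)) and levels[j] > 0:
                nbrs.append(levels[j])
        if not nbrs:
            continue
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - np.mean(nbrs))
    return n_i, s_i


def random_level_maps(n=8, max_shape=6, max_levels=4, seed=0):
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n):
        shape = tuple(rng.integers(2, max_shape + 1, 3))
        levels = rng.integers(0, max_levels + 1, shape)
        if (levels > 0).sum() < 2:
            levels[0, 0, 0] = 1
            levels[1, 0, 0] = 2
        maps.append((levels.astype(np.int64), max_levels))
    return maps


class TestMatricesAgainstOracles:
    @pytest.mark.parametrize("case", range(8))
    def test_glcm_and_glrlm_all_directions(self, case):
        levels, ng = random_level_maps(seed=11)[case]
        for d in DIRECTIONS_13:
            assert np.array_equal(glcm_matrix(levels, ng, d), oracle_glcm(levels, ng, d)), d
            got = glrlm_matrix(levels, ng, d)
            want = oracle_glrlm(levels, ng, d)
            w = max(got.shape[1], want.shape[1])
            got = np.pad(got, ((0, 0), (0, w - got.shape[1])))
            want = np.pad(want, ((0, 0), (0, w - want.shape[1])))
            assert np.array_equal(got, want), d

    @pytest.mark.parametrize("case", range(8))
    def test_zone_dependence_tone_matrices(self, case):
        levels, ng = random_level_maps(seed=29)[case]
        got = glszm_matrix(levels, ng)
        want = oracle_glszm(levels, ng)
        w = max(got.shape[1], want.shape[1])
        assert np.array_equal(np.pad(got, ((0, 0), (0, w - got.shape[1]))),
                              np.pad(want, ((0, 0), (0, w - want.shape[1]))))
        gotd = gldm_matrix(levels, ng)
        wantd = oracle_gldm(levels, ng)
        w = max(gotd.shape[1], wantd.shape[1])
        assert np.array_equal(np.pad(gotd, ((0, 0), (0, w - gotd.shape[1]))),
                              np.pad(wantd, ((0, 0), (0, w - wantd.shape[1]))))
        n_got, s_got = ngtdm_matrix(levels, ng)
        n_want, s_want = oracle_ngtdm(levels, ng)
        assert np.array_equal(n_got, n_want)
        assert np.allclose(s_got, s_want)


class TestTextureFeatures:
    def test_count_is_75(self):
        rng = np.random.default_rng(1)
        levels = rng.integers(1, 5, (5, 5, 5)).astype(np.int64)
        f = texture_features(levels, 4)
        assert len(f) == 75
        assert len(TEXTURE_NAMES) == 75
        families = {}
        for n in f:
            fam = n.split("__")[0]
            families[fam] = families.get(fam, 0) + 1
        assert families == {"glcm": 24, "glrlm": 16, "glszm": 16, "ngtdm": 5, "gldm": 14}

    def test_constant_roi_guards(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        f = texture_features(levels, 1)
        assert f["glcm__Contrast"] == 0.0
        assert f["glcm__Correlation"] == 1.0  # documented single-level convention
        assert f["glcm__MCC"] == 1.0
        # one run per direction covering the whole line
        assert f["glrlm__RunPercentage"] < 1.0
        assert f["ngtdm__Contrast"] == 0.0
        assert all(np.isfinite(v) for v in f.values())

    def test_checkerboard_glcm_hand_computed(self):
        # 2x2x1 checkerboard of levels {1,2}: every in-plane axial neighbour
        # pair couples 1 with 2 -> contrast along those directions is 1
        levels = np.array([[[1], [2]], [[2], [1]]], dtype=np.int64)
        for d in ((1, 0, 0), (0, 1, 0)):
            p = glcm_matrix(levels, 2, d)
            # two ordered pairs per direction, all discordant
            assert p[0, 0] == 0 and p[1, 1] == 0
            assert p[0, 1] == 2 and p[1, 0] == 2
            pn = p / p.sum()
            contrast = sum(
                pn[i, j] * (i - j) ** 2 for i in range(2) for j in range(2)
            )
            assert contrast == 1.0

    def test_rotation_invariance_of_direction_averaged_features(self):
        rng = np.random.default_rng(5)
        levels = rng.integers(0, 5, (6, 6, 6)).astype(np.int64)
        f0 = texture_features(levels, 4)
        f90 = texture_features(np.rot90(levels, k=1, axes=(0, 1)), 4)
        for k in f0:
            assert f0[k] == pytest.approx(f90[k], abs=1e-6), k

    def test_single_voxel_rejected(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        levels[1, 1, 1] = 1
        with pytest.raises(ValueError):
            texture_features(levels, 1)
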