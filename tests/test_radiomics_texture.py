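"""Texture matrices and features against exhaustive brute-force oracles.

The oracles below re-derive every count structure by explicit enumeration
(pixel-pair loops, line walks, flood fill, neighborhood loops) without any
of the vectorized machinery used by the implementation.
"""

import numpy as np
import pytest

from radfusion.radiomics.texture import (
    DIRECTIONS,
    QuantizedRoi,
    discretize,
    texture_features,
    texture_matrix,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_glcm(levels, mask, ng, direction):
    h, w = levels.shape
    dr, dc = direction
    out = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                out[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                out[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    return out


def brute_runs(levels, mask, direction):
    """All maximal constant-level in-mask runs along a direction."""
    h, w = levels.shape
    dr, dc = direction
    runs = []
    starts = [(r, c) for r in range(h) for c in range(w)]
    for r, c in starts:
        pr, pc = r - dr, c - dc  # only start where the previous cell breaks
        prev_same = (
            0 <= pr < h and 0 <= pc < w and mask[pr, pc] and mask[r, c]
            and levels[pr, pc] == levels[r, c]
        )
        if not mask[r, c] or prev_same:
            continue
        length, rr, cc = 0, r, c
        while (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
               and levels[rr, cc] == levels[r, c]):
            length += 1
            rr, cc = rr + dr, cc + dc
        runs.append((levels[r, c], length))
    return runs


def brute_glszm(levels, mask, ng):
    h, w = levels.shape
    seen = np.zeros((h, w), bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                g = levels[r, c]
                stack, size = [(r, c)], 0
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                                    and not seen[r2, c2] and levels[r2, c2] == g):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                zones.append((g, size))
    smax = int(mask.sum())
    out = np.zeros((ng, smax))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def brute_ngtdm(levels, mask, ng):
    h, w = levels.shape
    out = np.zeros((ng, 2))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = [levels[r2, c2]
                  for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                  if (dr, dc) != (0, 0)
                  and 0 <= (r2 := r + dr) < h and 0 <= (c2 := c + dc) < w
                  and mask[r2, c2]]
            if not nb:
                continue
            g = levels[r, c]
            out[g - 1, 0] += 1
            out[g - 1, 1] += abs(g - np.mean(nb))
    return out


def brute_gldm(levels, mask, ng, alpha=0):
    h, w = levels.shape
    out = np.zeros((ng, 9))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = sum(
                1
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
                and 0 <= (r2 := r + dr) < h and 0 <= (c2 := c + dc) < w
                and mask[r2, c2]
                and abs(int(levels[r2, c2]) - int(levels[r, c])) <= alpha
            )
            out[levels[r, c] - 1, dep] += 1
    return out


def _random_quantized(rng, ng=4):
    h, w = rng.integers(2, 7, size=2)
    levels = rng.integers(1, ng + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[0, 0] = True
    levels = np.where(mask, levels, 0)
    return QuantizedRoi(levels=levels, mask=mask, n_bins=ng,
                        bin_edges=np.linspace(0, 1, ng + 1))


# ---------------------------------------------------------------------------
# hand-worked examples
# ---------------------------------------------------------------------------

def test_glcm_checkerboard_horizontal_counts():
    levels = np.array([[1, 2], [2, 1]])
    q = QuantizedRoi(levels=levels, mask=np.ones((2, 2), bool), n_bins=2,
                     bin_edges=np.linspace(0, 1, 3))
    mats = texture_matrix("glcm", q)
    horiz = mats[0]  # direction (0, 1)
    assert horiz[0, 1] == 2 and horiz[1, 0] == 2
    assert horiz[0, 0] == 0 and horiz[1, 1] == 0


def test_constant_roi_degenerate_features():
    img = np.full((3, 3), 0.5)
    q = discretize(img, np.ones((3, 3), bool), 4)
    szm = texture_matrix("glszm", q)
    assert szm.sum() == 1 and szm[0, 8] == 1  # one zone of size 9
    glcm_f = texture_features("glcm", texture_matrix("glcm", q), n_pixels=9)
    assert glcm_f["JointEntropy"] == pytest.approx(0.0)
    ngtdm_f = texture_features("ngtdm", texture_matrix("ngtdm", q), n_pixels=9)
    assert ngtdm_f["Contrast"] == pytest.approx(0.0)


def test_glrlm_long_run_emphasis_hand_formula():
    # single row "1 1 2 2": horizontal runs (1,len2),(2,len2) -> LRE = 4
    levels = np.array([[1, 1, 2, 2]])
    q = QuantizedRoi(levels=levels, mask=np.ones((1, 4), bool), n_bins=2,
                     bin_edges=np.linspace(0, 1, 3))
    mats = texture_matrix("glrlm", q)
    horiz = mats[0]
    assert horiz[0, 1] == 1 and horiz[1, 1] == 1
    from radfusion.radiomics.texture import glrlm_features_single

    f = glrlm_features_single(horiz, n_pixels=4)
    assert f["LongRunEmphasis"] == pytest.approx(4.0)


def test_glszm_high_gray_level_zone_emphasis():
    # one zone of size 9 at top level g -> HGLZE = g^2
    for g in (2, 4):
        levels = np.full((3, 3), g)
        q = QuantizedRoi(levels=levels, mask=np.ones((3, 3), bool), n_bins=g,
                         bin_edges=np.linspace(0, 1, g + 1))
        f = texture_features("glszm", texture_matrix("glszm", q), n_pixels=9)
        assert f["HighGrayLevelZoneEmphasis"] == pytest.approx(g**2)


def test_unknown_kind_rejected():
    q = discretize(np.eye(3), np.ones((3, 3), bool), 2)
    with pytest.raises(ValueError):
        texture_matrix("wavelet", q)


# ---------------------------------------------------------------------------
# exhaustive property tests: >= 100 random small ROIs per family
# ---------------------------------------------------------------------------

N_TRIALS = 120


@pytest.mark.parametrize("trial", range(N_TRIALS))
def test_all_matrices_match_bruteforce(trial):
    rng = np.random.default_rng(1000 + trial)
    q = _random_quantized(rng)
    ng = q.n_bins

    for d, mat in zip(DIRECTIONS, texture_matrix("glcm", q)):
        assert np.array_equal(mat, brute_glcm(q.levels, q.mask, ng, d))

    for d, mat in zip(DIRECTIONS, texture_matrix("glrlm", q)):
        expected = np.zeros_like(mat)
        for g, length in brute_runs(q.levels, q.mask, d):
            expected[g - 1, length - 1] += 1
        assert np.array_equal(mat, expected)

    assert np.array_equal(texture_matrix("glszm", q),
                          brute_glszm(q.levels, q.mask, ng))
    assert np.allclose(texture_matrix("ngtdm", q),
                       brute_ngtdm(q.levels, q.mask, ng), atol=1e-10)
    assert np.array_equal(texture_matrix("gldm", q),
                          brute_gldm(q.levels, q.mask, ng))


def test_rotation_invariance_of_direction_averaged_features():
    rng = np.random.default_rng(5)
    img = rng.random((12, 12))
    mask = np.ones((12, 12), bool)
    q1 = discretize(img, mask, 6)
    q2 = discretize(np.rot90(img), np.rot90(mask), 6)
    for kind in ("glcm", "glrlm"):
        f1 = texture_features(kind, texture_matrix(kind, q1), n_pixels=144)
        f2 = texture_features(kind, texture_matrix(kind, q2), n_pixels=144)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), (kind, k)


def test_feature_cardinalities():
    q = discretize(np.random.default_rng(2).random((8, 8)),
                   np.ones((8, 8), bool), 5)
    expected = dict(glcm=24, glszm=16, glrlm=16, ngtdm=5, gldm=14)
    for kind, n in expected.items():
        f = texture_features(kind, texture_matrix(kind, q), n_pixels=64)
        assert len(f) == n, kind
        assert all(np.isfinite(v) for v in f.values())
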