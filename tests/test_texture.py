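import numpy as np
import pytest

from radharm import (
    DiscretisationSettings,
    builtin_profile,
    build_glcm,
    build_ngtdm,
    discretise_with,
    extract_single,
    glcm_features,
    ngtdm_features,
)
from radharm.discretise import DiscretisedROI
from radharm.texture import COARSENESS_CAP, NgtdmTable
from tests.conftest import make_volume
from tests.oracles import glcm_brute, ngtdm_brute

HARM = builtin_profile("harmonised")


def disc_from_levels(levels, mask=None, ng=None):
    """Wrap an integer level array directly as a DiscretisedROI."""
    levels = np.asarray(levels, dtype=np.int64)
    while levels.ndim < 3:
        levels = levels[np.newaxis]
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask).astype(bool)
        while mask.ndim < 3:
            mask = mask[np.newaxis]
    lv = np.where(mask, levels, 0)
    return DiscretisedROI(levels=lv, mask=mask, ng_eff=ng or int(levels.max()),
                          resolved_bounds=(0.0, float(levels.max())))


class TestGlcmConstruction:
    def test_uniform_roi_single_cell(self):
        vol = make_volume(np.full((4, 4, 4), 7.0))
        disc = discretise_with(vol, HARM.glcm)
        m = build_glcm(disc, HARM)
        p = m.probabilities
        assert p.shape == (1, 1)
        assert p[0, 0] == 1.0

    def test_2x2x1_grid_matches_exhaustive_enumeration(self):
        disc = disc_from_levels([[1, 2], [1, 2]])
        m = build_glcm(disc, HARM)
        brute = glcm_brute(disc.levels, disc.mask, HARM.glcm_directions,
                           HARM.glcm_offsets, ng=2)
        assert (m.counts == brute).all()
        assert m.counts.sum() == m.counts.T.sum()

    @pytest.mark.parametrize("profile_name", ["harmonised", "ibex_default", "cerr_default"])
    def test_random_toy_matches_enumeration(self, profile_name):
        # covers 13-direction offset-1, multi-offset {1,4,7}, and 4-direction 2D
        prof = builtin_profile(profile_name)
        rng = np.random.default_rng(11)
        levels = rng.integers(1, 5, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        disc = disc_from_levels(np.where(mask, levels, 0), mask, ng=4)
        m = build_glcm(disc, prof)
        brute = glcm_brute(disc.levels, disc.mask, prof.glcm_directions,
                           prof.glcm_offsets, ng=4)
        assert (m.counts == brute).all()

    def test_symmetry_and_marginal_identity(self):
        rng = np.random.default_rng(3)
        disc = disc_from_levels(rng.integers(1, 7, size=(5, 5, 5)), ng=6)
        m = build_glcm(disc, HARM)
        assert (m.counts == m.counts.T).all()
        p = m.probabilities
        assert p.sum() == pytest.approx(1.0)
        assert p.sum(axis=0) == pytest.approx(p.sum(axis=1))

    def test_isolated_voxel_degenerate(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True  # beyond offset-1 reach of the other voxel
        disc = disc_from_levels(np.where(mask, 1, 0), mask, ng=2)
        m = build_glcm(disc, HARM)
        assert m.degenerate

    def test_direction_order_irrelevant(self):
        rng = np.random.default_rng(5)
        disc = disc_from_levels(rng.integers(1, 5, size=(4, 4, 4)), ng=4)
        prof2 = HARM.perturbed(name="shuffled",
                               glcm_directions=tuple(reversed(HARM.glcm_directions)))
        assert (build_glcm(disc, HARM).counts == build_glcm(disc, prof2).counts).all()


class TestGlcmFeatures:
    def test_homogeneous_conventions(self):
        vol = make_volume(np.full((4, 4, 4), 3.0))
        m = build_glcm(discretise_with(vol, HARM.glcm), HARM)
        f = glcm_features(m)
        assert f == {
            "glcm_correlation": 1.0, "glcm_contrast": 0.0,
            "glcm_angular_second_moment": 1.0, "glcm_joint_entropy": 0.0,
            "glcm_difference_average": 0.0, "glcm_inverse_difference": 1.0,
        }

    def test_checkerboard_against_brute_force(self):
        # strict two-level checkerboard along one axis, single direction
        levels = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        disc = disc_from_levels(levels[np.newaxis, :, :, 0], ng=2)
        prof = HARM.perturbed(name="one_dir", glcm_directions=((0, 0, 1),))
        m = build_glcm(disc, prof)
        p = m.probabilities
        # brute-force feature evaluation straight from the 2x2 matrix
        i, j = np.indices((2, 2)) + 1.0
        mu = (i * p).sum()
        sd = np.sqrt((((i - mu) ** 2) * p).sum())
        f = glcm_features(m)
        assert f["glcm_contrast"] == pytest.approx((((i - j) ** 2) * p).sum())
        assert f["glcm_correlation"] == pytest.approx(
            (((i - mu) * (j - mu) * p).sum()) / sd ** 2)
        assert f["glcm_angular_second_moment"] == pytest.approx((p ** 2).sum())
        nz = p[p > 0]
        assert f["glcm_joint_entropy"] == pytest.approx(-(nz * np.log2(nz)).sum())
        # off-diagonal mass dominates for an alternating pattern
        assert p[0, 1] + p[1, 0] > p[0, 0] + p[1, 1]

    def test_entropy_self_consistency(self, textured_phantom):
        m = build_glcm(discretise_with(textured_phantom, HARM.glcm), HARM)
        f = glcm_features(m)
        p = m.probabilities.ravel()
        p = p[p > 0]
        assert f["glcm_joint_entropy"] == pytest.approx(-(p * np.log2(p)).sum(), abs=1e-12)

    def test_feature_bounds(self, textured_phantom):
        m = build_glcm(discretise_with(textured_phantom, HARM.glcm), HARM)
        f = glcm_features(m)
        ng = m.n_levels
        assert 0 < f["glcm_angular_second_moment"] <= 1
        assert 0 < f["glcm_inverse_difference"] <= 1
        assert f["glcm_contrast"] >= 0
        assert f["glcm_joint_entropy"] <= 2 * np.log2(ng)
        assert -1 <= f["glcm_correlation"] <= 1


class TestNgtdm:
    def test_uniform_roi_zero_differences(self):
        vol = make_volume(np.full((4, 4, 4), 9.0))
        t = build_ngtdm(discretise_with(vol, HARM.ngtdm), HARM)
        assert (t.s == 0).all()
        f = ngtdm_features(t)
        assert f["ngtdm_coarseness"] == COARSENESS_CAP
        assert f["ngtdm_busyness"] == 0.0
        assert f["ngtdm_contrast"] == 0.0

    def test_centre_spike_plane_exhaustive(self):
        levels = np.ones((3, 3), dtype=int)
        levels[1, 1] = 2
        disc = disc_from_levels(levels, ng=2)
        t = build_ngtdm(disc, HARM)
        n, s, n_valid = ngtdm_brute(disc.levels, disc.mask, d=1, ng=2)
        assert (t.n == n).all()
        assert t.s == pytest.approx(s)
        assert t.n_valid == n_valid == 9
        assert t.s[1] == pytest.approx(1.0)  # centre: |2 - 1| over 8 level-1 neighbours

    @pytest.mark.parametrize("distance", [1, 2])
    def test_random_toy_matches_enumeration(self, distance):
        prof = HARM.perturbed(name=f"d{distance}", ngtdm_distance=distance)
        rng = np.random.default_rng(23)
        levels = rng.integers(1, 5, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.25
        disc = disc_from_levels(np.where(mask, levels, 0), mask, ng=4)
        t = build_ngtdm(disc, prof)
        n, s, n_valid = ngtdm_brute(disc.levels, disc.mask, d=distance, ng=4)
        assert (t.n == n).all()
        assert t.s == pytest.approx(s)
        assert t.n_valid == n_valid

    def test_masked_neighbours_excluded_from_mean(self):
        # centre 2 with one ring voxel masked out: its level must not enter Abar
        levels = np.ones((3, 3), dtype=int)
        levels[1, 1] = 2
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        disc = disc_from_levels(levels, mask, ng=2)
        t = build_ngtdm(disc, HARM)
        assert t.s[1] == pytest.approx(1.0)  # all 7 masked neighbours are level 1
        assert t.n_valid == 8

    def test_features_match_direct_formula(self, textured_phantom):
        t = build_ngtdm(discretise_with(textured_phantom, HARM.ngtdm), HARM)
        f = ngtdm_features(t)
        # independent evaluation straight from the table definition
        p, s = t.p, t.s
        idx = np.where(p > 0)[0]
        i = idx + 1.0
        ps = (p * s).sum()
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / ps)
        den = sum(abs(a * p[int(a - 1)] - b * p[int(b - 1)]) for a in i for b in i)
        assert f["ngtdm_busyness"] == pytest.approx(ps / den)
        ngp = len(i)
        con = sum(p[int(a - 1)] * p[int(b - 1)] * (a - b) ** 2 for a in i for b in i)
        con = con / (ngp * (ngp - 1)) * (s.sum() / t.n_valid)
        assert f["ngtdm_contrast"] == pytest.approx(con)

    def test_coarseness_inverse_homogeneity(self):
        t = NgtdmTable(n=np.array([5, 5]), s=np.array([1.0, 2.0]), n_valid=10)
        t2 = NgtdmTable(n=np.array([5, 5]), s=np.array([2.0, 4.0]), n_valid=10)
        c1 = ngtdm_features(t)["ngtdm_coarseness"]
        c2 = ngtdm_features(t2)["ngtdm_coarseness"]
        assert c2 == pytest.approx(c1 / 2)

    def test_single_level_contrast_zero(self):
        t = NgtdmTable(n=np.array([10]), s=np.array([0.5]), n_valid=10)
        assert ngtdm_features(t)["ngtdm_contrast"] == 0.0


def test_bin_count_moves_texture_not_raw_intensity(textured_phantom):
    """Changing only the grey-level count alters every texture feature but
    leaves raw-intensity first-order features untouched."""
    p64 = builtin_profile("harmonised")
    p400 = p64.perturbed(name="h400", histogram={"n_bins": 400},
                         glcm={"n_bins": 400}, ngtdm={"n_bins": 400})
    f64 = extract_single(textured_phantom, p64)
    f400 = extract_single(textured_phantom, p400)
    raw = ["volume", "area", "sphericity", "minimum", "maximum", "mean",
           "standard_deviation"]
    texture = ["skewness", "glcm_correlation", "glcm_contrast",
               "glcm_angular_second_moment", "glcm_joint_entropy",
               "glcm_difference_average", "glcm_inverse_difference",
               "ngtdm_coarseness", "ngtdm_busyness", "ngtdm_contrast"]
    for feat in raw:
        assert f64[feat] == f400[feat]
    changed = [feat for feat in texture if not np.isclose(f64[feat], f400[feat], rtol=1e-6)]
    assert len(changed) >= 9  # skewness may shift little; all matrix features move
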