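import numpy as np
import pytest

from petex.preprocess import quantize
from petex.texture import (
    DEFAULT_DIRECTIONS,
    average_directional,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    matrix_features,
    ngtdm_features,
)

from conftest import constant_quantized_voi, random_quantized_voi
from oracles import naive_glcm, naive_gldm, naive_glrlm, naive_glszm, naive_ngtdm

SPACING = (4.7, 4.7, 3.27)


def quantized_from_bins(bins_3d, n_bins=None):
    """QuantizedVoi with prescribed bin labels (0 = outside VOI)."""
    bins_3d = np.asarray(bins_3d, dtype=np.int64)
    mask = bins_3d > 0
    idx = np.argwhere(mask)
    n_bins = n_bins or max(2, int(bins_3d.max()))
    q = quantize(bins_3d[mask].astype(float), n_bins=n_bins, indices=idx, spacing=SPACING)
    # use the prescribed labels verbatim
    q.bin_values = bins_3d[mask]
    q.bin_grid = bins_3d.copy()
    return q


class TestGlcm:
    def test_two_by_two_hand_example(self):
        # single slice [[1,1],[1,2]], offset along the second axis:
        # pairs (1,1) and (1,2) -> P(1,1)=0.5, P(1,2)=P(2,1)=0.25
        bins = np.array([[[1], [1]], [[1], [2]]])
        q = quantized_from_bins(bins)
        m = build_glcm(q, (0, 1, 0))
        assert m.probabilities[0, 0] == pytest.approx(0.5)
        assert m.probabilities[0, 1] == pytest.approx(0.25)
        assert m.probabilities[1, 0] == pytest.approx(0.25)
        vals, _ = glcm_features(m)
        assert vals["glcm_contrast"] == pytest.approx(0.5)
        assert vals["glcm_dissimilarity"] == pytest.approx(0.5)
        assert vals["glcm_energy"] == pytest.approx(0.375)
        assert vals["glcm_maximum_probability"] == pytest.approx(0.5)

    def test_constant_voi_degenerate(self):
        q = constant_quantized_voi()
        m = build_glcm(q, (1, 0, 0))
        vals, flags = glcm_features(m)
        assert vals["glcm_energy"] == 1.0
        assert vals["glcm_entropy"] == 0.0
        assert vals["glcm_contrast"] == 0.0
        assert vals["glcm_maximum_probability"] == 1.0
        assert vals["glcm_homogeneity"] == 1.0
        assert flags.get("glcm_correlation") == "zero_variance_marginal"

    def test_symmetry_random(self, rng):
        for _ in range(10):
            q = random_quantized_voi(rng)
            off = tuple(int(v) for v in rng.integers(-2, 3, size=3))
            if off == (0, 0, 0):
                off = (1, 0, 0)
            m = build_glcm(q, off)
            if m.empty:
                continue
            np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_uniform_matrix_entropy(self):
        # uniform over k^2 cells -> entropy 2 log2 k
        k = 4
        from petex.texture import CooccurrenceMatrix

        P = np.full((k, k), 1.0 / k**2)
        m = CooccurrenceMatrix(P * 16, P, k, (1, 0, 0), False)
        vals, _ = glcm_features(m)
        assert vals["glcm_entropy"] == pytest.approx(2 * np.log2(k), rel=1e-12)

    def test_too_thin_voi_flagged_empty(self):
        bins = np.ones((1, 1, 3), dtype=int)
        q = quantized_from_bins(bins)
        assert build_glcm(q, (5, 0, 0)).empty


class TestGldmIdentities:
    def test_constant_voi(self):
        q = constant_quantized_voi()
        vals = gldm_features(build_gldm(q, (1, 0, 0)))
        assert vals["gldm_mean"] == 0.0
        assert vals["gldm_contrast"] == 0.0
        assert vals["gldm_entropy"] == 0.0

    @pytest.mark.parametrize("offset", [(1, 0, 0), (0, 1, 1), (2, 2, 0), (1, 1, 1)])
    def test_cross_family_identities(self, rng, offset):
        # shared-pair construction forces: GLDM mean == GLCM dissimilarity,
        # GLDM/GLCM contrast == GLCM difference variance, GLDM entropy ==
        # GLCM difference entropy, homogeneity == inverse difference moment
        for _ in range(10):
            q = random_quantized_voi(rng, shape=(5, 5, 4))
            m = build_glcm(q, offset)
            if m.empty:
                continue
            g, _ = glcm_features(m)
            d = gldm_features(build_gldm(q, offset))
            assert d["gldm_mean"] == pytest.approx(g["glcm_dissimilarity"], abs=1e-9)
            assert d["gldm_contrast"] == pytest.approx(g["glcm_contrast"], abs=1e-9)
            assert g["glcm_difference_variance"] == pytest.approx(g["glcm_contrast"], abs=1e-9)
            assert d["gldm_entropy"] == pytest.approx(g["glcm_difference_entropy"], abs=1e-9)
            assert g["glcm_homogeneity"] == pytest.approx(
                g["glcm_inverse_difference_moment"], abs=1e-12
            )


class TestGlrlm:
    def test_1d_hand_example(self):
        # bins [1,1,2,2,2] -> runs (1,len2),(2,len3)
        bins = np.array([1, 1, 2, 2, 2]).reshape(5, 1, 1)
        q = quantized_from_bins(bins)
        m = build_glrlm(q, (1, 0, 0))
        vals = glrlm_features(m)
        assert m.n_runs == 2
        assert vals["glrl_short_run_emphasis"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert vals["glrl_long_run_emphasis"] == pytest.approx(6.5)
        assert vals["glrl_run_percentage"] == pytest.approx(2 / 5)

    def test_constant_line_closed_form(self):
        length = 7
        bins = np.ones((length, 1, 1), dtype=int)
        q = quantized_from_bins(bins)
        vals = glrlm_features(build_glrlm(q, (1, 0, 0)))
        assert vals["glrl_long_run_emphasis"] == pytest.approx(length**2)
        assert vals["glrl_run_percentage"] == pytest.approx(1 / length)

    def test_run_conservation_every_direction(self, rng):
        for _ in range(5):
            q = random_quantized_voi(rng, shape=(5, 4, 4))
            n_vox = int((q.bin_grid > 0).sum())
            for d in DEFAULT_DIRECTIONS:
                m = build_glrlm(q, d)
                lengths = np.arange(1, m.counts.shape[1] + 1)
                assert int((m.counts * lengths).sum()) == n_vox

    def test_voi_gap_terminates_run(self):
        bins = np.array([1, 1, 0, 1, 1]).reshape(5, 1, 1)
        q = quantized_from_bins(bins)
        m = build_glrlm(q, (1, 0, 0))
        assert m.n_runs == 2
        assert m.counts[0, 1] == 2  # two runs of length 2


class TestGlszm:
    def test_constant_voi_single_zone(self):
        q = constant_quantized_voi(shape=(3, 3, 3))
        m = build_glszm(q)
        vals = glszm_features(m)
        assert m.n_zones == 1
        assert vals["glszm_zone_percentage"] == pytest.approx(1 / 27)
        assert vals["glszm_long_zone_emphasis"] == pytest.approx(27**2)

    def test_checkerboard_26_connectivity_merges_diagonals(self):
        # single-slice 4x4 checkerboard of 2 bins: with 26-connectivity the
        # diagonal contacts merge each colour into one zone of 8 voxels
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        bins = board[:, :, None]
        q = quantized_from_bins(bins)
        oracle = naive_glszm(bins, 2, connectivity=26)
        m = build_glszm(q)
        np.testing.assert_array_equal(m.counts, oracle)
        assert m.n_zones == 2
        assert m.counts[0, 7] == 1 and m.counts[1, 7] == 1

    def test_zone_conservation(self, rng):
        for _ in range(5):
            q = random_quantized_voi(rng, shape=(5, 5, 3))
            m = build_glszm(q)
            sizes = np.arange(1, m.counts.shape[1] + 1)
            assert int((m.counts * sizes).sum()) == int((q.bin_grid > 0).sum())


class TestNgtdm:
    def test_constant_voi_degenerate(self):
        q = constant_quantized_voi(shape=(3, 3, 3))
        t = build_ngtdm(q)
        vals = ngtdm_features(t)
        assert vals["ngtdm_contrast"] == 0.0
        assert vals["ngtdm_busyness"] == 0.0
        assert vals["ngtdm_coarseness"] == pytest.approx(1e12)

    def test_two_level_alternation_matches_bruteforce(self):
        bins = (np.arange(6) % 2 + 1).reshape(6, 1, 1)
        q = quantized_from_bins(bins)
        t = build_ngtdm(q)
        p, s, n_valid = naive_ngtdm(bins, 2)
        np.testing.assert_allclose(t.p, p, atol=1e-12)
        np.testing.assert_allclose(t.s, s, atol=1e-12)
        assert t.n_valid == n_valid
        ours = ngtdm_features(t)
        assert ours["ngtdm_contrast"] > 0

    def test_occupancy_sums_to_one(self, rng):
        for _ in range(5):
            q = random_quantized_voi(rng)
            t = build_ngtdm(q)
            if not t.empty:
                assert t.p.sum() == pytest.approx(1.0, rel=1e-12)

    def test_isolated_voxel_excluded(self):
        bins = np.zeros((5, 1, 1), dtype=int)
        bins[0] = 1
        bins[4] = 2
        q = quantized_from_bins(bins)
        assert build_ngtdm(q).empty  # no voxel has an in-VOI neighbour


class TestOracleEquivalence:
    """Optimized builders equal naive triple-loop enumeration exactly."""

    def test_all_matrix_builders_match_naive(self, rng):
        offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 1, 1), (2, 0, 0), (-1, 1, 0)]
        for _ in range(30):
            q = random_quantized_voi(rng, shape=(4, 4, 3), n_bins=6)
            grid = q.bin_grid
            for off in offsets:
                np.testing.assert_array_equal(
                    build_glcm(q, off).counts, naive_glcm(grid, off, 6)
                )
                np.testing.assert_array_equal(
                    build_gldm(q, off).counts, naive_gldm(grid, off, 6)
                )
            for d in DEFAULT_DIRECTIONS:
                ours = build_glrlm(q, d).counts
                ref = naive_glrlm(grid, d, 6)
                np.testing.assert_array_equal(ours, ref)
            np.testing.assert_array_equal(build_glszm(q).counts, naive_glszm(grid, 6))
            p, s, n_valid = naive_ngtdm(grid, 6)
            t = build_ngtdm(q)
            np.testing.assert_allclose(t.p, p, atol=1e-12)
            np.testing.assert_allclose(t.s, s, atol=1e-10)


class TestAveraging:
    def test_isotropic_constant_equals_single_direction(self):
        q = constant_quantized_voi(shape=(5, 5, 5))
        avg, _ = average_directional(q)
        single, _ = glcm_features(build_glcm(q, (1, 0, 0)))
        for name, v in single.items():
            assert avg[name] == pytest.approx(v, abs=1e-12)

    def test_direction_order_irrelevant(self, rng):
        q = random_quantized_voi(rng, shape=(5, 5, 4))
        a, _ = average_directional(q, DEFAULT_DIRECTIONS)
        perm = tuple(reversed(DEFAULT_DIRECTIONS))
        b, _ = average_directional(q, perm)
        for name in a:
            assert a[name] == pytest.approx(b[name], rel=1e-12)

    def test_stripe_phantom_contrast_between_extremes(self):
        # stripes along x: along-stripe contrast 0 < averaged < across-stripe
        bins = np.tile((np.arange(6) % 2 + 1)[None, :, None], (6, 1, 3))
        q = quantized_from_bins(bins)
        along, _ = glcm_features(build_glcm(q, (1, 0, 0)))
        across, _ = glcm_features(build_glcm(q, (0, 1, 0)))
        avg, _ = average_directional(q)
        assert along["glcm_contrast"] < avg["glcm_contrast"] < across["glcm_contrast"]

    def test_axis_permutation_symmetry(self, rng):
        # axis permutations map the 7-direction set onto itself (90-degree
        # rotations do not: they send the face diagonal (1,1,0) to the
        # anti-diagonal, which is outside the set)
        q = random_quantized_voi(rng, shape=(5, 5, 4), n_bins=6)
        grid_rot = q.bin_grid.transpose(1, 0, 2).copy()
        q_rot = quantized_from_bins(grid_rot, n_bins=q.n_bins)
        a, _ = matrix_features(q)
        b, _ = matrix_features(q_rot)
        for name in a:
            if np.isnan(a[name]):
                assert np.isnan(b[name])
            else:
                assert a[name] == pytest.approx(b[name], rel=1e-9), name
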