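"""Feature extractors vs analytic values and brute-force recomputation."""

import numpy as np
import pytest

from skimage.draw import disk as skdisk

from chestcad.detect import Candidate, LikelihoodMap
from chestcad.features import (
    BASELINE_FEATURE_NAMES,
    PER_DOMAIN_FEATURE_NAMES,
    baseline_features,
    binarize_and_label,
    candidate_likelihood_features,
    circularity,
    extract_all,
    false_positive_feature,
    gradient_features,
    gray_features,
    perimeter_length,
    preprocess,
    shape_features,
    surface_features,
    texture_features,
)


def disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = skdisk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestPreprocess:
    def test_salt_pixel_removed_by_median(self):
        img = np.full((32, 32), 10.0)
        img[16, 16] = 1000.0
        out = preprocess(img, sharpen=False, equalize=False)
        assert out[16, 16] == 10.0

    def test_uniform_histogram_is_equalization_fixed_point(self):
        rng = np.random.default_rng(0)
        img = rng.permutation(np.linspace(0, 1, 32 * 32)).reshape(32, 32)
        out = preprocess(img, median=False, sharpen=False, equalize=True)
        # already-uniform histogram: change bounded by one 8-bit gray level
        assert np.abs(out - img).max() <= 1.0 / 255.0

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(32, 32))
        np.testing.assert_array_equal(preprocess(img), preprocess(img))


class TestBinarize:
    def test_all_below_threshold_empty(self):
        assert binarize_and_label(np.zeros((8, 8)), 0.5).max() == 0

    def test_two_squares_two_components(self):
        img = np.zeros((16, 16))
        img[2:5, 2:5] = 1.0
        img[10:14, 10:14] = 1.0
        labels = binarize_and_label(img, 0.5)
        assert labels.max() == 2
        areas = sorted(np.bincount(labels.ravel())[1:])
        assert areas == [9, 16]

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(2)
        img = (rng.random((16, 16)) > 0.6).astype(float)
        labels = binarize_and_label(img, 0.5)

        def flood_count(binary):
            seen = np.zeros_like(binary, bool)
            count = 0
            for r in range(16):
                for c in range(16):
                    if binary[r, c] and not seen[r, c]:
                        count += 1
                        stack = [(r, c)]
                        seen[r, c] = True
                        while stack:
                            y, x = stack.pop()
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    ny, nx = y + dy, x + dx
                                    if (0 <= ny < 16 and 0 <= nx < 16
                                            and binary[ny, nx]
                                            and not seen[ny, nx]):
                                        seen[ny, nx] = True
                                        stack.append((ny, nx))
            return count

        assert labels.max() == flood_count(img > 0.5)


class TestCircularity:
    def test_disk_near_one(self):
        m = disk_mask((61, 61), (30, 30), 20)
        assert 0.95 <= circularity(m) <= 1.05

    def test_square_is_pi_over_four(self):
        m = np.zeros((31, 31), bool)
        m[5:26, 5:26] = True
        assert perimeter_length(m) == pytest.approx(84.0)
        assert circularity(m) == pytest.approx(np.pi / 4.0)

    def test_line_is_elongated(self):
        m = np.zeros((5, 30), bool)
        m[2, 4:25] = True
        assert circularity(m) < 0.2

    def test_single_pixel_defined(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert perimeter_length(m) == 4.0
        assert circularity(m) == pytest.approx(4 * np.pi / 16)

    def test_perimeter_matches_shapely_hull_oracle(self):
        """Independent oracle: union of pixel boxes -> convex hull length."""
        from shapely.geometry import box
        from shapely.ops import unary_union

        rng = np.random.default_rng(3)
        m = disk_mask((41, 41), (20, 18), 12)
        m |= disk_mask((41, 41), (22, 24), 9)
        boxes = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5)
                 for r, c in zip(*np.nonzero(m))]
        oracle = unary_union(boxes).convex_hull.length
        assert perimeter_length(m) == pytest.approx(oracle, rel=1e-9)


class TestShape:
    def test_centered_disk(self):
        m = disk_mask((64, 64), (31.5, 31.5), 12)
        lung = np.ones((64, 64), bool)
        f = shape_features(m, lung)
        assert f["Shape_2"] == pytest.approx(1.0, abs=0.05)
        assert f["Shape_3"] == pytest.approx(1.0, abs=0.05)
        assert f["Shape_4"] == pytest.approx(0.0, abs=0.1)

    def test_rectangle_axis_ratio(self):
        m = np.zeros((64, 64), bool)
        m[10:20, 10:50] = True  # 10 x 40
        f = shape_features(m)
        assert f["Shape_1"] == 400
        assert f["Shape_2"] == pytest.approx(0.25, abs=0.02)
        assert f["Shape_3"] == pytest.approx(1.0, abs=0.02)

    def test_c_shape_not_solid(self):
        m = disk_mask((64, 64), (32, 32), 15)
        m &= ~disk_mask((64, 64), (32, 40), 12)
        f = shape_features(m)
        assert f["Shape_3"] < 1.0


class TestGray:
    def test_constant_image_all_zero(self):
        m = disk_mask((32, 32), (16, 16), 6)
        img = np.full((32, 32), 3.0)
        f = gray_features(m, img, img)
        assert all(v == 0.0 for v in f.values())

    def test_bright_disk_hand_computed(self):
        m = disk_mask((64, 64), (32, 32), 8)
        img = np.where(m, 10.0, 2.0)
        f = gray_features(m, img, img, dilation_radius=4)
        assert f["Gray_1"] == pytest.approx(8.0)
        assert f["Gray_2"] == pytest.approx(0.0)
        assert f["Gray_3"] == pytest.approx(8.0)
        assert f["Gray_4"] == pytest.approx(8.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        m = disk_mask((32, 32), (16, 16), 6)
        img = rng.normal(size=(32, 32))
        enh = rng.normal(size=(32, 32))
        f1 = gray_features(m, img, enh)
        f2 = gray_features(m, img + 5.0, enh + 5.0)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9)

    def test_region_covering_whole_image_rejected(self):
        m = np.ones((16, 16), bool)
        with pytest.raises(ValueError, match="surround"):
            gray_features(m, np.zeros((16, 16)), np.zeros((16, 16)))


def brute_force_gradient(region, image, t1, t2):
    """Loop-based recomputation of the sector gradient-concentration stats."""
    gr, gc = np.gradient(np.asarray(image, float))
    rows, cols = np.nonzero(region)
    cr, cc = rows.mean(), cols.mean()
    sector_vals = [[] for _ in range(8)]
    for r, c in zip(rows, cols):
        g = np.array([gr[r, c], gc[r, c]])
        mag = np.linalg.norm(g)
        d = np.array([cr - r, cc - c])
        dist = np.linalg.norm(d)
        if not (t1 <= mag <= t2) or mag == 0 or dist == 0:
            continue
        cosang = float(g @ d / (mag * dist))
        theta = np.arctan2(r - cr, c - cc)
        sector_vals[int((theta + np.pi) / (np.pi / 4)) % 8].append(cosang)
    means = np.array([np.mean(v) if v else 0.0 for v in sector_vals])
    g1 = means.mean()
    g2 = np.sqrt(((means - g1) ** 2).sum())
    return g1, g2, (g1 / g2 if g2 > 1e-12 else 0.0)


class TestGradient:
    def test_radial_dome_concentrates(self):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 100.0 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 8.0**2))
        m = disk_mask((64, 64), (32, 32), 12) & ~disk_mask((64, 64), (32, 32), 3)
        f = gradient_features(m, img, t1=0.0, t2=1e9)
        assert f["Grad_1"] > 0.9  # gradients point uphill toward the center
        assert f["Grad_2"] < 0.3

    def test_uniform_ramp_cancels_over_sectors(self):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 3.0 * cc
        m = disk_mask((64, 64), (32, 32), 10)
        f = gradient_features(m, img, t1=0.0, t2=1e9)
        assert abs(f["Grad_1"]) < 0.1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(40, 40)).cumsum(axis=0).cumsum(axis=1)
        m = disk_mask((40, 40), (20, 20), 7)
        t1, t2 = 0.5, 200.0
        f = gradient_features(m, img, t1=t1, t2=t2)
        g1, g2, g3 = brute_force_gradient(m, img, t1, t2)
        assert f["Grad_1"] == pytest.approx(g1, abs=1e-12)
        assert f["Grad_2"] == pytest.approx(g2, abs=1e-12)
        assert f["Grad_3"] == pytest.approx(g3, abs=1e-9)

    def test_identity_grad3(self):
        rng = np.random.default_rng(6)
        img = rng.normal(size=(40, 40)).cumsum(axis=1)
        m = disk_mask((40, 40), (20, 20), 8)
        f = gradient_features(m, img, t1=0.0, t2=1e9)
        if f["Grad_2"] != 0:
            assert f["Grad_3"] == pytest.approx(f["Grad_1"] / f["Grad_2"])

    def test_gating_everything_out_rejected(self):
        m = disk_mask((32, 32), (16, 16), 6)
        with pytest.raises(ValueError, match="gating|t1"):
            gradient_features(m, np.zeros((32, 32)), t1=5.0, t2=10.0)


class TestSurface:
    def test_exact_paraboloid(self):
        rr, cc = np.mgrid[0:32, 0:32].astype(float)
        img = -((rr - 16) ** 2 + (cc - 16) ** 2)
        m = disk_mask((32, 32), (16, 16), 8)
        f = surface_features(m, img)
        assert f["Surface_1"] == pytest.approx(-2.0, abs=1e-6)
        assert f["Surface_2"] == pytest.approx(-2.0, abs=1e-6)
        assert f["Surface_3"] == pytest.approx(4.0, abs=1e-5)

    def test_product_identity(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(40, 40)).cumsum(axis=0)
        m = disk_mask((40, 40), (20, 20), 9)
        f = surface_features(m, img)
        assert f["Surface_3"] == pytest.approx(
            f["Surface_1"] * f["Surface_2"], rel=1e-9
        )

    def test_small_region_rejected(self):
        m = np.zeros((16, 16), bool)
        m[4:7, 4:8] = True  # 12 px < 15
        with pytest.raises(ValueError, match="15"):
            surface_features(m, np.zeros((16, 16)))


def brute_force_glcm(region, image, n_bins, offsets):
    vals = image[region]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((image - lo) / (hi - lo) * n_bins).astype(int), 0,
                    n_bins - 1)
    else:
        q = np.zeros_like(image, int)
    C = np.zeros((n_bins, n_bins))
    h, w = image.shape
    for r in range(h):
        for c in range(w):
            if not region[r, c]:
                continue
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and region[nr, nc]:
                    C[q[r, c], q[nr, nc]] += 1
                    C[q[nr, nc], q[r, c]] += 1
    return C / C.sum()


class TestTexture:
    def test_constant_region(self):
        m = disk_mask((16, 16), (8, 8), 4)
        f = texture_features(m, np.full((16, 16), 2.0))
        assert f["Texture_1"] == 1.0
        assert f["Texture_2"] == 0.0

    def test_checkerboard_energy(self):
        board = (np.indices((16, 16)).sum(axis=0) % 2).astype(float)
        m = np.ones((16, 16), bool)
        f = texture_features(m, board, n_bins=2, offsets=((0, 1),))
        # all pairs off-diagonal, split over two symmetric cells
        assert f["Texture_1"] == pytest.approx(0.5)

    def test_one_bin_degenerate(self):
        rng = np.random.default_rng(8)
        m = disk_mask((16, 16), (8, 8), 5)
        f = texture_features(m, rng.normal(size=(16, 16)), n_bins=1)
        assert f["Texture_1"] == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        img = rng.normal(size=(20, 20))
        m = disk_mask((20, 20), (10, 10), 6)
        offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
        C = brute_force_glcm(m, img, 8, offsets)
        f = texture_features(m, img, n_bins=8, offsets=offsets)
        i, j = np.indices(C.shape)
        assert f["Texture_1"] == pytest.approx((C**2).sum(), abs=1e-12)
        assert f["Texture_2"] == pytest.approx(
            (((i - j) ** 2) * C**2).sum(), abs=1e-12
        )
        assert f["Texture_3"] == pytest.approx(
            (((i - j) ** 2) * C).sum(), abs=1e-12
        )
        nz = C[C > 0]
        assert f["Texture_6"] == pytest.approx(-(nz * np.log2(nz)).sum())

    def test_single_pixel_rejected(self):
        m = np.zeros((8, 8), bool)
        m[4, 4] = True
        with pytest.raises(ValueError, match="pairs"):
            texture_features(m, np.zeros((8, 8)))


class TestFalsePositive:
    def test_boundary_on_step_edge_scores_high(self):
        img = np.where(disk_mask((64, 64), (32, 32), 14), 10.0, 0.0)
        region = disk_mask((64, 64), (32, 32), 14)
        v = false_positive_feature(region, img)
        assert v > 0.9

    def test_constant_image_scores_zero(self):
        region = disk_mask((64, 64), (32, 32), 10)
        assert false_positive_feature(region, np.full((64, 64), 5.0)) == 0.0

    def test_half_disk_flat_side_on_edge(self):
        """A half-disk whose flat side traces a step edge scores near the
        flat side's share of the boundary (~0.4)."""
        img = np.zeros((64, 64))
        img[:32] = 10.0  # step between rows 31 and 32
        region = disk_mask((64, 64), (31, 32), 10)
        region[32:] = False  # keep the half above the step
        v = false_positive_feature(region, img)
        assert 0.25 < v < 0.65


class TestLikelihoodFeatures:
    def _cand(self, region):
        return Candidate(region=region, centroid=(8, 8), peak_likelihood=1.0,
                         basin_count=1)

    def test_constant_region_zero_cv(self):
        region = disk_mask((16, 16), (8, 8), 4)
        maps = LikelihoodMap(np.where(region, 0.5, 0.0), 1)
        f = candidate_likelihood_features(
            self._cand(region), maps, maps, np.full((16, 16), 7.0)
        )
        assert f["can.CV_1"] == 0.0 and f["can.CV_2"] == 0.0

    def test_peak_read_directly(self):
        region = disk_mask((16, 16), (8, 8), 4)
        vals = np.where(region, 0.3, 0.0)
        vals[8, 8] = 0.8
        f = candidate_likelihood_features(
            self._cand(region), LikelihoodMap(vals, 1), LikelihoodMap(vals, 2),
            np.ones((16, 16)),
        )
        assert f["can.Grad_2"] == pytest.approx(0.8)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(10)
        region = disk_mask((16, 16), (8, 8), 4)
        vals = np.where(region, 0.5, 0.0)
        img = np.abs(rng.normal(5.0, 1.0, size=(16, 16)))
        lm = LikelihoodMap(vals, 1)
        f1 = candidate_likelihood_features(self._cand(region), lm, lm, img)
        f3 = candidate_likelihood_features(self._cand(region), lm, lm, 3 * img)
        assert f1["can.CV_1"] == pytest.approx(f3["can.CV_1"])


class TestExtractAll:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(11)
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = (
            50.0
            + 20.0 * np.exp(-((rr - 32) ** 2 + (cc - 30) ** 2) / (2 * 6.0**2))
            + rng.normal(0, 0.5, size=(64, 64))
        )
        region = disk_mask((64, 64), (32, 30), 7)
        vals = np.exp(-((rr - 32) ** 2 + (cc - 30) ** 2) / (2 * 6.0**2))
        cand = Candidate(region=region, centroid=(32.0, 30.0),
                         peak_likelihood=1.0, basin_count=1,
                         core_region=region)
        maps = (LikelihoodMap(vals, 1), LikelihoodMap(vals, 2))
        return cand, img, maps

    def test_identical_domains_give_identical_blocks(self, setup):
        cand, img, maps = setup
        f = extract_all(cand, img, img, maps, maps, np.ones((64, 64), bool))
        assert len(f) == 62
        for name in PER_DOMAIN_FEATURE_NAMES:
            assert f[f"xray.{name}"] == f[f"soft.{name}"]

    def test_translation_invariance(self, setup):
        """Extractors are translation-equivariant when the global stages
        (preprocessing, edge chains) are shifted along with the region."""
        from chestcad.features import edge_chains

        cand, img, maps = setup
        ones = np.ones((64, 64), bool)
        pre = preprocess(img)
        edges = edge_chains(img)
        f0 = extract_all(cand, img, img, maps, maps, ones,
                         preprocessed=(pre, pre), edges=(edges, edges))
        sh = 5
        roll = lambda a: np.roll(a, (sh, sh), axis=(0, 1))
        img2, pre2, edges2 = roll(img), roll(pre), roll(edges)
        vals2 = roll(maps[0].values)
        region2 = roll(cand.region)
        cand2 = Candidate(region=region2,
                          centroid=(cand.centroid[0] + sh, cand.centroid[1] + sh),
                          peak_likelihood=1.0, basin_count=1,
                          core_region=region2)
        maps2 = (LikelihoodMap(vals2, 1), LikelihoodMap(vals2, 2))
        f1 = extract_all(cand2, img2, img2, maps2, maps2, ones,
                         preprocessed=(pre2, pre2), edges=(edges2, edges2))
        variant = {"xray.can.u", "xray.can.v", "soft.can.u", "soft.can.v",
                   "xray.Shape_4", "soft.Shape_4"}
        for name, v0 in f0.items():
            if name in variant:
                continue
            assert f1[name] == pytest.approx(v0, rel=1e-6, abs=1e-9), name


class TestBaseline:
    def test_constant_region_values(self):
        m = disk_mask((32, 32), (16, 16), 6)
        f = baseline_features(m, np.full((32, 32), 4.0))
        assert set(f) == set(BASELINE_FEATURE_NAMES)
        assert f["std"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["smoothness"] == 0.0
        assert f["skewness"] == 0.0

    def test_disk_circularity_slot_consistent(self):
        m = disk_mask((41, 41), (20, 20), 11)
        rng = np.random.default_rng(12)
        f = baseline_features(m, rng.normal(size=(41, 41)))
        assert f["circularity"] == pytest.approx(circularity(m))
        assert f["area"] == m.sum()
        assert f["perimeter"] == pytest.approx(perimeter_length(m))
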