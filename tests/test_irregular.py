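"""Threshold / closing / connected-component segmentation of irregular mosaics."""

import warnings

import numpy as np
import pytest

from panelseg import (
    FrameworkConfig,
    MontageSpec,
    binarize,
    connected_components,
    generate,
    match_and_score,
    morphological_close,
    otsu_threshold,
    segment_irregular,
)


def brute_force_otsu(image):
    """Exhaustive search oracle: variance-maximizing set over all 256 splits."""
    pix = np.asarray(image, dtype=np.float64).ravel()
    n = pix.size
    variances = np.zeros(256)
    for t in range(256):
        c0 = pix[pix <= t]
        c1 = pix[pix > t]
        if c0.size and c1.size:
            variances[t] = (c0.size / n) * (c1.size / n) * (c0.mean() - c1.mean()) ** 2
    best = variances.max()
    argmax = np.flatnonzero(variances >= best * (1 - 1e-12))
    return variances, set(int(t) for t in argmax)


def naive_close(binary, kr, kc):
    """Double-loop max-then-min over clipped neighborhoods."""
    m, n = binary.shape
    rr, rc = kr // 2, kc // 2
    dilated = np.zeros_like(binary)
    for i in range(m):
        for j in range(n):
            dilated[i, j] = binary[
                max(0, i - rr) : i + rr + 1, max(0, j - rc) : j + rc + 1
            ].max()
    closed = np.zeros_like(binary)
    for i in range(m):
        for j in range(n):
            closed[i, j] = dilated[
                max(0, i - rr) : i + rr + 1, max(0, j - rc) : j + rc + 1
            ].min()
    return closed


def flood_fill_components(binary):
    """8-connected components by explicit BFS; returns pixel sets."""
    fg = np.asarray(binary) > 0
    seen = np.zeros_like(fg)
    comps = []
    m, n = fg.shape
    for si in range(m):
        for sj in range(n):
            if not fg[si, sj] or seen[si, sj]:
                continue
            stack = [(si, sj)]
            seen[si, sj] = True
            pixels = []
            while stack:
                i, j = stack.pop()
                pixels.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < m and 0 <= jj < n and fg[ii, jj] and not seen[ii, jj]:
                            seen[ii, jj] = True
                            stack.append((ii, jj))
            comps.append(frozenset(pixels))
    return comps


class TestOtsu:
    def test_bimodal_split_recovers_the_modes(self, rng):
        image = np.concatenate(
            [np.zeros(50, dtype=np.uint8), np.full(50, 200, dtype=np.uint8)]
        ).reshape(10, 10)
        t = otsu_threshold(image)
        binary = binarize(image, t)
        assert set(binary[image == 0].tolist()) == {0}
        assert set(binary[image == 200].tolist()) == {255}

    def test_constant_image_is_degenerate(self):
        with pytest.warns(UserWarning):
            assert otsu_threshold(np.full((8, 8), 77, dtype=np.uint8)) == 0

    @pytest.mark.parametrize("n", [1, 5, 100])
    def test_two_point_histogram_matches_oracle(self, n):
        image = np.array([10] * n + [240] * n, dtype=np.uint8).reshape(-1, 2)
        variances, argmax = brute_force_otsu(image)
        assert otsu_threshold(image) in argmax

    def test_random_images_match_exhaustive_search(self, rng):
        for _ in range(30):
            image = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            variances, argmax = brute_force_otsu(image)
            t = otsu_threshold(image)
            assert variances[t] >= variances.max() * (1 - 1e-12)
            assert t in argmax

    def test_agrees_with_reference_library_binarization(self, rng):
        """Cross-check: same foreground mask as scikit-image's Otsu."""
        from skimage.filters import threshold_otsu

        for seed in range(5):
            r = np.random.default_rng(seed)
            image = np.concatenate(
                [
                    r.normal(60, 10, 300).clip(0, 255),
                    r.normal(200, 10, 300).clip(0, 255),
                ]
            ).round().astype(np.uint8).reshape(20, 30)
            ours = binarize(image, otsu_threshold(image)) > 0
            theirs = image > threshold_otsu(image)
            np.testing.assert_array_equal(ours, theirs)


class TestBinarize:
    def test_equality_goes_to_background(self):
        np.testing.assert_array_equal(
            binarize(np.array([[0, 128, 255]], dtype=np.uint8), 128),
            [[0, 0, 255]],
        )

    def test_threshold_255_gives_all_background(self):
        image = np.array([[0, 255]], dtype=np.uint8)
        assert not binarize(image, 255).any()

    def test_threshold_0_keeps_exactly_nonzero(self):
        image = np.array([[0, 255, 0, 255]], dtype=np.uint8)
        np.testing.assert_array_equal(binarize(image, 0), image)


class TestMorphologicalClose:
    def test_fills_interior_hole(self):
        square = np.full((20, 20), 255, dtype=np.uint8)
        square[10, 10] = 0
        closed = morphological_close(square, 3, 3)
        assert closed[10, 10] == 255
        assert closed.min() == 255

    def test_all_zero_stays_zero(self):
        zeros = np.zeros((15, 15), dtype=np.uint8)
        assert not morphological_close(zeros, 5, 5).any()

    def test_matches_naive_neighborhood_oracle(self, rng):
        for _ in range(10):
            binary = (rng.random((32, 32)) < 0.4).astype(np.uint8) * 255
            np.testing.assert_array_equal(
                morphological_close(binary, 5, 5), naive_close(binary, 5, 5)
            )

    def test_extensive_and_idempotent(self, rng):
        for _ in range(10):
            binary = (rng.random((40, 40)) < 0.3).astype(np.uint8) * 255
            once = morphological_close(binary, 7, 5)
            assert (once >= binary).all()  # extensive
            np.testing.assert_array_equal(morphological_close(once, 7, 5), once)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            morphological_close(np.zeros((10, 10), dtype=np.uint8), 4, 3)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            morphological_close(np.zeros((10, 10), dtype=np.uint8), 11, 3)


class TestConnectedComponents:
    def test_two_disjoint_squares(self):
        binary = np.zeros((20, 20), dtype=np.uint8)
        binary[2:7, 2:7] = 255
        binary[10:15, 12:17] = 255
        stats = connected_components(binary)
        assert len(stats) == 2
        assert sorted(c.area for c in stats) == [25, 25]
        boxes = sorted((c.y, c.x, c.h, c.w) for c in stats)
        assert boxes == [(2, 2, 5, 5), (10, 12, 5, 5)]

    def test_all_background(self):
        assert connected_components(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_diagonal_touch_merges_under_8_connectivity(self):
        binary = np.zeros((4, 4), dtype=np.uint8)
        binary[0, 0] = binary[1, 1] = 255
        assert len(connected_components(binary)) == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            binary = (rng.random((24, 24)) < 0.35).astype(np.uint8) * 255
            stats = connected_components(binary)
            oracle = flood_fill_components(binary)
            assert len(stats) == len(oracle)
            # label-permutation invariant: compare stat multisets
            got = sorted((c.area, c.y, c.x, c.h, c.w) for c in stats)
            want = sorted(
                (
                    len(px),
                    min(i for i, _ in px),
                    min(j for _, j in px),
                    max(i for i, _ in px) - min(i for i, _ in px) + 1,
                    max(j for _, j in px) - min(j for _, j in px) + 1,
                )
                for px in oracle
            )
            assert got == want

    def test_area_conservation(self, rng):
        binary = (rng.random((30, 30)) < 0.4).astype(np.uint8) * 255
        stats = connected_components(binary)
        assert sum(c.area for c in stats) == int(np.count_nonzero(binary))


class TestSegmentIrregular:
    def test_two_panel_mosaic_recovered(self, config):
        img, truth, _ = generate(MontageSpec.irregular(2, seed=21))
        result = segment_irregular(img, config)
        report = match_and_score(result.regions, truth)
        assert report.n_extracted == 2
        assert report.precision == report.recall == 1.0

    def test_single_dark_panel_on_white(self, config):
        img = np.full((200, 200), 255, dtype=np.uint8)
        img[40:160, 50:170] = 90
        result = segment_irregular(img, config)
        assert len(result.regions) == 1
        region = result.regions[0]
        assert (region.row_start, region.row_end) == (40, 160)
        assert (region.col_start, region.col_end) == (50, 170)

    def test_small_panel_filtered_by_area_threshold(self, config):
        # three panels; one below area_fraction * M * N = 0.02 * 90000 = 1800
        img = np.full((300, 300), 255, dtype=np.uint8)
        img[10:130, 10:130] = 100      # 14400 px
        img[160:280, 160:280] = 100    # 14400 px
        img[20:50, 200:230] = 100      # 900 px < 1800
        result = segment_irregular(img, config)
        assert len(result.regions) == 2

    def test_area_fraction_monotonicity(self):
        img, _, _ = generate(MontageSpec.irregular(5, seed=33))
        counts = []
        for frac in (0.005, 0.02, 0.05, 0.2, 0.6):
            cfg = FrameworkConfig(area_fraction=frac)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = segment_irregular(img, cfg)
            counts.append(0 if result.fallback else len(result.regions))
        assert counts == sorted(counts, reverse=True)

    def test_no_surviving_component_falls_back_to_full_frame(self):
        cfg = FrameworkConfig(area_fraction=0.99)
        img, _, _ = generate(MontageSpec.irregular(4, seed=2))
        with pytest.warns(UserWarning):
            result = segment_irregular(img, cfg)
        assert result.fallback
        assert len(result.regions) == 1
        assert result.regions[0].area == img.shape[0] * img.shape[1]

    def test_parameter_recovery_across_seeds(self, config):
        rng = np.random.default_rng(55)
        nc = ne = nt = 0
        for _ in range(25):
            n = int(rng.integers(2, 7))
            seed = int(rng.integers(0, 2**31))
            img, truth, _ = generate(MontageSpec.irregular(n, seed=seed))
            result = segment_irregular(img, config)
            report = match_and_score(result.regions, truth)
            nc += report.n_correct
            ne += report.n_extracted
            nt += report.n_truth
        assert nc / ne >= 0.9
        assert nc / nt >= 0.9
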