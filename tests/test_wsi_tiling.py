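"""Tissue masking, patch extraction, pyramids and the record store."""

import numpy as np
import pytest

from pcead.wsi_tiling import (ArraySlide, DegenerateHistogramError, Patch,
                              RecordParseError, TissueMask,
                              build_resolution_pyramid, compute_tissue_mask,
                              extract_patches, otsu_threshold,
                              read_record_shards, write_record_shards)


def brute_force_otsu(hist):
    """Independent exhaustive maximizer of between-class variance.

    Threshold T splits values into {v < T} and {v >= T}; smallest
    maximizing T wins.
    """
    total = sum(hist)
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        w0 = sum(hist[:t])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(v * h for v, h in enumerate(hist[:t])) / w0
        mu1 = sum(v * h for v, h in enumerate(hist[t:], start=t)) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_single_bin_is_degenerate(self):
        h = np.zeros(256, dtype=int)
        h[128] = 1000
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(h)

    def test_two_spikes_strictly_separated(self):
        h = np.zeros(256, dtype=int)
        h[10], h[200] = 50, 50
        t = otsu_threshold(h)
        assert 10 < t <= 200
        assert t == brute_force_otsu(h.tolist())

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(101)
        for _ in range(100):
            h = rng.integers(0, 50, size=256)
            h[rng.integers(0, 256, size=5)] += rng.integers(100, 1000, size=5)
            if np.count_nonzero(h) < 2:
                continue
            assert otsu_threshold(h) == brute_force_otsu(h.tolist())


def disc_slide(size=256, radius=60, tissue_val=120, bg_val=245):
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    disc = (xx - c) ** 2 + (yy - c) ** 2 <= radius**2
    px = np.full((size, size, 3), bg_val, dtype=np.uint8)
    px[disc] = tissue_val
    return ArraySlide(identifier="disc", pixels=px), disc


class TestTissueMask:
    def test_dark_disc_recovered_within_boundary_band(self):
        slide, disc = disc_slide()
        d = 8
        tm = compute_tissue_mask(slide, downsample=d)
        # analytic disc membership on the thumbnail grid
        up = np.repeat(np.repeat(tm.mask, d, axis=0), d, axis=1)
        # interior/exterior eroded by one thumbnail pixel must agree exactly
        yy, xx = np.mgrid[0 : slide.height, 0 : slide.width]
        c, r = 128, 60
        rad = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
        interior = rad <= r - d * np.sqrt(2)
        exterior = rad >= r + d * np.sqrt(2)
        assert up[interior].all()
        assert not up[exterior].any()

    def test_blank_slide_propagates_degenerate_error(self):
        blank = ArraySlide("blank", np.full((64, 64, 3), 200, dtype=np.uint8))
        with pytest.raises(DegenerateHistogramError):
            compute_tissue_mask(blank, downsample=4)

    def test_inverted_polarity_is_complement(self):
        slide, _ = disc_slide()
        a = compute_tissue_mask(slide, 8, tissue_darker=True)
        b = compute_tissue_mask(slide, 8, tissue_darker=False)
        assert (a.mask ^ b.mask).all()


def block_slide(size=256, patch=32):
    """One 3x3-patch tissue block with its top-left at (32, 32)."""
    px = np.full((size, size, 3), 245, dtype=np.uint8)
    px[32 : 32 + 3 * patch, 32 : 32 + 3 * patch] = 100
    return ArraySlide(identifier="block", pixels=px)


class TestExtractPatches:
    def test_all_false_mask_yields_nothing(self):
        slide = block_slide()
        tm = TissueMask(mask=np.zeros((32, 32), bool), downsample=8, threshold=100)
        assert list(extract_patches(slide, tm, 32, 0.5)) == []

    def test_zero_threshold_yields_full_grid(self):
        slide = block_slide()
        tm = TissueMask(mask=np.zeros((32, 32), bool), downsample=8, threshold=100)
        got = list(extract_patches(slide, tm, 32, 0.0))
        assert len(got) == (256 // 32) ** 2
        origins = [p.origin for p in got]
        assert origins == sorted(origins, key=lambda o: (o[1], o[0]))

    def test_tissue_fraction_matches_per_pixel_oracle(self):
        slide = block_slide()
        tm = compute_tissue_mask(slide, downsample=8)
        got = {p.origin for p in extract_patches(slide, tm, 32, 0.5)}
        # brute force: per level-0 pixel lookup into the thumbnail mask
        d, ps = tm.downsample, 32
        expected = set()
        for gy in range(256 // ps):
            for gx in range(256 // ps):
                count = sum(
                    tm.mask[py // d, px // d]
                    for py in range(gy * ps, (gy + 1) * ps)
                    for px in range(gx * ps, (gx + 1) * ps))
                if count / ps**2 >= 0.5:
                    expected.add((gx * ps, gy * ps))
        assert got == expected

    def test_oversized_patch_warns_and_yields_nothing(self):
        slide = block_slide(size=64)
        tm = TissueMask(mask=np.ones((8, 8), bool), downsample=8, threshold=100)
        with pytest.warns(UserWarning, match="exceeds slide"):
            assert list(extract_patches(slide, tm, 128, 0.5)) == []

    def test_emitted_extents_tile_without_overlap(self):
        slide = block_slide()
        tm = compute_tissue_mask(slide, 8)
        got = list(extract_patches(slide, tm, 32, 0.0))
        cover = np.zeros((256, 256), dtype=int)
        for p in got:
            x, y = p.origin
            assert x + 32 <= slide.width and y + 32 <= slide.height
            cover[y : y + 32, x : x + 32] += 1
        assert cover.max() == 1


class TestPyramid:
    def test_constant_patch_stays_constant(self):
        p = Patch(image=np.full((32, 32, 3), 0.625), slide="s", origin=(0, 0))
        for lvl in build_resolution_pyramid(p):
            assert np.allclose(lvl.image, 0.625)
            assert lvl.slide == "s" and lvl.origin == (0, 0)

    def test_4x4_block_means_hand_computed(self):
        img = np.arange(48, dtype=np.float64).reshape(4, 4, 3) / 48.0
        p = Patch(image=img, slide="s", origin=(8, 16))
        levels = build_resolution_pyramid(p)
        assert [l.level_size for l in levels] == [4]
        q = build_resolution_pyramid(Patch(image=img, slide="s", origin=(8, 16)),
                                     min_size=4)
        # manual halving of the 4x4 via its four 2x2 blocks
        expect = np.zeros((2, 2, 3))
        for by in range(2):
            for bx in range(2):
                expect[by, bx] = img[2 * by : 2 * by + 2,
                                     2 * bx : 2 * bx + 2].mean(axis=(0, 1))
        from pcead.wsi_tiling import downsample2

        assert np.allclose(downsample2(img), expect)

    def test_ladder_64_has_five_levels(self):
        p = Patch(image=np.zeros((64, 64, 3)), slide="s", origin=(0, 0))
        levels = build_resolution_pyramid(p)
        assert [l.level_size for l in levels] == [64, 32, 16, 8, 4]

    def test_pixel_count_and_mean_preserved(self, rng):
        img = rng.random((64, 64, 3))
        levels = build_resolution_pyramid(Patch(image=img, slide="s", origin=(0, 0)))
        for n, lvl in enumerate(levels):
            assert lvl.image.size == img.size * 0.25**n
            assert np.isclose(lvl.image.mean(), img.mean(), atol=1e-12)

    def test_non_power_of_two_rejected(self):
        p = Patch(image=np.zeros((24, 24, 3)), slide="s", origin=(0, 0))
        with pytest.raises(ValueError, match="power of two"):
            build_resolution_pyramid(p)


class TestRecordStore:
    def _patches(self, rng, n, size=16):
        return [Patch(image=rng.integers(0, 256, (size, size, 3)).astype(float) / 255.0,
                      slide="s1", origin=(16 * i, 0)) for i in range(n)]

    def test_empty_stream_writes_no_shards(self, tmp_path):
        assert write_record_shards([], tmp_path) == []
        assert list(read_record_shards([])) == []

    def test_sharding_and_bitwise_round_trip(self, tmp_path, rng):
        patches = self._patches(rng, 10)
        paths = write_record_shards(patches, tmp_path, shard_size=4)
        assert len(paths) == 3
        back = list(read_record_shards(paths))
        assert len(back) == 10
        by_origin = {p.origin: p for p in back}
        for p in patches:
            q = by_origin[p.origin]
            assert np.array_equal(p.to_uint8(), q.to_uint8())
            assert (q.slide, q.level_size) == (p.slide, p.level_size)

    def test_level_filter_with_no_match_is_empty(self, tmp_path, rng):
        paths = write_record_shards(self._patches(rng, 3), tmp_path)
        assert list(read_record_shards(paths, level=999)) == []

    def test_corrupt_shard_reports_path_and_index(self, tmp_path, rng):
        paths = write_record_shards(self._patches(rng, 3), tmp_path, shard_size=10)
        data = bytearray(paths[0].read_bytes())
        data[len(data) // 2] ^= 0xFF          # flip a byte mid-file
        data = data[:-50]                     # and truncate
        paths[0].write_bytes(bytes(data))
        with pytest.raises(RecordParseError) as exc:
            list(read_record_shards(paths))
        assert str(paths[0]) in str(exc.value)
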