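"""Polygonization, cross-patch merging, slide inference, GeoJSON I/O."""

import json

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from pcead.anomaly_model import CutoffThreshold
from pcead.segmentation import (AnomalyMask, PolygonSet, TilingConfig,
                                mask_to_polygons, merge_patch_polygons,
                                read_polygons, segment_slide, write_polygons)
from pcead.wsi_tiling import TissueMask, compute_tissue_mask


class TestMaskToPolygons:
    def test_empty_mask_empty_set(self):
        assert len(mask_to_polygons(np.zeros((8, 8), bool))) == 0

    def test_filled_square_traced_exactly(self):
        m = np.zeros((20, 20), bool)
        m[3:13, 5:15] = True
        pset = mask_to_polygons(AnomalyMask(mask=m, origin=(100, 200)))
        assert len(pset) == 1
        p = pset.polygons[0]
        assert p.area == 100
        assert p.bounds == (105.0, 203.0, 115.0, 213.0)

    def test_diagonal_pixels_are_two_components(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        pset = mask_to_polygons(m, closing_radius=0)
        assert len(pset) == 2
        assert all(p.area == 1 for p in pset.polygons)

    def test_area_equals_pixel_count_on_random_masks(self, rng):
        """Integer identity: with no closing and no area filter, total
        polygon area is exactly the number of true pixels."""
        for _ in range(10):
            m = rng.random((24, 24)) < 0.35
            pset = mask_to_polygons(m, min_area=0, closing_radius=0)
            assert pset.total_area == m.sum()

    def test_min_area_drops_small_components(self):
        m = np.zeros((16, 16), bool)
        m[0:4, 0:4] = True       # 16 px
        m[10, 10] = True         # 1 px
        pset = mask_to_polygons(m, min_area=4)
        assert len(pset) == 1 and pset.polygons[0].area == 16

    def test_closing_bridges_a_gap(self):
        m = np.zeros((10, 10), bool)
        m[3:6, 2:4] = True
        m[3:6, 5:7] = True
        assert len(mask_to_polygons(m)) == 2
        assert len(mask_to_polygons(m, closing_radius=1)) == 1

    def test_polygonization_inverts_rasterization_on_rectangles(self, rng):
        """Rasterize an axis-aligned lattice rectangle, polygonize the
        raster, and recover the rectangle."""
        for _ in range(10):
            x0, y0 = rng.integers(0, 10, 2)
            w, h = rng.integers(1, 10, 2)
            m = np.zeros((24, 24), bool)
            m[y0 : y0 + h, x0 : x0 + w] = True
            pset = mask_to_polygons(m)
            assert len(pset) == 1
            expected = box(float(x0), float(y0), float(x0 + w), float(y0 + h))
            assert pset.polygons[0].equals(expected)


class TestMerge:
    def test_disjoint_parts_unchanged(self):
        a = PolygonSet([box(0, 0, 5, 5)], slide="s")
        b = PolygonSet([box(10, 10, 12, 12)], slide="s")
        merged = merge_patch_polygons([a, b])
        assert len(merged) == 2
        assert merged.total_area == 25 + 4

    def test_edge_sharing_squares_fuse(self):
        a = PolygonSet([box(0, 0, 10, 10)], slide="s")
        b = PolygonSet([box(10, 0, 20, 10)], slide="s")
        merged = merge_patch_polygons([a, b])
        assert len(merged) == 1
        assert merged.total_area == 200

    def test_duplicate_counted_once(self):
        a = PolygonSet([box(0, 0, 5, 5)], slide="s")
        b = PolygonSet([box(0, 0, 5, 5)], slide="s")
        assert merge_patch_polygons([a, b]).total_area == 25

    def test_mixed_slides_rejected(self):
        a = PolygonSet([box(0, 0, 5, 5)], slide="s1")
        b = PolygonSet([box(0, 0, 5, 5)], slide="s2")
        with pytest.raises(ValueError, match="different slides"):
            merge_patch_polygons([a, b])


class TestSegmentSlide:
    def test_pure_normal_slide_has_calibrated_false_positive_area(
            self, small_cohort, oracle, fitted_nerd, calibrated_threshold):
        """On normal texture the flagged area cannot exceed ~2q of the
        tissue area (q = 0.05 calibration), even before area filtering."""
        entry = next(e for e in small_cohort["slides"]
                     if e["phase"] == "inference" and e["type"] == "normal")
        slide, _ = small_cohort["rendered"][entry["slide"]]
        tiling = TilingConfig(patch_size=128, thumbnail_downsample=16,
                              min_area=0.0)
        pset = segment_slide(slide, oracle, fitted_nerd, calibrated_threshold,
                             tiling)
        mask = compute_tissue_mask(slide, 16)
        tissue_area = mask.mask.sum() * 16 * 16
        assert pset.total_area <= 2 * 0.05 * tissue_area

    def test_planted_disc_is_hit(self, small_cohort, oracle, fitted_nerd,
                                 calibrated_threshold):
        entry = next(e for e in small_cohort["slides"] if e["type"] == "tumor")
        slide, truth = small_cohort["rendered"][entry["slide"]]
        tiling = TilingConfig(patch_size=128, thumbnail_downsample=16)
        pset = segment_slide(slide, oracle, fitted_nerd, calibrated_threshold,
                             tiling)
        assert len(pset) >= 1
        assert pset.union().intersection(truth.union()).area > 0

    def test_zero_tissue_slide_is_empty(self, small_cohort, oracle, fitted_nerd,
                                        calibrated_threshold):
        slide, _ = small_cohort["rendered"]["normal_000"]
        empty = TissueMask(mask=np.zeros((32, 32), bool), downsample=16,
                           threshold=128)
        pset = segment_slide(slide, oracle, fitted_nerd, calibrated_threshold,
                             TilingConfig(patch_size=128), tissue_mask=empty)
        assert len(pset) == 0

    def test_deterministic_and_inside_patch_extents(
            self, small_cohort, oracle, fitted_nerd, calibrated_threshold):
        entry = next(e for e in small_cohort["slides"] if e["type"] == "tumor")
        slide, _ = small_cohort["rendered"][entry["slide"]]
        tiling = TilingConfig(patch_size=128, thumbnail_downsample=16)
        a = segment_slide(slide, oracle, fitted_nerd, calibrated_threshold, tiling)
        b = segment_slide(slide, oracle, fitted_nerd, calibrated_threshold, tiling)
        assert len(a) == len(b)
        for pa, pb in zip(a.polygons, b.polygons):
            assert pa.equals(pb)
        x0, y0, x1, y1 = a.union().bounds
        assert 0 <= x0 and 0 <= y0 and x1 <= slide.width and y1 <= slide.height


class TestGeoJsonRoundTrip:
    def test_empty_set_round_trips(self, tmp_path):
        path = tmp_path / "empty.geojson"
        write_polygons(PolygonSet([], slide="s"), path)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection" and doc["features"] == []
        assert len(read_polygons(path)) == 0

    def test_fifty_random_rectangles_vertex_exact(self, tmp_path, rng):
        rects = []
        for _ in range(50):
            x0, y0 = rng.random(2) * 100
            w, h = rng.random(2) * 50 + 1
            rects.append(box(x0, y0, x0 + w, y0 + h))
        pset = PolygonSet(rects, slide="s", role="predicted")
        path = tmp_path / "r.geojson"
        write_polygons(pset, path)
        back = read_polygons(path)
        assert len(back) == 50
        for a, b in zip(pset.polygons, back.polygons):
            assert np.array_equal(np.asarray(a.exterior.coords),
                                  np.asarray(b.exterior.coords))
        assert back.slide == "s" and back.role == "predicted"

    def test_qupath_style_nested_holes_preserved(self, tmp_path):
        # hand-written FeatureCollection the way QuPath exports annotations
        doc = {
            "type": "FeatureCollection",
            "features": [{
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[0, 0], [100, 0], [100, 100], [0, 100], [0, 0]],
                        [[20, 20], [40, 20], [40, 40], [20, 40], [20, 20]],
                        [[60, 60], [80, 60], [80, 80], [60, 80], [60, 60]],
                    ],
                },
                "properties": {"slide": "wsi1", "role": "annotated",
                               "classification": {"name": "Tumor"}},
            }],
        }
        path = tmp_path / "qupath.geojson"
        path.write_text(json.dumps(doc))
        pset = read_polygons(path)
        assert len(pset) == 1
        p = pset.polygons[0]
        assert len(p.interiors) == 2
        assert p.area == 100 * 100 - 2 * 400

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.geojson"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_polygons(bad)
        worse = tmp_path / "worse.geojson"
        worse.write_text(json.dumps({
            "type": "FeatureCollection",
            "features": [{"type": "Feature", "geometry": {"type": "Polygon"},
                          "properties": {}}]}))
        with pytest.raises(ValueError, match="feature 0"):
            read_polygons(worse)
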