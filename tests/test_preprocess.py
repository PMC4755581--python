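"""Filtering, edge detection, edge cleanup and nucleus geometry tests."""

import warnings

import numpy as np
import pytest

from conftest import make_ellipse_mask, simple_geometry
from vsmc3d.preprocess import (
    EdgeSegment,
    classify_edge,
    clean_edges,
    coherence_filter,
    detect_edges,
    extract_nucleus_geometry,
    remove_inner_edges,
)


class TestCoherenceFilter:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 3.7)
        np.testing.assert_allclose(coherence_filter(img), img)

    def test_respects_input_range(self, band_image):
        out = coherence_filter(band_image)
        assert out.min() >= band_image.min() - 1e-12
        assert out.max() <= band_image.max() + 1e-12

    def test_smooths_along_band_but_keeps_its_edge(self, band_image):
        out = coherence_filter(band_image)
        # variance along the coherent (vertical) direction shrinks
        inner = slice(10, 86)
        var_in = band_image[inner, 46:50].var(axis=0).mean()
        var_out = out[inner, 46:50].var(axis=0).mean()
        assert var_out < var_in
        # the cross-band gradient magnitude at the edge survives
        g_in = np.abs(np.diff(band_image[48], n=1))[40:44].max()
        g_out = np.abs(np.diff(out[48], n=1))[40:44].max()
        assert g_out > 0.8 * g_in

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            coherence_filter(np.zeros((0, 0)))


class TestDetectEdges:
    def test_constant_image_yields_no_edges(self):
        assert not detect_edges(np.ones((32, 32))).any()

    def test_disk_edge_is_a_ring_near_the_true_circle(self, disk_image):
        edges = detect_edges(disk_image)
        yy, xx = np.nonzero(edges)
        r = np.hypot(xx - 48, yy - 48)
        assert len(r) > 60
        assert np.abs(r - 25).max() < 1.5

    def test_synthetic_cell_edge_recall(self):
        from vsmc3d.phantom import make_cell_stack
        st = make_cell_stack(1, seed=9, noise_sd=0.02,
                             shape=(48, 256, 256), overlap_fraction=0.0)
        t = st.truth[0]
        z = int(round(t.center_um[2] / st.spacing[2]))
        edges = detect_edges(st.cell_channel[z])
        contour = t.contours_px[z]
        yy, xx = np.nonzero(edges)
        pts = np.column_stack([xx, yy]).astype(float)
        d = np.linalg.norm(contour[:, None, :] - pts[None, :, :],
                           axis=2).min(axis=1)
        assert (d <= 2.0).mean() >= 0.90


class TestCleanEdges:
    def test_y_junction_splits_into_three_chains(self):
        img = np.zeros((32, 32), bool)
        img[16, 4:16] = True          # stem
        img[17:28, 16] = True         # down branch (longer than spur)
        img[5:16, 16] = True          # up branch
        segs = clean_edges(img, spur_length=3, min_length=3)
        assert len(segs) == 3
        union = {tuple(p) for s in segs for p in
                 np.round(s.points).astype(int)}
        assert (16, 16) not in union  # junction pixel deleted

    def test_short_spur_removed_main_chain_intact(self):
        img = np.zeros((32, 32), bool)
        img[16, 2:30] = True
        img[13:16, 15] = True         # 3-px spur
        segs = clean_edges(img, spur_length=3, min_length=3)
        assert len(segs) == 1
        assert len(segs[0]) == 28

    def test_every_chain_has_two_endpoints_on_random_maps(self, rng):
        for _ in range(5):
            img = rng.random((48, 48)) < 0.08
            for seg in clean_edges(img):
                assert seg.is_valid_chain()
                pts = {tuple(p) for p in
                       np.round(seg.points).astype(int)}
                assert len(pts) == len(seg)

    def test_clockwise_ordering_with_center(self):
        img = np.zeros((64, 64), bool)
        img[20, 28:37] = True
        img[44, 28:37] = True
        segs = clean_edges(img, center=(32.0, 32.0),
                           cell_vector=(0.0, 1.0))
        assert len(segs) == 2
        from vsmc3d.geometry import scattering_angle_deg
        mids = [s.points[len(s) // 2] for s in segs]
        angles = [scattering_angle_deg(m[None], (32.0, 32.0),
                                       (0.0, 1.0))[0] for m in mids]
        assert angles == sorted(angles)

    def test_empty_map_gives_empty_list(self):
        assert clean_edges(np.zeros((16, 16), bool)) == []


class TestNucleusGeometry:
    def test_axis_aligned_ellipse(self):
        mask = make_ellipse_mask(semi=(30, 10), angle_deg=0.0)
        geom = extract_nucleus_geometry(mask)
        # long axis along +Y: endpoints near the two poles
        ys = sorted(geom.endpoints[:, 1])
        assert ys[0] < 30 and ys[1] > 66
        assert abs(geom.cell_vector[0]) < 0.15

    def test_rotated_ellipse_vector_angle(self):
        mask = make_ellipse_mask(semi=(30, 10), angle_deg=25.0)
        geom = extract_nucleus_geometry(mask)
        ang = np.degrees(np.arctan2(abs(geom.cell_vector[0]),
                                    abs(geom.cell_vector[1])))
        assert ang == pytest.approx(25.0, abs=3.0)

    def test_moment_axis_agreement_on_elongated_masks(self):
        for angle in (-60.0, -20.0, 40.0):
            mask = make_ellipse_mask(semi=(28, 9), angle_deg=angle)
            geom = extract_nucleus_geometry(mask)
            coords = np.column_stack(np.nonzero(mask))[:, ::-1].astype(
                float)
            cov = np.cov((coords - coords.mean(axis=0)).T)
            _, vecs = np.linalg.eigh(cov)
            major = vecs[:, -1]
            cosang = abs(geom.cell_vector @ major)
            assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0

    def test_circle_falls_back_to_moments_with_warning(self):
        mask = make_ellipse_mask(semi=(12, 12))
        with pytest.warns(UserWarning, match="isotropic"):
            geom = extract_nucleus_geometry(mask)
        assert geom.low_anisotropy

    def test_empty_and_multicomponent_masks_rejected(self):
        with pytest.raises(ValueError):
            extract_nucleus_geometry(np.zeros((16, 16), bool))
        two = np.zeros((32, 32), bool)
        two[4:8, 4:8] = True
        two[20:24, 20:24] = True
        with pytest.raises(ValueError, match="multiple"):
            extract_nucleus_geometry(two)

    def test_center_inside_mask(self):
        mask = make_ellipse_mask(semi=(25, 8), angle_deg=30.0)
        geom = extract_nucleus_geometry(mask)
        cx, cy = np.round(geom.center).astype(int)
        assert mask[cy, cx]


def _band_with_center(center_x=36.0):
    """Bright band [30, 42) in x; cell center inside the band."""
    img = np.zeros((64, 64))
    img[:, 30:42] = 1.0
    geom = simple_geometry(center=(center_x, 32.0), vector=(0.0, 1.0))
    return img, geom


class TestClassifyEdge:
    def test_own_edge_with_inward_gradient_is_A(self):
        img, geom = _band_with_center()
        seg = EdgeSegment(points=np.column_stack(
            [np.full(20, 42.0), np.arange(22.0, 42.0)]))
        assert classify_edge(seg, img, geom) == "A"
        assert seg.side in ("left", "right")

    def test_neighbor_edge_with_outward_gradient_is_B(self):
        img, geom = _band_with_center()
        img[:, 50:60] = 1.0       # second cell to the right
        seg = EdgeSegment(points=np.column_stack(
            [np.full(20, 50.0), np.arange(22.0, 42.0)]))
        assert classify_edge(seg, img, geom) == "B"

    def test_shared_edge_between_abutting_cells_is_C(self):
        img, geom = _band_with_center(center_x=36.0)
        img[:, 42:54] = 0.95      # abutting second cell
        seg = EdgeSegment(points=np.column_stack(
            [np.full(20, 42.0), np.arange(22.0, 42.0)]))
        assert classify_edge(seg, img, geom) == "C"

    def test_too_short_segment_is_unknown(self):
        img, geom = _band_with_center()
        seg = EdgeSegment(points=np.array([[42.0, 30.0], [42.0, 31.0]]))
        assert classify_edge(seg, img, geom) == "unknown"

    def test_mirror_symmetry_swaps_sides_keeps_classes(self):
        img, geom = _band_with_center()
        seg = EdgeSegment(points=np.column_stack(
            [np.full(20, 42.0), np.arange(22.0, 42.0)]))
        cls = classify_edge(seg, img, geom)
        side = seg.side
        w = img.shape[1]
        img_m = img[:, ::-1].copy()
        geom_m = simple_geometry(
            center=(w - 1 - geom.center[0], geom.center[1]),
            vector=(0.0, 1.0))
        pts_m = seg.points.copy()
        pts_m[:, 0] = w - 1 - pts_m[:, 0]
        seg_m = EdgeSegment(points=pts_m)
        assert classify_edge(seg_m, img_m, geom_m) == cls
        assert {side, seg_m.side} == {"left", "right"}


class TestRemoveInnerEdges:
    def _nucleus(self):
        mask = np.zeros((64, 64), bool)
        mask[28:36, 28:36] = True
        return mask

    def test_touching_segment_removed(self):
        seg = EdgeSegment(points=np.column_stack(
            [np.arange(36.0, 46.0), np.full(10, 32.0)]))
        assert remove_inner_edges([seg], self._nucleus()) == []
        assert seg.edge_class == "inner"

    def test_distant_segment_kept(self):
        seg = EdgeSegment(points=np.column_stack(
            [np.arange(50.0, 60.0), np.full(10, 32.0)]))
        assert remove_inner_edges([seg], self._nucleus()) == [seg]

    def test_bridging_chain_fully_removed(self):
        """Touching segments that chain outward all disappear."""
        s1 = EdgeSegment(points=np.column_stack(
            [np.arange(36.0, 44.0), np.full(8, 32.0)]))
        s2 = EdgeSegment(points=np.column_stack(
            [np.arange(44.0, 56.0), np.full(12, 32.0)]))
        far = EdgeSegment(points=np.column_stack(
            [np.arange(44.0, 56.0), np.full(12, 50.0)]))
        kept = remove_inner_edges([s1, s2, far], self._nucleus())
        assert kept == [far]

    def test_min_fraction_spares_grazing_contours(self):
        long_seg = EdgeSegment(points=np.column_stack(
            [np.arange(30.0, 60.0), np.full(30, 37.0)]))
        kept = remove_inner_edges([long_seg], self._nucleus(),
                                  dilation=2, min_fraction=0.5)
        assert kept == [long_seg]
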