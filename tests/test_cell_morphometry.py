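"""Morphometry: segmentation, boundaries, tracking, kymographs, statistics."""

import numpy as np
import pytest

import promscope as p


def disk_mask(shape=(101, 101), center=(50, 50), radius=25):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestSegmentCell:
    def test_rendered_scene_resegments_with_high_overlap(self,
                                                         adhesion_sequence):
        si = adhesion_sequence["shifts"][-1]
        truth = adhesion_sequence["scene"].masks[-1]
        seg = p.segment_cell(si.pis_image)
        jaccard = (seg & truth).sum() / (seg | truth).sum()
        assert jaccard >= 0.9

    def test_all_zero_image_raises(self):
        with pytest.raises(p.NoCellError):
            p.segment_cell(np.zeros((40, 40)))

    def test_full_frame_foreground_survives_closing_and_fill(self):
        img = np.ones((30, 30))
        img[0, 0] = 0.0  # give Otsu a threshold to find
        seg = p.segment_cell(img)
        assert seg.sum() >= 30 * 30 - 4


class TestExtractBoundary:
    def test_disk_perimeter_within_one_percent(self):
        for r in (15, 25, 40):
            b = p.extract_boundary(disk_mask(radius=r))
            assert b.perimeter_px == pytest.approx(2 * np.pi * r, rel=0.01)

    def test_disk_normals_radial_within_two_degrees(self):
        b = p.extract_boundary(disk_mask(radius=25))
        radial = b.points - np.array([50.0, 50.0])
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.abs((b.normals * radial).sum(axis=1)).clip(0, 1)
        assert np.degrees(np.arccos(cosang)).max() <= 2.0

    def test_normals_point_outward(self):
        mask = disk_mask(radius=20)
        b = p.extract_boundary(mask)
        probes = np.round(b.points + 2.5 * b.normals).astype(int)
        inside = mask[probes[:, 0], probes[:, 1]]
        assert inside.mean() < 0.02

    def test_square_corners_present_perimeter_within_two_percent(self):
        mask = np.zeros((101, 101), bool)
        mask[35:66, 30:61] = True  # 0.5-level boundary: 31 px sides
        b = p.extract_boundary(mask)
        assert b.perimeter_px == pytest.approx(4 * 31, rel=0.02)
        for corner in [(34.5, 29.5), (34.5, 60.5), (65.5, 29.5), (65.5, 60.5)]:
            d = np.hypot(b.points[:, 0] - corner[0],
                         b.points[:, 1] - corner[1]).min()
            assert d < 0.8

    def test_arclength_samples_equally_spaced(self):
        b = p.extract_boundary(disk_mask(radius=25), n_samples=180)
        closed = np.vstack([b.points, b.points[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        assert seg.std() / seg.mean() < 0.01

    def test_single_pixel_mask_degenerate(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        with pytest.raises(p.DegenerateContourError):
            p.extract_boundary(mask)


class TestTrackBoundary:
    def test_identical_masks_zero_displacement(self):
        mask = disk_mask(radius=22)
        b = p.extract_boundary(mask)
        b2 = p.track_boundary(b, mask)
        assert np.abs(b2.displacement_px).max() < 0.3

    def test_dilated_disk_uniform_outward_displacement(self):
        b = p.extract_boundary(disk_mask(radius=20))
        b2 = p.track_boundary(b, disk_mask(radius=22))
        assert np.all(np.abs(b2.displacement_px - 2.0) <= 0.5)

    def test_translated_disk_sinusoidal_displacement(self):
        b = p.extract_boundary(disk_mask(radius=20, center=(50, 50)))
        b2 = p.track_boundary(b, disk_mask(radius=20, center=(50, 51)))
        d = b2.displacement_px
        assert d.max() == pytest.approx(1.0, abs=0.3)
        assert d.min() == pytest.approx(-1.0, abs=0.3)
        assert abs(d.mean()) < 0.1

    def test_inverse_consistency(self):
        a, bm = disk_mask(radius=20), disk_mask(radius=24)
        fwd = p.track_boundary(p.extract_boundary(a), bm)
        back = p.track_boundary(fwd, a)
        total = fwd.displacement_px + back.displacement_px
        assert np.abs(total).max() <= 0.5

    def test_disjoint_masks_raise(self):
        a = disk_mask(radius=8, center=(20, 20))
        b = np.zeros_like(a)
        b[80:85, 80:85] = True
        with pytest.raises(ValueError):
            p.track_boundary(p.extract_boundary(a), b)


class TestBandKymograph:
    def test_uniform_image_constant_kymograph(self):
        mask = disk_mask(radius=25)
        b = p.extract_boundary(mask)
        img = np.full(mask.shape, 0.37)
        kg = p.band_kymograph([img, img], [b, b], 0.0, 3.0)
        assert kg.matrix.shape == (360, 2)
        assert np.allclose(kg.matrix, 0.37, atol=1e-6)

    def test_ring_scene_band_separation(self, adhesion_sequence):
        """Band 1 (0-3 um inward) sees the FA ring; band 2 (6-12 um) the
        quiet interior."""
        si = adhesion_sequence["shifts"][-1]
        seg = p.segment_cell(si.pis_image)
        b = p.extract_boundary(seg, pixel_pitch_um=si.pixel_pitch_um)
        k1 = p.band_kymograph([si.pis_image], [b], 0.0, 3.0)
        k2 = p.band_kymograph([si.pis_image], [b], 6.0, 6.0)
        assert np.nanmean(k1.matrix) > 5 * abs(np.nanmean(k2.matrix))

    def test_zero_width_band_is_line_profile(self):
        yy = np.mgrid[0:101, 0:101][0].astype(float)
        mask = disk_mask(radius=25)
        b = p.extract_boundary(mask)
        kg = p.band_kymograph([yy], [b], 3.0, 0.0)
        # single-sample line at 3 um (5 px) inside the boundary
        expect = b.points[:, 0] - (3.0 / 0.6) * b.normals[:, 0]
        assert np.allclose(kg.matrix[:, 0], expect, atol=0.05)


class TestEdgeCenterStats:
    def test_uniform_image_equal_means(self):
        mask = disk_mask(radius=25)
        t = p.edge_center_stats(np.full(mask.shape, 1.3), mask)
        means = t.set_index("region")["mean"]
        assert means["edge"] == pytest.approx(means["center"])

    def test_regions_disjoint_within_mask(self):
        mask = disk_mask(radius=25)
        t = p.edge_center_stats(np.ones(mask.shape), mask,
                                edge_depth_um=3.0, center_margin_um=6.0)
        n = t.set_index("region")["n_pixels"]
        assert n["edge"] + n["center"] <= mask.sum()

    def test_tiny_mask_raises_region_empty(self):
        mask = disk_mask(radius=4)  # 2.4 um radius < 6 um margin
        with pytest.raises(p.RegionEmptyError):
            p.edge_center_stats(np.ones(mask.shape), mask)

    def test_multi_cell_pooled_row(self):
        m1 = disk_mask(radius=20, center=(30, 30))
        m2 = disk_mask(radius=20, center=(70, 70))
        t = p.edge_center_stats(np.ones((101, 101)), [m1, m2])
        assert (t["cell"] == "pooled").sum() == 2
        assert len(t) == 6


class TestCrossSection:
    def test_constant_image_flat_profile(self):
        prof = p.cross_section(np.full((50, 50), 2.5), (25, 5), (25, 45), 80)
        assert np.allclose(prof["value"], 2.5)

    def test_linear_ramp_recovers_analytic_slope(self):
        xx = np.mgrid[0:50, 0:50][1].astype(float)
        prof = p.cross_section(3.0 * xx, (10, 5), (10, 45), 200,
                               pixel_pitch_um=0.6)
        # value = 3 * x_px; position advances 0.6 um per pixel
        slope = np.polyfit(prof["position_um"], prof["value"], 1)[0]
        assert slope == pytest.approx(3.0 / 0.6, rel=1e-6)

    def test_endpoint_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            p.cross_section(np.ones((20, 20)), (5, 5), (25, 5))

    def test_ring_scene_profile_has_two_boundary_peaks(self,
                                                       adhesion_sequence):
        from scipy.signal import find_peaks
        si = adhesion_sequence["shifts"][-1]
        prof = p.cross_section(si.pis_image, (49.5, 5), (49.5, 95), 181,
                               si.pixel_pitch_um)
        v = np.nan_to_num(prof["value"].to_numpy())
        peaks, _ = find_peaks(v, height=0.5 * np.nanmax(v), distance=20)
        assert len(peaks) == 2


class TestTemporalCurves:
    def test_static_scene_flat_curves(self):
        mask = disk_mask((40, 40), (20, 20), 12)
        si = p.ShiftImages(np.full((40, 40), 1.5), np.full((40, 40), 0.05),
                           np.ones((40, 40), bool))
        t = p.temporal_curves([si, si, si], [mask] * 3, normalize_pis=False)
        assert t["pws_mean"].nunique() == 1
        assert t["pis_mean"].nunique() == 1

    def test_single_frame_sd_over_pixels(self):
        rng = np.random.default_rng(2)
        img = rng.normal(1.0, 0.2, (40, 40))
        mask = disk_mask((40, 40), (20, 20), 12)
        si = p.ShiftImages(img, img, np.ones((40, 40), bool))
        t = p.temporal_curves([si], [mask], normalize_pis=False)
        assert len(t) == 1
        assert t["pws_sd"].iloc[0] == pytest.approx(img[mask].std(ddof=1))

    def test_adhesion_ramp_slope_recovered(self, adhesion_sequence):
        """The generator ramps shift amplitudes linearly; the fitted slope
        of the in-mask mean PWS (over the final mask region present in all
        frames) tracks the programmed ramp within 5%."""
        scene = adhesion_sequence["scene"]
        shifts = adhesion_sequence["shifts"]
        # probe the region attached in every frame: the first-frame interior
        core = scene.masks[0] & (scene.mass_maps[0] >=
                                 0.99 * scene.mass_maps[0].max())
        t = p.temporal_curves(shifts, [core] * len(shifts),
                              normalize_pis=False)
        truth_interior = [m.max() * p.synthetic_scene.PWS_CANONICAL_NM
                          for m in scene.mass_maps]
        fit_slope = np.polyfit(range(len(shifts)), t["pws_mean"], 1)[0]
        truth_slope = np.polyfit(range(len(shifts)), truth_interior, 1)[0]
        assert fit_slope == pytest.approx(truth_slope, rel=0.05)

    def test_empty_mask_frame_flagged(self):
        si = p.ShiftImages(np.ones((10, 10)), np.ones((10, 10)),
                           np.ones((10, 10), bool))
        t = p.temporal_curves([si], [np.zeros((10, 10), bool)],
                              normalize_pis=False)
        assert bool(t["flagged"].iloc[0])
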