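import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Point

from barrelcircuit import histomorph as hm
from barrelcircuit import io, synthdata as sd


def _uniform_map(n_barrels=4, width=100.0, septum=40.0, band=(-80.0, 0.0)):
    pitch = width + septum
    barrels = [(50.0 + i * pitch, 50.0 + i * pitch + width)
               for i in range(n_barrels)]
    poly = np.array([[0.0, 0.0], [1000.0, 0.0]])
    return hm.BarrelMap(reference_polyline=poly, barrels=barrels, l4_band=band)


def _chain_morphology(points, d=-40.0):
    """Polyline morphology through (s, d) points."""
    pts = np.asarray(points, dtype=float)
    nodes = pd.DataFrame({
        "id": np.arange(1, len(pts) + 1),
        "type": [1] + [3] * (len(pts) - 1),
        "x": pts[:, 0],
        "y": pts[:, 1] if pts.shape[1] > 1 else np.full(len(pts), d),
        "z": 0.0,
        "radius": 0.5,
        "parent": np.concatenate([[-1], np.arange(1, len(pts))]),
    })
    return hm.Morphology(nodes=nodes)


class TestStraighten:
    def test_horizontal_reference_is_identity(self, rng):
        poly = np.array([[0.0, 0.0], [100.0, 0.0]])
        pts = rng.uniform([5, -20], [95, 20], size=(50, 2))
        s, d = hm.straighten(pts, poly)
        np.testing.assert_allclose(s, pts[:, 0], atol=1e-12)
        np.testing.assert_allclose(d, pts[:, 1], atol=1e-12)

    @pytest.mark.parametrize("theta_deg", [0, 15, 45, 90, 135, 250])
    def test_rotation_preserves_perpendicular_distance(self, theta_deg, rng):
        theta = np.deg2rad(theta_deg)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        poly0 = np.array([[0.0, 0.0], [100.0, 0.0]])
        pts0 = rng.uniform([5, -20], [95, 20], size=(30, 2))
        _, d0 = hm.straighten(pts0, poly0)
        _, d1 = hm.straighten(pts0 @ R.T, poly0 @ R.T)
        np.testing.assert_allclose(np.abs(d1), np.abs(d0), atol=1e-9)

    def test_distance_preserved_against_shapely(self, rng):
        # |d| must equal the exact Euclidean point-to-polyline distance
        verts = np.column_stack([
            np.linspace(0, 300, 40),
            20 * np.sin(np.linspace(0, 3 * np.pi, 40)),
        ])
        line = LineString(verts)
        pts = rng.uniform([10, -60], [290, 60], size=(200, 2))
        _, d = hm.straighten(pts, verts)
        for p, di in zip(pts, d):
            assert abs(abs(di) - line.distance(Point(p))) < 1e-9

    def test_kink_ambiguity_flagged(self):
        poly = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0]])
        # on the inner bisector: two distinct feet at equal distance
        pts = np.array([[8.0, 2.0], [5.0, -1.0]])
        _, _, flags = hm.straighten(pts, poly, return_flags=True)
        assert flags[0]
        assert not flags[1]

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            hm.straighten(np.zeros((1, 2)), np.array([[0, 0], [0, 0]]))


class TestStraightenImage:
    def test_curved_band_becomes_flat(self):
        p = sd.BarrelImageParams(seed=0, noise_sd=0.0, curvature=8e-4)
        scene = sd.gen_barrel_image(p)
        bmap = scene.barrel_map
        st_img, s_axis, d_axis = hm.straighten_image(
            scene.image, bmap.reference_polyline,
            (bmap.l4_band[0] - 15, bmap.l4_band[1] + 15))
        # superficial band edge per column, from threshold crossings
        thr = (p.background + p.septum_intensity) / 2.0
        inner = slice(40, st_img.shape[1] - 40)
        edges = []
        for col in range(*inner.indices(st_img.shape[1])):
            above = st_img[:, col] > thr
            if above.any():
                edges.append(d_axis[np.argmax(above)])
        edges = np.asarray(edges)
        rms = np.sqrt(np.mean((edges - np.median(edges)) ** 2))
        assert rms < 1.0


class TestDetectBarrels:
    def test_noiseless_plateaus_recovered(self):
        s = np.arange(0.0, 500.0)
        y = np.full(s.size, 10.0)
        truth = [(60.0, 140.0), (200.0, 280.0), (340.0, 420.0)]
        for a, b in truth:
            y[(s >= a) & (s <= b)] = 100.0
        out = hm.detect_barrels(s, y, smooth_sigma_um=0.0)
        assert len(out) == 3
        for (a, b), (da, db) in zip(truth, out):
            assert abs(da - a) <= 1.0
            assert abs(db - b) <= 1.0

    def test_constant_profile_no_barrels(self):
        s = np.arange(0.0, 300.0)
        with pytest.raises(ValueError, match="no barrels"):
            hm.detect_barrels(s, np.full(s.size, 42.0))

    def test_affine_intensity_invariance(self):
        s = np.arange(0.0, 500.0)
        rngl = np.random.default_rng(5)
        y = np.full(s.size, 10.0) + rngl.normal(0, 1.0, s.size)
        for a, b in [(60.0, 140.0), (220.0, 320.0)]:
            y[(s >= a) & (s <= b)] += 90.0
        out0 = hm.detect_barrels(s, y)
        out1 = hm.detect_barrels(s, 3.7 * y + 123.0)
        np.testing.assert_allclose(out1, out0, atol=1e-9)

    def test_narrow_runs_rejected(self):
        s = np.arange(0.0, 300.0)
        y = np.full(s.size, 10.0)
        y[(s >= 100) & (s <= 110)] = 100.0  # 10 um, below min width
        with pytest.raises(ValueError, match="no barrels"):
            hm.detect_barrels(s, y, smooth_sigma_um=0.0, min_width_um=20.0)

    def test_noisy_scene_recovery(self, barrel_scene):
        bmap = barrel_scene.barrel_map
        st_img, s_axis, d_axis = hm.straighten_image(
            barrel_scene.image, bmap.reference_polyline,
            (bmap.l4_band[0] - 10, bmap.l4_band[1] + 10))
        profile = hm.band_profile(st_img, d_axis, bmap.l4_band)
        detected = hm.detect_barrels(s_axis, profile)
        assert len(detected) == bmap.n_barrels
        for (a, b), (da, db) in zip(bmap.barrels, detected):
            assert abs((da + db) / 2 - (a + b) / 2) < 5.0


class TestSomaPositionIndex:
    def test_center_is_one(self):
        bmap = _uniform_map()
        c = bmap.centers[1]
        assert hm.soma_position_index(c, bmap) == pytest.approx(1.0)

    def test_septal_midpoint_is_zero(self):
        bmap = _uniform_map()
        m = (bmap.barrels[0][1] + bmap.barrels[1][0]) / 2.0
        assert hm.soma_position_index(m, bmap) == pytest.approx(0.0)

    def test_halfway_is_half(self):
        bmap = _uniform_map()
        c = bmap.centers[1]
        m = (bmap.barrels[1][1] + bmap.barrels[2][0]) / 2.0
        assert hm.soma_position_index((c + m) / 2.0, bmap) == pytest.approx(0.5)

    def test_reflection_symmetry(self, rng):
        bmap = _uniform_map()
        span = 1000.0
        mirrored = hm.BarrelMap(
            reference_polyline=bmap.reference_polyline,
            barrels=sorted((span - b, span - a) for a, b in bmap.barrels),
            l4_band=bmap.l4_band)
        for s in rng.uniform(60.0, 600.0, 25):
            assert hm.soma_position_index(s, bmap) == pytest.approx(
                hm.soma_position_index(span - s, mirrored), abs=1e-9)

    def test_no_barrels_errors(self):
        bmap = hm.BarrelMap(reference_polyline=np.array([[0, 0], [10, 0]]),
                            barrels=[], l4_band=(-10.0, 0.0))
        with pytest.raises(ValueError, match="no barrels"):
            hm.soma_position_index(5.0, bmap)

    def test_outside_mirrored_span_flagged(self):
        bmap = _uniform_map()
        idx, outside = hm.soma_position_index(2.0, bmap, return_flag=True)
        assert outside
        _, inside_flag = hm.soma_position_index(bmap.centers[1],
                                                bmap, return_flag=True)
        assert not inside_flag

    def test_cosine_ramp_shares_anchors(self):
        bmap = _uniform_map()
        c = bmap.centers[0]
        m = (bmap.barrels[0][1] + bmap.barrels[1][0]) / 2.0
        assert hm.soma_position_index(c, bmap, ramp="cosine") == pytest.approx(1.0)
        assert hm.soma_position_index(m, bmap, ramp="cosine") == pytest.approx(0.0)
        assert hm.soma_position_index((c + m) / 2, bmap, ramp="cosine") == \
            pytest.approx(0.5)

    def test_generator_truth_recovered(self, barrel_scene):
        bmap = barrel_scene.barrel_map
        for row in barrel_scene.somata.itertuples():
            idx = hm.soma_position_index(row.s, bmap)
            assert idx == pytest.approx(row.true_index, abs=1e-9)


class TestDendriticOverlap:
    def test_fully_inside_one_barrel(self):
        bmap = _uniform_map()
        s0, s1 = bmap.barrels[1]
        morph = _chain_morphology([(s0 + 10, -40.0), (s1 - 10, -40.0)])
        res = hm.dendritic_overlap(morph, bmap)
        assert res.principal_barrel == 1
        assert res.pct_principal == pytest.approx(100.0)
        assert res.pct_adjacent == pytest.approx(0.0)
        assert res.pct_outside == pytest.approx(0.0, abs=1e-9)

    def test_60_40_split_matches_dense_sampling_oracle(self):
        bmap = _uniform_map()
        morph, truth = sd.planted_morphology(
            bmap.barrels[1], bmap.l4_band, frac_inside=0.6, total_length=100.0)
        res = hm.dendritic_overlap(morph, bmap)
        assert res.pct_principal == pytest.approx(60.0, abs=0.5)

        # oracle: dense point sampling along the polyline
        seg = morph.segments()
        n_pts = 200001
        samples = np.concatenate([
            np.linspace(0, 1, n_pts // len(seg))[:, None] * (p1 - p0) + p0
            for p0, p1 in seg
        ])
        (s0, s1), (d0, d1) = bmap.barrels[1], bmap.l4_band
        inside = ((samples[:, 0] >= s0) & (samples[:, 0] <= s1)
                  & (samples[:, 1] >= d0) & (samples[:, 1] <= d1))
        oracle_pct = 100.0 * inside.mean()
        assert res.pct_principal == pytest.approx(oracle_pct, abs=0.5)

    def test_four_percent_overlap_excluded(self):
        # 100 um dendrite dips only 4 um into the L4 band at a barrel center
        bmap = _uniform_map()
        c = bmap.centers[1]
        morph = _chain_morphology([(c, -4.0), (c, 96.0)])
        res = hm.dendritic_overlap(morph, bmap)
        assert res.excluded
        assert res.pct_principal == pytest.approx(4.0, abs=1e-9)

    def test_zero_length_errors(self):
        bmap = _uniform_map()
        nodes = pd.DataFrame({"id": [1], "type": [1], "x": [100.0],
                              "y": [-40.0], "z": [0.0], "radius": [5.0],
                              "parent": [-1]})
        with pytest.raises(ValueError, match="zero total"):
            hm.dendritic_overlap(hm.Morphology(nodes=nodes), bmap)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_percentages_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        bmap = _uniform_map()
        pts = rng.uniform([0, -120], [1000, 40], size=(rng.integers(2, 12), 2))
        res = hm.dendritic_overlap(_chain_morphology(pts), bmap)
        total = sum(res.per_barrel_pct.values()) + res.pct_outside
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_adjacent_rules(self):
        bmap = _uniform_map()
        # soma in barrel 1, spill into barrel 2
        s0, s1 = bmap.barrels[1]
        morph = _chain_morphology([(s0 + 5, -40.0), (bmap.barrels[2][0] + 30, -40.0)])
        near = hm.dendritic_overlap(morph, bmap, adjacent_rule="nearest_center")
        second = hm.dendritic_overlap(morph, bmap, adjacent_rule="second_overlap")
        assert near.principal_barrel == 1
        assert second.adjacent_barrel == 2


class TestIntensityOps:
    def test_lhx2_ratio_equal_intensities(self):
        assert hm.lhx2_ratio(80.0, [80.0, 80.0, 80.0]) == pytest.approx(1.0)

    def test_lhx2_ratio_half(self):
        assert hm.lhx2_ratio(50.0, [100.0, 100.0, 100.0]) == pytest.approx(0.5)

    def test_lhx2_requires_exactly_three_neighbors(self):
        with pytest.raises(ValueError, match="exactly 3"):
            hm.lhx2_ratio(50.0, [100.0, 100.0])
        with pytest.raises(ValueError, match="exactly 3"):
            hm.lhx2_ratio(50.0, [100.0] * 4)

    def test_disk_mpi_recovery(self, rng):
        # planted intensity disks recover the target ratio
        ratios = []
        for _ in range(50):
            img = rng.normal(1000.0, 30.0, (60, 120))
            yy, xx = np.mgrid[0:60, 0:120]
            centers = [(20.0, 30.0), (90.0, 20.0), (95.0, 45.0), (70.0, 40.0)]
            intensities = [7000.0, 10000.0, 10000.0, 10000.0]
            for (cx, cy), level in zip(centers, intensities):
                mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= 36.0
                img[mask] = level + rng.normal(0, 200.0, int(mask.sum()))
            cell = hm.soma_mpi(img, centers[0], radius_um=5.0)
            neigh = [hm.soma_mpi(img, c, radius_um=5.0) for c in centers[1:]]
            ratios.append(hm.lhx2_ratio(cell, neigh))
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.05)

    def test_roi_fraction_all_inside(self):
        img = np.zeros((50, 50))
        img[10:20, 10:20] = 1000.0
        roi = np.zeros((50, 50), dtype=bool)
        roi[5:25, 5:25] = True
        fractions, mean = hm.roi_expression_fraction([img], [roi])
        assert mean == pytest.approx(1.0)

    def test_roi_fraction_quarter(self):
        img = np.zeros((40, 40))
        img[0:20, :] = 1000.0  # uniform expression over the top half
        roi = np.zeros((40, 40), dtype=bool)
        roi[0:10, 0:20] = True  # 25% of the suprathreshold area
        _, mean = hm.roi_expression_fraction([img], [roi])
        assert mean == pytest.approx(0.25)

    def test_roi_fraction_planted_0p8(self, rng):
        img = rng.normal(100.0, 10.0, (100, 100))
        expr = rng.random((100, 100)) < 0.0  # start empty
        img[10:50, 10:50] = 5000.0  # 1600 px inside ROI
        img[70:90, 70:90] = 5000.0  # 400 px outside
        roi = np.zeros((100, 100), dtype=bool)
        roi[0:60, 0:60] = True
        _, mean = hm.roi_expression_fraction([img], [roi])
        assert mean == pytest.approx(0.8, abs=0.02)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shapes differ"):
            hm.roi_expression_fraction([np.zeros((5, 5))],
                                       [np.zeros((6, 6), dtype=bool)])


class TestSwcRoundTrip:
    def test_write_read_preserves_morphology(self, tmp_path):
        morph, _ = sd.planted_morphology((100.0, 300.0), (-80.0, 0.0), 0.5)
        path = tmp_path / "cell.swc"
        io.write_swc(morph, path)
        back = io.read_swc(path)
        pd.testing.assert_frame_equal(
            back.nodes.astype(float), morph.nodes.astype(float),
            check_exact=False, atol=1e-5)
        assert back.total_length == pytest.approx(morph.total_length, abs=1e-3)

    def test_cycle_detection(self):
        nodes = pd.DataFrame({
            "id": [1, 2, 3], "type": [1, 3, 3],
            "x": [0.0, 1.0, 2.0], "y": [0.0] * 3, "z": [0.0] * 3,
            "radius": [1.0] * 3, "parent": [-1, 3, 2],
        })
        with pytest.raises(ValueError, match="cycle"):
            hm.Morphology(nodes=nodes)
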