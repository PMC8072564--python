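"""Pruned medial-axis skeletonization: shape contracts and oracle equivalence."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

import neuritrace.skeleton as skeleton_mod
from neuritrace.skeleton import (
    Skeleton,
    branch_statistics,
    skeletonize_propagated,
    smooth_mask,
    total_length_um,
    upscale_mask,
)

from .conftest import draw_soma_arm_shape, make_mask, reconstruction_hausdorff


def disk_mask(radius, pad=10):
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2


def _bar(canvas):
    out = np.zeros_like(canvas, dtype=float)
    out[130:170, 50:250] = 1.0
    return out


def bar_with_protrusion(extent_px, bar=(400, 60), canvas=(160, 440)):
    """Horizontal bar with one centred square protrusion on its top edge."""
    H, W = canvas
    bar_w, bar_h = bar
    top = (H - bar_h) // 2 + 10
    img = np.zeros((H, W), dtype=bool)
    img[top : top + bar_h, 20 : 20 + bar_w] = True
    s = extent_px
    c0 = W // 2 - s // 2
    img[top - s : top, c0 : c0 + s] = True
    return img, top


class TestUpscale:
    def test_dimensions(self):
        mask = make_mask(np.ones((10, 10), bool))
        up = upscale_mask(mask, 3)
        assert up.raster.shape == (30, 30)
        assert up.scale_factor == 3

    def test_area_multiplies_by_factor_squared(self):
        rng = np.random.default_rng(0)
        mask = make_mask(rng.random((20, 20)) < 0.3)
        up = upscale_mask(mask, 3)
        assert up.raster.sum() == 9 * mask.raster.sum()

    def test_factor_one_is_identity(self):
        mask = make_mask(np.eye(8, dtype=bool))
        up = upscale_mask(mask, 1)
        np.testing.assert_array_equal(up.raster, mask.raster)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            upscale_mask(make_mask(np.ones((4, 4), bool)), 0)

    def test_effective_pixel_size(self):
        mask = make_mask(np.ones((10, 10), bool))
        up = upscale_mask(mask, 3)
        assert up.effective_pixel_size_um == pytest.approx(mask.effective_pixel_size_um / 3)


class TestSkeletonShapes:
    def test_empty_mask_empty_skeleton(self):
        sk = skeletonize_propagated(make_mask(np.zeros((20, 20), bool)), 10.0)
        assert sk.is_empty
        assert total_length_um(sk) == 0.0
        assert branch_statistics(sk) == {
            "endpoint_count": 0,
            "branch_point_count": 0,
            "branch_segment_count": 0,
        }

    def test_disk_collapses_to_near_point(self):
        sk = skeletonize_propagated(make_mask(disk_mask(30)), 10.0)
        assert sk.total_length_px() <= 2.0

    def test_rectangle_central_segment(self):
        img = np.zeros((60, 220), dtype=bool)
        img[10:50, 10:210] = True  # 200 x 40
        sk = skeletonize_propagated(make_mask(img), 10.0)
        assert sk.total_length_px() == pytest.approx(160, abs=3)
        stats = branch_statistics(sk)
        assert stats["branch_point_count"] == 0
        assert stats["branch_segment_count"] == 1

    @pytest.mark.parametrize("multiple, has_branch", [(1.5, False), (1.75, False), (2.0, True), (2.5, True)])
    def test_protrusion_rule(self, multiple, has_branch):
        eps = 10.0
        img, top = bar_with_protrusion(int(round(multiple * eps)))
        sk = skeletonize_propagated(make_mask(img), eps)
        in_protrusion = bool(np.any(sk.coords[:, 0] < top)) if not sk.is_empty else False
        assert in_protrusion == has_branch

    def test_rotation_robustness(self):
        # rasterization of the rotated bar leaves a jagged boundary, which
        # the pipeline always smooths before skeletonization; apply the same
        # smoothing to both orientations
        from skimage.transform import rotate

        img = np.zeros((300, 300), dtype=float)
        l0_mask = smooth_mask(make_mask((img + _bar(img)) > 0.5), 1.5)
        l0 = skeletonize_propagated(l0_mask, 10.0).total_length_px()
        rot = rotate(_bar(img), 30, resize=False, order=0) > 0.5
        l1 = skeletonize_propagated(smooth_mask(make_mask(rot), 1.5), 10.0).total_length_px()
        assert abs(l1 - l0) / l0 < 0.05

    def test_epsilon_monotonicity(self):
        img = np.zeros((200, 300), dtype=bool)
        img[95:105, 20:280] = True
        img[40:95, 60:66] = True
        img[105:170, 150:156] = True
        img[60:64, 66:120] = True
        prev = None
        for eps in (2, 5, 10, 20):
            length = skeletonize_propagated(make_mask(img), eps).total_length_px()
            if prev is not None:
                assert length <= prev + 1e-9
            prev = length

    def test_connected_components_preserved(self):
        img = np.zeros((120, 120), dtype=bool)
        img[10:40, 10:40] = True
        img[70:110, 70:110] = True
        sk = skeletonize_propagated(make_mask(img), 5.0)
        import networkx as nx

        assert nx.number_connected_components(sk.graph) == 2

    def test_radii_match_boundary_distance(self):
        img = np.zeros((80, 200), dtype=bool)
        img[30:50, 20:180] = True
        sk = skeletonize_propagated(make_mask(img), 5.0)
        dist = ndimage.distance_transform_edt(img)
        for (r, c), rad in zip(np.round(sk.coords).astype(int), sk.radii):
            assert img[r, c]
            assert abs(rad - dist[r, c]) <= 1.0

    def test_reconstruction_certificate_sample(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            img = draw_soma_arm_shape(rng)
            sk = skeletonize_propagated(make_mask(img), 10.0)
            assert reconstruction_hausdorff(img, sk.coords, sk.radii) <= 10.0


class TestBranchStatistics:
    def _skeleton_from_points(self, pts, edges):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(range(len(pts)))
        G.add_edges_from(edges)
        return Skeleton(np.array(pts, float), np.ones(len(pts)), G, 10.0)

    def test_open_polyline(self):
        sk = self._skeleton_from_points([(0, i) for i in range(5)], [(i, i + 1) for i in range(4)])
        assert branch_statistics(sk) == {
            "endpoint_count": 2,
            "branch_point_count": 0,
            "branch_segment_count": 1,
        }

    def test_y_shape(self):
        pts = [(5, 5), (4, 5), (3, 5), (6, 4), (7, 3), (6, 6), (7, 7)]
        edges = [(0, 1), (1, 2), (0, 3), (3, 4), (0, 5), (5, 6)]
        sk = self._skeleton_from_points(pts, edges)
        assert branch_statistics(sk) == {
            "endpoint_count": 3,
            "branch_point_count": 1,
            "branch_segment_count": 3,
        }

    def test_cycle_counts_one_segment(self):
        pts = [(0, 0), (0, 1), (1, 1), (1, 0)]
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]
        sk = self._skeleton_from_points(pts, edges)
        stats = branch_statistics(sk)
        assert stats["endpoint_count"] == 0
        assert stats["branch_point_count"] == 0
        assert stats["branch_segment_count"] == 1


class TestLength:
    def test_upscaled_length_conversion(self, printed_calibration):
        # 300 upscaled px at factor 3 = 100 source px = 64.31 um
        import networkx as nx

        pts = [(10.0, float(10 + i)) for i in range(301)]
        G = nx.Graph()
        G.add_nodes_from(range(301))
        G.add_edges_from((i, i + 1) for i in range(300))
        sk = Skeleton(np.array(pts), np.full(301, 4.0), G, 10.0,
                      scale_factor=3, calibration=printed_calibration)
        assert total_length_um(sk) == pytest.approx(100 * printed_calibration.pixel_size_um)
        assert round(total_length_um(sk), 2) == 64.31

    def test_scale_factor_linearity(self, printed_calibration):
        import networkx as nx

        pts = [(10.0, float(10 + i)) for i in range(100)]
        G = nx.Graph()
        G.add_nodes_from(range(100))
        G.add_edges_from((i, i + 1) for i in range(99))
        radii = np.full(100, 3.0)
        sk1 = Skeleton(np.array(pts), radii, G, 10.0, 1, printed_calibration)
        sk3 = Skeleton(np.array(pts), radii, G.copy(), 10.0, 3, printed_calibration)
        assert total_length_um(sk1) == pytest.approx(3 * total_length_um(sk3))

    def test_tip_correction_adds_end_radii(self, printed_calibration):
        import networkx as nx

        pts = [(10.0, float(10 + i)) for i in range(50)]
        G = nx.Graph()
        G.add_nodes_from(range(50))
        G.add_edges_from((i, i + 1) for i in range(49))
        sk = Skeleton(np.array(pts), np.full(50, 2.0), G, 10.0, 1, printed_calibration)
        plain = total_length_um(sk)
        corrected = total_length_um(sk, tip_correction=True)
        assert corrected == pytest.approx(plain + 4.0 * printed_calibration.pixel_size_um)


class TestSmoothMask:
    def test_preserves_area_of_upscaled_tube(self):
        from skimage.draw import line

        img = np.zeros((40, 40), dtype=bool)
        rr, cc = line(5, 5, 33, 30)
        img[rr, cc] = True
        img = ndimage.binary_dilation(img, structure=np.ones((3, 3), bool))
        up = upscale_mask(make_mask(img), 3)
        sm = smooth_mask(up, 1.5)
        assert abs(int(sm.raster.sum()) - int(up.raster.sum())) / up.raster.sum() < 0.05

    def test_removes_staircase_braiding(self):
        from skimage.draw import line

        img = np.zeros((40, 40), dtype=bool)
        rr, cc = line(5, 5, 33, 30)
        img[rr, cc] = True
        img = ndimage.binary_dilation(img, structure=np.ones((3, 3), bool))
        up = smooth_mask(upscale_mask(make_mask(img), 3), 1.5)
        sk = skeletonize_propagated(up, 10.0)
        stats = branch_statistics(sk)
        assert stats["branch_point_count"] == 0
        assert stats["branch_segment_count"] == 1


# --------------------------------------------------------------------------
# Brute-force discrete medial-axis oracle
# --------------------------------------------------------------------------

TIE_TOLERANCE = np.sqrt(2) / 2  # grid half-diagonal: boundary positions are
# only known to half-step accuracy on the lattice
MIN_CONTACT_SEPARATION = 2.0  # the two nearest boundary points must be
# distinct contacts, not same-wall lattice neighbours


def brute_force_medial_axis(mask):
    """Pixels with >= 2 (distinct) nearest boundary pixels, by exhaustion."""
    fg = np.argwhere(mask)
    dil = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
    bg = np.argwhere(dil & ~mask)
    pts, radii = [], []
    for (r, c) in fg:
        d = np.hypot(bg[:, 0] - r, bg[:, 1] - c)
        d0 = d.min()
        q = bg[d <= d0 + TIE_TOLERANCE]
        if len(q) >= 2 and pdist(q).max() > MIN_CONTACT_SEPARATION:
            pts.append((float(r), float(c)))
            radii.append(float(d0))
    return np.array(pts), np.array(radii), bg.astype(float)


def oracle_pruned_skeleton(mask, epsilon):
    """Brute-force medial axis with the identical pruning criterion applied."""
    pts, radii, bg = brute_force_medial_axis(mask)
    G = skeleton_mod._adjacency_graph(pts)
    keep = skeleton_mod._prune_component(pts, radii, G, cKDTree(bg), bg, epsilon)
    return pts[keep]


def corridor_polyomino(rng, grid=8, pitch=4, size=5, steps=10):
    """Random corridor polyomino (odd strip widths, no 2x2 blocks, dead ends
    extended so no protrusion sits at the pruning threshold), <= 40x40 px."""
    g = np.zeros((grid, grid), bool)
    r = c = grid // 2
    g[r, c] = True
    for _ in range(steps):
        for _try in range(8):
            dr, dc = [(0, 1), (0, -1), (1, 0), (-1, 0)][rng.integers(4)]
            nr = int(np.clip(r + dr, 0, grid - 1))
            nc = int(np.clip(c + dc, 0, grid - 1))
            g2 = g.copy()
            g2[nr, nc] = True
            if not any(g2[i : i + 2, j : j + 2].all() for i in range(grid - 1) for j in range(grid - 1)):
                g = g2
                r, c = nr, nc
                break
    for _ in range(3):
        changed = False
        for (i, j) in np.argwhere(g):
            nbr = [
                (i + d[0], j + d[1])
                for d in ((0, 1), (0, -1), (1, 0), (-1, 0))
                if 0 <= i + d[0] < grid and 0 <= j + d[1] < grid
            ]
            on = [(a, b) for a, b in nbr if g[a, b]]
            if len(on) == 1:
                ai, aj = on[0]
                ext = (2 * i - ai, 2 * j - aj)
                if 0 <= ext[0] < grid and 0 <= ext[1] < grid and not g[ext]:
                    g2 = g.copy()
                    g2[ext] = True
                    if not any(
                        g2[a : a + 2, b : b + 2].all() for a in range(grid - 1) for b in range(grid - 1)
                    ):
                        g = g2
                        changed = True
        if not changed:
            break
    mask = np.zeros((grid * pitch + 1,) * 2, bool)
    for (i, j) in np.argwhere(g):
        mask[i * pitch : i * pitch + size, j * pitch : j * pitch + size] = True
    return np.pad(mask, 3)


def test_oracle_equivalence_on_polyominoes():
    """Skeleton centres agree with the exhaustive discrete medial axis
    (same pruning criterion) within 1.5 px Hausdorff distance."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        mask = corridor_polyomino(rng)
        assert mask.shape[0] <= 40
        sk = skeletonize_propagated(make_mask(mask), 3.0)
        oracle = oracle_pruned_skeleton(mask, 3.0)
        d1, _ = cKDTree(oracle).query(sk.coords)
        d2, _ = cKDTree(sk.coords).query(oracle)
        assert max(d1.max(), d2.max()) <= 1.5
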