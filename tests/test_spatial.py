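"""Spatial statistics against brute-force and constructed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from stromspat import (
    ParameterError,
    UndefinedResultError,
    Window,
    build_scene,
    buffer_zone,
    detect_clusters,
    pair_correlation,
    proximity_fractions,
    type2_spec,
    vertical_profile,
)
from stromspat.classify import ClassMasks
from stromspat.image import SurfaceLine
from stromspat.spatial import area_fraction_srm
from stromspat.scenes import _surface_um

PX = 682.67 / 512.0


def flat_surface(n_cols, row=0.0, px=PX):
    return SurfaceLine(np.full(n_cols, float(row)), 1, px)


class TestBufferZone:
    def test_133_um_is_100_map_pixels_from_row_zero(self):
        zone = buffer_zone(flat_surface(512), 133.0, n_rows=512)
        assert zone.depth_px == 100
        assert zone.mask[:100].all()
        assert not zone.mask[100:].any()

    def test_zone_clipped_to_image(self):
        zone = buffer_zone(flat_surface(64), 133.0, n_rows=50)
        assert zone.mask.all()

    def test_shifted_surface_shifts_zone(self):
        a = buffer_zone(flat_surface(64, 10), 40.0, n_rows=128).mask
        b = buffer_zone(flat_surface(64, 17), 40.0, n_rows=128).mask
        assert np.array_equal(b[17:], a[10:-7])

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ParameterError):
            buffer_zone(flat_surface(8), 0.0)


def class_masks(srm, other=None, fil=None, precip=None, px=PX):
    shape = srm.shape
    zeros = np.zeros(shape, dtype=bool)
    other = zeros if other is None else other
    fil = zeros if fil is None else fil
    precip = zeros if precip is None else precip
    return ClassMasks(
        srm=srm, other_bacteria=other, filaments=fil, precipitates=precip,
        background=~(srm | other | fil), pixel_size_um=px,
    )


class TestAreaFraction:
    def test_all_srm_is_100_percent(self):
        srm = np.zeros((64, 64), dtype=bool)
        srm[5:20, 5:20] = True
        zone = buffer_zone(flat_surface(64), 50.0, n_rows=64)
        assert area_fraction_srm(class_masks(srm), zone) == 100.0

    def test_empty_srm_is_0_percent(self):
        other = np.zeros((64, 64), dtype=bool)
        other[5:20, 5:20] = True
        zone = buffer_zone(flat_surface(64), 50.0, n_rows=64)
        masks = class_masks(np.zeros_like(other), other=other)
        assert area_fraction_srm(masks, zone) == 0.0

    def test_empty_zone_is_undefined_not_zero(self):
        zone = buffer_zone(flat_surface(64), 10.0, n_rows=64)
        with pytest.raises(UndefinedResultError):
            area_fraction_srm(class_masks(np.zeros((64, 64), dtype=bool)), zone)

    def test_known_mixture_fraction_exact(self):
        srm = np.zeros((64, 64), dtype=bool)
        other = np.zeros_like(srm)
        srm[2:4, :10] = True       # 20 px
        other[10:14, :20] = True   # 80 px
        zone = buffer_zone(flat_surface(64), 60.0, n_rows=64)
        assert area_fraction_srm(class_masks(srm, other), zone) == pytest.approx(20.0)


class TestVerticalProfile:
    def test_all_cells_at_surface_fill_first_bin(self):
        pts = np.column_stack([np.linspace(1, 60, 20), np.zeros(20)])
        prof = vertical_profile(pts, flat_surface(64), bin_um=10, max_depth_um=100)
        assert prof.cumulative[0] == pytest.approx(1.0)

    def test_planted_90_10_split_recovered_exactly(self):
        rng = np.random.default_rng(0)
        shallow = np.column_stack([rng.uniform(0, 600, 90), rng.uniform(0, 125, 90)])
        deep = np.column_stack([rng.uniform(0, 600, 10), rng.uniform(140, 490, 10)])
        pts = np.vstack([shallow, deep])
        prof = vertical_profile(pts, flat_surface(512), bin_um=10, max_depth_um=500)
        assert prof.fraction_above(130.0) == pytest.approx(0.9)

    def test_type2_scene_majority_in_top_130_of_500(self):
        scene = build_scene(type2_spec(seed=2))
        pts = scene.srm_points().copy()
        surface = SurfaceLine(scene.surface_px, 1, scene.window.pixel_size_um)
        prof = vertical_profile(pts, surface, bin_um=10, max_depth_um=500)
        assert prof.fraction_above(130.0) > 0.85

    def test_no_cells_above_max_depth_is_undefined(self):
        pts = np.array([[10.0, 400.0]])
        with pytest.raises(UndefinedResultError):
            vertical_profile(pts, flat_surface(64), bin_um=10, max_depth_um=100)


def brute_force_clusters(points, diameter):
    """Union-find over the full pairwise distance matrix (the oracle)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) < diameter:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


class TestClusters:
    def test_isolated_cells_yield_no_selected_clusters(self):
        pts = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0], [40.0, 40.0]])
        cs = detect_clusters(pts)
        assert cs.n_clusters == 4
        assert not cs.table["selected"].any()

    @pytest.mark.parametrize("n,expected", [(5, False), (6, True)])
    def test_selection_needs_strictly_more_than_five_cells(self, n, expected):
        chain = np.column_stack([5.0 * np.arange(n), np.zeros(n)])
        cs = detect_clusters(chain)
        assert cs.n_clusters == 1
        assert bool(cs.table["selected"].iloc[0]) is expected

    def test_empty_input_gives_empty_clusterset(self):
        cs = detect_clusters(np.empty((0, 2)))
        assert cs.n_clusters == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 2**20))
    def test_memberships_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 80, size=(50, 2))
        cs = detect_clusters(pts, region_diameter_um=10.0)
        oracle = brute_force_clusters(pts, 10.0)
        # same partition: co-membership matrices agree
        ours = cs.membership
        assert np.array_equal(
            ours[:, None] == ours[None, :], oracle[:, None] == oracle[None, :]
        )

    def test_cluster_area_is_dissolved_disk_union(self):
        # two coincident cells: union area = single 5-um-radius disk
        pts = np.array([[10.0, 10.0], [10.0, 10.0]])
        cs = detect_clusters(pts)
        assert cs.table["area_um2"].iloc[0] == pytest.approx(np.pi * 25.0, rel=0.01)
        # far-apart cells: each cluster area one disk
        pts = np.array([[10.0, 10.0], [60.0, 60.0]])
        cs = detect_clusters(pts)
        assert np.allclose(cs.table["area_um2"], np.pi * 25.0, rtol=0.01)


def brute_force_g(points, window, r_grid, ring_width):
    """Direct double-loop ĝ(r) with translation edge correction (oracle)."""
    n = len(points)
    W, H = window.width_um, window.height_um
    g = np.zeros_like(r_grid)
    for k, r in enumerate(r_grid):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(points[i, 0] - points[j, 0])
                dy = abs(points[i, 1] - points[j, 1])
                d = np.hypot(dx, dy)
                if abs(d - r) <= ring_width / 2:
                    c = (W - dx) * (H - dy) / (W * H)
                    total += 1.0 / c
        g[k] = W * H / (n * (n - 1)) * total / (2 * np.pi * r * ring_width)
    return g


class TestPairCorrelation:
    def test_matches_brute_force_on_small_pattern(self):
        rng = np.random.default_rng(3)
        w = Window(100.0, 100.0, 1.0)
        pts = rng.uniform(0, 100, size=(10, 2))
        r_grid = np.linspace(2.0, 40.0, 20)
        curve = pair_correlation(pts, window=w, r_grid_um=r_grid, ring_width_um=4.0)
        oracle = brute_force_g(pts, w, r_grid, 4.0)
        assert np.allclose(curve.g, oracle, rtol=1e-10, atol=1e-12)

    def test_csr_pattern_mostly_inside_envelope(self, default_window):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 682.67, size=(300, 2))
        curve = pair_correlation(pts, window=default_window, envelope_sims=39, seed=1)
        assert not curve.exceeds_envelope()

    def test_auto_excludes_self_pairs(self):
        w = Window(50.0, 50.0, 1.0)
        pts = np.array([[10.0, 10.0], [40.0, 40.0]])
        curve = pair_correlation(pts, window=w, r_grid_um=np.array([1.0]),
                                 ring_width_um=0.5)
        assert curve.g[0] == 0.0  # the only separation is far from r=1

    def test_cross_mode_counts_all_ordered_pairs(self):
        w = Window(50.0, 50.0, 1.0)
        a = np.array([[10.0, 10.0], [30.0, 10.0]])
        b = np.array([[12.0, 10.0], [28.0, 10.0]])
        r_grid = np.array([2.0])
        curve = pair_correlation(a, b, window=w, r_grid_um=r_grid, ring_width_um=1.0)
        # two ordered (a, b) pairs at distance 2
        c = (50 - 2) * 50 / 2500.0
        expected = 2500.0 / 4 * (2 / c) / (2 * np.pi * 2.0 * 1.0)
        assert curve.g[0] == pytest.approx(expected)

    def test_fewer_than_two_points_rejected(self, default_window):
        with pytest.raises(ParameterError):
            pair_correlation(np.array([[1.0, 1.0]]), window=default_window)


def brute_force_min_distances(object_mask, precip_mask, px):
    """Min over all object-pixel/precipitate-pixel centre distances."""
    from scipy import ndimage as ndi

    labels, n = ndi.label(object_mask, structure=np.ones((3, 3)))
    precip = np.argwhere(precip_mask)
    out = []
    for l in range(1, n + 1):
        obj = np.argwhere(labels == l)
        d = np.sqrt(((obj[:, None, :] - precip[None, :, :]) ** 2).sum(axis=2))
        out.append(d.min() * px)
    return np.array(out)


class TestProximity:
    PX_FINE = 0.2

    def test_single_srm_one_um_away_is_100_percent_everywhere(self):
        srm = np.zeros((64, 64), dtype=bool)
        precip = np.zeros_like(srm)
        precip[30, 30] = True
        srm[30, 35] = True  # 5 px = 1.0 um away
        res = proximity_fractions(srm, np.zeros_like(srm), precip, self.PX_FINE)
        assert all(res.percent_srm(t) == 100.0 for t in (1.1, 2.2, 4.4))

    def test_threshold_arithmetic_at_two_um(self):
        srm = np.zeros((64, 64), dtype=bool)
        precip = np.zeros_like(srm)
        precip[30, 30] = True
        srm[30, 40] = True  # 2.0 um
        res = proximity_fractions(srm, np.zeros_like(srm), precip, self.PX_FINE)
        assert res.table.set_index("threshold_um")["srm_near"].to_dict() == {
            1.1: 0, 2.2: 1, 4.4: 1,
        }

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_object_distances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        srm = rng.uniform(size=(40, 40)) < 0.05
        precip = rng.uniform(size=(40, 40)) < 0.03
        precip &= ~srm
        if not precip.any():
            precip[5, 5] = True
        oracle = brute_force_min_distances(srm, precip, self.PX_FINE)
        thresholds = tuple(np.round(np.linspace(0.2, 8.0, 12), 3))
        res = proximity_fractions(srm, np.zeros_like(srm), precip, self.PX_FINE,
                                  thresholds_um=thresholds)
        for t in thresholds:
            expected = int((oracle <= t + 1e-9).sum())
            assert res.table.set_index("threshold_um")["srm_near"][t] == expected

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        srm = rng.uniform(size=(64, 64)) < 0.04
        other = rng.uniform(size=(64, 64)) < 0.04
        precip = rng.uniform(size=(64, 64)) < 0.02
        res = proximity_fractions(srm, other, precip, self.PX_FINE,
                                  thresholds_um=(0.5, 1.1, 2.2, 4.4, 8.8))
        for col in ("srm_near", "other_near", "total_near"):
            assert res.table[col].is_monotonic_increasing

    def test_no_precipitates_flagged_undefined(self):
        srm = np.ones((8, 8), dtype=bool)
        res = proximity_fractions(srm, np.zeros_like(srm), np.zeros_like(srm), 1.0)
        assert not res.table["defined"].any()
        assert res.table["percent_srm"].isna().all()
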