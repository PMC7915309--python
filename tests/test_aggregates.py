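"""Denoising, component labelling vs a flood-fill oracle, area accounting."""

import numpy as np
import pytest

from octquant import (
    Aggregate,
    IntensityGrid,
    ScanSession,
    aggregate_metrics,
    denoise,
    detect_aggregates,
    filter_min_area,
    min_pixels_for_area,
    pixel_area_ratio,
    reconstruct_volume,
)
from octquant.errors import EmptyRegionError, GeometryMismatchError


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Independent oracle: BFS flood fill, returns list of pixel-count sizes."""
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    n_rows, n_cols = mask.shape
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if mask[r0, c0] and not seen[r0, c0]:
                queue = [(r0, c0)]
                seen[r0, c0] = True
                size = 0
                while queue:
                    r, c = queue.pop()
                    size += 1
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < n_rows and 0 <= cc < n_cols
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                sizes.append(size)
    return sorted(sizes, reverse=True)


def _detect_on_mask(mask: np.ndarray, connectivity: int = 8):
    """Run the detector on a binary mask turned into an intensity image."""
    img = np.where(mask, 100.0, 1.0)
    g = IntensityGrid(img, pixel_area=9.0)
    vit = np.ones_like(mask, dtype=bool)
    return detect_aggregates(g, vit, threshold=50.0, refine=False,
                             connectivity=connectivity)


class TestDenoise:
    def test_uniform_image_is_fixed_point(self):
        g = IntensityGrid(np.full((32, 32), 77.0))
        np.testing.assert_array_equal(denoise(g).pixels, g.pixels)

    def test_single_hot_pixel_removed(self):
        img = np.full((32, 32), 10.0)
        img[16, 16] = 250.0
        out = denoise(IntensityGrid(img))
        assert out.pixels[16, 16] == 10.0

    def test_block_interior_preserved(self):
        img = np.full((32, 32), 10.0)
        img[10:15, 10:15] = 200.0
        out = denoise(IntensityGrid(img))
        # interior of a 5x5 block survives a 3x3 median untouched
        np.testing.assert_array_equal(out.pixels[11:14, 11:14], 200.0)

    def test_window_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            denoise(IntensityGrid(np.ones((16, 16))), window=17)


class TestDetection:
    def test_noiseless_background_yields_no_components(self):
        g = IntensityGrid(np.full((64, 64), 30.0))
        vit = np.ones((64, 64), dtype=bool)
        assert detect_aggregates(g, vit) == []

    def test_three_planted_blobs_match_flood_fill(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:10, 5:12] = True       # 35 px
        mask[30:36, 40:44] = True     # 24 px
        mask[50:53, 20:23] = True     # 9 px
        found = _detect_on_mask(mask)
        assert [a.n_pixels for a in found] == flood_fill_components(mask)

    def test_diagonal_contact_connectivity(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:6, 4:6] = True
        mask[6:8, 6:8] = True          # touches only diagonally
        assert len(_detect_on_mask(mask, connectivity=8)) == 1
        assert len(_detect_on_mask(mask, connectivity=4)) == 2

    def test_random_masks_match_flood_fill_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mask = rng.random((48, 48)) < 0.25
            for conn in (8, 4):
                found = _detect_on_mask(mask, connectivity=conn)
                assert [a.n_pixels for a in found] == \
                    flood_fill_components(mask, connectivity=conn)

    def test_aggregates_confined_to_vitreous_mask(self):
        img = np.full((64, 64), 10.0)
        img[40:45, 10:15] = 200.0       # below the vitreous: must be ignored
        img[5:10, 5:10] = 200.0
        vit = np.zeros((64, 64), dtype=bool)
        vit[:30] = True
        found = detect_aggregates(IntensityGrid(img, pixel_area=9.0), vit,
                                  threshold=100.0, refine=False)
        assert len(found) == 1
        assert found[0].pixel_coords[:, 0].max() < 30

    def test_empty_mask_raises(self):
        g = IntensityGrid(np.ones((32, 32)))
        with pytest.raises(EmptyRegionError):
            detect_aggregates(g, np.zeros((32, 32), dtype=bool))


def _agg(n_px, pixel_area=9.0, scan=0):
    return Aggregate(
        pixel_coords=np.zeros((n_px, 2), dtype=int), n_pixels=n_px,
        area=n_px * pixel_area, centroid=(0.0, 0.0),
        mean_intensity=100.0, bscan_index=scan,
    )


class TestMinAreaFilter:
    def test_spec_example_400_600(self):
        aggs = [_agg(1, pixel_area=400.0), _agg(1, pixel_area=600.0)]
        kept = filter_min_area(aggs, 500.0)
        assert len(kept) == 1 and kept[0].area == 600.0

    def test_zero_min_is_identity(self):
        aggs = [_agg(n) for n in (1, 5, 100)]
        assert filter_min_area(aggs, 0.0) == aggs

    def test_matches_brute_force_on_random_sizes(self):
        rng = np.random.default_rng(8)
        aggs = [_agg(int(n)) for n in rng.integers(1, 200, 50)]
        kept = filter_min_area(aggs, 500.0)
        brute = [a for a in aggs if a.n_pixels * 9.0 >= 500.0]
        assert kept == brute
        assert min_pixels_for_area(500.0, 9.0) == 56
        assert all(a.n_pixels >= 56 for a in kept)

    def test_retained_count_monotone_in_min_area(self):
        rng = np.random.default_rng(9)
        aggs = [_agg(int(n)) for n in rng.integers(1, 300, 80)]
        counts = [len(filter_min_area(aggs, m)) for m in (0, 100, 500, 1000, 5000)]
        totals = [sum(a.area for a in filter_min_area(aggs, m))
                  for m in (0, 100, 500, 1000, 5000)]
        assert counts == sorted(counts, reverse=True)
        assert totals == sorted(totals, reverse=True)


class TestPixelAreaRatio:
    def test_trivial_and_isotropic(self):
        assert pixel_area_ratio(100, 100.0) == pytest.approx(1.0)
        # 1536 x 496 px over 4.608 mm x 1.488 mm at 3 um pitch
        n = 1536 * 496
        area_um2 = 4608.0 * 1488.0
        assert pixel_area_ratio(n, area_um2) == pytest.approx(9.0)

    def test_printed_device_calibration(self):
        # 2906 mm^2 over 761,856 px; the published constant rounds to 3815
        ratio = pixel_area_ratio(761_856, 2906e6)
        assert ratio == pytest.approx(2906e6 / 761_856, rel=1e-12)
        assert abs(ratio - 3815.0) < 1.0

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            pixel_area_ratio(0, 100.0)
        with pytest.raises(ValueError):
            pixel_area_ratio(10, 0.0)


class TestSummaryAndVolume:
    def test_empty_summary(self):
        s = aggregate_metrics([[]])
        assert (s.count, s.total_area, s.mean_area) == (0, 0.0, 0.0)

    def test_two_aggregate_summary(self):
        s = aggregate_metrics([[_agg(1, 1000.0)], [_agg(1, 3000.0)]])
        assert s.count == 2
        assert s.total_area == pytest.approx(4000.0)
        assert s.mean_area == pytest.approx(2000.0)

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(10)
        per_scan = [[_agg(int(n), scan=i) for n in rng.integers(56, 400, 10)]
                    for i in range(20)]
        s = aggregate_metrics(per_scan)
        flat = [a for scan in per_scan for a in scan]
        assert s.count == len(flat)
        assert s.total_area == pytest.approx(sum(a.area for a in flat))
        assert s.mean_area == pytest.approx(s.total_area / s.count)
        # conservation: total area = pixel_area * sum of pixel counts
        assert s.total_area == pytest.approx(
            9.0 * sum(a.n_pixels for a in flat))

    def _session(self, n_scans=3, shape=(32, 32)):
        grids = [IntensityGrid(np.ones(shape)) for _ in range(n_scans)]
        return ScanSession(eye_id="x", bscans=grids)

    def test_empty_volume_all_false(self):
        s = self._session()
        vol = reconstruct_volume(s, [[], [], []])
        assert vol.shape == (3, 32, 32)
        assert not vol.any()

    def test_single_aggregate_on_its_page(self):
        s = self._session()
        coords = np.array([[5, c] for c in range(10)])
        agg = Aggregate(coords, 10, 90.0, (5.0, 4.5), 100.0, bscan_index=1)
        vol = reconstruct_volume(s, [[], [agg], []])
        assert int(vol.sum()) == 10
        assert int(vol[1].sum()) == 10

    def test_voxel_conservation(self):
        rng = np.random.default_rng(11)
        s = self._session(4)
        per_scan = []
        total = 0
        for i in range(4):
            aggs = []
            for _ in range(3):
                n = int(rng.integers(2, 10))
                rs = rng.integers(0, 32, n)
                cs = rng.integers(0, 32, n)
                coords = np.unique(np.column_stack([rs, cs]), axis=0)
                aggs.append(Aggregate(coords, len(coords), len(coords) * 9.0,
                                      (0.0, 0.0), 1.0, bscan_index=i))
                total += len(coords)
            per_scan.append(aggs)
        vol = reconstruct_volume(s, per_scan)
        # unique voxels may overlap across aggregates of the same scan
        assert int(vol.sum()) <= total
        assert int(vol.sum()) >= max(len(a.pixel_coords)
                                     for scan in per_scan for a in scan)

    def test_geometry_mismatch(self):
        s = self._session()
        with pytest.raises(GeometryMismatchError):
            reconstruct_volume(s, [[], []])

    def test_volume_tiff_export_round_trip(self, tmp_path):
        import tifffile

        from octquant import export_volume

        s = self._session()
        coords = np.array([[3, 3], [3, 4], [4, 3]])
        agg = Aggregate(coords, 3, 27.0, (3.3, 3.3), 1.0, bscan_index=2)
        vol = reconstruct_volume(s, [[], [], [agg]])
        p = export_volume(vol, tmp_path / "vol.tif")
        back = tifffile.imread(p)
        assert back.shape == vol.shape
        np.testing.assert_array_equal(back > 0, vol)
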