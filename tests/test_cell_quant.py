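"""Segmentation and per-cell quantification closure against planted truth."""

import numpy as np
import pytest

from elasuite.cell_quant import (
    detect_maxima,
    map_to_cell_frame,
    per_cell_intensity,
    segment_cells,
    spots_per_cell,
    spots_to_frame,
)
from elasuite.synth_images import Cell, CellScene, Spot, random_rod_scene, render_cells


def polar_spot_cells(n, amplitude=500.0, tip=False):
    """Grid of rods with two spots at opposite poles (deterministic)."""
    rng = np.random.default_rng(77)
    cells = []
    side = int(np.ceil(np.sqrt(n)))
    for k in range(n):
        i, j = divmod(k, side)
        L, W = 2.4, 0.8
        d = L / 2 - 0.1 if tip else (L - W) / 2
        ang = rng.uniform(0, np.pi)
        cells.append(Cell((3.0 + j * 6.0, 3.0 + i * 6.0), ang, L, W, 100.0,
                          spots=(Spot(-d, 0, amplitude), Spot(d, 0, amplitude))))
    return tuple(cells)


@pytest.fixture(scope="module")
def spot_scene():
    scene = CellScene(shape=(512, 512), cells=polar_spot_cells(16),
                      gaussian_noise=2.0, poisson=True, seed=5)
    img, truth = render_cells(scene)
    mask, records = segment_cells(img)
    return img, truth, mask, records


class TestSegmentCells:
    def test_count_and_iou_against_truth(self, spot_scene):
        img, truth, mask, records = spot_scene
        assert len(records) == 16
        for i in range(1, 17):
            tm = truth.label_image == i
            lab = np.bincount(mask[tm].ravel()).argmax()
            sm = mask == lab
            iou = (tm & sm).sum() / (tm | sm).sum()
            assert iou >= 0.9

    def test_touching_cells_split_in_two(self):
        cells = (Cell((4.0, 5.0), 0.0, 2.4, 0.8, 100.0),
                 Cell((6.5, 5.0), 0.0, 2.4, 0.8, 100.0))  # tips ~0.1 um apart
        scene = CellScene(shape=(256, 256), cells=cells, gaussian_noise=1.0,
                          poisson=True, seed=1)
        img, _ = render_cells(scene)
        _, records = segment_cells(img)
        assert len(records) == 2

    def test_blank_image_yields_no_cells(self):
        mask, records = segment_cells(np.zeros((64, 64)))
        assert records == [] and mask.sum() == 0

    def test_labels_ordered_row_major(self, spot_scene):
        _, _, _, records = spot_scene
        ys = [r.centroid[1] for r in records]
        assert ys == sorted(ys) or all(
            y2 > y1 - 1e-6 for y1, y2 in zip(ys, ys[1:]))


class TestPerCellIntensity:
    def test_noise_free_closure_within_one_percent(self):
        scene = CellScene(shape=(256, 256), background=5.0, psf_sigma=0.0,
                          cells=(Cell((4.0, 4.0), 0.4, 2.4, 0.8, 100.0),))
        img, truth = render_cells(scene)
        df = per_cell_intensity(truth.label_image, img)
        assert df.mean_rfu.iloc[0] == pytest.approx(100.0, rel=0.01)

    def test_reduced_uptake_ratio_recovered(self):
        """Halving the planted cytoplasmic signal (protonophore-style
        reduced uptake) halves the measured per-cell mean."""
        def measure(intensity, seed):
            scene = random_rod_scene(8, seed=seed, shape=(384, 384),
                                     cyt_intensity=intensity)
            img, truth = render_cells(scene)
            df = per_cell_intensity(truth.label_image, img)
            return df.mean_rfu.mean()
        ratio = measure(50.0, 31) / measure(100.0, 31)
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_blank_cell_clamped_at_zero(self):
        img = np.zeros((32, 32))
        mask = np.zeros((32, 32), dtype=int)
        mask[10:20, 10:20] = 1
        df = per_cell_intensity(mask, img)
        assert df.mean_rfu.iloc[0] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_cell_intensity(np.zeros((4, 4), int), np.zeros((5, 5)))


class TestDetectMaxima:
    def test_uniform_cells_have_no_spots(self):
        scene = random_rod_scene(6, seed=41, shape=(384, 384))
        img, _ = render_cells(scene)
        mask, records = segment_cells(img)
        assert detect_maxima(img, mask) == []

    def test_exact_recovery_at_5x_amplitude(self, spot_scene):
        img, truth, mask, records = spot_scene
        spots = detect_maxima(img, mask)
        mean_spots, _ = spots_per_cell(spots, records)
        assert mean_spots == pytest.approx(2.0)

    def test_positions_within_two_px(self, spot_scene):
        img, truth, mask, _ = spot_scene
        spots = detect_maxima(img, mask)
        planted = np.array([p for percell in truth.spot_positions_px for p in percell])
        for s in spots:
            dist = np.hypot(planted[:, 0] - s.x, planted[:, 1] - s.y).min()
            assert dist <= 2.0

    def test_monotone_in_prominence_threshold(self, spot_scene):
        img, _, mask, _ = spot_scene
        counts = [len(detect_maxima(img, mask, min_prominence=p))
                  for p in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_subthreshold_amplitude_gives_no_spots(self):
        scene = CellScene(shape=(256, 256), cells=polar_spot_cells(4, amplitude=20.0),
                          gaussian_noise=2.0, poisson=True, seed=6)
        img, _ = render_cells(scene)
        mask, _ = segment_cells(img)
        assert detect_maxima(img, mask) == []

    def test_invalid_prominence_rejected(self, spot_scene):
        img, _, mask, _ = spot_scene
        with pytest.raises(ValueError):
            detect_maxima(img, mask, min_prominence=0.0)


class TestCellFrame:
    def test_spot_at_centroid_maps_to_origin(self, spot_scene):
        _, _, _, records = spot_scene
        from elasuite.cell_quant import SpotCall
        rec = records[0]
        s = SpotCall(x=rec.centroid[0], y=rec.centroid[1], intensity=1.0,
                     prominence=1.0, cell_id=rec.cell_id)
        map_to_cell_frame([s], records)
        assert abs(s.dlong) < 1e-9 and abs(s.dtrans) < 1e-9
        assert s.folded_long == 0.0

    def test_pole_tip_spot_near_half_length(self):
        cells = polar_spot_cells(4, tip=True)
        scene = CellScene(shape=(256, 256), cells=cells, gaussian_noise=2.0,
                          poisson=True, seed=7)
        img, _ = render_cells(scene)
        mask, records = segment_cells(img)
        spots = map_to_cell_frame(detect_maxima(img, mask), records)
        assert spots
        for s in spots:
            assert abs(s.dlong) == pytest.approx(2.4 / 2, abs=0.2)  # +- PSF

    def test_polar_bias_recovered_within_5_percent(self):
        planted = 0.8
        scene = random_rod_scene(24, seed=51, shape=(768, 768), spots_per_cell=2,
                                 polar_fraction=planted)
        img, truth = render_cells(scene)
        mask, records = segment_cells(img)
        spots = map_to_cell_frame(detect_maxima(img, mask), records)
        # planted polar spots sit beyond 80% of the centreline half-length;
        # measured folded coordinates are |dlong| / (L/2) with L the full
        # length, so the same cut in measured units is 0.8*(L-W)/L ~ 0.53
        measured = np.array([s.folded_long for s in spots])
        frac = (measured > 0.53).mean()
        n = len(spots)
        tol = 0.05 + 2 * np.sqrt(planted * (1 - planted) / n)
        assert frac == pytest.approx(planted, abs=tol)

    def test_unknown_cell_rejected(self, spot_scene):
        from elasuite.cell_quant import SpotCall
        with pytest.raises(ValueError):
            map_to_cell_frame([SpotCall(0, 0, 1, 1, cell_id=999)], [])


class TestSpotsPerCell:
    def test_exact_two_per_cell(self, spot_scene):
        img, _, mask, records = spot_scene
        spots = detect_maxima(img, mask)
        mean, df = spots_per_cell(spots, records)
        assert mean == 2.0
        assert set(df.spots) == {2}

    def test_empty_scene_zero(self):
        assert spots_per_cell([], [])[0] == 0.0

    def test_poisson_planted_rate_recovered(self):
        rng = np.random.default_rng(61)
        lam = 1.5
        counts = rng.poisson(lam, 200)
        cells, k = [], 0
        side = 15
        for idx, c in enumerate(counts):
            i, j = divmod(idx, side)
            spots = tuple(Spot(dlong, 0.0, 500.0) for dlong in
                          np.linspace(-0.7, 0.7, c)) if c else ()
            cells.append(Cell((2.5 + j * 4.2, 2.5 + i * 4.2), 0.0, 2.4, 0.8,
                              100.0, spots=spots))
        scene = CellScene(shape=(1300, 1300), cells=tuple(cells),
                          gaussian_noise=2.0, poisson=True, seed=62)
        img, truth = render_cells(scene)
        mask, records = segment_cells(img)
        assert len(records) == 200
        spots = detect_maxima(img, mask)
        mean, _ = spots_per_cell(spots, records)
        assert mean == pytest.approx(counts.mean(), abs=0.25)

    def test_spot_table_columns(self, spot_scene):
        img, _, mask, records = spot_scene
        spots = map_to_cell_frame(detect_maxima(img, mask), records)
        df = spots_to_frame(spots)
        assert {"cell_id", "x_px", "dlong_um", "folded_long"} <= set(df.columns)
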