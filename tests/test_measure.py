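import math

import numpy as np
import pytest

import stomakit as sk
from stomakit.measure import gsmax_formula, round2
from stomakit.network import HeadOutputs
from stomakit.nn import Tensor


def brute_force_peaks(hm: np.ndarray) -> set[tuple[int, int]]:
    """A cell is a peak iff >= all 8 neighbours (independent oracle)."""
    h, w = hm.shape
    peaks = set()
    for y in range(h):
        for x in range(w):
            v = hm[y, x]
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and hm[yy, xx] > v:
                        ok = False
            if ok:
                peaks.add((x, y))
    return peaks


def _gauss(h, w, cy, cx, sigma=1.5, amp=0.9):
    ys, xs = np.mgrid[0:h, 0:w]
    return amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))


class TestExtractPeaks:
    def test_single_smooth_maximum(self):
        hm = np.clip(_gauss(21, 21, 10, 10), 1e-6, 1 - 1e-6)
        peaks = sk.extract_peaks(hm, top_k=100, score_threshold=0.3)
        assert [cell for cell, _ in peaks] == [(10, 10)]

    def test_uniform_plateau_ties_all_capped_at_top_k(self):
        hm = np.full((8, 8), 0.5)
        peaks = sk.extract_peaks(hm, top_k=10)
        assert len(peaks) == 10
        assert all(s == 0.5 for _, s in peaks)

    def test_two_gaussians_ten_cells_apart(self):
        hm = np.maximum(_gauss(16, 32, 8, 8), _gauss(16, 32, 8, 18))
        hm = np.clip(hm, 1e-6, 1 - 1e-6)
        peaks = sk.extract_peaks(hm, score_threshold=0.3)
        assert sorted(cell for cell, _ in peaks) == [(8, 8), (18, 8)]

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            hm = np.clip(rng.random((12, 12)), 1e-6, 1 - 1e-6)
            got = {cell for cell, _ in
                   sk.extract_peaks(hm, top_k=144, score_threshold=0.0)}
            assert got == brute_force_peaks(hm)

    def test_scores_sorted_descending(self, rng):
        hm = np.clip(rng.random((16, 16)), 1e-6, 1 - 1e-6)
        scores = [s for _, s in sk.extract_peaks(hm, top_k=5)]
        assert scores == sorted(scores, reverse=True)


def _heads_from_arrays(heat, size, offset, angle, stride=4):
    return HeadOutputs(Tensor(heat[None, None]), Tensor(size[None]),
                       Tensor(offset[None]), Tensor(angle[None, None]),
                       stride, (heat.shape[0] * stride, heat.shape[1] * stride))


class TestDecodeDetections:
    def test_offset_recovers_subcell_center(self):
        heat = np.full((16, 16), 1e-4, np.float32)
        heat[7, 10] = 0.9
        size = np.zeros((2, 16, 16), np.float32)
        size[:, 7, 10] = (16.0, 5.6)
        offset = np.zeros((2, 16, 16), np.float32)
        offset[:, 7, 10] = (0.3, 0.4)
        angle = np.full((16, 16), 30.0, np.float32)
        dets = sk.decode_detections(_heads_from_arrays(heat, size, offset,
                                                       angle))
        assert len(dets) == 1
        d = dets[0]
        assert d.box.cx == pytest.approx(41.2, abs=1e-5)
        assert d.box.cy == pytest.approx(29.6, abs=1e-5)
        assert d.box.length == pytest.approx(64.0, abs=1e-4)
        assert d.box.width == pytest.approx(22.4, abs=1e-4)
        assert d.box.angle_deg == pytest.approx(30.0)
        assert d.score == pytest.approx(0.9)

    def test_zero_offset_center_on_grid(self):
        heat = np.full((8, 8), 1e-4, np.float32)
        heat[2, 3] = 0.8
        size = np.full((2, 8, 8), 4.0, np.float32)
        offset = np.zeros((2, 8, 8), np.float32)
        angle = np.full((8, 8), 10.0, np.float32)
        det = sk.decode_detections(_heads_from_arrays(heat, size, offset,
                                                      angle))[0]
        assert (det.box.cx, det.box.cy) == (12.0, 8.0)

    def test_swapped_size_channels_canonicalized(self):
        heat = np.full((8, 8), 1e-4, np.float32)
        heat[4, 4] = 0.7
        size = np.zeros((2, 8, 8), np.float32)
        size[:, 4, 4] = (3.0, 9.0)  # predicted "length" < "width"
        offset = np.zeros((2, 8, 8), np.float32)
        angle = np.full((8, 8), 40.0, np.float32)
        det = sk.decode_detections(_heads_from_arrays(heat, size, offset,
                                                      angle))[0]
        assert det.box.length == pytest.approx(36.0)
        assert det.box.width == pytest.approx(12.0)
        assert det.box.angle_deg == pytest.approx(130.0)


class TestEncodeDecodeRoundTrip:
    def test_noiseless_targets_recover_annotations(self):
        sample = sk.generate_sample(sk.SynthConfig.test_scale(seed=21), 21)
        ann = sample.annotation_set()
        t = sk.encode_targets(ann, 4)
        hg, wg = t.heatmap_q.shape[1:]
        heat = np.clip(t.heatmap_q[0], 1e-4, 1 - 1e-4).astype(np.float32)
        size = np.zeros((2, hg, wg), np.float32)
        offset = np.zeros((2, hg, wg), np.float32)
        angle = np.zeros((hg, wg), np.float32)
        for j, (cx, cy) in enumerate(t.centers):
            size[:, cy, cx] = t.size[j]
            offset[:, cy, cx] = t.offset[j]
            angle[cy, cx] = t.angle[j]
        dets = sk.decode_detections(
            _heads_from_arrays(heat, size, offset, angle),
            score_threshold=0.9)
        assert len(dets) == len(ann.boxes)
        for d in dets:
            box = min(ann.boxes,
                      key=lambda b: math.hypot(b.cx - d.box.cx,
                                               b.cy - d.box.cy))
            assert math.hypot(box.cx - d.box.cx, box.cy - d.box.cy) <= 0.5
            assert abs(box.length - d.box.length) <= 0.5
            assert abs(box.width - d.box.width) <= 0.5
            assert abs(box.angle_deg - d.box.angle_deg) <= 0.5


class TestDensityAndConductance:
    @pytest.mark.parametrize("count, want", [(11, 42.22), (0, 0.0),
                                             (20, 76.76)])
    def test_density_production_frame(self, count, want):
        got = sk.stomatal_density(count, 1000, 667, 0.625)
        assert round2(got) == pytest.approx(want, abs=0.005)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            sk.stomatal_density(5, 0, 100, 0.625)

    @pytest.mark.parametrize("sl, want", [(2.0, math.pi), (0.0, 0.0),
                                          (40.17, 1267.3)])
    def test_alpha_max(self, sl, want):
        assert sk.alpha_max(sl) == pytest.approx(want, abs=0.05)

    def test_alpha_max_negative_rejected(self):
        with pytest.raises(ValueError):
            sk.alpha_max(-1.0)

    def test_gsmax_worked_examples(self):
        assert sk.gsmax(41.93, 13.23, 42.22) == pytest.approx(1.40, abs=0.005)
        assert sk.gsmax(42.09, 14.35, 53.74) == pytest.approx(1.75327,
                                                              abs=2e-5)
        assert sk.gsmax(10.0, 5.0, 0.0) == 0.0
        assert sk.gsmax(0.0, 0.0, 50.0) == 0.0  # defined limit, not an error

    def test_gsmax_monotonicity_grids(self):
        sls = np.linspace(20, 60, 9)
        gs = [sk.gsmax(sl, 14.0, 50.0) for sl in sls]
        assert all(a < b for a, b in zip(gs, gs[1:]))
        sds = np.linspace(10, 80, 8)
        gd = [sk.gsmax(40.0, 14.0, sd) for sd in sds]
        assert all(a < b for a, b in zip(gd, gd[1:]))
        ls = np.linspace(8, 24, 9)
        gl = [sk.gsmax(40.0, l, 50.0) for l in ls]
        assert all(a > b for a, b in zip(gl, gl[1:]))

    def test_formula_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sk.gsmax(-1.0, 10.0, 50.0)


class TestMeasureImage:
    def test_empty_detections(self):
        rec = sk.measure_image([], 1000, 667, 0.625)
        assert rec.count == 0
        assert rec.density_per_mm2 == 0.0
        assert rec.gsmax_mol_m2_s == 0.0

    def test_table_row_means_reproduce_conductance(self):
        # 9 boxes with mean traits (46.04, 17.01) µm in the full frame
        boxes = [sk.RotatedBox(100 + 80 * i, 300, 46.04 / 0.625,
                               17.01 / 0.625, 20.0) for i in range(9)]
        dets = [sk.Detection(b, 0.9) for b in boxes]
        rec = sk.measure_image(dets, 1000, 667, 0.625)
        assert rec.count == 9
        assert rec.density_per_mm2 == pytest.approx(34.54, abs=0.005)
        assert rec.gsmax_mol_m2_s == pytest.approx(1.20, abs=0.005)

    def test_unit_conversion_single_detection(self):
        det = sk.Detection(sk.RotatedBox(50, 50, 64.0, 22.4, 10), 0.8)
        rec = sk.measure_image([det], 256, 256, 0.625)
        assert rec.lengths_um[0] == pytest.approx(40.0)
        assert rec.widths_um[0] == pytest.approx(14.0)

    def test_traits_csv(self, tmp_path):
        det = sk.Detection(sk.RotatedBox(50, 50, 64.0, 22.4, 10), 0.8)
        rec = sk.measure_image([det], 256, 256, 0.625, image_id="img_0000")
        path = tmp_path / "traits.csv"
        sk.write_traits_csv([rec], path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == ("image_id,avg_length_um,avg_width_um,count,"
                            "density_per_mm2,gsmax")
        assert lines[1].startswith("img_0000,40.0,14.0,1,")


class TestRounding:
    def test_half_away_from_zero(self):
        assert round2(1.315) == 1.32
        assert round2(1.20218) == 1.20
        assert round2(-1.315) == -1.32
        assert round2(34.5443) == 34.54
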