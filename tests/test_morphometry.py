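import numpy as np
import pytest
from scipy import ndimage as ndi

import myoseg as ms
from myoseg.core import ValidationError
from myoseg.morphometry import (FiberRecord, FiberTable, filter_fibers,
                                measure_fibers, min_max_feret, summarize)


def brute_force_min_feret(points, step_deg=0.1):
    """Width minimized over a dense rotation sweep — independent oracle."""
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def _label_img(mask, res=1.0):
    return ms.LabelImage(labels=np.asarray(mask, dtype=int), resolution=res)


class TestMinMaxFeret:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((20, 30), dtype=int)
        mask[5:11, 4:24] = 1     # 6 x 20 px rectangle
        t = measure_fibers(_label_img(mask))
        r = t.records[0]
        assert r.min_feret_um == pytest.approx(6.0, abs=1e-9)
        assert r.max_feret_um == pytest.approx(np.hypot(6.0, 20.0), abs=1e-9)
        assert r.csa_um2 == pytest.approx(120.0)
        assert r.centroid_x_px == pytest.approx((4 + 23) / 2.0)
        assert r.centroid_y_px == pytest.approx((5 + 10) / 2.0)

    def test_discrete_disk(self):
        yy, xx = np.mgrid[0:41, 0:41]
        mask = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2).astype(int)
        t = measure_fibers(_label_img(mask))
        r = t.records[0]
        assert r.min_feret_um == pytest.approx(30.0, abs=1.0)
        assert r.max_feret_um == pytest.approx(30.0, abs=1.5)

    def test_single_pixel_width_one(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = 1
        r = measure_fibers(_label_img(mask)).records[0]
        assert r.min_feret_um == pytest.approx(1.0, abs=1e-9)

    def test_calipers_match_rotation_sweep_on_random_polygons(self):
        """Exact rotating calipers vs 0.1 deg brute-force on 100 hulls."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(4, 40))
            pts = rng.normal(size=(n, 2)) * rng.uniform(1, 50)
            mn, _ = min_max_feret(pts)
            ref = brute_force_min_feret(pts)
            if ref > 0:
                worst = max(worst, abs(mn - ref) / ref)
        assert worst < 0.005

    def test_feret_rotation_robustness(self):
        """Rotating a fiber-sized blob 17 deg changes min Feret < 2%."""
        yy, xx = np.mgrid[0:81, 0:81]
        mask = (((yy - 40) / 30.0) ** 2 + ((xx - 40) / 18.0) ** 2 <= 1).astype(float)
        rot = ndi.rotate(mask, 17.0, reshape=True, order=0)
        m0 = measure_fibers(_label_img(mask.astype(int))).records[0].min_feret_um
        m1 = measure_fibers(_label_img(rot.astype(int))).records[0].min_feret_um
        assert abs(m1 - m0) / m0 < 0.02


class TestMeasureFibers:
    def test_no_labels_error(self):
        with pytest.raises(ValidationError):
            measure_fibers(_label_img(np.zeros((5, 5))))

    def test_touches_edge_flag(self):
        lab = np.zeros((10, 10), dtype=int)
        lab[0:3, 0:3] = 1       # touches border
        lab[5:8, 5:8] = 2       # interior
        t = measure_fibers(_label_img(lab))
        assert t.records[0].touches_edge
        assert not t.records[1].touches_edge

    def test_roi_mask_edge(self):
        lab = np.zeros((10, 10), dtype=int)
        lab[4:7, 2:5] = 1
        mask = np.ones((10, 10), dtype=bool)
        mask[:, :2] = False     # fiber 1 is adjacent to the masked strip
        t = measure_fibers(_label_img(lab), roi_mask=mask)
        assert t.records[0].touches_edge

    def test_min_le_max_invariant(self):
        rng = np.random.default_rng(8)
        lab = np.zeros((60, 60), dtype=int)
        for i in range(1, 6):
            y, x = rng.integers(5, 45, 2)
            lab[y:y + rng.integers(3, 12), x:x + rng.integers(3, 12)] = i
        for r in measure_fibers(_label_img(lab)).records:
            assert r.min_feret_um <= r.max_feret_um + 1e-12

    def test_csa_partition_conservation(self, hex_phantom_small):
        spec, img, truth = hex_phantom_small
        lab = truth.labels.labels
        res = spec.resolution
        csa_sum = sum(r.csa_um2 for r in truth.records.records)
        zero_area = (lab == 0).sum() * res ** 2
        total = lab.size * res ** 2
        assert csa_sum + zero_area == pytest.approx(total, rel=1e-9)


class TestFilterFibers:
    def _table(self, csas, edges=None):
        edges = edges or [False] * len(csas)
        recs = tuple(FiberRecord(fiber_id=i + 1, csa_um2=c, min_feret_um=10.0,
                                 max_feret_um=12.0, centroid_x_px=0.0,
                                 centroid_y_px=0.0, touches_edge=e)
                     for i, (c, e) in enumerate(zip(csas, edges)))
        return FiberTable(records=recs, resolution=1.0)

    def test_hand_counts(self):
        t = filter_fibers(self._table([150.0, 500.0, 12000.0]), 200.0, 10000.0)
        assert t.n_kept == 1
        assert t.frac_below == pytest.approx(1.0 / 3.0)
        assert t.frac_above == pytest.approx(1.0 / 3.0)
        reasons = [r.excluded_reason for r in t.records]
        assert reasons == ["below_csa", None, "above_csa"]

    def test_all_kept(self):
        t = filter_fibers(self._table([300.0, 400.0]), 200.0, 10000.0)
        assert t.n_kept == t.n_detected == 2

    def test_edge_exclusion_toggle(self):
        t = self._table([500.0, 500.0], edges=[True, False])
        assert filter_fibers(t, exclude_edges=True).n_kept == 1
        assert filter_fibers(t, exclude_edges=False).n_kept == 2

    def test_widening_range_monotone(self):
        csas = list(np.random.default_rng(9).uniform(50, 15000, 30))
        t = self._table(csas)
        kept_narrow = filter_fibers(t, 500.0, 5000.0).n_kept
        kept_wide = filter_fibers(t, 200.0, 10000.0).n_kept
        assert kept_wide >= kept_narrow


class TestSummarize:
    def _kept(self, ferets):
        recs = tuple(FiberRecord(fiber_id=i + 1, csa_um2=500.0, min_feret_um=f,
                                 max_feret_um=f, centroid_x_px=0, centroid_y_px=0,
                                 touches_edge=False)
                     for i, f in enumerate(ferets))
        return FiberTable(records=recs, resolution=1.0)

    def test_mean_sd(self):
        s = summarize(self._kept([40.0, 50.0, 60.0]))
        assert s["mean_min_feret_um"] == pytest.approx(50.0)
        assert s["sd_min_feret_um"] == pytest.approx(10.0)

    def test_single_fiber_sd_undefined(self):
        s = summarize(self._kept([42.0]))
        assert s["sd_min_feret_um"] is None

    def test_histogram_counts_sum(self):
        vals = list(np.random.default_rng(10).uniform(20, 80, 57))
        s = summarize(self._kept(vals), bin_width_um=5.0)
        assert sum(s["histogram"]["count"]) == 57

    def test_zero_kept_warns_not_crashes(self):
        s = summarize(FiberTable(records=(), resolution=1.0))
        assert s["mean_min_feret_um"] is None
        assert "warning" in s
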