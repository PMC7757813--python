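import json

import numpy as np
import pytest
import tifffile

import myoseg as ms
from myoseg.core import ValidationError, odd_kernel_px
from myoseg.morphometry import FiberRecord, FiberTable


class TestUmToPx:
    @pytest.mark.parametrize("um,res,expected", [
        (45.0, 0.462, 45.0 / 0.462),     # default median kernel at scanner res
        (6.0, 0.368, 6.0 / 0.368),       # line width at camera res
        (0.0, 0.5, 0.0),
    ])
    def test_hand_arithmetic(self, um, res, expected):
        assert ms.um_to_px(um, res) == pytest.approx(expected, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0, 100, 2)
            r = rng.uniform(0.1, 2.0)
            assert ms.um_to_px(a + b, r) == pytest.approx(
                ms.um_to_px(a, r) + ms.um_to_px(b, r), rel=1e-12)

    def test_invalid_resolution(self):
        with pytest.raises(ValidationError):
            ms.um_to_px(10.0, 0.0)
        with pytest.raises(ValidationError):
            ms.um_to_px(10.0, -1.0)


class TestOddKernel:
    def test_forced_odd(self):
        # 45/0.462 = 97.4 -> 97 (already odd)
        assert odd_kernel_px(45.0, 0.462) == 97
        # 46/1.0 = 46 -> even, bumped to 47
        assert odd_kernel_px(46.0, 1.0) == 47

    def test_minimum_one(self):
        assert odd_kernel_px(0.1, 1.0) == 1


class TestRasterImage:
    def test_degenerate_single_pixel(self):
        img = ms.RasterImage(pixels=np.zeros((1, 1)), resolution=1.0)
        assert img.height == img.width == 1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            ms.RasterImage(pixels=np.zeros((2, 2)), resolution=0.0)
        with pytest.raises(ValidationError):
            ms.RasterImage(pixels=np.zeros((2, 2, 3)), resolution=1.0)


class TestReadImage:
    def test_16bit_tiff_roundtrip(self, tmp_path):
        arr = np.arange(12, dtype=np.uint16).reshape(3, 4) * 5000
        p = tmp_path / "img.tif"
        tifffile.imwrite(p, arr)
        img = ms.read_image(p, resolution=0.462)
        assert img.pixels.dtype == np.uint16
        assert img.pixels.max() <= 65535
        np.testing.assert_array_equal(img.pixels, arr)
        assert img.resolution == 0.462

    def test_rgb_channel_selection(self, tmp_path):
        import imageio.v3 as iio
        rgb = np.zeros((5, 6, 3), dtype=np.uint8)
        rgb[..., 0] = np.arange(30).reshape(5, 6)
        p = tmp_path / "img.png"
        iio.imwrite(p, rgb)
        img = ms.read_image(p, resolution=1.0, channel=0)
        np.testing.assert_array_equal(img.pixels, iio.imread(p)[..., 0])

    def test_channel_errors(self, tmp_path):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        p = tmp_path / "img.tif"
        tifffile.imwrite(p, rgb)
        with pytest.raises(ValidationError):
            ms.read_image(p, resolution=1.0, channel=7)
        with pytest.raises(ValidationError):
            ms.read_image(p, resolution=1.0)   # needs explicit channel

    def test_missing_file(self, tmp_path):
        with pytest.raises((FileNotFoundError, OSError)):
            ms.read_image(tmp_path / "nope.tif", resolution=1.0)


def _toy_table(ferets, resolution=1.0):
    recs = tuple(
        FiberRecord(fiber_id=i + 1, csa_um2=500.0, min_feret_um=f,
                    max_feret_um=f + 5, centroid_x_px=10.0 * i,
                    centroid_y_px=5.0, touches_edge=False)
        for i, f in enumerate(ferets))
    return FiberTable(records=recs, resolution=resolution)


class TestWriteResults:
    def test_empty_table(self, tmp_path):
        labels = ms.LabelImage(labels=np.zeros((4, 4), dtype=int), resolution=1.0)
        table = FiberTable(records=(), resolution=1.0)
        paths = ms.write_results(labels, table, {"n_kept": 0}, tmp_path)
        lines = paths["fibers"].read_text().strip().splitlines()
        assert len(lines) == 1  # header only
        assert json.loads(paths["summary"].read_text())["n_kept"] == 0

    def test_three_fiber_table_and_label_roundtrip(self, tmp_path):
        table = _toy_table([40.0, 50.0, 60.0])
        lab = np.zeros((6, 6), dtype=int)
        lab[0, :3] = 1; lab[2, :3] = 2; lab[4, :3] = 3
        labels = ms.LabelImage(labels=lab, resolution=1.0)
        summary = {"mean_min_feret_um": float(np.mean([40.0, 50.0, 60.0]))}
        paths = ms.write_results(labels, table, summary, tmp_path)
        df_lines = paths["fibers"].read_text().strip().splitlines()
        assert len(df_lines) == 4
        assert json.loads(paths["summary"].read_text())["mean_min_feret_um"] == 50.0
        # written label image re-reads bit-exactly
        back = tifffile.imread(paths["labels"])
        np.testing.assert_array_equal(back, lab.astype(np.uint16))


class TestPipelineConfig:
    def test_defaults_valid(self):
        cfg = ms.PipelineConfig()
        assert cfg.median_kernel_um == 45.0
        assert cfg.seed_threshold == 70.0

    @pytest.mark.parametrize("kw", [
        {"csa_min_um2": 500.0, "csa_max_um2": 300.0},
        {"seed_threshold": 0.0},
        {"seed_threshold": 255.0},
        {"boost_exponent": 0.5},
        {"pm_timestep": 0.3},
        {"median_kernel_um": -1.0},
    ])
    def test_rejects_invalid(self, kw):
        with pytest.raises(ValidationError):
            ms.PipelineConfig(**kw)

    def test_dict_roundtrip(self):
        cfg = ms.PipelineConfig(line_width_um=8.0)
        assert ms.PipelineConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValidationError):
            ms.PipelineConfig.from_dict({"no_such_key": 1})
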