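import numpy as np
import pytest
import tifffile

from hrfcount import BScanImage, crop_central, image_mean, load_bscan, to_8bit


class TestTo8Bit:
    def test_8bit_passthrough(self, rng):
        img = rng.integers(0, 256, (16, 16))
        assert np.array_equal(to_8bit(img, 8), img)

    @pytest.mark.parametrize("value,expected", [
        (0, 0), (256, 1), (32768, 128), (65535, 255),
    ])
    def test_16bit_exact_rational_map(self, value, expected):
        # round-half-up of v*255/65535, checked by integer arithmetic
        assert to_8bit(np.array([[value]]), 16)[0, 0] == expected
        assert (value * 255 * 2 + 65535) // (2 * 65535) == expected

    def test_16bit_monotone_and_endpoint_surjective(self):
        v = np.arange(0, 65536, 17, dtype=np.uint16)[None, :]
        out = to_8bit(v, 16)[0]
        assert (np.diff(out.astype(int)) >= 0).all()
        assert to_8bit(np.array([[0]]), 16) == 0
        assert to_8bit(np.array([[65535]]), 16) == 255

    def test_float_requires_declared_range(self):
        with pytest.raises(ValueError, match="range"):
            to_8bit(np.array([[0.5]]), "float")

    def test_float_with_range(self):
        out = to_8bit(np.array([[0.0, 0.5, 1.0]]), (0.0, 1.0))
        assert out.tolist() == [[0, 128, 255]]


class TestLoadBScan:
    def test_8bit_png_identity(self, tmp_path, rng):
        import imageio.v3 as iio
        img = rng.integers(0, 256, (32, 40), dtype=np.uint8)
        path = tmp_path / "scan.png"
        iio.imwrite(path, img)
        scan = load_bscan(path, 10.0, 4.0, 20)
        assert np.array_equal(scan.pixels, img)
        assert scan.fovea_col == 20

    def test_16bit_tiff_scaled(self, tmp_path):
        raw = np.array([[0, 32768, 65535]], dtype=np.uint16)
        path = tmp_path / "scan16.tif"
        tifffile.imwrite(path, raw)
        scan = load_bscan(path, 10.0, 4.0, 1)
        assert scan.pixels.tolist() == [[0, 128, 255]]

    def test_multiframe_stack_rejected(self, tmp_path, rng):
        stack = rng.integers(0, 256, (3, 16, 16), dtype=np.uint8)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, stack, photometric="minisblack")
        with pytest.raises(ValueError, match="3 frames"):
            load_bscan(path, 10.0, 4.0, 8)

    def test_missing_file(self, tmp_path):
        with pytest.raises((IOError, FileNotFoundError)):
            load_bscan(tmp_path / "nope.png", 10.0, 4.0, 0)


class TestBScanImageInvariants:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            BScanImage(np.array([[300]]), 10.0, 4.0, 0)

    def test_rejects_bad_fovea(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        with pytest.raises(ValueError, match="fovea"):
            BScanImage(img, 10.0, 4.0, 8)

    def test_rejects_nonpositive_scale(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        with pytest.raises(ValueError, match="scale"):
            BScanImage(img, 0.0, 4.0, 2)


class TestCropCentral:
    def _scan(self, width=880, fovea=440, lateral=10.0):
        img = np.tile((np.arange(width) % 256).astype(np.uint8), (20, 1))
        return BScanImage(img, lateral, 4.0, fovea)

    def test_index_arithmetic(self):
        scan = self._scan()
        out = crop_central(scan, 1500)
        # 1500 um at 10 um/px -> 150 px half-width, columns [290, 590)
        assert out.pixels.shape == (20, 300)
        assert np.array_equal(out.pixels, scan.pixels[:, 290:590])
        assert out.fovea_col == 150

    def test_width_is_twice_halfwidth_rounded(self):
        scan = self._scan(lateral=11.0)
        out = crop_central(scan, 1500)   # 1500/11 = 136.36 -> 136
        assert out.pixels.shape[1] == 2 * 136

    def test_idempotent_at_same_halfwidth(self):
        once = crop_central(self._scan(), 1500)
        twice = crop_central(once, 1500)
        assert np.array_equal(once.pixels, twice.pixels)
        assert once.fovea_col == twice.fovea_col

    def test_zero_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            crop_central(self._scan(), 0)

    def test_missing_margin_reported_in_um(self):
        scan = self._scan(width=200, fovea=50)
        with pytest.raises(ValueError, match="margin.*um"):
            crop_central(scan, 1500)


class TestImageMean:
    def test_hand_examples(self):
        assert image_mean(np.full((5, 5), 37)) == 37.0
        assert image_mean(np.array([[0, 0], [255, 255]])) == 127.5

    def test_matches_bruteforce_sum(self, rng):
        img = rng.integers(0, 256, (16, 16))
        total = sum(int(v) for v in img.ravel())
        assert image_mean(img) == pytest.approx(total / 256, abs=1e-12)

    def test_permutation_invariant(self, rng):
        img = rng.integers(0, 256, (12, 12))
        shuffled = rng.permutation(img.ravel()).reshape(img.shape)
        assert image_mean(img) == image_mean(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            image_mean(np.empty((0, 4)))
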