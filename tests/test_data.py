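"""Colorization, color assignment and IDX loading."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

import psmdim as p
from psmdim.data import DatasetConsistencyError, IdxFormatError


def _gray(pixels, label=0):
    return p.GrayscaleDigitImage(np.asarray(pixels, dtype=float), label)


class TestColorize:
    def test_background_stays_white(self):
        img = _gray(np.zeros((28, 28)))
        out = p.colorize(img, (1.0, 0.0, 0.0))
        assert np.all(out.pixels == 1.0)

    def test_full_ink_takes_pure_color(self):
        img = _gray(np.ones((28, 28)), label=3)
        out = p.colorize(img, (1.0, 0.0, 0.0))
        assert np.all(out.pixels == np.array([1.0, 0.0, 0.0]))
        assert out.label == 3

    def test_half_ink_blends_halfway(self):
        img = _gray(np.full((28, 28), 0.5))
        out = p.colorize(img, (1.0, 0.0, 0.0))
        assert np.allclose(out.pixels, np.array([1.0, 0.5, 0.5]))

    def test_non_palette_color_rejected(self):
        with pytest.raises(ValueError, match="palette"):
            p.colorize(_gray(np.zeros((28, 28))), (0.5, 0.5, 0.5))

    @settings(deadline=None, max_examples=25)
    @given(
        g=st.floats(0.0, 1.0),
        color_id=st.integers(0, 5),
        row=st.integers(0, 27),
        col=st.integers(0, 27),
    )
    def test_blend_formula_and_support(self, g, color_id, row, col):
        """channel = (1-g) + g*color, so ink support is exactly preserved."""
        pixels = np.zeros((28, 28))
        pixels[row, col] = g
        out = p.colorize(_gray(pixels), p.PALETTE[color_id])
        expected = (1.0 - g) + g * p.PALETTE[color_id]
        assert np.allclose(out.pixels[row, col], expected)
        # pixels without ink are pure white; ink pixels deviate iff g > 0
        mask = pixels > 0
        assert np.all(out.pixels[~mask] == 1.0)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestAssignColor:
    @pytest.mark.parametrize(
        "label,color_name", [(0, "red"), (1, "red"), (2, "cyan"), (5, "green"),
                             (7, "magenta"), (9, "yellow")]
    )
    def test_fixed_mode_uses_digit_map(self, label, color_name):
        out = p.assign_color(
            _gray(np.ones((28, 28)), label), p.ColorAssignment("FC")
        )
        assert p.PALETTE_NAMES[out.color_id] == color_name

    def test_random_mode_requires_rng(self):
        with pytest.raises(ValueError, match="random generator"):
            p.assign_color(_gray(np.zeros((28, 28))), p.ColorAssignment("RC"))

    def test_random_mode_frequencies_near_uniform(self):
        """Each of the 6 colors is drawn at a rate within 3 binomial sd of 1/6."""
        big = p.GrayDataset(
            np.zeros((6000, 28, 28)), np.tile(np.arange(10), 600)
        )
        ds = p.build_dataset(big, p.ColorAssignment("RC"), seed=42)
        counts = np.bincount(ds.color_ids, minlength=6)
        n = len(ds)
        sd = np.sqrt(n * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - n / 6) <= 3 * sd)
        assert np.all(counts > 0)  # all six palette colors occur


class TestBuildDataset:
    def test_deterministic_given_seed(self, glyph_data):
        sub = glyph_data.subset(np.arange(50))
        a = p.build_dataset(sub, p.ColorAssignment("RC"), seed=9)
        b = p.build_dataset(sub, p.ColorAssignment("RC"), seed=9)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.color_ids, b.color_ids)

    def test_fixed_mode_color_is_function_of_label(self, glyph_data):
        ds = p.build_dataset(glyph_data, p.ColorAssignment("FC"), seed=0)
        for digit in range(10):
            ids = np.unique(ds.color_ids[ds.labels == digit])
            assert ids.size == 1
        # exactly 5 of the 6 palette colors occur; blue (id 2) never does
        assert set(np.unique(ds.color_ids)) == {0, 1, 3, 4, 5}

    def test_matches_single_image_assignment(self, glyph_data):
        sub = glyph_data.subset(np.arange(8))
        ds = p.build_dataset(sub, p.ColorAssignment("RC"), seed=13)
        rng = np.random.default_rng(13)
        for i in range(8):
            single = p.assign_color(sub[i], p.ColorAssignment("RC"), rng)
            assert single.color_id == ds.color_ids[i]
            assert np.allclose(single.pixels, ds.images[i])

    def test_label_color_mutual_information_near_zero(self):
        """In RC mode color carries no label information (plug-in MI ~ 0)."""
        big = p.GrayDataset(np.zeros((6000, 28, 28)), np.tile(np.arange(10), 600))
        ds = p.build_dataset(big, p.ColorAssignment("RC"), seed=21)
        mi = mutual_info_score(ds.labels, ds.color_ids)
        assert mi < 0.02  # plug-in bias bound ~ (10-1)(6-1)/(2n) nats

    def test_png_round_trip_preserves_channels(self, glyph_data, tmp_path):
        from PIL import Image

        ds = p.build_dataset(glyph_data.subset(np.arange(1)),
                             p.ColorAssignment("RC"), seed=2)
        path = tmp_path / "img.png"
        p.data.save_png(ds[0], path)
        back = np.asarray(Image.open(path), dtype=float) / 255.0
        assert np.abs(back - ds.images[0]).max() <= 0.5 / 255.0 + 1e-9


def _idx_bytes(images: np.ndarray, labels: np.ndarray,
               img_magic=0x803, lab_magic=0x801):
    n, r, c = images.shape
    img = struct.pack(">iiii", img_magic, n, r, c) + images.astype(np.uint8).tobytes()
    lab = struct.pack(">ii", lab_magic, labels.size) + labels.astype(np.uint8).tobytes()
    return img, lab


class TestLoadMnistIdx:
    def _write(self, tmp_path, img, lab):
        ip, lp = tmp_path / "imgs", tmp_path / "labs"
        ip.write_bytes(img)
        lp.write_bytes(lab)
        return ip, lp

    def test_reads_values_scaled_to_unit_interval(self, tmp_path):
        rng = np.random.default_rng(0)
        images = rng.integers(0, 256, size=(3, 28, 28))
        labels = np.array([4, 0, 9])
        ds = p.load_mnist_idx(*self._write(tmp_path, *_idx_bytes(images, labels)))
        assert len(ds) == 3
        assert np.allclose(ds.images, images / 255.0)
        assert np.array_equal(ds.labels, labels)

    def test_bad_magic_is_format_error(self, tmp_path):
        img, lab = _idx_bytes(np.zeros((2, 28, 28)), np.zeros(2), img_magic=0x700)
        with pytest.raises(IdxFormatError, match="magic"):
            p.load_mnist_idx(*self._write(tmp_path, img, lab))

    def test_truncated_payload_is_consistency_error(self, tmp_path):
        img, lab = _idx_bytes(np.zeros((2, 28, 28)), np.zeros(2))
        with pytest.raises(DatasetConsistencyError, match="payload"):
            p.load_mnist_idx(*self._write(tmp_path, img[:-10], lab))

    def test_count_mismatch_is_consistency_error(self, tmp_path):
        img, _ = _idx_bytes(np.zeros((2, 28, 28)), np.zeros(2))
        _, lab = _idx_bytes(np.zeros((3, 28, 28)), np.zeros(3))
        with pytest.raises(DatasetConsistencyError, match="labels"):
            p.load_mnist_idx(*self._write(tmp_path, img, lab))
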