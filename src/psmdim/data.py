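"""Colorized handwritten-digit datasets.

Greyscale 28x28 digit images (MNIST IDX files or the synthetic glyph
generator) are converted to RGB and assigned one of six saturated colors —
the RGB primaries (red, green, blue) and their complements (cyan, magenta,
yellow) — under one of two modes:

* **RC** (random color): the color of each image is drawn uniformly from the
  six-entry palette, independently of the digit.  Shape and color are
  orthogonal stimulus dimensions.
* **FC** (fixed color): the color is a deterministic function of the digit
  (0,1 -> red; 2,3 -> cyan; 4,5 -> green; 6,7 -> magenta; 8,9 -> yellow), so
  color is fully confounded with class and blue never occurs.

Ink convention: greyscale pixel values live in [0, 1] with 1 = full ink and
0 = background.  Colorization is a linear blend between the white background
and the assigned color, weighted by ink intensity ``g``::

    channel_c = (1 - g) * 1 + g * color_c

so anti-aliased grey levels become saturation levels of the assigned color
and the background stays white.  Note MNIST IDX files store ink as high byte
values; dividing by 255 therefore already yields this ink-on-white
convention once rendering maps 0 ink to white.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

IMAGE_SHAPE = (28, 28)
N_CLASSES = 10

#: Ordered six-color palette; ``color_id`` indexes this order.
PALETTE_NAMES: tuple[str, ...] = ("red", "green", "blue", "cyan", "magenta", "yellow")
PALETTE: np.ndarray = np.array(
    [
        (1.0, 0.0, 0.0),  # red
        (0.0, 1.0, 0.0),  # green
        (0.0, 0.0, 1.0),  # blue
        (0.0, 1.0, 1.0),  # cyan
        (1.0, 0.0, 1.0),  # magenta
        (1.0, 1.0, 0.0),  # yellow
    ]
)

#: Digit -> color_id map used in FC mode.  Blue (id 2) is never assigned.
FIXED_COLOR_MAP: dict[int, int] = {
    0: 0, 1: 0,   # red
    2: 3, 3: 3,   # cyan
    4: 1, 5: 1,   # green
    6: 4, 7: 4,   # magenta
    8: 5, 9: 5,   # yellow
}

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    """An IDX file does not have the expected magic number / header."""


class DatasetConsistencyError(ValueError):
    """Image and label records disagree, or a payload is truncated."""


@dataclass(frozen=True)
class GrayscaleDigitImage:
    """A single 28x28 ink-on-white greyscale digit."""

    pixels: np.ndarray  # (28, 28), values in [0, 1], 1 = full ink
    label: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.shape != IMAGE_SHAPE:
            raise ValueError(f"expected {IMAGE_SHAPE} pixels, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if not (0 <= int(self.label) < N_CLASSES):
            raise ValueError(f"label must be in 0..9, got {self.label}")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ColoredDigitImage:
    """A single 28x28x3 RGB digit with its palette color id."""

    pixels: np.ndarray  # (28, 28, 3), values in [0, 1]
    label: int
    color_id: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.shape != IMAGE_SHAPE + (3,):
            raise ValueError(f"expected {IMAGE_SHAPE + (3,)} pixels, got {px.shape}")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ColorAssignment:
    """Color assignment mode: RC (random) or FC (fixed digit->color)."""

    mode: str  # "RC" | "FC"
    fixed_map: Mapping[int, int] = field(default_factory=lambda: dict(FIXED_COLOR_MAP))

    def __post_init__(self) -> None:
        if self.mode not in ("RC", "FC"):
            raise ValueError(f"mode must be 'RC' or 'FC', got {self.mode!r}")
        if self.mode == "FC":
            if sorted(self.fixed_map) != list(range(N_CLASSES)):
                raise ValueError("FC mode requires a color for every digit 0..9")


@dataclass(frozen=True)
class GrayDataset:
    """Array-of-images container for greyscale digit sets."""

    images: np.ndarray  # (n, 28, 28) in [0, 1]
    labels: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        if self.images.ndim != 3 or self.images.shape[1:] != IMAGE_SHAPE:
            raise ValueError(f"images must be (n, 28, 28), got {self.images.shape}")
        if self.labels.shape != (self.images.shape[0],):
            raise DatasetConsistencyError(
                f"{self.images.shape[0]} images but {self.labels.shape[0]} labels"
            )

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, i: int) -> GrayscaleDigitImage:
        return GrayscaleDigitImage(self.images[i], int(self.labels[i]))

    def subset(self, idx: np.ndarray) -> "GrayDataset":
        return GrayDataset(self.images[idx], self.labels[idx])


@dataclass(frozen=True)
class ColorDataset:
    """Array-of-images container for colorized digit sets."""

    images: np.ndarray     # (n, 28, 28, 3) in [0, 1]
    labels: np.ndarray     # (n,) int
    color_ids: np.ndarray  # (n,) int, indexes PALETTE

    def __post_init__(self) -> None:
        n = self.images.shape[0]
        if self.images.ndim != 4 or self.images.shape[1:] != IMAGE_SHAPE + (3,):
            raise ValueError(f"images must be (n, 28, 28, 3), got {self.images.shape}")
        if self.labels.shape != (n,) or self.color_ids.shape != (n,):
            raise DatasetConsistencyError("images/labels/color_ids lengths disagree")

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, i: int) -> ColoredDigitImage:
        return ColoredDigitImage(self.images[i], int(self.labels[i]), int(self.color_ids[i]))

    def one_hot_labels(self) -> np.ndarray:
        """(n, 10) one-hot encoding of the digit labels."""
        out = np.zeros((len(self), N_CLASSES))
        out[np.arange(len(self)), self.labels] = 1.0
        return out


# ---------------------------------------------------------------------------
# IDX loading
# ---------------------------------------------------------------------------

def load_mnist_idx(images_path: str | Path, labels_path: str | Path) -> GrayDataset:
    """Read an MNIST-style IDX image/label file pair.

    Big-endian headers with magic numbers 2051 (images) and 2049 (labels).
    Raw bytes are scaled to [0, 1]; since IDX stores ink as high byte values,
    the scaled value is directly the ink intensity of the ink-on-white
    convention used throughout this package.

    Raises
    ------
    IdxFormatError
        Wrong magic number or header too short.
    DatasetConsistencyError
        Truncated payload or image/label count mismatch.
    """
    img_bytes = Path(images_path).read_bytes()
    lab_bytes = Path(labels_path).read_bytes()

    if len(img_bytes) < 16 or len(lab_bytes) < 8:
        raise IdxFormatError("IDX header truncated")
    magic_i, n_img, rows, cols = struct.unpack(">iiii", img_bytes[:16])
    magic_l, n_lab = struct.unpack(">ii", lab_bytes[:8])
    if magic_i != _IDX_IMAGES_MAGIC:
        raise IdxFormatError(f"bad images magic {magic_i:#010x}")
    if magic_l != _IDX_LABELS_MAGIC:
        raise IdxFormatError(f"bad labels magic {magic_l:#010x}")
    if (rows, cols) != IMAGE_SHAPE:
        raise IdxFormatError(f"expected 28x28 images, got {rows}x{cols}")
    if n_img != n_lab:
        raise DatasetConsistencyError(f"{n_img} images but {n_lab} labels")
    if len(img_bytes) - 16 != n_img * rows * cols:
        raise DatasetConsistencyError("images payload size does not match header count")
    if len(lab_bytes) - 8 != n_lab:
        raise DatasetConsistencyError("labels payload size does not match header count")

    images = (
        np.frombuffer(img_bytes, dtype=np.uint8, offset=16)
        .reshape(n_img, rows, cols)
        .astype(np.float64)
        / 255.0
    )
    labels = np.frombuffer(lab_bytes, dtype=np.uint8, offset=8).astype(np.int64)
    if labels.size and (labels.min() < 0 or labels.max() > 9):
        raise DatasetConsistencyError("labels outside 0..9")
    return GrayDataset(images, labels)


# ---------------------------------------------------------------------------
# Colorization
# ---------------------------------------------------------------------------

def colorize(image: GrayscaleDigitImage, color: Sequence[float]) -> ColoredDigitImage:
    """Blend a greyscale digit onto a white background in the given color."""
    color = np.asarray(color, dtype=np.float64)
    matches = np.where((PALETTE == color).all(axis=1))[0]
    if matches.size == 0:
        raise ValueError(f"color {color} is not a palette entry")
    g = image.pixels[:, :, None]
    pixels = (1.0 - g) + g * color[None, None, :]
    return ColoredDigitImage(pixels, image.label, int(matches[0]))


def assign_color(
    image: GrayscaleDigitImage,
    assignment: ColorAssignment,
    rng: np.random.Generator | None = None,
) -> ColoredDigitImage:
    """Colorize one image under the RC or FC rule.

    RC mode draws the color uniformly from the palette and therefore requires
    ``rng``; FC mode looks the color up in the fixed digit->color map.
    """
    if assignment.mode == "RC":
        if rng is None:
            raise ValueError("RC mode requires a random generator")
        color_id = int(rng.integers(0, len(PALETTE)))
    else:
        color_id = int(assignment.fixed_map[image.label])
    return colorize(image, PALETTE[color_id])


def build_dataset(
    source: GrayDataset,
    assignment: ColorAssignment,
    seed: int | np.random.Generator = 0,
) -> ColorDataset:
    """Colorize a whole greyscale dataset under one assignment mode.

    Deterministic given ``seed``; the source order is preserved.  Element
    ``i`` of the result equals ``assign_color(source[i], ...)`` with the same
    RC draw sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(source)
    if assignment.mode == "RC":
        color_ids = rng.integers(0, len(PALETTE), size=n)
    else:
        lut = np.array([assignment.fixed_map[d] for d in range(N_CLASSES)])
        color_ids = lut[source.labels]
    g = source.images[:, :, :, None]
    colors = PALETTE[color_ids][:, None, None, :]
    images = (1.0 - g) + g * colors
    return ColorDataset(images, source.labels.copy(), color_ids.astype(np.int64))


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def dataset_manifest(dataset: ColorDataset) -> pd.DataFrame:
    """CSV-ready manifest: index, digit label, color id and color name."""
    return pd.DataFrame(
        {
            "index": np.arange(len(dataset)),
            "label": dataset.labels,
            "color_id": dataset.color_ids,
            "color": [PALETTE_NAMES[c] for c in dataset.color_ids],
        }
    )


def save_png(image: ColoredDigitImage | GrayscaleDigitImage, path: str | Path) -> None:
    """Write one image as an 8-bit PNG (greyscale images render ink-on-white)."""
    from PIL import Image

    if isinstance(image, GrayscaleDigitImage):
        arr = (1.0 - image.pixels) * 255.0  # render: 0 ink -> white
    else:
        arr = image.pixels * 255.0
    Image.fromarray(np.round(arr).astype(np.uint8)).save(path)
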