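"""Harvesting intermediate-layer activation features.

For each test image the three convolutional layers are read out after their
rectified-linear nonlinearity (before the following pooling layer, so the
feature counts are 26*26*32 = 21,632, 11*11*64 = 7,744 and 3*3*64 = 576).
Two granularities feed the downstream dimensionality analysis:

* pixel level — every activation value is one feature (row-major flattening
  h, then w, then filter; PCA is permutation-invariant but the order is
  fixed so saved matrices are reproducible);
* filter level — each filter contributes its mean pixel activation, giving
  32 / 64 / 64 features per layer and 160 concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import ColorDataset
from .network import TrainedNetwork

LAYER_SCOPES = ("1", "2", "3", "all")


@dataclass(frozen=True)
class ActivationTensor:
    """Post-relu output of one convolutional layer for a batch of images."""

    layer_index: int            # 1..3
    values: np.ndarray          # (n, h, w, d)

    def __post_init__(self) -> None:
        if not 1 <= self.layer_index <= 3:
            raise ValueError("layer_index must be in 1..3")
        if self.values.ndim != 4:
            raise ValueError("values must be (n, h, w, d)")


@dataclass(frozen=True)
class PixelFeatureMatrix:
    """n_samples x N matrix of single-pixel activations."""

    values: np.ndarray
    layer_scope: str  # "1" | "2" | "3" | "all"

    def __post_init__(self) -> None:
        if self.layer_scope not in LAYER_SCOPES:
            raise ValueError(f"layer_scope must be one of {LAYER_SCOPES}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FilterFeatureMatrix:
    """n_samples x M matrix of per-filter mean activations."""

    values: np.ndarray
    layer_scope: str

    def __post_init__(self) -> None:
        if self.layer_scope not in LAYER_SCOPES:
            raise ValueError(f"layer_scope must be one of {LAYER_SCOPES}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def extract_activations(
    network: TrainedNetwork, images: ColorDataset | np.ndarray, layer_index: int
) -> ActivationTensor:
    """Read one convolutional layer's activations for a set of images.

    Batch order is preserved and values are independent of how the images
    are split into prediction batches.
    """
    arr = images.images if isinstance(images, ColorDataset) else images
    values = network.layer_activations(arr, layer_index)
    return ActivationTensor(layer_index, values)


def flatten_pixels(tensor: ActivationTensor) -> PixelFeatureMatrix:
    """Row-major (h, w, filter) flattening of the activation tensor."""
    n = tensor.values.shape[0]
    return PixelFeatureMatrix(tensor.values.reshape(n, -1), str(tensor.layer_index))


def unflatten_pixels(matrix: PixelFeatureMatrix, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_pixels` for a single-layer matrix."""
    return matrix.values.reshape((matrix.values.shape[0],) + shape)


def filter_means(tensor: ActivationTensor) -> FilterFeatureMatrix:
    """Mean activation over each filter's h x w pixels, per sample."""
    return FilterFeatureMatrix(
        tensor.values.mean(axis=(1, 2)), str(tensor.layer_index)
    )


def concat_scopes(
    matrices: Sequence[PixelFeatureMatrix] | Sequence[FilterFeatureMatrix],
):
    """Column-wise concatenation of per-layer matrices into the 'all' scope.

    A single input matrix is returned unchanged (identity).  All inputs must
    share the sample count and order and be of the same granularity.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    if len(matrices) == 1:
        return matrices[0]
    kinds = {type(m) for m in matrices}
    if len(kinds) != 1:
        raise TypeError("cannot mix pixel- and filter-level matrices")
    n_rows = {m.values.shape[0] for m in matrices}
    if len(n_rows) != 1:
        raise ValueError(f"sample counts disagree: {sorted(n_rows)}")
    values = np.concatenate([m.values for m in matrices], axis=1)
    return kinds.pop()(values, "all")


def harvest_all(
    network: TrainedNetwork, test_set: ColorDataset
) -> tuple[dict[str, PixelFeatureMatrix], dict[str, FilterFeatureMatrix]]:
    """Pixel- and filter-level feature matrices for scopes 1, 2, 3 and all."""
    pixel: dict[str, PixelFeatureMatrix] = {}
    filt: dict[str, FilterFeatureMatrix] = {}
    for layer_index in (1, 2, 3):
        tensor = extract_activations(network, test_set, layer_index)
        scope = str(layer_index)
        pixel[scope] = flatten_pixels(tensor)
        filt[scope] = filter_means(tensor)
    pixel["all"] = concat_scopes([pixel["1"], pixel["2"], pixel["3"]])
    filt["all"] = concat_scopes([filt["1"], filt["2"], filt["3"]])
    return pixel, filt
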