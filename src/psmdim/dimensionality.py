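"""Phase-space dimensionality of activation patterns.

Each network configuration's internal representation is modelled as a point
cloud — one point per test image — in the feature space of its activation
values, and summarized by PCA.  Three indices describe how the explained
variance spreads over principal components:

* **WPD** (weight of primary dimensions): cumulative explained variance of
  the first two components, in percent.
* **WSD** (weight of secondary dimensions): cumulative explained variance of
  the components after the first two whose eigenvalue strictly exceeds 1
  (a Kaiser-like retention rule), in percent, together with their count.
* **D90**: the smallest number of leading components whose cumulative
  explained variance reaches 90%.

A representation that leans on a spurious low-dimensional cue (color)
concentrates variance on the first components — higher WPD, lower WSD and
D90 — whereas a shape-driven representation spreads it out.

PCA runs on mean-centered activations (covariance matrix) by default.  The
Kaiser criterion is classically defined on correlation matrices, so a
correlation mode (features standardized, zero-variance features dropped) is
also available; both are legitimate conventions and the indices can be
reported under either.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .activations import FilterFeatureMatrix, PixelFeatureMatrix, harvest_all
from .data import ColorDataset
from .network import TrainedNetwork

_FULL_SOLVER_LIMIT = 2000  # exact SVD whenever min(n, N) is at most this


class DegenerateInputError(ValueError):
    """Every feature is constant; there is no variance to decompose."""


class InsufficientComponentsError(ValueError):
    """Retained components explain less than the requested variance share."""


@dataclass(frozen=True)
class PCAConfig:
    matrix_type: str = "covariance"  # or "correlation"
    max_components: int | None = None  # None -> min(n_samples - 1, N)

    def __post_init__(self) -> None:
        if self.matrix_type not in ("covariance", "correlation"):
            raise ValueError("matrix_type must be 'covariance' or 'correlation'")
        if self.max_components is not None and self.max_components < 1:
            raise ValueError("max_components must be positive")


@dataclass(frozen=True)
class PCAResult:
    """Descending eigenvalue spectrum with exact explained-variance ratios.

    ``ev_ratio`` divides each eigenvalue by the total variance of the (possibly
    standardized) data — the sum over *all* features, not just retained
    components — so ratios stay exact under truncation.
    """

    eigenvalues: np.ndarray   # descending, ddof=1 scale
    ev_ratio: np.ndarray
    cumulative: np.ndarray
    n_samples: int
    n_features: int
    matrix_type: str = "covariance"

    @classmethod
    def from_spectrum(cls, eigenvalues, n_samples: int = 0,
                      matrix_type: str = "covariance") -> "PCAResult":
        """Build a result directly from a full eigenvalue spectrum."""
        ev = np.asarray(eigenvalues, dtype=np.float64)
        ratio = ev / ev.sum()
        return cls(ev, ratio, np.cumsum(ratio), n_samples, ev.size, matrix_type)


def run_pca(
    matrix: PixelFeatureMatrix | FilterFeatureMatrix | np.ndarray,
    config: PCAConfig = PCAConfig(),
) -> PCAResult:
    """PCA of a feature matrix, exact for small problems, truncated for large.

    The data are mean-centered (and standardized in correlation mode, with
    constant features dropped first).  When ``min(n_samples, N)`` is small
    the full SVD is used; otherwise a seeded randomized solver computes the
    leading ``max_components`` components, with the total variance taken
    from the feature-variance sum so ``ev_ratio`` and ``cumulative`` remain
    exact for the retained components.
    """
    X = matrix if isinstance(matrix, np.ndarray) else matrix.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    n, _ = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")

    variances = X.var(axis=0, ddof=1)
    nonconstant = variances > 0
    if not nonconstant.any():
        raise DegenerateInputError("all features are constant")

    if config.matrix_type == "correlation":
        Xw = X[:, nonconstant]
        Xw = (Xw - Xw.mean(axis=0)) / Xw.std(axis=0, ddof=1)
        total_var = float(Xw.shape[1])  # standardized features have unit variance
    else:
        Xw = X - X.mean(axis=0)
        total_var = float(variances.sum())

    n_feat = Xw.shape[1]
    rank_cap = min(n - 1, n_feat)
    n_comp = rank_cap if config.max_components is None else min(config.max_components, rank_cap)
    if min(n, n_feat) <= _FULL_SOLVER_LIMIT:
        pca = PCA(n_components=n_comp, svd_solver="full")
    else:
        pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=0)
    pca.fit(Xw)

    eigenvalues = pca.explained_variance_  # ddof=1 covariance eigenvalues
    ev_ratio = eigenvalues / total_var
    return PCAResult(
        eigenvalues=eigenvalues,
        ev_ratio=ev_ratio,
        cumulative=np.cumsum(ev_ratio),
        n_samples=n,
        n_features=n_feat,
        matrix_type=config.matrix_type,
    )


def wpd(pca: PCAResult) -> float:
    """Weight of primary dimensions: percent variance of the first two PCs."""
    if pca.ev_ratio.size < 2:
        raise ValueError("WPD needs at least 2 retained components")
    return 100.0 * float(pca.ev_ratio[0] + pca.ev_ratio[1])


def wsd(pca: PCAResult) -> tuple[float, int]:
    """Weight of secondary dimensions and their count.

    Sums the explained-variance percent of components beyond the first two
    whose eigenvalue strictly exceeds 1.  An empty secondary set yields
    (0.0, 0).
    """
    secondary = pca.eigenvalues[2:] > 1.0
    return 100.0 * float(pca.ev_ratio[2:][secondary].sum()), int(secondary.sum())


def d90(pca: PCAResult, threshold: float = 0.90) -> int:
    """Minimal number of leading components reaching the variance threshold."""
    reached = pca.cumulative >= threshold - 1e-12
    if not reached.any():
        raise InsufficientComponentsError(
            f"retained components explain {pca.cumulative[-1]:.4f} < {threshold}; "
            "raise max_components"
        )
    return int(np.argmax(reached)) + 1


@dataclass(frozen=True)
class DimensionalityIndices:
    wpd: float
    wsd: float | None       # None at filter level
    n_secondary: int | None
    d90: int


def indices_from_matrix(
    matrix: PixelFeatureMatrix | FilterFeatureMatrix | np.ndarray,
    config: PCAConfig = PCAConfig(),
    include_wsd: bool = True,
) -> DimensionalityIndices:
    """Run PCA and compute all indices, escalating to the full spectrum if
    the truncated one does not reach 90% cumulative variance."""
    pca = run_pca(matrix, config)
    try:
        n90 = d90(pca)
    except InsufficientComponentsError:
        pca = run_pca(matrix, PCAConfig(config.matrix_type, None))
        n90 = d90(pca)
    w, k = wsd(pca)
    return DimensionalityIndices(
        wpd=wpd(pca),
        wsd=w if include_wsd else None,
        n_secondary=k if include_wsd else None,
        d90=n90,
    )


def table_from_matrices(
    rr: Mapping[str, PixelFeatureMatrix] | Mapping[str, FilterFeatureMatrix],
    fr: Mapping[str, PixelFeatureMatrix] | Mapping[str, FilterFeatureMatrix],
    level: str,
    config: PCAConfig = PCAConfig(),
) -> pd.DataFrame:
    """Index table over scopes 1, 2, 3, all for both conditions.

    WSD/secondary counts are reported at pixel level only; at filter level
    the spectra are too short for a meaningful secondary set.
    """
    if level not in ("pixel", "filter"):
        raise ValueError("level must be 'pixel' or 'filter'")
    include_wsd = level == "pixel"
    rows = []
    for scope in ("1", "2", "3", "all"):
        for condition, mats in (("RR", rr), ("FR", fr)):
            idx = indices_from_matrix(mats[scope], config, include_wsd)
            rows.append(
                {
                    "layer_scope": scope,
                    "condition": condition,
                    "wpd": idx.wpd,
                    "wsd": idx.wsd,
                    "n_secondary": idx.n_secondary,
                    "d90": idx.d90,
                }
            )
    return pd.DataFrame(rows)


def dimensionality_table(
    rr_network: TrainedNetwork,
    fr_network: TrainedNetwork,
    test_set: ColorDataset,
    level: str,
    config: PCAConfig = PCAConfig(),
) -> pd.DataFrame:
    """Harvest activations from both networks on the shared test set and
    tabulate WPD/WSD/D90 per layer scope and condition."""
    rr_pixel, rr_filter = harvest_all(rr_network, test_set)
    fr_pixel, fr_filter = harvest_all(fr_network, test_set)
    if level == "pixel":
        return table_from_matrices(rr_pixel, fr_pixel, level, config)
    return table_from_matrices(rr_filter, fr_filter, level, config)
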