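"""Two-sample comparison of activation-intensity distributions.

The FR and RR networks' filter-level activations are compared as flat
samples of per-(image, filter) mean activation values, one sample per
condition per layer scope.  Each scope gets a Welch (unequal-variance)
two-sample t-test, FR first, so a positive t means the FR network activates
more intensely; the four tests (layers 1, 2, 3 and all together) are jointly
corrected with the Benjamini-Hochberg false-discovery-rate step-up at
alpha = 0.05.

Welch's variant is used because the two conditions' variances differ
visibly (the FR distributions have heavier tails); its Welch-Satterthwaite
degrees of freedom are reported alongside the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .activations import FilterFeatureMatrix


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t-test; positive t => first sample has larger mean."""

    t: float
    p_uncorrected: float
    df: float
    p_fdr: float | None = None
    significant: bool | None = None


def two_sample_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Welch unequal-variance t-test of ``a`` (first) vs ``b``, two-sided."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both samples are constant; t is undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), p_uncorrected=float(res.pvalue),
                       df=float(res.df))


def fdr_correct(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, significance flags at ``alpha``).  The
    adjustment is monotone and never decreases a p-value.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def _sample(matrix: FilterFeatureMatrix) -> np.ndarray:
    # one observation per (image, filter) pair
    return matrix.values.ravel()


def compare_conditions(
    rr: Mapping[str, FilterFeatureMatrix],
    fr: Mapping[str, FilterFeatureMatrix],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Four FR-vs-RR Welch t-tests (scopes 1, 2, 3, all) with joint BH-FDR.

    FR is the first sample, so positive t means the FR network's mean
    activation exceeds RR's.  Also reports per-condition distribution
    summaries (mean, sd, 1%/99% tail quantiles) to characterize the heavier
    FR tails.
    """
    scopes = ("1", "2", "3", "all")
    rows = []
    for scope in scopes:
        fr_s, rr_s = _sample(fr[scope]), _sample(rr[scope])
        if fr_s.var(ddof=1) == 0.0 and rr_s.var(ddof=1) == 0.0:
            res = TTestResult(t=0.0, p_uncorrected=1.0, df=float(fr_s.size + rr_s.size - 2))
        else:
            res = two_sample_t(fr_s, rr_s)
        rows.append(
            {
                "layer_scope": scope,
                "t": res.t,
                "df": res.df,
                "p_uncorrected": res.p_uncorrected,
                "n_fr": fr_s.size,
                "n_rr": rr_s.size,
                "mean_fr": float(fr_s.mean()),
                "mean_rr": float(rr_s.mean()),
                "sd_fr": float(fr_s.std(ddof=1)),
                "sd_rr": float(rr_s.std(ddof=1)),
                "q01_fr": float(np.quantile(fr_s, 0.01)),
                "q99_fr": float(np.quantile(fr_s, 0.99)),
                "q01_rr": float(np.quantile(rr_s, 0.01)),
                "q99_rr": float(np.quantile(rr_s, 0.99)),
            }
        )
    table = pd.DataFrame(rows)
    p_adj, reject = fdr_correct(table["p_uncorrected"].to_numpy(), alpha)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return table
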