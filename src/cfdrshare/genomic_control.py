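"""Genomic-control correction of inflated test statistics.

The inflation factor lambda_GC is the median of the squared null-panel Z
scores divided by the median of the chi-square(1) distribution.  All test
statistics are rescaled as z^2 -> z^2 / lambda and p values recomputed,
so globally null p values can be assumed uniform downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_design import z_to_p

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df (~0.4549), from the
#: inverse CDF rather than a hard-coded constant
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class GcResult:
    lambda_gc: float
    n_null_snps: int


def estimate_lambda(null_z) -> GcResult:
    """Estimate lambda_GC from |Z| values at a user-supplied null panel.

    Requires >= 30 values (warns below 200, where the median is noisy).
    """
    z = np.asarray(null_z, float)
    if z.size == 0:
        raise ValueError("null panel is empty")
    if not np.all(np.isfinite(z)):
        raise ValueError("null panel contains non-finite values")
    if z.size < 30:
        raise ValueError(f"null panel too small ({z.size} < 30)")
    if z.size < 200:
        logger.warning("null panel has only %d SNPs; lambda estimate is noisy",
                       z.size)
    lam = float(np.median(z * z) / CHI2_1_MEDIAN)
    return GcResult(lambda_gc=lam, n_null_snps=int(z.size))


def apply_gc(records: pd.DataFrame, lambda_gc: float,
             p_col: str = "p", z_col: str = "z") -> pd.DataFrame:
    """Rescale z and recompute p by a given inflation factor.

    The originals are kept in ``<col>_raw`` side columns.  Lambda below 1
    (deflation) is applied but warned about; the estimator has no floor.
    """
    if not lambda_gc > 0:
        raise ValueError(f"lambda_gc must be > 0, got {lambda_gc}")
    if lambda_gc < 1:
        logger.warning("lambda_gc = %.4f < 1: applying deflation", lambda_gc)
    out = records.copy()
    out[z_col + "_raw"] = out[z_col]
    out[p_col + "_raw"] = out[p_col]
    z_corr = out[z_col].to_numpy(float) / np.sqrt(lambda_gc)
    out[z_col] = z_corr
    out[p_col] = z_to_p(z_corr)
    return out
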