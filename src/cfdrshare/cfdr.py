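"""Unconditional and conditional FDR estimation and significance calibration.

The unconditional FDR estimate at a p value p is

    ufdr(p) = p / (#{p_k <= p} / N)

i.e. the expected null quantile over the observed quantile; it is
conservative because Pr(H0) is set to 1.  The conditional version
restricts both the numerator and the empirical quantile to the N1 SNPs
whose conditional-phenotype p values fall at or below p_j, and replaces
the numerator p_i by the shared-control expected quantile
Pr(P_i <= p_i | P_j <= p_j, H0_i):

    cfdr(p_i | p_j) = expected_quantile / (#{p_ik <= p_i, p_jk <= p_j} / N1).

Counting is inclusive on both coordinates and the query SNP counts
itself, so denominators are never zero at observed points.  Estimates are
clamped at 1 (the raw ratio is kept in a diagnostic column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shared_control import BivariateNullSpec, expected_quantile_cum

logger = logging.getLogger(__name__)

GW_THRESHOLD = 5e-8


def ufdr_hat(p_values, p_target: float) -> float:
    """Estimate the unconditional FDR at one target p value."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p value collection")
    count = int(np.sum(p <= p_target))
    if count == 0:
        raise ValueError(
            f"no p values at or below target {p_target}; estimate undefined"
        )
    return float(min(p_target / (count / p.size), 1.0))


def ufdr_values(p_values) -> np.ndarray:
    """Vectorised ufdr at every observed p value (clamped at 1)."""
    p = np.asarray(p_values, float)
    sorted_p = np.sort(p)
    counts = np.searchsorted(sorted_p, p, side="right")
    return np.minimum(p * p.size / counts, 1.0)


def ufdr_monotone(p_values) -> np.ndarray:
    """ufdr smoothed to be non-decreasing in p by a running maximum.

    The least-gamma threshold definition assumes ufdr is monotone in p;
    sampling noise can break that locally, so the running maximum over
    sorted p restores it before thresholds are extracted.
    """
    p = np.asarray(p_values, float)
    order = np.argsort(p, kind="mergesort")
    raw = ufdr_values(p)[order]
    smoothed = np.maximum.accumulate(raw)
    out = np.empty_like(smoothed)
    out[order] = smoothed
    return out


class _Fenwick:
    """Binary indexed tree for prefix counts (1-based)."""

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def _dominance_counts(p_i: np.ndarray, p_j: np.ndarray) -> np.ndarray:
    """For each k, #{m : p_i[m] <= p_i[k] and p_j[m] <= p_j[k]} (inclusive).

    O(N log N) via a Fenwick tree over p_j ranks, sweeping groups of
    equal p_i so ties are counted inclusively on both coordinates.
    """
    n = p_i.size
    j_rank = np.searchsorted(np.sort(p_j), p_j, side="left")
    order = np.lexsort((j_rank, p_i))
    tree = _Fenwick(n)
    counts = np.zeros(n, dtype=np.int64)
    start = 0
    while start < n:
        stop = start
        while stop < n and p_i[order[stop]] == p_i[order[start]]:
            stop += 1
        for t in range(start, stop):
            tree.add(int(j_rank[order[t]]))
        # equal p_j values share a rank (side="left"), so the prefix up to
        # a SNP's own rank counts every inserted item with p_j <= its own
        for t in range(start, stop):
            k = order[t]
            counts[k] = tree.prefix(int(j_rank[k]))
        start = stop
    return counts


def cfdr_hat(pairs: pd.DataFrame, p_i: float, p_j: float,
             spec: BivariateNullSpec) -> float:
    """Conditional FDR estimate at one query point (p_i, p_j)."""
    pi_all = pairs["p_i"].to_numpy(float)
    pj_all = pairs["p_j"].to_numpy(float)
    n1 = int(np.sum(pj_all <= p_j))
    if n1 == 0:
        raise ValueError(f"no pairs with p_j <= {p_j}")
    # the query point itself always counts, so the denominator is >= 1/N1
    count = max(int(np.sum((pi_all <= p_i) & (pj_all <= p_j))), 1)
    num = float(expected_quantile_cum(p_i, p_j, spec))
    return float(min(num / (count / n1), 1.0))


def cfdr_table(pairs: pd.DataFrame, spec: BivariateNullSpec) -> pd.DataFrame:
    """Per-SNP ufdr and cfdr evaluated at each SNP's own (p_i, p_j).

    Returns the input table with added columns ``ufdr_i``,
    ``ufdr_i_monotone``, ``cfdr_i_given_j``, ``cfdr_raw``,
    ``numerator_used``, ``denominator_used``, ``n1`` and (when rho > 0)
    ``p_adj``, the cumulative expected quantile at the SNP's own point.
    """
    out = pairs.copy()
    p_i = out["p_i"].to_numpy(float)
    p_j = out["p_j"].to_numpy(float)
    n = p_i.size
    if n == 0:
        raise ValueError("empty pair table")

    out["ufdr_i"] = ufdr_values(p_i)
    out["ufdr_i_monotone"] = ufdr_monotone(p_i)

    sorted_pj = np.sort(p_j)
    n1 = np.searchsorted(sorted_pj, p_j, side="right")
    counts = _dominance_counts(p_i, p_j)
    num = np.asarray(expected_quantile_cum(p_i, p_j, spec), float)
    denom = counts / n1
    raw = num / denom
    out["numerator_used"] = num
    out["denominator_used"] = denom
    out["n1"] = n1
    out["cfdr_raw"] = raw
    out["cfdr_i_given_j"] = np.minimum(raw, 1.0)
    out["p_adj"] = num
    return out


@dataclass(frozen=True)
class SignificanceThresholds:
    """uFDR / cFDR cutoffs calibrated against genome-wide significance."""

    beta_i: float
    alpha_ji: float
    capped: bool
    defined: bool = True


def calibrate_thresholds(table: pd.DataFrame,
                         p_gw: float = GW_THRESHOLD) -> SignificanceThresholds:
    """Map the genome-wide p threshold onto uFDR and cFDR cutoffs.

    beta is the largest (monotone-smoothed) ufdr among SNPs with
    p_i <= p_gw -- the least gamma with ufdr <= gamma iff p <= p_gw.
    alpha is the analogous largest cfdr, capped at beta so that SNPs with
    near-1 conditional p values cannot be declared more leniently than by
    p value alone.  With no SNP at or below p_gw the thresholds are
    undefined and flagged.
    """
    mask = table["p_i"].to_numpy(float) <= p_gw
    if not mask.any():
        logger.warning("no SNP with p_i <= %g; thresholds undefined", p_gw)
        return SignificanceThresholds(float("nan"), float("nan"),
                                      capped=False, defined=False)
    beta = float(table.loc[mask, "ufdr_i_monotone"].max())
    alpha_raw = float(table.loc[mask, "cfdr_i_given_j"].max())
    capped = alpha_raw > beta
    return SignificanceThresholds(
        beta_i=beta, alpha_ji=min(alpha_raw, beta), capped=capped
    )


def declare(table: pd.DataFrame,
            thresholds: SignificanceThresholds) -> pd.Index:
    """SNP ids declared non-null for the principal phenotype.

    A SNP is declared if cfdr(p_i | p_j) <= alpha, and all SNPs with
    ufdr(p_i) <= beta are included explicitly (the uFDR-declared set is
    always a subset).
    """
    if not thresholds.defined:
        logger.warning("thresholds undefined; declaring nothing")
        return pd.Index([], name="snp_id")
    hit = (table["cfdr_i_given_j"].to_numpy(float) <= thresholds.alpha_ji) | (
        table["ufdr_i_monotone"].to_numpy(float) <= thresholds.beta_i
    )
    ids = table.loc[hit, "snp_id"] if "snp_id" in table.columns else table.index[hit]
    return pd.Index(ids, name="snp_id")
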