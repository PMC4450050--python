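"""Multiple-testing combination, LD pruning and pleiotropy summaries.

Conditioning one principal phenotype on k different conditional
phenotypes produces k highly correlated tests.  The effective number of
tests is estimated from the eigenvalue variance of the Spearman
rank-correlation matrix of the k cfdr columns,

    M_eff = 1 + k (1 - Var(lambda_obs) / k),

which is 1 for perfectly rank-correlated columns (one test) and k + 1
for uncorrelated columns.  The per-conditional FDR bounds c_j with
declared counts n_j combine as

    c0 = M_eff * sum_j c_j n_j / sum_j n_j.

Also here: greedy LD pruning of declared SNPs, the conditional
significance-cutoff / fold-ratio pleiotropy statistic, conditional Q-Q
table construction, and the TDT effective-case-count calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cfdr import cfdr_hat, ufdr_hat
from .region import FdrBound
from .shared_control import BivariateNullSpec

logger = logging.getLogger(__name__)

#: network edge threshold on the conditional cutoff p*
EDGE_THRESHOLD = 4e-7
R2_MAX = 0.1


@dataclass(frozen=True)
class MtcResult:
    meff: float
    eigen_variance: float
    k: int


def meff(cfdr_columns: pd.DataFrame) -> MtcResult:
    """Effective number of tests across k conditional phenotypes.

    ``cfdr_columns`` holds one cfdr column per conditional phenotype,
    restricted to potentially non-null rows (>= 50 of them).  Constant
    columns make the rank correlation undefined and raise.
    """
    k = cfdr_columns.shape[1]
    if k < 2:
        raise ValueError("need at least 2 cfdr columns")
    if len(cfdr_columns) < 50:
        raise ValueError("need at least 50 rows to estimate the correlation")
    x = cfdr_columns.to_numpy(float)
    if np.any(np.ptp(x, axis=0) == 0.0):
        raise ValueError("constant cfdr column: rank correlation undefined")
    omega = spearmanr(x).statistic
    if k == 2:  # spearmanr returns a scalar for two columns
        omega = np.array([[1.0, omega], [omega, 1.0]])
    eigvals = np.linalg.eigvalsh(omega)
    var = float(np.var(eigvals, ddof=1))
    m = 1.0 + k * (1.0 - var / k)
    return MtcResult(meff=float(m), eigen_variance=var, k=k)


def combined_bound(bounds: list[FdrBound], meff_value: float) -> float:
    """Overall FDR bound across conditional phenotypes (undefined if no
    SNPs were declared for any of them)."""
    n_total = sum(b.n_ji for b in bounds)
    if n_total == 0:
        raise ValueError("no declared SNPs in any pair: combined bound undefined")
    weighted = sum(b.c_ji * b.n_ji for b in bounds)
    return float(meff_value * weighted / n_total)


def ld_prune(declared: pd.DataFrame, r2_pairs: pd.DataFrame,
             r2_max: float = R2_MAX) -> pd.DataFrame:
    """Greedy LD pruning of declared SNPs.

    ``declared`` has columns ``snp_id`` and ``min_cfdr`` (the best cfdr
    across conditional phenotypes); ``r2_pairs`` has ``id_a, id_b, r2``
    (symmetric; absent pairs mean r2 = 0).  SNPs are scanned in
    increasing min_cfdr order; each kept SNP removes all later-ranked
    SNPs in LD with it at r2 >= r2_max, ideally retaining one SNP per LD
    block.
    """
    r2 = r2_pairs["r2"].to_numpy(float)
    if np.any((r2 < 0.0) | (r2 > 1.0)):
        raise ValueError("r2 values must lie in [0, 1]")
    neighbours: dict[str, set[str]] = {}
    for a, b, v in zip(r2_pairs["id_a"].astype(str),
                       r2_pairs["id_b"].astype(str), r2):
        if v >= r2_max:
            neighbours.setdefault(a, set()).add(b)
            neighbours.setdefault(b, set()).add(a)

    ordered = declared.sort_values(["min_cfdr", "snp_id"], kind="mergesort")
    removed: set[str] = set()
    keep: list[str] = []
    for snp in ordered["snp_id"].astype(str):
        if snp in removed:
            continue
        keep.append(snp)
        removed |= neighbours.get(snp, set())
    return ordered[ordered["snp_id"].astype(str).isin(keep)].reset_index(drop=True)


@dataclass(frozen=True)
class PleiotropyStat:
    p_star: float
    fold_ratio: float
    edge: bool
    defined: bool = True


def conditional_cutoff(pairs: pd.DataFrame, spec: BivariateNullSpec,
                       p_cond: float = 5e-6, p_gw: float = 5e-8,
                       edge_threshold: float = EDGE_THRESHOLD) -> PleiotropyStat:
    """Pleiotropy summary: how far conditioning relaxes the p_i cutoff.

    p* is the largest p_i with cfdr(p_i | p_cond) <= ufdr(p_gw), found by
    bisection on the empirical estimator; the fold ratio p*/p_gw
    quantifies the gain, and an edge is drawn in the pleiotropy network
    when p* >= the edge threshold.  Undefined (flagged) when no SNP
    reaches p_gw or no SNP has p_j <= p_cond.
    """
    p_i = pairs["p_i"].to_numpy(float)
    p_j = pairs["p_j"].to_numpy(float)
    if not np.any(p_i <= p_gw) or not np.any(p_j <= p_cond):
        logger.warning("conditional cutoff undefined for this pair")
        return PleiotropyStat(float("nan"), float("nan"), False, defined=False)
    target = ufdr_hat(p_i, p_gw)

    def ok(log_pi: float) -> bool:
        return cfdr_hat(pairs, 10.0 ** log_pi, p_cond, spec) <= target

    hi = 0.0
    lo = np.log10(max(p_i.min(), 1e-300)) - 2.0
    if ok(hi):
        p_star = 1.0
    elif not ok(lo):
        p_star = 0.0
    else:
        while hi - lo > 1e-3:
            mid = 0.5 * (lo + hi)
            if ok(mid):
                lo = mid
            else:
                hi = mid
        p_star = 10.0 ** lo
    return PleiotropyStat(
        p_star=float(p_star),
        fold_ratio=float(p_star / p_gw),
        edge=bool(p_star >= edge_threshold),
    )


def qq_conditional(pairs: pd.DataFrame,
                   cutoffs=(1.0, 0.1, 0.01, 1e-3, 1e-4)) -> pd.DataFrame:
    """Plot-ready conditional Q-Q series of adjusted principal p values.

    For each conditional-p cutoff, the subset {p_j <= cutoff} is ranked
    by the adjusted expected quantile ``p_adj`` (falling back to ``p_i``)
    and paired with uniform order-statistic quantiles k/(n+1).  Returns
    long-format columns ``cutoff, expected_log10, observed_log10``; a
    cutoff with no SNPs is omitted with a warning.  Leftward shift of a
    series with decreasing cutoff indicates enrichment, i.e. pleiotropy.
    """
    p_col = "p_adj" if "p_adj" in pairs.columns else "p_i"
    frames = []
    for cutoff in cutoffs:
        sub = pairs.loc[pairs["p_j"] <= cutoff, p_col].to_numpy(float)
        if sub.size == 0:
            logger.warning("no SNPs with p_j <= %g; series omitted", cutoff)
            continue
        sub = np.sort(sub)
        expected = np.arange(1, sub.size + 1) / (sub.size + 1)
        frames.append(pd.DataFrame({
            "cutoff": cutoff,
            "expected_log10": -np.log10(expected),
            "observed_log10": -np.log10(sub),
        }))
    return (pd.concat(frames, ignore_index=True)
            if frames else pd.DataFrame(
                columns=["cutoff", "expected_log10", "observed_log10"]))


@dataclass(frozen=True)
class TdtCalibration:
    m_median: float
    n_controls_equiv: int
    n_cases_equiv: float
    n_snps_used: int


def tdt_effective_cases(se, maf, p, n0: int,
                        null_p_min: float = 0.5) -> TdtCalibration:
    """Convert TDT log-OR standard errors to an equivalent case count.

    In a case-control study with n0 controls, n1 cases and control MAF f,
    Var(log OR) = (n0 + n1) / (n0 n1 f (1 - f)) under the null, so
    M = se^2 f (1 - f) estimates 1/n0 + 1/n1.  Taking the median of M
    over SNPs showing no deviation from the null (p > 0.5) and solving
    gives n1 = 1 / (median(M) - 1/n0).
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    se = np.asarray(se, float)
    maf = np.asarray(maf, float)
    p = np.asarray(p, float)
    keep = p > null_p_min
    if not keep.any():
        raise ValueError("no null SNPs (p > 0.5) to calibrate on")
    m = se[keep] ** 2 * maf[keep] * (1.0 - maf[keep])
    m_med = float(np.median(m))
    if m_med <= (1.0 / n0) * (1.0 + 1e-9):
        raise ValueError(
            f"median M = {m_med:g} <= 1/n0 = {1.0 / n0:g}: no finite case count"
        )
    n1 = 1.0 / (m_med - 1.0 / n0)
    return TdtCalibration(m_median=m_med, n_controls_equiv=n0,
                          n_cases_equiv=float(n1), n_snps_used=int(keep.sum()))
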