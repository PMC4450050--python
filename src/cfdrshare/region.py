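"""The significance region L and the upper bound on its overall FDR.

Declaring every SNP whose estimated conditional FDR falls below alpha
amounts to declaring the union L of all rectangles
[0, p_i] x [0, p_j] with cfdr(p_i | p_j) <= alpha.  Each individual
rectangle has expected FDR at most alpha, but their union generally does
not: when the non-null SNPs are concentrated near the origin, every
rectangle along the boundary contains the same non-nulls while the union
accumulates extra null mass.  The bound implemented here is

    FDR(L) <= alpha_star * v(L) / v(M*)

where M* is the rectangle inside L with the largest expected null
content v(.), and alpha_star is the cfdr estimate at M*'s upper-right
vertex (usually equal to alpha).

v(.) is computed as null-model mass -- N times the two-component joint
tail probability -- rather than literal area; with rho = 0 and pi0 = 1
the two coincide (``mode="area"`` forces literal area).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfdr import cfdr_hat
from .io_design import p_to_z
from .shared_control import BivariateNullSpec, tail_prob

logger = logging.getLogger(__name__)

GRID_SIZE = 200
#: bisection tolerance in log10(p_i)
BISECT_TOL = 1e-3


@dataclass
class RegionL:
    """Boundary and null-mass summary of the declarable region."""

    alpha: float
    #: (p_j, max p_i with cfdr <= alpha), sorted by p_j ascending; the
    #: p_i column is monotone non-increasing in p_j (union geometry)
    boundary: pd.DataFrame
    v_l: float = float("nan")
    m_star: tuple[float, float] | None = None
    v_m: float = float("nan")
    alpha_star: float = float("nan")
    bound: float = float("nan")
    empty: bool = False
    meta: dict = field(default_factory=dict)

    def contains(self, p_i, p_j) -> np.ndarray:
        """Membership of points in L = union of boundary rectangles."""
        if self.empty:
            return np.zeros(np.broadcast(p_i, p_j).shape, bool)
        pj_grid = self.boundary["p_j"].to_numpy()
        bi = self.boundary["p_i_max"].to_numpy()
        # effective boundary at height y: the rectangle of the smallest
        # grid p_j >= y (p_i_max non-increasing makes this the max width)
        idx = np.searchsorted(pj_grid, np.asarray(p_j, float), side="left")
        inside = idx < pj_grid.size
        width = np.where(inside, bi[np.minimum(idx, pj_grid.size - 1)], 0.0)
        return inside & (np.asarray(p_i, float) <= width)


def _bisect_boundary(pairs, p_j, alpha, spec, lo_log10: float) -> float:
    """Largest p_i with cfdr(p_i | p_j) <= alpha, by bisection in log10."""

    def ok(log_pi: float) -> bool:
        try:
            return cfdr_hat(pairs, 10.0 ** log_pi, p_j, spec) <= alpha
        except ValueError:
            return False

    hi = 0.0  # log10(1)
    if ok(hi):
        return 1.0
    lo = lo_log10
    if not ok(lo):
        return 0.0
    while hi - lo > BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return 10.0 ** lo


def build_region(pairs: pd.DataFrame, alpha: float, spec: BivariateNullSpec,
                 grid_size: int = GRID_SIZE,
                 extra_p_j=None) -> RegionL:
    """Trace the boundary of L on a log-spaced p_j grid.

    For each grid p_j the largest p_i with cfdr(p_i | p_j) <= alpha is
    found by bisection; the boundary is then forced monotone
    non-increasing in p_j by a running maximum taken downwards from
    large p_j, which is exactly the effective boundary of the union of
    rectangles.  ``extra_p_j`` (e.g. observed p_j at declared SNPs) are
    added to the grid.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    pj_obs = pairs["p_j"].to_numpy(float)
    pj_lo = max(pj_obs.min(), 1e-300)
    grid = np.geomspace(pj_lo, 1.0, grid_size)
    if extra_p_j is not None:
        grid = np.union1d(grid, np.asarray(extra_p_j, float))
    grid = np.unique(grid)

    lo_log10 = np.log10(max(pairs["p_i"].to_numpy(float).min(), 1e-300)) - 2.0
    bi = np.array([_bisect_boundary(pairs, pj, alpha, spec, lo_log10)
                   for pj in grid])
    # union geometry: a point at height y is in L if any rectangle with
    # p_j >= y is wide enough, so take the running max from the top down
    bi_eff = np.maximum.accumulate(bi[::-1])[::-1]

    boundary = pd.DataFrame({"p_j": grid, "p_i_max": bi_eff})
    if np.all(bi_eff <= 0.0):
        logger.warning("alpha=%g below the attainable cfdr range: empty region",
                       alpha)
        return RegionL(alpha=alpha, boundary=boundary, empty=True)
    return RegionL(alpha=alpha, boundary=boundary)


def null_mass_rect(p_i: float, p_j: float, spec: BivariateNullSpec,
                   n_snps: int, mode: str = "mass") -> float:
    """Expected number of null-principal SNPs in [0, p_i] x [0, p_j].

    ``mode="mass"`` uses the two-component shared-control null model;
    ``mode="area"`` uses the uniform-independence approximation
    N * p_i * p_j (the two agree at rho = 0, pi0 = 1).
    """
    if mode == "area":
        return float(n_snps * p_i * p_j)
    if mode != "mass":
        raise ValueError(f"unknown mode {mode!r}")
    if p_i <= 0.0 or p_j <= 0.0:
        return 0.0
    pi0, sigma2 = spec.mixture.pi0, spec.mixture.sigma2
    z_i, z_j = p_to_z(p_i), p_to_z(p_j)
    mass = (pi0 * tail_prob(z_i, z_j, spec.rho, 0.0)
            + (1.0 - pi0) * tail_prob(z_i, z_j, spec.rho, sigma2))
    return float(n_snps * mass)


def null_mass_region(region: RegionL, spec: BivariateNullSpec, n_snps: int,
                     mode: str = "mass") -> float:
    """Expected null count in L, by strip decomposition of the boundary.

    L is a staircase of rectangles; between consecutive boundary heights
    the horizontal strip has width p_i_max(upper height), and its mass is
    the difference of two rectangle masses.
    """
    pj = region.boundary["p_j"].to_numpy()
    bi = region.boundary["p_i_max"].to_numpy()
    total = 0.0
    prev_pj = 0.0
    for height, width in zip(pj, bi):
        if width > 0.0:
            total += (null_mass_rect(width, height, spec, n_snps, mode)
                      - null_mass_rect(width, prev_pj, spec, n_snps, mode))
        prev_pj = height
    return total


def largest_rectangle(region: RegionL, pairs: pd.DataFrame,
                      spec: BivariateNullSpec, n_snps: int,
                      mode: str = "mass") -> RegionL:
    """Locate M*, compute v(L), v(M*), alpha_star and the FDR bound.

    Scans the boundary vertices for the rectangle maximising null mass;
    alpha_star is the cfdr estimate re-evaluated at the chosen vertex
    (not assumed equal to alpha).  Fills the region's summary fields in
    place and returns it.
    """
    if region.empty:
        raise ValueError("cannot find a rectangle in an empty region")
    pj = region.boundary["p_j"].to_numpy()
    bi = region.boundary["p_i_max"].to_numpy()
    masses = np.array([
        null_mass_rect(w, h, spec, n_snps, mode) if w > 0 else 0.0
        for h, w in zip(pj, bi)
    ])
    k = int(np.argmax(masses))
    region.m_star = (float(bi[k]), float(pj[k]))
    region.v_m = float(masses[k])
    region.v_l = null_mass_region(region, spec, n_snps, mode)
    region.alpha_star = cfdr_hat(pairs, bi[k], pj[k], spec)
    region.bound = fdr_bound(region)
    return region


def fdr_bound(region: RegionL) -> float:
    """Upper bound alpha_star * v(L) / v(M*) on the expected FDR over L."""
    if not region.v_m > 0.0:
        raise ValueError("v(M*) must be positive")
    return float(region.alpha_star * region.v_l / region.v_m)


@dataclass(frozen=True)
class FdrBound:
    """Per (principal, conditional) pair: bound c and declared count n."""

    c_ji: float
    n_ji: int
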