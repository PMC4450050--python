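"""The shared-control null model and the expected-quantile adjustment.

Two case-control studies that reuse the same control subjects produce
positively correlated association Z scores at SNPs that are null for
both.  Conditioning on a small p value for one phenotype then makes the
other phenotype's p values look "falsely low" even under its null.  This
module computes

* ``rho_shared`` -- the asymptotic correlation rho of the null Z scores
  from the case/control/shared-control counts;
* ``tail_prob`` -- joint two-sided tail probabilities of the bivariate
  normal null model;
* ``expected_quantile_cum``  -- Pr(P_i <= p_i | P_j <= p_j, H0_i), the
  quantity that replaces p_i in the conditional FDR estimator;
* ``expected_quantile_point`` -- the same conditioned on P_j = p_j exactly;
* ``expected_quantile_cum_numeric`` -- a quadrature variant that accepts
  an arbitrary tabulated density for the latent effect H instead of the
  fitted normal mixture.

Model: conditional on the latent effect eta of a SNP on the conditional
phenotype and on the principal-phenotype null,

    (Z_i, Z_j) ~ N((0, eta), [[1, rho], [rho, 1]]).

Integrating eta over the fitted point-mass-plus-normal mixture gives the
marginal two-component form with covariances [[1, rho], [rho, 1]] (null
component) and [[1, rho], [rho, 1 + sigma^2]] (non-null component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._bvn import both_tails_exceed, both_tails_exceed_shifted
from .io_design import StudyPairDesign, p_to_z
from .null_mixture import NullMixture


def rho_shared(design: StudyPairDesign) -> float:
    """Asymptotic correlation of null Z scores under shared controls.

    With N_i, N_j cases, N_0i, N_0j unique controls and N_0 shared
    controls,

        rho = N_0 sqrt(N_i N_j) /
              [ sqrt((N_0i + N_0)(N_0j + N_0)) *
                sqrt((N_i + N_0i + N_0)(N_j + N_0j + N_0)) ]

    which is 0 exactly when no controls are shared.  The formula is exact
    in the large-sample limit and accurate for group sizes above ~100;
    the genotype-level simulator provides an empirical cross-check.
    """
    n0 = design.n_controls_shared
    if n0 == 0:
        return 0.0
    ni, nj = design.n_cases_i, design.n_cases_j
    mi = design.n_controls_total_i
    mj = design.n_controls_total_j
    rho = (n0 * np.sqrt(ni * nj)
           / (np.sqrt(mi * mj) * np.sqrt((ni + mi) * (nj + mj))))
    return float(rho)


@dataclass(frozen=True)
class BivariateNullSpec:
    """Null correlation plus the conditional-effect mixture for one pair."""

    rho: float
    mixture: NullMixture

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")

    @classmethod
    def from_design(cls, design: StudyPairDesign,
                    mixture: NullMixture) -> "BivariateNullSpec":
        return cls(rho=rho_shared(design), mixture=mixture)


def marginal_tail(z_j, sigma2: float):
    """lambda_sigma2(z_j) = P(|Y| > z_j) for Y ~ N(0, 1 + sigma^2)."""
    z_j = np.abs(np.asarray(z_j, float))
    return np.minimum(2.0 * norm.sf(z_j / np.sqrt(1.0 + sigma2)), 1.0)


def tail_prob(z_i, z_j, rho: float, sigma2: float = 0.0):
    """Lambda_(rho, sigma2)(z_i, z_j) = P(|X| > z_i, |Y| > z_j).

    (X, Y) is centred bivariate normal with covariance
    [[1, rho], [rho, 1 + sigma^2]].  The second coordinate is rescaled to
    unit variance (effective correlation rho / sqrt(1 + sigma^2)) and the
    quadrant decomposition evaluated by the tail-stable bivariate normal
    routine.  Exactly factorises at rho = 0.
    """
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    z_i = np.abs(np.asarray(z_i, float))
    z_j = np.abs(np.asarray(z_j, float))
    s = np.sqrt(1.0 + sigma2)
    if rho == 0.0:
        return np.minimum(2.0 * norm.sf(z_i), 1.0) * np.minimum(
            2.0 * norm.sf(z_j / s), 1.0
        )
    return both_tails_exceed(z_i, z_j / s, rho / s)


def _check_p(p, name, allow_one=True):
    p = np.asarray(p, float)
    hi_ok = (p <= 1.0) if allow_one else (p < 1.0)
    if not np.all((p > 0.0) & hi_ok):
        raise ValueError(f"{name} must lie in (0, 1{']' if allow_one else ')'}")
    return p


def expected_quantile_cum(p_i, p_j, spec: BivariateNullSpec):
    """Pr(P_i <= p_i | P_j <= p_j, H0_i) under the shared-control null.

    Vectorised over (p_i, p_j).  Equals p_i exactly when rho = 0 or
    p_j = 1 (independence / vacuous conditioning).
    """
    p_i = _check_p(p_i, "p_i")
    p_j = _check_p(p_j, "p_j")
    rho = spec.rho
    if rho == 0.0:
        return np.broadcast_arrays(p_i, p_j)[0].copy()
    pi0, sigma2 = spec.mixture.pi0, spec.mixture.sigma2
    z_i = p_to_z(p_i)
    z_j = p_to_z(p_j)
    num = (pi0 * tail_prob(z_i, z_j, rho, 0.0)
           + (1.0 - pi0) * tail_prob(z_i, z_j, rho, sigma2))
    den = (pi0 * marginal_tail(z_j, 0.0)
           + (1.0 - pi0) * marginal_tail(z_j, sigma2))
    return np.clip(num / den, 0.0, 1.0)


def expected_quantile_point(p_i, p_j, spec: BivariateNullSpec):
    """Pr(P_i <= p_i | P_j = p_j, H0_i): the partial-derivative version.

    For mixture component k with Z_j variance v_k in {1, 1 + sigma^2},
    the conditional of Z_i given Z_j = z_j is normal with mean
    rho z_j / v_k and variance 1 - rho^2 / v_k; the component weights are
    the Z_j marginal densities.  Conditioning is on the magnitude
    |Z_j| = z_j; by symmetry of the centred model the two signed
    conditionals give equal two-sided tail probabilities, so a single
    evaluation at +z_j suffices.
    """
    p_i = _check_p(p_i, "p_i")
    p_j = _check_p(p_j, "p_j")  # p_j = 1 maps to z_j = 0, still valid
    rho = spec.rho
    pi0, sigma2 = spec.mixture.pi0, spec.mixture.sigma2
    z_i = p_to_z(p_i)
    z_j = p_to_z(p_j)

    if rho == 0.0:
        return np.broadcast_arrays(p_i, p_j)[0].copy()

    def comp_tail(v):
        mean = rho * z_j / v
        sd = np.sqrt(1.0 - rho * rho / v)
        # P(|X| >= z_i) for X ~ N(mean, sd^2)
        return norm.sf((z_i - mean) / sd) + norm.cdf((-z_i - mean) / sd)

    w0 = pi0 * norm.pdf(z_j)
    w1 = (1.0 - pi0) * norm.pdf(z_j, scale=np.sqrt(1.0 + sigma2))
    num = w0 * comp_tail(1.0) + w1 * comp_tail(1.0 + sigma2)
    return np.clip(num / (w0 + w1), 0.0, 1.0)


def expected_quantile_cum_numeric(p_i, p_j, rho: float,
                                  eta_grid, eta_density,
                                  point_mass0: float = 0.0):
    """Expected quantile for an arbitrary tabulated effect-size density.

    Evaluates the defining ratio by trapezoidal quadrature over the
    latent effect eta:

        num = pm0 * P_0(...) + (1 - pm0) * int P_eta(...) f(eta) d eta

    where P_eta uses (Z_i, Z_j) ~ N((0, eta), [[1, rho], [rho, 1]]).
    ``point_mass0`` is the probability mass placed exactly at eta = 0 (the
    null spike); ``eta_density`` is the density of the continuous
    component on ``eta_grid`` and is renormalised to integrate to 1.

    With the fitted mixture discretised on a fine grid this agrees with
    ``expected_quantile_cum``; it exists so that heavier- or
    lighter-tailed effect distributions can be handled without the
    normality assumption.
    """
    import logging

    p_i = _check_p(p_i, "p_i")
    p_j = _check_p(p_j, "p_j")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if not (0.0 <= point_mass0 <= 1.0):
        raise ValueError("point_mass0 must be in [0, 1]")
    eta_grid = np.asarray(eta_grid, float)
    eta_density = np.asarray(eta_density, float)
    if np.any(eta_density < 0):
        raise ValueError("eta_density must be non-negative")
    if eta_grid.size < 51:
        logging.getLogger(__name__).warning(
            "eta grid has only %d points; quadrature may be coarse",
            eta_grid.size,
        )

    # trapezoid weights, renormalised so the continuous part has mass 1
    w = np.zeros_like(eta_grid)
    if eta_grid.size > 1:
        d = np.diff(eta_grid)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
    w = w * eta_density
    tot = w.sum()
    if tot > 0:
        w = w / tot
    cont_mass = 1.0 - point_mass0

    z_i = np.atleast_1d(p_to_z(p_i))
    z_j = np.atleast_1d(p_to_z(p_j))
    z_i, z_j = np.broadcast_arrays(z_i, z_j)

    # joint tail and Z_j marginal tail, integrated over eta
    joint0 = both_tails_exceed(z_i, z_j, rho)
    marg0 = np.minimum(2.0 * norm.sf(z_j), 1.0)
    # shifted evaluations: shape (n_points, n_eta)
    joint_eta = both_tails_exceed_shifted(
        z_i[..., None], z_j[..., None], rho, eta_grid
    )
    marg_eta = (norm.sf(z_j[..., None] - eta_grid)
                + norm.sf(z_j[..., None] + eta_grid))
    num = point_mass0 * joint0 + cont_mass * (joint_eta * w).sum(axis=-1)
    den = point_mass0 * marg0 + cont_mass * (marg_eta * w).sum(axis=-1)
    out = np.clip(num / den, 0.0, 1.0)
    return out if np.asarray(p_i).shape or np.asarray(p_j).shape else float(out[0])


def discretise_normal_effects(sigma: float, n: int = 801, span: float = 6.0):
    """Convenience grid + density for a N(0, sigma^2) effect component."""
    grid = np.linspace(-span * sigma, span * sigma, n)
    return grid, norm.pdf(grid, scale=sigma)
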