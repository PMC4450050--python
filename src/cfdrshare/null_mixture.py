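"""Two-component mixture model for latent conditional-phenotype effects.

The true standardised effect H of a SNP on the conditional phenotype is
modelled as a point mass at 0 with probability pi0 and N(0, sigma^2)
otherwise.  With the observation model Z | H = eta ~ N(eta, 1), the
marginal of the observed Z score is

    Z ~ N(0, 1)           with probability pi0
        N(0, 1 + sigma^2) with probability 1 - pi0.

Both components are symmetric about zero, so |Z| (equivalently Z^2) is
sufficient and signed or unsigned inputs give identical fits.  The
parameters are estimated by expectation-maximisation on the marginal
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

#: lower bound on the fitted sigma^2, keeping the expected-quantile
#: integrals well-conditioned; a fit at the floor is flagged
SIGMA2_FLOOR = 1e-2

TOL = 1e-8
MAX_ITER = 10_000


@dataclass
class NullMixture:
    """Fitted (pi0, sigma^2) mixture for conditional-phenotype effects."""

    pi0: float
    sigma2: float
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    at_floor: bool = False
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def degenerate(self) -> bool:
        """True when the non-null component is not identifiable.

        Either sigma^2 was pinned at its floor, or the excess variance
        the component contributes, (1 - pi0) sigma^2, is so small that
        the mixture is indistinguishable from a pure standard normal (a
        flat likelihood ridge on which EM stalls).
        """
        return self.at_floor or (1.0 - self.pi0) * self.sigma2 < 0.02

    def to_dict(self) -> dict:
        return {
            "pi0": self.pi0,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "at_floor": self.at_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullMixture":
        return cls(
            pi0=float(d["pi0"]),
            sigma2=float(d["sigma2"]),
            loglik=float(d.get("loglik", float("nan"))),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", True)),
            at_floor=bool(d.get("at_floor", False)),
        )


def loglik(z, pi0: float, sigma2: float) -> float:
    """Marginal log-likelihood of the two-component model."""
    z = np.asarray(z, float)
    dens = pi0 * norm.pdf(z) + (1.0 - pi0) * norm.pdf(z, scale=np.sqrt(1.0 + sigma2))
    return float(np.sum(np.log(dens)))


def fit_em(z, tol: float = TOL, max_iter: int = MAX_ITER) -> NullMixture:
    """Fit (pi0, sigma^2) to observed conditional Z scores by EM.

    Parameters
    ----------
    z
        Signed or unsigned Z scores, n >= 100.
    tol
        Convergence threshold on the relative log-likelihood change.

    Notes
    -----
    Initialisation is pi0 = 0.9 and sigma^2 = max(E[z^2] - 1, 0.5) (the
    symmetric model has mean zero, so the second moment about zero is
    the right scale and keeps the fit identical for signed and unsigned
    input), which starts in the basin matching GWAS-scale data and away
    from the degenerate sigma^2 -> 0 boundary.  If the M-step pins
    sigma^2 at its floor the data carry no evidence of a non-null
    component and the fit is flagged ``at_floor``; see also
    ``NullMixture.degenerate``.
    """
    z = np.asarray(z, float).ravel()
    if z.size < 100:
        raise ValueError(f"need >= 100 observations, got {z.size}")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z scores")

    z2 = z * z
    pi0 = 0.9
    sigma2 = max(float(np.mean(z2)) - 1.0, 0.5)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibility of the null component given z^2
        v1 = 1.0 + sigma2
        log_d0 = np.log(pi0) - 0.5 * z2
        log_d1 = np.log1p(-pi0) - 0.5 * z2 / v1 - 0.5 * np.log(v1)
        m = np.maximum(log_d0, log_d1)
        d0 = np.exp(log_d0 - m)
        d1 = np.exp(log_d1 - m)
        tot = d0 + d1
        gamma0 = d0 / tot
        ll = float(np.sum(np.log(tot) + m) - 0.5 * z2.size * np.log(2 * np.pi))
        trace.append(ll)

        # M-step
        w1 = 1.0 - gamma0
        s1 = float(np.sum(w1))
        pi0_new = float(np.mean(gamma0))
        if s1 > 0:
            sigma2_new = max(float(np.sum(w1 * z2) / s1) - 1.0, SIGMA2_FLOOR)
        else:
            sigma2_new = SIGMA2_FLOOR
        pi0_new = min(max(pi0_new, 0.0), 1.0 - 1e-12)

        if prev > -np.inf and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
        pi0, sigma2 = pi0_new, sigma2_new

    return NullMixture(
        pi0=pi0,
        sigma2=sigma2,
        loglik=trace[-1],
        n_iter=it,
        converged=converged,
        at_floor=bool(sigma2 <= SIGMA2_FLOOR * (1 + 1e-12)),
        loglik_trace=trace,
    )
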