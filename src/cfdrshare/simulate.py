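"""Synthetic GWAS summary statistics with the exact model structure.

Two simulators:

* ``simulate_pair`` draws per-SNP latent effects from the two-component
  mixture for each phenotype (with configurable overlap of non-null
  status, i.e. pleiotropy) and then observed Z scores from the bivariate
  normal with the shared-control correlation rho.  This is the model the
  estimators assume, so it serves as the ground-truth test bed.

* ``simulate_genotype_studies`` works one level lower: it samples
  binomial allele counts for two case groups, unique control groups and
  a shared control group, and computes each study's allele-frequency
  difference Z with its full control pool.  It is the independent oracle
  for the asymptotic correlation formula, which never sees genotypes.

Reproducibility: a root seed spawns one substream per fixed-size block of
SNPs, so results are bit-reproducible and enlarging ``n_snps`` does not
perturb earlier SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_design import StudyPairDesign, z_to_p
from .shared_control import rho_shared

_BLOCK = 8192


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated phenotype pair.

    Defaults mirror the reference scenario used throughout the tests:
    20,000 SNPs, null proportion 0.9 and non-null effect SD 3 for the
    conditional phenotype (the magnitudes seen in real immune-disease
    data), principal phenotype all-null, and a half-shared control
    design giving rho = 0.5.
    """

    n_snps: int = 20_000
    pi0_i: float = 1.0
    pi0_j: float = 0.9
    sigma_i: float = 3.0
    sigma_j: float = 3.0
    #: P(non-null for principal | non-null for conditional)
    overlap: float = 0.0
    rho: float | None = 0.5
    design: StudyPairDesign | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("pi0_i", "pi0_j", "overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rho is None and self.design is None:
            raise ValueError("either rho or design must be given")
        # conditional non-null probabilities must be consistent with the
        # marginal pi0_i: P(nonnull_i) = overlap * (1 - pi0_j) + q * pi0_j
        q = self._q_nonnull_i_given_null_j
        if not (-1e-12 <= q <= 1.0 + 1e-12):
            raise ValueError(
                "inconsistent (pi0_i, pi0_j, overlap): implied "
                f"P(non-null i | null j) = {q:.4f} outside [0, 1]"
            )

    @property
    def _q_nonnull_i_given_null_j(self) -> float:
        if self.pi0_j == 0.0:
            return 0.0
        return ((1.0 - self.pi0_i) - (1.0 - self.pi0_j) * self.overlap) / self.pi0_j

    @property
    def rho_effective(self) -> float:
        return rho_shared(self.design) if self.rho is None else self.rho


@dataclass(frozen=True)
class SimulationEvaluation:
    """False discoveries V, total discoveries R, proportion Q = V/R."""

    v: int
    r: int
    q: float = field(init=False)

    def __post_init__(self):
        if not (0 <= self.v <= self.r):
            raise ValueError("need 0 <= v <= r")
        object.__setattr__(self, "q", self.v / self.r if self.r else 0.0)


def simulate_pair(config: SimulationConfig) -> pd.DataFrame:
    """Draw one pair of summary-statistic series plus true labels.

    Returns a table with ``snp_id, chrom, pos, p_i, p_j, z_i, z_j``
    (|Z| magnitudes consistent with the p values), the signed scores
    ``z_i_signed, z_j_signed``, latent effects ``eta_i, eta_j`` and
    boolean labels ``nonnull_i, nonnull_j``.
    """
    n = config.n_snps
    rho = config.rho_effective
    q = min(max(config._q_nonnull_i_given_null_j, 0.0), 1.0)
    root = np.random.SeedSequence(config.seed)

    cols = {k: np.empty(n) for k in
            ("eta_i", "eta_j", "zi", "zj")}
    nonnull_i = np.empty(n, bool)
    nonnull_j = np.empty(n, bool)
    for b0 in range(0, n, _BLOCK):
        block = min(_BLOCK, n - b0)
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(b0 // _BLOCK,))
        )
        # fixed draw layout per block: status uniforms, effect normals,
        # then the bivariate noise
        u_j = rng.uniform(size=_BLOCK)[:block]
        u_i = rng.uniform(size=_BLOCK)[:block]
        g_j = rng.standard_normal(_BLOCK)[:block]
        g_i = rng.standard_normal(_BLOCK)[:block]
        e1 = rng.standard_normal(_BLOCK)[:block]
        e2 = rng.standard_normal(_BLOCK)[:block]

        nn_j = u_j >= config.pi0_j
        p_nn_i = np.where(nn_j, config.overlap, q)
        nn_i = u_i < p_nn_i
        eta_j = np.where(nn_j, config.sigma_j * g_j, 0.0)
        eta_i = np.where(nn_i, config.sigma_i * g_i, 0.0)
        zi = eta_i + e1
        zj = eta_j + rho * e1 + np.sqrt(1.0 - rho * rho) * e2

        sl = slice(b0, b0 + block)
        nonnull_i[sl], nonnull_j[sl] = nn_i, nn_j
        cols["eta_i"][sl], cols["eta_j"][sl] = eta_i, eta_j
        cols["zi"][sl], cols["zj"][sl] = zi, zj

    return pd.DataFrame({
        "snp_id": [f"snp{k}" for k in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1),
        "p_i": z_to_p(cols["zi"]),
        "p_j": z_to_p(cols["zj"]),
        "z_i": np.abs(cols["zi"]),
        "z_j": np.abs(cols["zj"]),
        "z_i_signed": cols["zi"],
        "z_j_signed": cols["zj"],
        "eta_i": cols["eta_i"],
        "eta_j": cols["eta_j"],
        "nonnull_i": nonnull_i,
        "nonnull_j": nonnull_j,
    })


def simulate_genotype_studies(n_snps: int, maf_range: tuple[float, float],
                              design: StudyPairDesign, seed: int = 0,
                              pi0: float = 1.0, shift_sd: float = 0.0):
    """Allele-count-level Monte Carlo of two studies sharing controls.

    Per SNP a population MAF is drawn uniformly in ``maf_range`` and
    binomial allele counts are sampled for each case group, each unique
    control group and the shared control group; each study's Z is the
    allele-frequency-difference test using its own cases against its
    full (unique + shared) control pool.  With probability 1 - pi0 a SNP
    is non-null: both case groups' allele frequencies are shifted by a
    common N(0, shift_sd^2) draw (a pleiotropic effect).

    Returns a DataFrame with ``z_i, z_j, maf, nonnull``.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    sizes = (design.n_cases_i, design.n_cases_j,
             design.n_controls_unique_i, design.n_controls_unique_j,
             design.n_controls_shared)
    if any(0 < s < 10 for s in sizes):
        raise ValueError("all non-empty groups must have >= 10 subjects")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    f = rng.uniform(lo, hi, n_snps)
    nonnull = rng.uniform(size=n_snps) >= pi0
    delta = np.where(nonnull, rng.normal(0.0, shift_sd, n_snps), 0.0)
    f_case = np.clip(f + delta, 1e-4, 1.0 - 1e-4)

    def freq(n_subjects, prob):
        if n_subjects == 0:
            return np.zeros(n_snps), 0
        counts = rng.binomial(2 * n_subjects, prob)
        return counts / (2.0 * n_subjects), n_subjects

    fc_i, n_ci = freq(design.n_cases_i, f_case)
    fc_j, n_cj = freq(design.n_cases_j, f_case)
    fu_i, n_ui = freq(design.n_controls_unique_i, f)
    fu_j, n_uj = freq(design.n_controls_unique_j, f)
    fs, n_s = freq(design.n_controls_shared, f)

    def study_z(f_cases, n_cases, f_uni, n_uni):
        n_ctl = n_uni + n_s
        f_ctl = (f_uni * n_uni + fs * n_s) / n_ctl
        pooled = (f_cases * n_cases + f_ctl * n_ctl) / (n_cases + n_ctl)
        se = np.sqrt(pooled * (1.0 - pooled)
                     * (1.0 / (2 * n_cases) + 1.0 / (2 * n_ctl)))
        return (f_cases - f_ctl) / se

    return pd.DataFrame({
        "z_i": study_z(fc_i, n_ci, fu_i, n_ui),
        "z_j": study_z(fc_j, n_cj, fu_j, n_uj),
        "maf": f,
        "nonnull": nonnull,
    })


def evaluate_fdr(declared_ids, labels: pd.Series) -> SimulationEvaluation:
    """Count false and total discoveries against known labels.

    ``labels`` maps snp_id to the true non-null indicator; every declared
    id must be present.
    """
    declared = pd.Index(declared_ids)
    unknown = declared.difference(labels.index)
    if len(unknown):
        raise ValueError(f"unknown snp_id in declared set: {unknown[0]!r}")
    if len(declared) == 0:
        return SimulationEvaluation(v=0, r=0)
    hits = labels.loc[declared]
    return SimulationEvaluation(v=int((~hits.astype(bool)).sum()),
                                r=int(len(declared)))
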