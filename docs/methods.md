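# Methods

## Model

For each SNP and each phenotype pair (principal *i*, conditional *j*) the
observed two-sided association Z magnitudes arise from

    (Z_i, Z_j) | eta  ~  N((eta_i, eta_j), [[1, rho], [rho, 1]])

where `eta` are latent standardised true effects and `rho` is the
correlation of the noise induced by shared control subjects. Under the
principal null (`eta_i = 0`) and the two-component effect model for the
conditional phenotype,

    H = eta_j  ~  0 with prob. pi0,   N(0, sigma^2) with prob. 1 - pi0,

the marginal joint law of (Z_i, Z_j) given the principal null is the
two-component bivariate normal with covariances [[1, rho], [rho, 1]] and
[[1, rho], [rho, 1 + sigma^2]]. Everything downstream — the expected
quantile, the cFDR numerator, the null-mass function v(·) — is computed
from these two components.

Assumptions worth stating plainly:

* **Two-sided symmetry.** Only |Z| (equivalently p) enters any formula;
  effect signs are never needed and are not stored.
* **Exchangeable SNPs, no LD in estimation.** The mixture fit and the
  empirical quantile counts treat SNPs as exchangeable. LD enters only
  through the final greedy pruning step, which consumes a user-supplied
  r² table.
* **Asymptotic rho.** The shared-control correlation formula is a
  large-sample result; it is accurate for group sizes above ~100
  (cross-checked in the test suite against an allele-count-level
  simulation of the full design, agreement within 0.02).
* **Normal non-null component.** A numeric path
  (`expected_quantile_cum_numeric`) accepts an arbitrary tabulated effect
  density instead; with a heavy-tailed (scaled t, 3 df) truth the normal
  approximation fitted by EM stays within ~25% relative error of the exact
  expected quantile in the deep tail, without a uniform conservative or
  anti-conservative sign (see the robustness test).

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `pi0`, `sigma2` | fitted | mixture of conditional effects; EM on all harmonised SNPs |
| `rho` | from design | shared-control null correlation; 0 iff no shared controls |
| p floor | 1e-300 | p = 0 inputs are clamped (estimators divide by p-derived tails) |
| EM `tol` | 1e-8 | relative log-likelihood change at convergence |
| EM `max_iter` | 10 000 | ample for the ~30-iteration typical run |
| `sigma2` floor | 1e-2 | keeps the tail integrals conditioned; floor hit ⇒ flagged |
| EM init | pi0 = 0.9, sigma² = max(E[z²]−1, 0.5) | GWAS-scale basin, away from the degenerate boundary, sign-invariant |
| GW threshold | 5e-8 | genome-wide significance convention the FDR cutoffs are calibrated to |
| region grid | 200 log-spaced p_j values | boundary resolution; bisection tol 1e-3 in log10 p_i |
| `r2_max` | 0.1 | LD pruning threshold |
| edge threshold | 4e-7 | conditional-cutoff value at which a pleiotropy-network edge is drawn |
| QC | call rate ≥ 0.99, MAF ≥ 0.02, \|HWE Z\| ≤ 5, MHC band chr6:24.5–34.8 Mb excluded | standard ImmunoChip-era filters; all overridable |

## Estimators and procedures

**uFDR.** `ufdr(p) = p / (#{p_k <= p}/N)`, clamped at 1; conservative
because Pr(H0) is set to 1. Declaring at `ufdr <= alpha` is the
Benjamini–Hochberg-type rule whose expected FDR is below alpha (verified
by simulation in the test suite). For threshold extraction the estimate is
made monotone in p by a running maximum over sorted p, so the
"least gamma equivalent to p <= 5e-8" definition is well-posed under
sampling noise.

**cFDR.** The numerator is the shared-control expected quantile; the
denominator the empirical conditional quantile among the N1 SNPs with
p_jk <= p_j. Counting is inclusive on both coordinates and the query point
always counts itself, so denominators are never zero — this also gives the
region-boundary bisection a bracketing interval below the data support.
The per-pair significance threshold alpha is the largest cfdr among SNPs
with p_i <= 5e-8, capped at the uFDR threshold beta so that SNPs with
conditional p near 1 cannot be declared more leniently than by p value
alone; the declared set explicitly includes every SNP with ufdr <= beta.

**Region bound.** The boundary of L is traced by bisection on a log-spaced
p_j grid and forced monotone non-increasing in p_j by a running maximum
taken from large p_j downwards — exactly the effective boundary of the
union of rectangles, robust to non-monotonicity of the empirical cfdr.
v(·) defaults to null-model mass (N times the two-component joint tail),
with `mode="area"` available for the uniform-independence approximation;
the two coincide at rho = 0, pi0 = 1, which is the analytically tested
limit. The bound alpha* · v(L)/v(M*) uses alpha* re-evaluated at the
chosen vertex rather than assumed equal to alpha.

**Multiple testing across conditional phenotypes.** M_eff =
1 + k(1 − Var(λ)/k) from the eigenvalues of the Spearman rank-correlation
matrix of the k cfdr columns (sample variance, divisor k−1: perfectly
rank-correlated columns then give Var = k and M_eff = 1 exactly). Which
rows count as "potentially non-null" is the caller's choice; restricting
to rows with small best-cfdr is recommended so the correlation reflects
the region where declarations happen. The combined bound is
M_eff · Σ c_j n_j / Σ n_j.

**TDT calibration.** For meta-analyses mixing family (TDT) and
case-control data, the variance identity Var(log OR) =
(n0+n1)/(n0 n1 f(1−f)) is solved for the case count using the median of
se² f(1−f) over SNPs with p > 0.5.

## Numerical choices

* **Bivariate normal tails.** Upper-quadrant probabilities use the
  standard Drezner–Wesolowsky/Genz arcsine-integral algorithm (24-point
  Gauss–Legendre, separate expansion for |r| > 0.925), vectorised in
  numpy. The result has the form Φ(−h)Φ(−k) + small correction, so the
  far joint tails needed at genome-wide p values keep full relative
  accuracy; a CDF-difference decomposition would cancel catastrophically
  there. Absolute accuracy ≈ 1e-15, cross-checked against scipy's mvndst
  integration. The sigma²-inflated component is handled by rescaling the
  second coordinate to unit variance (effective correlation ρ/√(1+σ²)).
* **rho = 0 short-circuit.** Independence factorises the expected quantile
  to exactly p_i (down to p = 1e-300), as the split-control estimator
  requires.
* **Point expected quantile.** Conditioning is on the magnitude |Z_j|;
  by symmetry the two signed conditionals contribute equal two-sided
  tails, so one evaluation at +z_j is used. The non-null component's
  conditional is N(ρ z_j/(1+σ²), 1 − ρ²/(1+σ²)); this choice is pinned
  down by a quadrature-consistency test that reproduces the cumulative
  form to ~1e-6.
* **EM degeneracy.** On data with no real non-null component the
  likelihood is flat along the null boundary and EM stalls there; a fit
  is flagged `degenerate` when sigma² sits at its floor or the excess
  variance (1−pi0)·sigma² is below 0.02, i.e. the component is
  indistinguishable from the null.
* **Numeric effect-density path.** Trapezoidal quadrature over the
  tabulated density (renormalised), with the null point mass handled
  exactly; a grid under 51 points triggers a warning.
* **Determinism.** The simulator derives one substream per 8192-SNP block
  from the root seed, so runs are bit-reproducible and enlarging `n_snps`
  leaves earlier SNPs unchanged.

## What the simulator does and does not emulate

`simulate_pair` draws from exactly the model above: mixture effects,
optional label-level overlap between the phenotypes' non-null sets
(independent effect magnitudes — no joint effect-size law is imposed),
and the bivariate noise correlation. `simulate_genotype_studies` goes one
level deeper (binomial allele counts per case/control/shared-control
group, allele-frequency-difference Z with the pooled control group) and
serves as the independent oracle for the correlation formula; it can also
superimpose a shared case-frequency shift to study power. Neither
simulator generates LD between SNPs, genotyping error, population
stratification, or non-normal effect distributions — so passing tests
demonstrate correctness of the estimators *under the assumed model*, and
robustness only along the axes explicitly varied (effect-tail shape via
the numeric density path). Reference conditions used throughout the tests:
20,000 SNPs, conditional null proportion 0.9, non-null SD 3, rho = 0.5 —
the magnitudes reported for real immune-mediated-disease data.

Problem sizes in the test and acceptance runs (20,000-SNP tables, 10⁶-pair
Monte Carlo oracles, 50–200 simulation replicates) were chosen as the
smallest at which the Monte Carlo error is comfortably below the asserted
tolerances.

## Known limitations

* Only shared **controls** are modelled; shared or related cases are out
  of scope.
* The cfdr estimator is conservative (Pr(H0|P_j ≤ p_j) set to 1); with
  strong genuine pleiotropy the realised FDR is typically far below the
  nominal bound.
* The empirical cfdr is a step function; the region boundary inherits
  bisection tolerance (1e-3 in log10 p_i) and grid resolution.
* The expected-quantile adjustment assumes genomic control has already
  made null p values globally uniform; the mixture is fitted after GC.
* M_eff is a heuristic correction; it reduces multiple-testing inflation
  across conditional phenotypes but carries no finite-sample guarantee.
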