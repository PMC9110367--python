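# Methods

## Model and scope

The package treats a parcellated BOLD recording as an N × T matrix and
studies the edge-centric measures derived from its z-scored form together
with their expectations under the *static Gaussian null*: frames drawn
i.i.d. from N(0, **R**), with **R** the node correlation (nFC) matrix.
The null preserves the full spatial second-order structure and destroys
all temporal structure; every quantity it predicts is therefore a function
of **R** alone, usually through the eigendecomposition
**R** = **U** diag(λ₁ ≥ … ≥ λ_N) **U**ᵀ. The point of the construction is
diagnostic: any empirical edge-centric finding reproduced by this null
carries no information beyond the static nFC.

Derivations implemented analytically:

- eFC prediction via the Gaussian factorisation of fourth moments
  (Isserlis), entry `(r_jk r_lm + r_jl r_km + r_jm r_kl)` normalised by
  `√(1+2r²)` factors. The joint-cumulant bookkeeping behind it appears
  only as test properties, not as runtime symbols.
- RSS as a quadratic form: `RSS_all(t) = ‖z(t)‖² = Σ_i λ_i⟨u_i, w(t)⟩²`
  with `w = R^{−1/2}z` whitened, hence a generalised χ²: a sum of N
  independent Gamma(1/2, √2λ_i) components (upper-triangular calibration),
  mean N/√2, variance Σλ_i², MGF `Π(1−√2λ_i s)^{−1/2}`, subexponential
  tails. Squared cosines against eigenvectors sum to one per frame, giving
  the sharp bound `RSS ≤ λ_max‖w‖²/√2` attained at `w ∥ u₁`, where the
  frame FC estimate degenerates to `λ₁u₁u₁ᵀ`.
- Arcsine law for binary edges, `p_jk = ½ + arcsin(r_jk)/π`, by the
  bivariate-normal orthant probability.
- Edge distances in correlation units, node distances `√(1−r_ij)`, and
  conditional CAP seed maps `E[Z | Z_k = z*] = z* R_k`.

## Conventions

**Z-scoring and correlation.** Rows are z-scored with the population
standard deviation (divide by T). Under this convention the time mean of
an edge series equals the Pearson correlation exactly, the mean outer
product of all frames *is* the nFC, and every reconstruction identity in
the test suite holds to machine precision. Mixing a population z-score
with a 1/(T−1) correlation denominator would break the unit diagonal of
**R** by a factor T/(T−1); since the Pearson correlation itself is
denominator-free, nothing in the analytic theory depends on this choice,
and the uniform population convention is used throughout (recorded on
`BoldMatrix`).

**RSS conventions.** The published RSS sums squared cofluctuations over
the E = N(N−1)/2 unordered pairs; including all N² ordered pairs gives
exactly `‖z(t)‖²`. The Gamma-mixture law is exact for the all-pairs form
and approximates the upper-triangular form through
`RSS ≈ ‖z‖²/√2`, whose relative error is governed by the kurtosis ratio
`(Σ_i mean z_i⁴)/(mean ‖z‖⁴)` ≤ 3/N for Gaussian data
(`kurtosis_ratio_check`). Both conventions are first-class: distribution
objects and RSS series carry a convention tag and `ks_test_rss` refuses
to mix them. Exact-law significance tests (type-I calibration, two-route
equivalence) use `all_pairs`; the `upper_triangular` default mirrors the
published measure.

**Edge ordering and eigenvector signs.** Edges are lexicographic (i < j);
eigenvectors are sign-fixed by making the largest-magnitude component
positive (ties to the lowest index). Both are pure determinism
conventions — the mathematics is invariant.

## Null RSS distribution: numerics

The CDF of a sum of independent Gammas has no elementary form. The
primary evaluator is the Moschopoulos/Ruben series: the law is an infinite
mixture of Gamma(N/2 + k, β) distributions with β = 0.90625·min θ_i and
nonnegative masses summing to one, so the retained mass bounds the
truncation error rigorously (mass tolerance 1e−9, validated against the
Gamma closed form at a single component to 5e−11 and against direct
characteristic-function inversion to 3e−10). When the series underflows
(extreme eigenvalue spread), evaluation falls back to adaptive quadrature
of Imhof's inversion integrand (absolute tolerance 1e−6) and, as a last
resort, to Monte Carlo with a reported standard error. Bulk evaluation
(KS testing) uses a cached monotone PCHIP interpolant of the CDF on a
grid extending to a Chernoff-bounded upper tail point; quantiles invert
the CDF by Brent bracketing. Eigenvalues below 1e−10 are dropped (their
Gamma components are degenerate), and the same floor defines the
pseudo-inverse used for whitening.

**KS testing.** `ks_test_rss` computes the exact statistic against the
evaluated null CDF and the asymptotic (Kolmogorov) two-sided p-value,
appropriate in the T ≈ 1200 regime; a warning is issued below T = 10.
With a subject count, the decision flag is Bonferroni-adjusted at family
level 0.05. Two calibration caveats are documented deliberately:
(i) the p-value assumes independent frames — on strongly autocorrelated
series (e.g. AR(1) with a = 0.9) the statistic is inflated even though the
RSS *marginal* law is unchanged, so rejections there reflect the violated
independence assumption, not a wrong marginal; (ii) z-scoring pins each
row's sample variance, so RSS series computed from data-standardised
surrogates are slightly conservative against the fixed-R null. Type-I
calibration is therefore assessed on draws from the null law itself,
where the measured rejection rate sits at the nominal 5%.

## Synthetic data

The generator realises exactly the process the null hypothesis assumes:
frames `R^{1/2}g(t)` with standard-normal `g`, using the spectral square
root `UΛ^{1/2}Uᵀ` so whitening round-trips exactly. Correlation builders
cover the identity (independent nodes), modular block matrices (planted
functional modules; with uncoupled blocks the leading eigenvalue of a
block of size m at correlation ρ is 1 + (m−1)ρ, the mechanism by which
larger modules produce larger cofluctuation events), a random-factor
model for generic dense structure, and explicit user matrices (PSD repair
clips eigenvalues in (−1e−8, 0) and renormalises; anything more negative
is rejected). The AR(1) contrast scales innovations by √(1−a²) so its
stationary spatial covariance stays equal to **R**, isolating temporal
order as the only departure from the null. All sampling flows through a
single seeded numpy Generator per spec; identical specs give
bit-identical surrogates.

What the generator does *not* emulate: haemodynamics, scanner noise,
physiological confounds, non-Gaussian marginals, or realistic
autocorrelation spectra. Passing tests on these surrogates demonstrates
the internal consistency of the analytic theory and the correctness of
the implementation — not that real BOLD data satisfy the null (on real
data the same machinery is the hypothesis test, not a foregone
conclusion).

## Default parameters

| parameter | default | rationale |
|---|---|---|
| z-score denominator | population (T) | exact identities (above) |
| RSS convention | upper_triangular | matches the published measure |
| communities k | 10 | conventional choice for cortical eFC |
| k-means restarts | 20 | inertia-stable on blocky eFC inputs |
| CDF tolerance | 1e−6 | below any decision threshold used |
| eigenvalue floor | 1e−10 | numerical rank; shared across modules |
| eFC size guard | 2 GiB | E = 19900 needs ~3 GB; predicted node-level quantities are the low-memory path |

Simulation sizes in tests are chosen so each property resolves at 3
standard errors with comfortable margin: T = 10⁶ frames for Monte-Carlo
laws with ±0.0015–0.05 tolerances, T = 10⁵ for convergence-rate checks,
T = 1200 (a typical session length) for frame-sorting and KS behaviour,
N = 10–50 nodes with 2–3 planted modules for structure recovery.

## Design choices on open points

- Frame selection everywhere uses strict descending sort with ties broken
  by frame index (determinism; ties have measure zero under the null).
- Exactly-zero cofluctuations binarise to 0 and are counted in
  `tie_count`, keeping Bernoulli comparisons honest.
- Eigenvector-FC similarity uses `λ_i u_i u_iᵀ`; the unweighted
  alternative gives identical Pearson similarities (scale invariance), so
  the choice is cosmetic.
- Edge distances are computed in correlation units (the (T−1)² raw
  inner-product scale divided out): only relative distances matter for
  clustering and this makes them T-independent.
- The covariance form of the CAP seed-map argument is exercised through
  its proportionality to the seed value in tests rather than exposed as a
  public operation; it has no consumer beyond that explanation.
- Label matching across clustering runs solves the optimal assignment
  problem on the contingency table (greedy matching would make agreement
  depend on label order); consensus labels take the per-edge mode after
  alignment, ties to the lowest label.
- Node-pair similarity counts exclude the two self-columns of the edge
  label matrix (self-edges have no label), normalising by N−2.

## Limitations

- The analytic eFC, distances, and seed maps assume vanishing fourth
  joint cumulants (Gaussianity is sufficient); heavy-tailed or strongly
  nonlinear signals void them quantitatively though often not
  qualitatively.
- The upper-triangular RSS calibration inherits the `≈ ‖z‖²/√2` error at
  small N; monitor `kurtosis_ratio_check` and prefer `all_pairs` when an
  exact law is needed.
- k-means on the eFC is stochastic; only the distance structure, not the
  exact partition, is predicted by the theory.
- Materialising the eFC is O(N⁴) memory; beyond the size guard, use the
  predicted node-level quantities instead.
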