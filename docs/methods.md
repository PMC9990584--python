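# Methods

## Model and parametrization

The power Rayleigh law is taken, throughout, in the form

    F(x; α, β) = 1 − exp(−x^{2β}/α²),      x > 0,  α, β > 0,
    f(x; α, β) = (2β/α²) x^{2β−1} exp(−x^{2β}/α²),

i.e. the density is the exact derivative of the cdf, including the factor 2
that some published variants drop (without it the "density" integrates to ½).
Several published quantities for this model are stated in mutually
inconsistent scale conventions (exponents x^{2β}/α², x^{2β}/(2α²), and a rate
θ·x^{2β}/2 appear side by side); this package derives everything — density,
likelihood, score, Hessian, conditional posterior kernels — from the single
cdf above. Quantities that are invariant to the scale convention (the shape
MLE, the KS distance at the fitted law, P(X₁ < X₂)) are unaffected by this
choice; the scale estimate itself is reported in the α of the cdf above and
is **not** comparable across conventions.

Useful facts: X^{2β} is exponential with rate 1/α²; the quantile function is
x(u) = (α² ln(1/(1−u)))^{1/(2β)}; E X = α^{1/β} Γ(1 + 1/(2β)).

## Joint progressive type-II censoring

Sampling: m lifetimes from population 1 and n from population 2 go on test;
at each of r failure times, Rᵢ survivors are removed uniformly at random from
the pooled survivor set. Uniform removal makes the split (Sᵢ, Tᵢ) of Rᵢ
hypergeometric in the current survivor counts, and that is exactly the law
the likelihood's combinatorial constant C = D₁D₂ normalizes: D₂ is the
product of the hypergeometric ratios with the *post-failure* survivor counts
in the numerators. (A published variant of D₂ leaves the i-th failure in the
counts; that form is not the normalizer of any removal law and is not used.)
Floating-point lifetime ties are broken population 1 first, then by unit
index — deterministic and documented, with probability zero in the model.

The likelihood separates across populations. With w₁ᵢ = hᵢ + sᵢ and
w₂ᵢ = (1 − hᵢ) + tᵢ,

    ℓ = Σ_k { k_fail [ln(2β_k) − 2 ln α_k] + (2β_k − 1) Σᵢ 1{pop k} ln λᵢ
              − Σᵢ w_kᵢ λᵢ^{2β_k} / α_k² },

so the scale maximizer given the shape is closed form,
α̂_k²(β_k) = Σᵢ w_kᵢ λᵢ^{2β_k} / k_fail, and fitting is two bounded 1-D
profile maximizations (Brent, bracket β ∈ [10⁻³, 10³], tolerance 10⁻¹⁰).
The x^{2β} powers are accumulated through log-sum-exp so that large trial
shapes cannot overflow during the bracketed search. A 4-D Newton iteration
is deliberately avoided: at the small effective sample sizes progressive
censoring produces it is fragile, and the profile root is unique where the
model is identified.

Degenerate inputs: a population with zero observed failures is
unidentifiable and fitting raises an error naming it; a profile maximizer
pinned at the bracket edge (typical with a single failure) or an
under/overflowed scale is returned with `converged=False` rather than
silently. Validation of a record against its scheme returns *violation
objects* (identity name plus both sides), not exceptions — published records
that fail their own counting identities remain loadable and are flagged.

## Asymptotic intervals

The observed information is the analytic negative Hessian (block-diagonal
across populations; the cross-population second derivatives vanish
identically). The variance matrix is its exact inverse — a pseudo-inverse is
never substituted; a singular or indefinite information withholds the
variance matrix with a warning. Intervals are θ̂ ± z_{γ/2}·SE with lower
limits truncated at zero. Known limitation: for the scale parameters at
small effective sample sizes (≈10 failures per population) this symmetric
normal interval undercovers noticeably (measured ≈0.85–0.87 at nominal 0.95
for a (20,20,20) design) because the sampling distribution of α̂ is strongly
right-skewed; a log-scale interval would largely repair this but the plain
form is kept as the package's stated construction.

## Bayesian computation

Priors are independent Gamma(aᵢ, bᵢ) (shape/rate) on all four parameters,
default a = 0.02, b = 2 — a heavily right-skewed, small-mean choice kept as
the conventional default for this model. Note its rate term multiplies the
posterior by exp(−2β): for shape values around 2–3 this is a non-negligible
pull toward zero, and it measurably depresses credible-interval coverage for
the shapes (≈0.89–0.91 at nominal 0.95 in the calibration study below).

Sampling is Metropolis–Hastings within Gibbs: per sweep, one normal
random-walk proposal per coordinate in the fixed order
(α₁, α₂, β₁, β₂), accepted by the full-conditional kernel ratio;
nonpositive proposals have zero target density and are rejected, which
preserves the correct stationary law on the positive orthant. Default
proposal scales are the MLE standard errors; the chain starts at the MLE.
Randomness contract: each coordinate consumes one standard normal then one
uniform from a single seeded generator, so runs are bit-reproducible per
seed. Defaults are 10 000 sweeps with the first 1 000 discarded; the
Monte-Carlo harness uses a reduced 2 000/200 profile per replicate, with the
full profile available by configuration.

LINEX point estimates use the standard Bayes rule −(1/c)·ln E[e^{−cθ}],
computed by log-sum-exp; c → 0 recovers the posterior mean, and the c = 10⁻⁴
column agrees with the posterior mean to about c·Var(θ)/2. Credible
intervals are equal-tailed sample percentiles by default; a shortest-
contiguous (HPD) option exists but is not the default.

Correctness cross-checks in the test suite: each coordinate's directly
written conditional kernel differs from the restricted joint kernel by a
constant on a grid (10⁻⁸); and because the posterior factorizes across
populations, the (α₁, β₁) marginal is integrated on a 2-D grid and its mean
compared with the chain within Monte-Carlo error (batch-means SE).

## Monte-Carlo design evaluation

`run_study` repeats generate → fit (+ intervals) → optionally sample the
posterior, and reports MSE, mean interval length, and coverage per
(scheme, parameter, estimator), plus mean realized failure counts per
population. Replicates where a population never fails, or where the profile
fit is unidentifiable, are counted and reported separately and excluded from
estimator averages. `expected_failures_table` estimates the pre-experiment
expected number of population-1 failures and the mean realized count from
independent seed streams — both are Monte-Carlo estimates of the same
expectation (no closed-form approximation is used) — and attaches
P(X₁ < X₂) per truth configuration.

Study conditions used by the calibration tests (chosen once): truth
(α₁, α₂, β₁, β₂) = (0.5, 0.6, 2.5, 2.69); designs (10,10,5) with
R = (15,0,0,0,0), (20,20,20) with R = (20, 0×19), and (30,30,40) with
R = (20, 0×39) — the removal-at-first-failure pattern used consistently
across the three sizes; 500 replicates for MLE-based summaries, 300 for
MCMC-based ones with the reduced chain profile. At these sizes the ML shape
estimators carry a positive median bias of roughly 4–7%, shrinking as the
design grows; the simulated-data studies in the tests demonstrate the
qualitative conclusions (MSEs and interval lengths fall as m, n, r grow;
intervals are near-nominal for shapes, conservative for Bayes scales).

## Stress–strength probability

P(X₁ < X₂) = ∫ f₁(x) S₂(x) dx is evaluated after the probability-integral
substitution u = F₁(x), giving a bounded integrand on (0, 1) for adaptive
quadrature (tolerance 10⁻¹⁰, error estimate checked), and is cross-checked
by seeded inverse-transform Monte Carlo. For the two standard parameter
configurations the quadrature gives 0.61639 and 0.39756. Published
two-decimal values for this pair differ by one unit in the last place
(0.61/0.39); no scale convention reproduces those printed roundings exactly,
so the package reports its own computed values.

## Synthetic data: what it does and does not emulate

The generator draws i.i.d. power Rayleigh lifetimes and applies the exact
uniform-removal censoring mechanism — it is the model, exactly. Passing
calibration tests therefore demonstrates internal consistency of estimator,
sampler, and generator under the assumed law; it says nothing about
robustness to model misspecification, dependence between lines, inspection-
time rounding (the real aircraft data are recorded in whole hours and
contain ties), or non-random withdrawal. The shipped aircraft record
combining the two planes is kept exactly as published even though it fails
its own counting identities (ΣR = 38 ≠ 41, ΣS = 18 ≠ 17) and its failure
times are not derivable from the raw lifetimes; it is loaded with warnings
attached and its fit should be read as an illustration of the pipeline, not
as a reproducible benchmark.
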