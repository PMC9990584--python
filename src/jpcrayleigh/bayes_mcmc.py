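"""Bayesian inference for the JPC power Rayleigh model.

Each of (alpha1, alpha2, beta1, beta2) gets an independent Gamma(a_i, b_i)
prior (shape/rate).  The posterior kernel is the JPC log-likelihood plus
the log prior; none of the four full conditionals is a standard family, so
sampling is Metropolis-Hastings within Gibbs: one normal random-walk
update per coordinate per sweep, in the fixed order (alpha1, alpha2,
beta1, beta2).  Nonpositive proposals have zero target density and are
always rejected, which preserves the correct stationary law on the
positive orthant.

Point estimation: under squared-error loss the Bayes estimate is the
posterior mean; under LINEX loss with constant c it is

    theta_hat_c = -(1/c) * log E[exp(-c * theta)],

computed with a log-sum-exp so large |c| * theta cannot overflow.  As
c -> 0 the LINEX estimate converges to the posterior mean; c > 0
penalizes over-estimation more, c < 0 under-estimation.

Randomness contract: every sweep consumes, per coordinate in order, one
standard normal (the proposal) then one uniform (the accept decision),
all from a single seeded generator — runs are bit-reproducible per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .jpc_scheme import JPCSample
from .joint_mle import PARAM_NAMES, IntervalSet, JointParams

__all__ = [
    "GammaPriors",
    "MCMCConfig",
    "PosteriorDraws",
    "BayesSummary",
    "log_posterior_kernel",
    "log_conditional_kernel",
    "run_mh_gibbs",
    "bayes_point_estimates",
    "credible_intervals",
]


@dataclass(frozen=True)
class GammaPriors:
    """Gamma shape/rate hyperparameters for (alpha1, alpha2, beta1, beta2).

    Defaults a = 0.02, b = 2 for every coordinate (prior mean 0.01,
    variance 0.005) — a diffuse, heavily right-skewed choice.
    """

    a: np.ndarray = field(default_factory=lambda: np.full(4, 0.02))
    b: np.ndarray = field(default_factory=lambda: np.full(4, 2.0))

    def __post_init__(self) -> None:
        a = np.broadcast_to(np.asarray(self.a, dtype=float), (4,)).copy()
        b = np.broadcast_to(np.asarray(self.b, dtype=float), (4,)).copy()
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("gamma hyperparameters must be strictly positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def logpdf(self, theta: np.ndarray) -> float:
        """Unnormalized log prior density, -inf off the positive orthant."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            return -np.inf
        return float(np.sum((self.a - 1.0) * np.log(theta) - self.b * theta))


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length, burn-in, seed and random-walk proposal scales.

    ``proposal_sd`` defaults to the MLE standard errors when left None
    (resolved by :func:`run_mh_gibbs` callers such as the CLI); the
    sampler itself requires explicit scales.
    """

    n_iter: int = 10000
    burn_in: int = 1000
    seed: int | None = None
    proposal_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.proposal_sd is not None:
            sd = np.broadcast_to(
                np.asarray(self.proposal_sd, dtype=float), (4,)
            ).copy()
            if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
                raise ValueError("proposal scales must be positive finite")
            object.__setattr__(self, "proposal_sd", sd)


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained chain (after burn-in) and per-coordinate acceptance rates."""

    draws: np.ndarray  # (n_iter - burn_in, 4), columns in PARAM_NAMES order
    acceptance_rate: np.ndarray
    initial_state: JointParams

    @property
    def n_retained(self) -> int:
        return int(self.draws.shape[0])


@dataclass(frozen=True)
class BayesSummary:
    se_estimate: np.ndarray
    linex_estimates: dict  # c -> 4-vector
    cri: IntervalSet


# ---------------------------------------------------------------------------
# posterior kernels


def _suff(sample: JPCSample):
    loglam = np.log(sample.lam)
    w1 = (sample.h + sample.s).astype(float)
    w2 = ((1 - sample.h) + sample.t).astype(float)
    A1 = float(np.sum(sample.h * loglam))
    A2 = float(np.sum((1 - sample.h) * loglam))
    return loglam, w1, w2, A1, A2


def log_posterior_kernel(
    theta: JointParams | np.ndarray, sample: JPCSample, priors: GammaPriors
) -> float:
    """log posterior up to a theta-free constant; -inf outside (0, inf)^4."""
    vec = theta.as_array() if isinstance(theta, JointParams) else np.asarray(theta, float)
    if np.any(vec <= 0) or not np.all(np.isfinite(vec)):
        return -np.inf
    lp = priors.logpdf(vec)
    from .joint_mle import joint_loglik  # local import avoids cycle at module load

    return float(joint_loglik(JointParams.from_array(vec), sample) + lp)


def log_conditional_kernel(
    index: int, value: float, theta: np.ndarray, sample: JPCSample, priors: GammaPriors
) -> float:
    """Full-conditional log kernel of one coordinate, the others held fixed.

    Written directly from the conditional-density proportionalities (the
    alpha conditionals keep only power-of-alpha and exponential terms, the
    beta conditionals the lam^(2 beta) products), not by restricting the
    joint kernel — the two routes must agree up to an additive constant,
    which the test suite checks on a grid.
    """
    if value <= 0 or not np.isfinite(value):
        return -np.inf
    loglam, w1, w2, A1, A2 = _suff(sample)
    a_pr, b_pr = priors.a[index], priors.b[index]
    th = np.asarray(theta, dtype=float)
    if index == 0:  # alpha1 | rest
        W1 = float(np.sum(w1 * np.exp(2.0 * th[2] * loglam)))
        return (a_pr - 1.0 - 2.0 * sample.m_r) * np.log(value) - b_pr * value - W1 / value**2
    if index == 1:  # alpha2 | rest
        W2 = float(np.sum(w2 * np.exp(2.0 * th[3] * loglam)))
        return (a_pr - 1.0 - 2.0 * sample.n_r) * np.log(value) - b_pr * value - W2 / value**2
    if index == 2:  # beta1 | rest
        W1 = float(np.sum(w1 * np.exp(2.0 * value * loglam)))
        return (
            (sample.m_r + a_pr - 1.0) * np.log(value)
            - b_pr * value
            + 2.0 * value * A1
            - W1 / th[0] ** 2
        )
    if index == 3:  # beta2 | rest
        W2 = float(np.sum(w2 * np.exp(2.0 * value * loglam)))
        return (
            (sample.n_r + a_pr - 1.0) * np.log(value)
            - b_pr * value
            + 2.0 * value * A2
            - W2 / th[1] ** 2
        )
    raise IndexError("coordinate index must be 0..3")


# ---------------------------------------------------------------------------
# sampler


def run_mh_gibbs(
    sample: JPCSample,
    priors: GammaPriors,
    init: JointParams,
    config: MCMCConfig,
) -> PosteriorDraws:
    """Metropolis-Hastings within Gibbs over (alpha1, alpha2, beta1, beta2).

    One normal random-walk proposal per coordinate per sweep, accepted
    with probability min(1, kernel ratio) on the coordinate's full
    conditional.  The first ``burn_in`` sweeps are discarded.
    """
    if config.proposal_sd is None:
        raise ValueError(
            "proposal_sd unset; pass explicit scales (the MLE standard errors "
            "are the conventional default)"
        )
    loglam, w1, w2, A1, A2 = _suff(sample)
    m_r, n_r = sample.m_r, sample.n_r
    a_pr, b_pr = priors.a, priors.b
    sd = config.proposal_sd
    rng = np.random.default_rng(config.seed)

    th = init.as_array().copy()
    if np.any(th <= 0):
        raise ValueError("initial state must be strictly positive")
    # cached powers sum W_k(beta_k) and per-coordinate conditional values
    W1 = float(np.sum(w1 * np.exp(2.0 * th[2] * loglam)))
    W2 = float(np.sum(w2 * np.exp(2.0 * th[3] * loglam)))

    def cond(i: int, v: float, W1v: float, W2v: float) -> float:
        if i == 0:
            return (a_pr[0] - 1.0 - 2.0 * m_r) * np.log(v) - b_pr[0] * v - W1v / v**2
        if i == 1:
            return (a_pr[1] - 1.0 - 2.0 * n_r) * np.log(v) - b_pr[1] * v - W2v / v**2
        if i == 2:
            return ((m_r + a_pr[2] - 1.0) * np.log(v) - b_pr[2] * v
                    + 2.0 * v * A1 - W1v / th[0] ** 2)
        return ((n_r + a_pr[3] - 1.0) * np.log(v) - b_pr[3] * v
                + 2.0 * v * A2 - W2v / th[1] ** 2)

    n_keep = config.n_iter - config.burn_in
    draws = np.empty((n_keep, 4))
    accepted = np.zeros(4)
    for it in range(config.n_iter):
        for i in range(4):
            prop = th[i] + sd[i] * rng.standard_normal()
            u = rng.random()
            if prop <= 0:
                continue  # zero target density: reject, chain stays
            if i == 2:
                W1_prop = float(np.sum(w1 * np.exp(2.0 * prop * loglam)))
                logr = cond(2, prop, W1_prop, W2) - cond(2, th[2], W1, W2)
            elif i == 3:
                W2_prop = float(np.sum(w2 * np.exp(2.0 * prop * loglam)))
                logr = cond(3, prop, W1, W2_prop) - cond(3, th[3], W1, W2)
            else:
                logr = cond(i, prop, W1, W2) - cond(i, th[i], W1, W2)
            if np.log(u) < logr:
                th[i] = prop
                accepted[i] += 1
                if i == 2:
                    W1 = W1_prop
                elif i == 3:
                    W2 = W2_prop
        if it >= config.burn_in:
            draws[it - config.burn_in] = th
    rates = accepted / config.n_iter
    if np.any(rates == 0):
        warnings.warn(
            f"zero acceptance for coordinates "
            f"{[PARAM_NAMES[i] for i in np.nonzero(rates == 0)[0]]}; "
            "the proposal scales are likely far too large",
            RuntimeWarning,
        )
    return PosteriorDraws(draws=draws, acceptance_rate=rates, initial_state=init)


# ---------------------------------------------------------------------------
# posterior summaries


def linex_estimate(draws: np.ndarray, c: float) -> np.ndarray:
    """Bayes rule under LINEX loss: -(1/c) log mean(exp(-c theta)) per column."""
    if c == 0:
        raise ValueError("LINEX constant c must be nonzero; use the posterior "
                         "mean for squared-error loss")
    n = draws.shape[0]
    return -(logsumexp(-c * draws, axis=0) - np.log(n)) / c


def bayes_point_estimates(
    draws: PosteriorDraws,
    c_list=(-2.0, 0.0001, 2.0),
    level: float = 0.95,
) -> BayesSummary:
    """Squared-error (posterior mean) and LINEX point estimates plus CRIs."""
    if draws.n_retained == 0:
        raise ValueError("no retained draws")
    se_est = draws.draws.mean(axis=0)
    linex = {float(c): linex_estimate(draws.draws, float(c)) for c in c_list}
    cri = credible_intervals(draws, level=level)
    return BayesSummary(se_estimate=se_est, linex_estimates=linex, cri=cri)


def credible_intervals(
    draws: PosteriorDraws, level: float = 0.95, method: str = "equal-tailed"
) -> IntervalSet:
    """Per-coordinate credible interval from the retained draws.

    Default is the equal-tailed percentile interval; ``method="hpd"``
    gives the shortest contiguous interval containing ``level`` of the
    sorted draws.  Positivity of the support makes the lower bound
    automatically nonnegative.
    """
    if draws.n_retained < 100:
        raise ValueError("need at least 100 retained draws for interval summaries")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    d = draws.draws
    bounds = {}
    if method == "equal-tailed":
        lo = np.quantile(d, (1.0 - level) / 2.0, axis=0)
        hi = np.quantile(d, 1.0 - (1.0 - level) / 2.0, axis=0)
        for j, name in enumerate(PARAM_NAMES):
            bounds[name] = (float(lo[j]), float(hi[j]))
    elif method == "hpd":
        n = d.shape[0]
        k = max(1, int(np.ceil(level * n)))
        for j, name in enumerate(PARAM_NAMES):
            srt = np.sort(d[:, j])
            widths = srt[k - 1 :] - srt[: n - k + 1]
            i0 = int(np.argmin(widths))
            bounds[name] = (float(srt[i0]), float(srt[i0 + k - 1]))
    else:
        raise ValueError("method must be 'equal-tailed' or 'hpd'")
    return IntervalSet(bounds=bounds, level=level)
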