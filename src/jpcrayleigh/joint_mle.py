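"""Joint likelihood inference for two power Rayleigh populations under JPC.

With w1_i = h_i + s_i and w2_i = (1 - h_i) + t_i collecting failure and
withdrawal weights, the log-likelihood (up to the data-only combinatorial
constant) is

    l = m_r[log(2 b1) - 2 log a1] + n_r[log(2 b2) - 2 log a2]
        + (2 b1 - 1) sum_i h_i log lam_i + (2 b2 - 1) sum_i (1-h_i) log lam_i
        - sum_i w1_i lam_i^(2 b1) / a1^2 - sum_i w2_i lam_i^(2 b2) / a2^2,

which is separable across populations: each (alpha_k, beta_k) pair enters
only its own block.  For fixed shape the scale maximizer is closed form,
a_k^2(b_k) = sum_i w_k_i lam_i^(2 b_k) / (number of failures in pop k), so
fitting reduces to two bounded one-dimensional profile maximizations —
deliberately avoiding 4-D Newton-Raphson, which is fragile at the small
effective sample sizes progressive censoring produces.

Parameter vectors everywhere use the order (alpha1, alpha2, beta1, beta2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .jpc_scheme import CensoringScheme, JPCSample, log_norm_constant
from .power_rayleigh import PowerRayleighParams

__all__ = [
    "PARAM_NAMES",
    "JointParams",
    "MLEResult",
    "IntervalSet",
    "joint_loglik",
    "joint_score",
    "observed_information",
    "fit_joint_mle",
    "asymptotic_ci",
]

PARAM_NAMES = ("alpha1", "alpha2", "beta1", "beta2")


@dataclass(frozen=True)
class JointParams:
    """Parameters of both populations, (alpha1, beta1) and (alpha2, beta2)."""

    pop1: PowerRayleighParams
    pop2: PowerRayleighParams

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pop1.alpha, self.pop2.alpha, self.pop1.beta, self.pop2.beta]
        )

    @classmethod
    def from_array(cls, theta) -> "JointParams":
        a1, a2, b1, b2 = map(float, theta)
        return cls(PowerRayleighParams(a1, b1), PowerRayleighParams(a2, b2))


@dataclass(frozen=True)
class MLEResult:
    estimate: JointParams
    loglik: float
    info: np.ndarray
    vcov: np.ndarray | None
    converged: bool

    @property
    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("variance matrix unavailable (singular information)")
        return np.sqrt(np.diag(self.vcov))


@dataclass(frozen=True)
class IntervalSet:
    """Per-parameter (lower, upper) bounds at confidence/credibility level."""

    bounds: dict
    level: float

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    def lengths(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.bounds.values()])


def _pop_terms(sample: JPCSample):
    """Per-population sufficient pieces: (count, log-lam weights, w, log lam)."""
    loglam = np.log(sample.lam)
    w1 = sample.h + sample.s
    w2 = (1 - sample.h) + sample.t
    return loglam, w1.astype(float), w2.astype(float)


def _block_loglik(alpha, beta, k_fail, A, w, loglam):
    W = float(np.sum(w * np.exp(2.0 * beta * loglam)))
    return (
        k_fail * (np.log(2.0 * beta) - 2.0 * np.log(alpha))
        + (2.0 * beta - 1.0) * A
        - W / alpha**2
    )


def joint_loglik(
    theta: JointParams,
    sample: JPCSample,
    scheme: CensoringScheme | None = None,
    include_constant: bool = False,
) -> float:
    """Joint JPC log-likelihood; add log C when a scheme is supplied.

    The additive combinatorial constant does not move the maximizer; it is
    included only when ``include_constant`` is set (requires ``scheme``).
    """
    loglam, w1, w2 = _pop_terms(sample)
    A1 = float(np.sum(sample.h * loglam))
    A2 = float(np.sum((1 - sample.h) * loglam))
    ll = _block_loglik(theta.pop1.alpha, theta.pop1.beta, sample.m_r, A1, w1, loglam)
    ll += _block_loglik(theta.pop2.alpha, theta.pop2.beta, sample.n_r, A2, w2, loglam)
    if include_constant:
        if scheme is None:
            raise ValueError("scheme required to include the normalizing constant")
        ll += log_norm_constant(sample, scheme)
    return float(ll)


def joint_score(theta: JointParams, sample: JPCSample) -> np.ndarray:
    """Analytic gradient of the log-likelihood in (a1, a2, b1, b2) order."""
    loglam, w1, w2 = _pop_terms(sample)
    out = np.empty(4)
    for j, (p, k_fail, w, hmask) in enumerate(
        [
            (theta.pop1, sample.m_r, w1, sample.h),
            (theta.pop2, sample.n_r, w2, 1 - sample.h),
        ]
    ):
        a, b = p.alpha, p.beta
        lam2b = np.exp(2.0 * b * loglam)
        W = float(np.sum(w * lam2b))
        Wp = float(np.sum(2.0 * w * lam2b * loglam))
        A = float(np.sum(hmask * loglam))
        out[j] = -2.0 * k_fail / a + 2.0 * W / a**3
        out[2 + j] = k_fail / b + 2.0 * A - Wp / a**2
    return out


def observed_information(theta: JointParams, sample: JPCSample) -> np.ndarray:
    """Negative Hessian of the log-likelihood; block-diagonal across populations."""
    loglam, w1, w2 = _pop_terms(sample)
    info = np.zeros((4, 4))
    for j, (p, k_fail, w) in enumerate(
        [(theta.pop1, sample.m_r, w1), (theta.pop2, sample.n_r, w2)]
    ):
        a, b = np.float64(p.alpha), np.float64(p.beta)
        lam2b = np.exp(2.0 * b * loglam)
        W = float(np.sum(w * lam2b))
        Wp = float(np.sum(2.0 * w * lam2b * loglam))
        Wpp = float(np.sum(4.0 * w * lam2b * loglam**2))
        d2_aa = 2.0 * k_fail / a**2 - 6.0 * W / a**4
        d2_ab = 2.0 * Wp / a**3
        d2_bb = -k_fail / b**2 - Wpp / a**2
        ia, ib = j, 2 + j  # (alpha_k, beta_k) positions
        info[ia, ia] = -d2_aa
        info[ib, ib] = -d2_bb
        info[ia, ib] = info[ib, ia] = -d2_ab
    return info


def _fit_one_population(k_fail, A, w, loglam, bracket, tol):
    log_w = np.log(w, out=np.full_like(w, -np.inf), where=w > 0)

    def negprof(beta):
        log_W = logsumexp(2.0 * beta * loglam + log_w)
        log_a2 = log_W - np.log(k_fail)
        return -(
            k_fail * np.log(2.0 * beta)
            - k_fail * log_a2
            + (2.0 * beta - 1.0) * A
            - k_fail
        )

    res = optimize.minimize_scalar(
        negprof, bounds=bracket, method="bounded", options={"xatol": tol}
    )
    beta = float(res.x)
    log_a2 = logsumexp(2.0 * beta * loglam + log_w) - np.log(k_fail)
    alpha = float(np.exp(0.5 * log_a2))
    ok = bool(res.success)
    # a shape pinned at the search boundary, or a scale that under/overflowed,
    # marks an unidentifiable replicate (e.g. a single observed failure)
    lo, hi = bracket
    if beta <= lo * (1 + 1e-6) or beta >= hi * (1 - 1e-6):
        ok = False
    if not np.isfinite(alpha) or alpha <= 1e-150 or alpha >= 1e150:
        ok = False
        alpha = min(max(alpha, 1e-150), 1e150)
    return alpha, beta, ok


def fit_joint_mle(
    sample: JPCSample,
    *,
    bracket: tuple[float, float] = (1e-3, 1e3),
    tol: float = 1e-10,
) -> MLEResult:
    """Profile-likelihood MLE of (alpha1, alpha2, beta1, beta2).

    Each population is fitted independently (the likelihood is separable):
    closed-form scale given shape, bounded Brent search for the shape.
    Requires at least one observed failure in each population; otherwise
    that population's parameters are unidentifiable and an error names it.
    """
    if sample.m_r == 0:
        raise ValueError("population 1 registered no failures; its parameters are unidentifiable")
    if sample.n_r == 0:
        raise ValueError("population 2 registered no failures; its parameters are unidentifiable")
    loglam, w1, w2 = _pop_terms(sample)
    A1 = float(np.sum(sample.h * loglam))
    A2 = float(np.sum((1 - sample.h) * loglam))
    a1, b1, ok1 = _fit_one_population(sample.m_r, A1, w1, loglam, bracket, tol)
    a2, b2, ok2 = _fit_one_population(sample.n_r, A2, w2, loglam, bracket, tol)
    est = JointParams(PowerRayleighParams(a1, b1), PowerRayleighParams(a2, b2))
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll = joint_loglik(est, sample)
        info = observed_information(est, sample)
    vcov = None
    converged = bool(ok1 and ok2 and np.isfinite(ll))
    try:
        if np.all(np.isfinite(info)):
            vcov = np.linalg.inv(info)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                vcov = None
    except np.linalg.LinAlgError:
        vcov = None
    if vcov is None:
        warnings.warn(
            "observed information is singular or indefinite at the MLE; "
            "variance matrix withheld",
            RuntimeWarning,
        )
    if not converged:
        warnings.warn("profile maximization did not converge", RuntimeWarning)
    return MLEResult(estimate=est, loglik=float(ll), info=info, vcov=vcov,
                     converged=converged)


def asymptotic_ci(fit: MLEResult, level: float = 0.95) -> IntervalSet:
    """Normal-approximation intervals theta_hat +/- z_{gamma/2} SE.

    Lower limits are truncated at zero since all parameters are positive;
    widths before truncation are 2 z SE.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if fit.vcov is None:
        raise ValueError("fit has no valid variance matrix")
    z = stats.norm.ppf(0.5 + level / 2.0)
    theta = fit.estimate.as_array()
    se = fit.se
    bounds = {
        name: (max(0.0, float(t - z * s)), float(t + z * s))
        for name, t, s in zip(PARAM_NAMES, theta, se)
    }
    return IntervalSet(bounds=bounds, level=level)
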