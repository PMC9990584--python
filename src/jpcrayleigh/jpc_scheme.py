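"""Joint progressive type-II censoring (JPC) of two populations.

Two samples — m units from population 1 (X) and n units from population 2
(Y) — go on test simultaneously.  At the time of the i-th observed failure
a planned number R_i of surviving units is withdrawn uniformly at random
from the *pooled* survivors of both populations; the experiment stops at
the r-th failure.  The observable record is

    lam : the r ordered failure times,
    H   : 0/1 indicators (1 when the failure came from population 1),
    S,T : how each withdrawal R_i split between populations 1 and 2.

Under uniform removal the split (S_i, T_i) is hypergeometric in the
surviving counts, which is exactly the law the likelihood's combinatorial
normalizing constant C = D1 * D2 presupposes.

Counting identities every consistent record satisfies:
    S_i + T_i = R_i,  sum(S) = m - m_r,  sum(T) = n - n_r,
    sum(R) = m + n - r,  m_r + n_r = r,
where m_r = sum(H) is the realized number of population-1 failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .power_rayleigh import PowerRayleighParams, pr_sample

__all__ = [
    "CensoringScheme",
    "JPCSample",
    "Violation",
    "validate",
    "generate_jpc_sample",
    "log_norm_constant",
    "expected_failure_counts",
]


@dataclass(frozen=True)
class CensoringScheme:
    """Design of a JPC experiment: sample sizes, failure budget, removals.

    m, n
        Units placed on test from population 1 and 2.
    r
        Number of failures observed before termination, 1 <= r <= m + n
        (r = m + n with an all-zero removal plan is the uncensored
        experiment).
    R
        Planned removals (R_1, ..., R_r), nonnegative integers with
        sum(R) = m + n - r and, step by step, R_j no larger than the
        units still alive after the j-th failure.
    """

    m: int
    n: int
    r: int
    R: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", tuple(int(v) for v in np.atleast_1d(self.R)))
        K = self.m + self.n
        if self.m < 1 or self.n < 1:
            raise ValueError("both sample sizes must be >= 1")
        if not 1 <= self.r <= K:
            raise ValueError(f"r must satisfy 1 <= r <= m + n, got r={self.r}")
        if len(self.R) != self.r:
            raise ValueError(f"removal plan has length {len(self.R)}, expected r={self.r}")
        if any(v < 0 for v in self.R):
            raise ValueError("removals must be nonnegative")
        if sum(self.R) != K - self.r:
            raise ValueError(
                f"sum(R)={sum(self.R)} must equal m + n - r = {K - self.r}"
            )
        alive = K
        for j, Rj in enumerate(self.R, start=1):
            alive -= 1  # the j-th failure
            if Rj > alive:
                raise ValueError(
                    f"R_{j}={Rj} exceeds the {alive} units surviving at step {j}"
                )
            alive -= Rj

    @property
    def K(self) -> int:
        return self.m + self.n


@dataclass(frozen=True)
class JPCSample:
    """Observed record (lam, H, S, T) of a JPC experiment.

    Arrays are stored 0-based; step indices in reports are 1-based to
    match standard notation.
    """

    lam: np.ndarray
    h: np.ndarray
    s: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))
        for name in ("h", "s", "t"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        r = self.lam.size
        if not (self.h.size == self.s.size == self.t.size == r):
            raise ValueError("lam, h, s, t must share one length r")
        if not np.all(np.isin(self.h, (0, 1))):
            raise ValueError("population indicators must be 0 or 1")

    @property
    def r(self) -> int:
        return int(self.lam.size)

    @property
    def m_r(self) -> int:
        """Realized failures from population 1."""
        return int(self.h.sum())

    @property
    def n_r(self) -> int:
        """Realized failures from population 2."""
        return self.r - self.m_r


@dataclass(frozen=True)
class Violation:
    """A failed counting identity: name and both sides of the equation."""

    name: str
    lhs: float
    rhs: float

    def __str__(self) -> str:
        return f"{self.name}: {self.lhs} != {self.rhs}"


def validate(sample: JPCSample, scheme: CensoringScheme) -> list[Violation]:
    """Check every JPC counting identity; violations are data, not errors.

    Returns an empty list iff the record is internally consistent with the
    scheme.  Each violation names the identity and reports both sides.
    """
    out: list[Violation] = []
    if sample.r != scheme.r:
        out.append(Violation("r (record length vs scheme)", sample.r, scheme.r))
        return out
    if np.any(sample.lam <= 0):
        out.append(Violation("min(lam) > 0", float(sample.lam.min()), 0.0))
    if np.any(np.diff(sample.lam) < 0):
        out.append(Violation("lam nondecreasing (min successive diff >= 0)",
                             float(np.diff(sample.lam).min()), 0.0))
    R = np.asarray(scheme.R)
    bad = np.nonzero(sample.s + sample.t != R)[0]
    for i in bad:
        out.append(
            Violation(f"S_{i + 1} + T_{i + 1} = R_{i + 1}",
                      int(sample.s[i] + sample.t[i]), int(R[i]))
        )
    if np.any(sample.s < 0) or np.any(sample.t < 0):
        out.append(Violation("S, T nonnegative",
                             int(min(sample.s.min(), sample.t.min())), 0))
    if int(R.sum()) != scheme.K - scheme.r:
        out.append(Violation("sum(R) = m + n - r", int(R.sum()), scheme.K - scheme.r))
    if int(sample.s.sum()) != scheme.m - sample.m_r:
        out.append(Violation("sum(S) = m - m_r", int(sample.s.sum()),
                             scheme.m - sample.m_r))
    if int(sample.t.sum()) != scheme.n - sample.n_r:
        out.append(Violation("sum(T) = n - n_r", int(sample.t.sum()),
                             scheme.n - sample.n_r))
    if not 0 <= sample.m_r <= min(scheme.m, scheme.r):
        out.append(Violation("0 <= m_r <= min(m, r)", sample.m_r,
                             min(scheme.m, scheme.r)))
    return out


def generate_jpc_sample(
    p1: PowerRayleighParams,
    p2: PowerRayleighParams,
    scheme: CensoringScheme,
    seed,
) -> JPCSample:
    """Simulate one JPC experiment under uniform (hypergeometric) removal.

    m lifetimes are drawn from p1 and n from p2; at each of the r steps
    the smallest surviving lifetime is recorded and R_i survivors are
    deleted uniformly without replacement from the pooled survivor set.
    Floating-point ties are broken population 1 before population 2, then
    by original unit index (deterministic).
    """
    rng = np.random.default_rng(seed)
    life = np.concatenate(
        [pr_sample(scheme.m, p1, rng), pr_sample(scheme.n, p2, rng)]
    )
    pop = np.concatenate(
        [np.ones(scheme.m, dtype=int), np.zeros(scheme.n, dtype=int)]
    )
    # Sort once: ascending lifetime, pop-1 before pop-0 on ties, then index.
    order = np.lexsort((np.arange(scheme.K), -pop, life))
    life, pop = life[order], pop[order]
    alive = np.ones(scheme.K, dtype=bool)

    lam = np.empty(scheme.r)
    h = np.empty(scheme.r, dtype=int)
    s = np.empty(scheme.r, dtype=int)
    t = np.empty(scheme.r, dtype=int)
    for i, Ri in enumerate(scheme.R):
        idx_alive = np.nonzero(alive)[0]
        first = idx_alive[0]  # smallest surviving lifetime (pre-sorted)
        lam[i] = life[first]
        h[i] = pop[first]
        alive[first] = False
        if Ri:
            pool = np.nonzero(alive)[0]
            removed = rng.choice(pool, size=Ri, replace=False)
            s[i] = int(pop[removed].sum())
            alive[removed] = False
        else:
            s[i] = 0
        t[i] = Ri - s[i]
    return JPCSample(lam=lam, h=h, s=s, t=t)


def _log_binom(n: int, k: int) -> float:
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"binomial C({n}, {k}) has invalid arguments; "
                         "sample and scheme counts are inconsistent")
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def log_norm_constant(sample: JPCSample, scheme: CensoringScheme) -> float:
    """log C = log(D1 * D2), the likelihood's combinatorial constant.

    D1 collects, step by step, the count of units in the failing
    population just before each failure; D2 is the product of
    hypergeometric probabilities' combinatorial ratios for the observed
    withdrawal splits.  Independent of the failure times themselves.
    """
    m1, n1 = scheme.m, scheme.n  # survivors in each population pre-failure
    alive = scheme.K
    out = 0.0
    for j in range(scheme.r):
        hj, sj, tj, Rj = int(sample.h[j]), int(sample.s[j]), int(sample.t[j]), scheme.R[j]
        d1 = m1 * hj + n1 * (1 - hj)
        if d1 <= 0:
            raise ValueError(f"no surviving units in the failing population at step {j + 1}")
        out += np.log(d1)
        # post-failure survivor counts feed the withdrawal hypergeometric
        m_post = m1 - hj
        n_post = n1 - (1 - hj)
        out += _log_binom(m_post, sj) + _log_binom(n_post, tj)
        out -= _log_binom(alive - 1, Rj)
        m1 = m_post - sj
        n1 = n_post - tj
        alive -= 1 + Rj
    return float(out)


def expected_failure_counts(
    p1: PowerRayleighParams,
    p2: PowerRayleighParams,
    scheme: CensoringScheme,
    nrep: int,
    seed,
) -> dict:
    """Monte-Carlo expected failure counts per population for a design.

    Returns mean realized m_r and n_r (summing to r exactly), their
    Monte-Carlo standard errors, and the per-step probability that each
    failure comes from population 1.
    """
    if nrep < 1:
        raise ValueError("nrep must be >= 1")
    rng = np.random.default_rng(seed)
    mr = np.empty(nrep)
    step_p1 = np.zeros(scheme.r)
    for k in range(nrep):
        smp = generate_jpc_sample(p1, p2, scheme, rng)
        mr[k] = smp.m_r
        step_p1 += smp.h
    mean_mr = float(mr.mean())
    return {
        "mean_m_r": mean_mr,
        "mean_n_r": scheme.r - mean_mr,
        "se_m_r": float(mr.std(ddof=1) / np.sqrt(nrep)) if nrep > 1 else np.nan,
        "step_pop1_prob": step_p1 / nrep,
        "nrep": nrep,
    }
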