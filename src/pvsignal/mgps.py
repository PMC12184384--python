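"""Multi-item gamma Poisson shrinker (MGPS), DuMouchel's empirical-Bayes model.

Observed cell counts ``a_i`` are modelled as ``Poisson(λ_i · E_i)`` where
``E_i`` is the count expected under row/column independence and the relative
reporting ratio ``λ_i`` carries a two-component gamma mixture prior

    λ ~ P · Gamma(α₁, β₁) + (1 − P) · Gamma(α₂, β₂)      (shape, rate)

whose marginal is a mixture of negative binomials.  The five
hyperparameters are fitted by maximum marginal likelihood over all
drug–event cells of a database (bounded quasi-Newton, multistart).  The
posterior of λ given ``a`` is again a two-gamma mixture with updated
parameters (αₖ + a, βₖ + E) and evidence-weighted mixture weights;
``EBGM = 2^{E[log₂ λ | a]}`` is its geometric mean and ``EBGM05`` its fifth
percentile (root-solved on the mixture CDF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats


@dataclass
class MgpsPrior:
    p: float  # weight of component 1
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    loglik: float = math.nan
    converged: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"mixture weight must be in (0,1), got {self.p}")
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")

    @property
    def mean(self) -> float:
        """Prior mean of λ."""
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2

    @property
    def geometric_mean(self) -> float:
        """2^{E[log2 λ]} under the prior (the a = 0, E → 0 shrinkage target)."""
        g1 = special.digamma(self.alpha1) - math.log(self.beta1)
        g2 = special.digamma(self.alpha2) - math.log(self.beta2)
        return math.exp(self.p * g1 + (1 - self.p) * g2)


class MgpsConvergenceError(RuntimeError):
    def __init__(self, message: str, best: Optional[MgpsPrior] = None):
        super().__init__(message)
        self.best = best


def _log_nb(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log marginal P(a | E) for one gamma component (negative binomial)."""
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * np.log(beta / (beta + e))
        + a * np.log(e / (beta + e))
    )


def _neg_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    # clip so unbounded (simplex) steps cannot overflow exp/expit
    theta = np.clip(theta, -_BOUND * 3, _BOUND * 3)
    la1, lb1, la2, lb2, logit_p = theta
    alpha1, beta1, alpha2, beta2 = np.exp([la1, lb1, la2, lb2])
    # stable log p / log(1-p)
    log_p = -np.logaddexp(0.0, -logit_p)
    log_1mp = -np.logaddexp(0.0, logit_p)
    l1 = _log_nb(a, e, alpha1, beta1) + log_p
    l2 = _log_nb(a, e, alpha2, beta2) + log_1mp
    ll = np.logaddexp(l1, l2).sum()
    if not np.isfinite(ll):
        return 1e300
    return -float(ll)


#: DuMouchel's published starting point (α₁, β₁, α₂, β₂, P)
_DEFAULT_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
_BOUND = 12.0  # |log parameter| bound — generous but keeps the optimizer sane


def mgps_fit_prior(
    a_counts: Sequence[int] | np.ndarray,
    expected: Sequence[float] | np.ndarray,
    n_starts: int = 4,
    seed: int = 0,
) -> MgpsPrior:
    """Fit the five mixture hyperparameters by maximum marginal likelihood.

    ``a_counts``/``expected`` are the observed and independence-expected
    counts of *all* drug–event cells of a database (not just the target
    drug's), typically ≥ 50 cells.  Optimization is L-BFGS-B on log/logit
    scale from DuMouchel's classic start plus ``n_starts − 1`` seeded random
    restarts; the best converged optimum wins.  Raises
    :class:`MgpsConvergenceError` (carrying the best-so-far fit) when no
    start converges.
    """
    a = np.asarray(a_counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("a_counts and expected must be equal-length 1-D arrays")
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")

    rng = np.random.default_rng(seed)
    a1, b1, a2, b2, p = _DEFAULT_START
    starts = [np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                        math.log(p / (1 - p))])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform([-2, -2, -1, -1, -2], [1, 1, 2, 2, 2]))

    best: Optional[tuple[float, np.ndarray]] = None
    bounds = [(-_BOUND, _BOUND)] * 5
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik, x0, args=(a, e), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    assert best is not None
    # the mixture likelihood has a flat ridge where quasi-Newton line searches
    # stall; simplex polishes from the best point settle the optimum, and a
    # stationary polish (no meaningful further improvement) is the
    # convergence criterion
    ok = False
    for _ in range(5):
        polish = optimize.minimize(
            _neg_loglik, best[1], args=(a, e), method="Nelder-Mead",
            options={"maxiter": 5000, "maxfev": 8000, "xatol": 1e-8, "fatol": 1e-10},
        )
        improvement = best[0] - float(polish.fun)
        if polish.fun <= best[0]:
            best = (float(polish.fun), polish.x)
        if bool(polish.success) or improvement <= 1e-6 * max(1.0, abs(best[0])):
            ok = True
            break
    fun, x = best
    x = np.clip(x, -_BOUND * 3, _BOUND * 3)  # match the likelihood's domain
    ok = ok and math.isfinite(fun)
    alpha1, beta1, alpha2, beta2 = np.exp(x[:4])
    p = 1.0 / (1.0 + math.exp(-x[4]))
    # canonical order: component 1 is the lower-mean component
    if alpha1 / beta1 > alpha2 / beta2:
        alpha1, beta1, alpha2, beta2, p = alpha2, beta2, alpha1, beta1, 1 - p
    p = min(max(p, 1e-12), 1 - 1e-12)
    prior = MgpsPrior(
        p=p, alpha1=alpha1, beta1=beta1, alpha2=alpha2, beta2=beta2,
        loglik=-fun, converged=ok,
    )
    if not ok:
        raise MgpsConvergenceError("MGPS prior fit did not converge", best=prior)
    return prior


def _posterior(a: float, e: float, prior: MgpsPrior):
    """Posterior mixture: weights and (shape, rate) per component."""
    l1 = float(_log_nb(np.array([a]), np.array([e]), prior.alpha1, prior.beta1)[0])
    l2 = float(_log_nb(np.array([a]), np.array([e]), prior.alpha2, prior.beta2)[0])
    w1 = math.log(prior.p) + l1
    w2 = math.log1p(-prior.p) + l2
    m = max(w1, w2)
    q1 = math.exp(w1 - m) / (math.exp(w1 - m) + math.exp(w2 - m))
    return (
        (q1, prior.alpha1 + a, prior.beta1 + e),
        (1.0 - q1, prior.alpha2 + a, prior.beta2 + e),
    )


def mgps_ebgm(a: float, expected: float, prior: MgpsPrior) -> tuple[float, float]:
    """EBGM and its fifth posterior percentile for one cell.

    EBGM is the geometric mean of the posterior (exp of the posterior mean
    of log λ, exact via digamma); EBGM05 solves mixture-CDF(λ) = 0.05 by
    bracketed root finding to 1e-8 relative tolerance.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    comps = _posterior(a, expected, prior)
    mean_log = sum(q * (special.digamma(shape) - math.log(rate)) for q, shape, rate in comps)
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return sum(q * stats.gamma.cdf(x, s, scale=1.0 / r) for q, s, r in comps)

    lo, hi = 1e-12, 1.0
    while cdf(hi) < 0.05:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological prior
            raise RuntimeError("EBGM05 bracket failed")
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, rtol=1e-8)
    return ebgm, float(ebgm05)


def posterior_cdf(x: float, a: float, expected: float, prior: MgpsPrior) -> float:
    """Posterior CDF of λ at ``x`` (exposed for oracle cross-checks)."""
    comps = _posterior(a, expected, prior)
    return sum(q * stats.gamma.cdf(x, s, scale=1.0 / r) for q, s, r in comps)
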