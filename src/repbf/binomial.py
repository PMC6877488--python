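"""Conjugate Bayes factors for a binomial rate against a point null.

The test contrasts H0: theta = theta0 with H1: theta ~ Beta(alpha, beta)
(optionally truncated to a subinterval of [0, 1]).  Because the beta prior
is conjugate, both the Savage--Dickey density ratio and the marginal
(prior-predictive) likelihood ratio are available in closed form; the two
must agree, and both are computed here as an internal cross-check.  All
density and beta-function arithmetic goes through log-gamma, so counts up
to 10^4 and beyond are safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats
from scipy.special import betainc, betaln, gammaln

from .result import BayesFactorResult


@dataclass(frozen=True)
class BinomialCount:
    """Successes out of trials in a binomial experiment."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if not (0 <= self.successes <= self.trials):
            raise ValueError(
                f"need 0 <= successes <= trials, got {self.successes}/{self.trials}"
            )

    @property
    def failures(self) -> int:
        return self.trials - self.successes

    def __add__(self, other: "BinomialCount") -> "BinomialCount":
        return BinomialCount(self.successes + other.successes, self.trials + other.trials)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on the binomial rate, truncated to [lower, upper].

    The default bounds (0, 1) give an untruncated beta; under truncation the
    density is renormalized so it integrates to one on [lower, upper].
    """

    alpha: float
    beta: float
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError("need 0 <= lower < upper <= 1")

    @property
    def is_truncated(self) -> bool:
        return self.lower > 0.0 or self.upper < 1.0

    def mass_untruncated(self, lo: float, hi: float) -> float:
        """P(lo < X < hi) for an UNtruncated Beta(alpha, beta)."""
        return float(betainc(self.alpha, self.beta, hi) - betainc(self.alpha, self.beta, lo))

    @property
    def normalizer(self) -> float:
        """Prior mass of the untruncated beta on the truncation interval."""
        return self.mass_untruncated(self.lower, self.upper)

    def logpdf(self, theta: float) -> float:
        """Log density of the (renormalized) truncated beta at theta."""
        if not (self.lower <= theta <= self.upper):
            return -math.inf
        lp = float(stats.beta.logpdf(theta, self.alpha, self.beta))
        return lp - math.log(self.normalizer)

    def cdf(self, theta: float) -> float:
        if theta <= self.lower:
            return 0.0
        if theta >= self.upper:
            return 1.0
        return self.mass_untruncated(self.lower, theta) / self.normalizer

    def ppf(self, q: float) -> float:
        base = betainc(self.alpha, self.beta, self.lower) + q * self.normalizer
        return float(stats.beta.ppf(base, self.alpha, self.beta))

    def mass(self, lo: float, hi: float) -> float:
        """Probability assigned to (lo, hi) by the truncated prior."""
        lo, hi = max(lo, self.lower), min(hi, self.upper)
        if hi <= lo:
            return 0.0
        return self.mass_untruncated(lo, hi) / self.normalizer


def update_beta(prior: BetaPrior, data: BinomialCount) -> BetaPrior:
    """Conjugate posterior: shape parameters gain the counts, bounds persist."""
    return replace(
        prior, alpha=prior.alpha + data.successes, beta=prior.beta + data.failures
    )


def _log_marginal_h1(data: BinomialCount, prior: BetaPrior) -> float:
    """Log prior-predictive p(k, n | H1) under the (truncated) beta prior."""
    k, n = data.successes, data.trials
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    post = update_beta(prior, data)
    # Integral of the truncated-beta-weighted likelihood: the untruncated
    # beta-function ratio times the ratio of interval masses.
    log_ratio = betaln(post.alpha, post.beta) - betaln(prior.alpha, prior.beta)
    log_ratio += math.log(post.normalizer) - math.log(prior.normalizer)
    return float(log_choose + log_ratio)


def _log_marginal_h0(data: BinomialCount, theta0: float) -> float:
    """Log likelihood p(k, n | H0) at the point null theta0."""
    k, n = data.successes, data.trials
    if n == 0:
        return 0.0
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(log_choose + k * math.log(theta0) + (n - k) * math.log1p(-theta0))


def bf10_binomial(
    data: BinomialCount, prior: BetaPrior | None = None, theta0: float = 0.5
) -> BayesFactorResult:
    """Bayes factor for H1: theta ~ prior against H0: theta = theta0.

    The primary path is the Savage--Dickey density ratio: BF01 equals the
    posterior density at theta0 divided by the prior density at theta0
    (both renormalized under truncation).  The closed-form marginal
    likelihoods populate ``marginal_h1`` / ``marginal_h0`` and agree with
    the density ratio to floating-point precision.
    """
    if prior is None:
        prior = BetaPrior(1.0, 1.0)
    if not (prior.lower < theta0 < prior.upper):
        raise ValueError(
            f"theta0={theta0} lies outside the prior support "
            f"({prior.lower}, {prior.upper}); the Savage-Dickey ratio is undefined"
        )
    posterior = update_beta(prior, data)
    log_bf01 = posterior.logpdf(theta0) - prior.logpdf(theta0)
    m1 = _log_marginal_h1(data, prior)
    m0 = _log_marginal_h0(data, theta0)
    # Savage-Dickey is the primary path; the marginal ratio must agree.
    return BayesFactorResult(
        log_bf10=-log_bf01,
        marginal_h1=m1,
        marginal_h0=m0,
        hypothesis_labels=(
            f"theta = {theta0:g}",
            _prior_label(prior),
        ),
        method="savage_dickey",
        numerical_error=abs(math.exp(-log_bf01) - math.exp(m1 - m0)),
    )


def _prior_label(prior: BetaPrior) -> str:
    lab = f"theta ~ Beta({prior.alpha:g}, {prior.beta:g})"
    if prior.is_truncated:
        lab += f" on ({prior.lower:g}, {prior.upper:g})"
    return lab


def bf10_binomial_onesided(
    data: BinomialCount,
    prior: BetaPrior,
    theta0: float = 0.5,
    direction: str = "greater",
) -> BayesFactorResult:
    """Order-restricted Bayes factor: H+ (or H-) truncates the prior at theta0.

    Equivalent to the two-sided BF10 times the posterior-to-prior mass ratio
    on the requested side of theta0.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if prior.is_truncated:
        raise ValueError("supply an untruncated prior; truncation is applied here")
    lo, hi = (theta0, prior.upper) if direction == "greater" else (prior.lower, theta0)
    side_mass = prior.mass_untruncated(lo, hi)
    if side_mass <= 0.0:
        raise ValueError(f"prior puts zero mass on the {direction} side of {theta0}")
    truncated = BetaPrior(prior.alpha, prior.beta, lower=lo, upper=hi)
    m1 = _log_marginal_h1(data, truncated)
    m0 = _log_marginal_h0(data, theta0)
    sign = "+" if direction == "greater" else "-"
    return BayesFactorResult(
        log_bf10=m1 - m0,
        marginal_h1=m1,
        marginal_h0=m0,
        hypothesis_labels=(f"theta = {theta0:g}", f"H{sign}: {_prior_label(truncated)}"),
        method="closed_form",
    )


def beta_credible_interval(prior: BetaPrior, level: float = 0.95) -> tuple[float, float]:
    """Central (equal-tailed) credible interval of a (truncated) beta law."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    return prior.ppf(tail), prior.ppf(1.0 - tail)


def binomial_two_sided_p(data: BinomialCount, theta0: float = 0.5) -> float:
    """Exact two-sided binomial test p value (minimum-likelihood convention).

    Sums P(X = k) over all outcomes no more probable than the observed one;
    at theta0 = 0.5 this reduces to doubling the smaller tail (capped at 1).
    """
    if data.trials < 1:
        raise ValueError("need at least one trial")
    if not (0.0 < theta0 < 1.0):
        raise ValueError(f"theta0 must be in (0, 1), got {theta0}")
    res = stats.binomtest(data.successes, data.trials, theta0, alternative="two-sided")
    return float(res.pvalue)
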