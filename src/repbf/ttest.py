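"""Default Bayes factors for the independent-samples t test from summaries.

The alternative places a prior on the standardized effect size
delta = (mu1 - mu2) / sigma; under H0, delta = 0.  Given an observed t
statistic with df = n1 + n2 - 2 and effective sample size
n_eff = n1*n2/(n1 + n2), the marginal likelihood under H1 is the noncentral-t
density of t averaged over the prior on delta (noncentrality delta*sqrt(n_eff)),
and under H0 it is the central-t density, so

    BF10 = [ integral f_nct(t; df, delta*sqrt(n_eff)) pi(delta) d delta ]
           / f_t(t; df).

The integral is evaluated by adaptive quadrature after mapping delta to a
bounded interval with delta = location + scale*tan(u); the map absorbs the
Cauchy prior's heavy tails exactly.  The module also carries the exact
algebra for pooling two studies' per-group summaries into the summaries of
the concatenated raw data, so a combined t statistic can be formed without
ever seeing raw observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .result import BayesFactorResult

DEFAULT_CAUCHY_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class TwoSampleSummary:
    """Sufficient statistics of a two-group design: size, mean, sd per group."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("group standard deviations must be positive")


@dataclass(frozen=True)
class TStatSummary:
    """An observed t statistic with the two group sizes."""

    t: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("t must be finite")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")
        if self.df < 1:
            raise ValueError(f"need df >= 1, got df={self.df}")

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2

    @property
    def n_eff(self) -> float:
        return self.n1 * self.n2 / (self.n1 + self.n2)


@dataclass(frozen=True)
class EffectSizePrior:
    """Prior on the standardized effect size delta.

    family is one of 'cauchy', 'normal', 'student_t'; truncation restricts
    the support to the positive or negative half-line (renormalized).
    The default, a zero-centered Cauchy with scale sqrt(2)/2, is the common
    default of Bayesian t-test software.
    """

    family: str = "cauchy"
    location: float = 0.0
    scale: float = DEFAULT_CAUCHY_SCALE
    df: float | None = None
    truncation: str = "none"

    def __post_init__(self) -> None:
        if self.family not in ("cauchy", "normal", "student_t"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family == "student_t" and (self.df is None or self.df <= 0):
            raise ValueError("student_t prior requires df > 0")
        if self.truncation not in ("none", "positive", "negative"):
            raise ValueError(f"unknown truncation {self.truncation!r}")

    def _dist(self):
        if self.family == "cauchy":
            return stats.cauchy(loc=self.location, scale=self.scale)
        if self.family == "normal":
            return stats.norm(loc=self.location, scale=self.scale)
        return stats.t(df=self.df, loc=self.location, scale=self.scale)

    def support(self) -> tuple[float, float]:
        if self.truncation == "positive":
            return 0.0, math.inf
        if self.truncation == "negative":
            return -math.inf, 0.0
        return -math.inf, math.inf

    def mass_on_support(self) -> float:
        dist = self._dist()
        if self.truncation == "positive":
            return float(dist.sf(0.0))
        if self.truncation == "negative":
            return float(dist.cdf(0.0))
        return 1.0

    def pdf(self, delta: np.ndarray | float) -> np.ndarray | float:
        """Renormalized prior density on the (possibly truncated) support."""
        base = self._dist().pdf(delta)
        lo, hi = self.support()
        inside = (np.asarray(delta) >= lo) & (np.asarray(delta) <= hi)
        return np.where(inside, base / self.mass_on_support(), 0.0)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw from the truncated prior by inverse-cdf on the retained mass."""
        dist = self._dist()
        u = rng.uniform(size=size)
        if self.truncation == "positive":
            u = dist.cdf(0.0) + u * dist.sf(0.0)
        elif self.truncation == "negative":
            u = u * dist.cdf(0.0)
        return dist.ppf(u)

    def label(self) -> str:
        name = {"cauchy": "Cauchy", "normal": "Normal", "student_t": "Student-t"}[self.family]
        lab = f"delta ~ {name}({self.location:g}, {self.scale:g}"
        if self.family == "student_t":
            lab += f", df={self.df:g}"
        lab += ")"
        if self.truncation != "none":
            lab += f" truncated {self.truncation}"
        return lab


def bf10_ttest(data: TStatSummary, prior: EffectSizePrior | None = None) -> BayesFactorResult:
    """Bayes factor for the independent-samples t test from (t, n1, n2).

    Numerator and denominator are the prior-predictive densities of the
    observed t under H1 and H0; the H1 integral uses adaptive quadrature on
    the arctangent-transformed effect size with relative tolerance 1e-10.
    """
    if prior is None:
        prior = EffectSizePrior()
    df, n_eff, t = data.df, data.n_eff, data.t

    mass = prior.mass_on_support()
    if mass <= 0.0:
        raise ValueError("prior puts zero mass on the requested side")

    loc, scale = prior.location, prior.scale
    sqrt_neff = math.sqrt(n_eff)
    dist = prior._dist()

    def integrand(u: float) -> float:
        delta = loc + scale * math.tan(u)
        dens = float(dist.pdf(delta)) / mass
        jac = scale / math.cos(u) ** 2
        return stats.nct.pdf(t, df, delta * sqrt_neff) * dens * jac

    # u-bounds of the (possibly truncated) support under the tan map
    lo, hi = prior.support()
    u_lo = -math.pi / 2 if lo == -math.inf else math.atan((lo - loc) / scale)
    u_hi = math.pi / 2 if hi == math.inf else math.atan((hi - loc) / scale)

    num, err = integrate.quad(integrand, u_lo, u_hi, epsabs=1e-15, epsrel=1e-10, limit=200)
    if not (num > 0 and math.isfinite(num)):
        raise ArithmeticError(
            f"quadrature failed for t={t}, df={df}, prior={prior.label()}: value={num}"
        )
    den = float(stats.t.pdf(t, df))
    return BayesFactorResult(
        log_bf10=math.log(num) - math.log(den),
        marginal_h1=math.log(num),
        marginal_h0=math.log(den),
        hypothesis_labels=("delta = 0", prior.label()),
        method="quadrature",
        numerical_error=err / den,
    )


def bf10_ttest_onesided(data: TStatSummary, prior: EffectSizePrior) -> BayesFactorResult:
    """Order-restricted t-test BF; the prior must carry a truncation."""
    if prior.truncation == "none":
        raise ValueError("one-sided BF requires a truncated prior ('positive' or 'negative')")
    return bf10_ttest(data, prior)


def pool_two_sample_summaries(
    orig: TwoSampleSummary, rep: TwoSampleSummary
) -> TwoSampleSummary:
    """Exactly pool two studies' group summaries, per group.

    Combined size N = n_o + n_r, mean M = (n_o m_o + n_r m_r)/N, and the
    combined sum of squares adds the within-study sums of squares plus a
    between-study term (n_o n_r / N)(m_o - m_r)^2, so the result equals the
    summary of the concatenated raw samples.  Group 1 of each study must
    refer to the same experimental condition (caller's responsibility; the
    study-record layer aligns by condition label).
    """

    def pool_group(n_o, m_o, s_o, n_r, m_r, s_r):
        n = n_o + n_r
        m = (n_o * m_o + n_r * m_r) / n
        ss = (n_o - 1) * s_o**2 + (n_r - 1) * s_r**2 + (n_o * n_r / n) * (m_o - m_r) ** 2
        return n, m, math.sqrt(ss / (n - 1))

    n1, m1, s1 = pool_group(orig.n1, orig.mean1, orig.sd1, rep.n1, rep.mean1, rep.sd1)
    n2, m2, s2 = pool_group(orig.n2, orig.mean2, orig.sd2, rep.n2, rep.mean2, rep.sd2)
    return TwoSampleSummary(n1, m1, s1, n2, m2, s2)


def t_from_summaries(s: TwoSampleSummary) -> TStatSummary:
    """Pooled-variance independent-samples t statistic from group summaries."""
    if s.n1 < 2 or s.n2 < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / (s.n1 + s.n2 - 2)
    if sp2 <= 0.0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    t = (s.mean1 - s.mean2) / math.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
    return TStatSummary(t=t, n1=s.n1, n2=s.n2)
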