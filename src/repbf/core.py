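"""Evidence-updating identities: replication Bayes factors and study chains.

Two facts about Bayes factors drive everything here.  First, evidence
multiplies: the Bayes factor for pooled data equals the product of the
component Bayes factors, provided each component is computed with the prior
updated on the earlier data.  Second, the replication Bayes factor — the
evidence in the replication data given the original data, i.e. the test of
a skeptic's null against a proponent's prior informed by the original study
— is therefore simply the complete-data Bayes factor divided by the
original-study Bayes factor.  No explicit posterior-as-prior construction
is ever required; for the binomial design conjugacy makes the sequential
terms available directly, and for the t and contingency designs they are
defined as ratios of pooled-data Bayes factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce

from .binomial import BetaPrior, BinomialCount, bf10_binomial, update_beta
from .contingency import CrossTable, DirichletPrior, bf10_contingency, pool_tables
from .result import BayesFactorResult
from .ttest import (
    EffectSizePrior,
    TwoSampleSummary,
    bf10_ttest,
    pool_two_sample_summaries,
    t_from_summaries,
)

DESIGNS = ("binomial", "ttest", "contingency")


def _require_positive_finite(value: float, name: str) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def replication_bf(bf_complete: float, bf_orig: float) -> float:
    """BF10(d_rep | d_orig): complete-data BF divided by the original-study BF.

    Computed in log space to avoid under/overflow for extreme evidence.
    """
    _require_positive_finite(bf_complete, "bf_complete")
    _require_positive_finite(bf_orig, "bf_orig")
    return math.exp(math.log(bf_complete) - math.log(bf_orig))


def posterior_model_odds(bf10: float, prior_odds: float) -> float:
    """Posterior odds of H1 over H0: the Bayes factor times the prior odds."""
    _require_positive_finite(bf10, "bf10")
    _require_positive_finite(prior_odds, "prior_odds")
    return bf10 * prior_odds


@dataclass(frozen=True)
class EvidenceChain:
    """Ordered studies with their sequential (conditional) and complete BFs.

    ``sequential_bfs[i]`` is the Bayes factor of study i with the prior
    updated on studies 0..i-1; their product equals ``complete_bf.bf10``.
    """

    studies: tuple
    sequential_bfs: tuple[float, ...]
    complete_bf: BayesFactorResult
    design: str

    def __post_init__(self) -> None:
        if len(self.sequential_bfs) != len(self.studies):
            raise ValueError("one sequential BF per study is required")

    @property
    def chain_product(self) -> float:
        return math.exp(sum(math.log(b) for b in self.sequential_bfs))

    def replication_bf(self) -> float:
        """BF for studies 2..k given study 1 (requires >= 2 studies)."""
        if len(self.studies) < 2:
            raise ValueError("a replication BF needs at least two studies")
        return replication_bf(self.complete_bf.bf10, self.sequential_bfs[0])


def _chain_binomial(studies, prior: BetaPrior, theta0: float) -> EvidenceChain:
    seq = []
    running = prior
    for s in studies:
        seq.append(bf10_binomial(s, running, theta0).bf10)
        running = update_beta(running, s)
    pooled = reduce(lambda a, b: a + b, studies)
    complete = bf10_binomial(pooled, prior, theta0)
    return EvidenceChain(tuple(studies), tuple(seq), complete, "binomial")


def _chain_ttest(studies, prior: EffectSizePrior) -> EvidenceChain:
    seq = []
    pooled = None
    prev_log = 0.0
    for s in studies:
        pooled = s if pooled is None else pool_two_sample_summaries(pooled, s)
        res = bf10_ttest(t_from_summaries(pooled), prior)
        seq.append(math.exp(res.log_bf10 - prev_log))
        prev_log = res.log_bf10
    return EvidenceChain(tuple(studies), tuple(seq), res, "ttest")


def _chain_contingency(studies, prior: DirichletPrior) -> EvidenceChain:
    seq = []
    pooled = None
    prev_log = 0.0
    for s in studies:
        pooled = s if pooled is None else pool_tables(pooled, s)
        res = bf10_contingency(pooled, prior)
        seq.append(math.exp(res.log_bf10 - prev_log))
        prev_log = res.log_bf10
    return EvidenceChain(tuple(studies), tuple(seq), res, "contingency")


_PAYLOAD_TYPES = {
    "binomial": BinomialCount,
    "ttest": TwoSampleSummary,
    "contingency": CrossTable,
}


def chain_evidence(
    studies,
    design: str,
    *,
    prior=None,
    theta0: float = 0.5,
) -> EvidenceChain:
    """Sequentially chain studies of one design into an :class:`EvidenceChain`.

    Parameters
    ----------
    studies
        Ordered design-specific records: :class:`BinomialCount`,
        :class:`TwoSampleSummary`, or :class:`CrossTable`.
    design
        One of ``binomial``, ``ttest``, ``contingency``.
    prior
        Initial prior (design-appropriate); defaults: Beta(1,1),
        Cauchy(0, sqrt(2)/2) on delta, Dirichlet concentration 1.
    theta0
        Point null for the binomial design.

    For the binomial design the sequential terms come from conjugate
    posterior-as-prior updating; for the t and contingency designs they are
    ratios of pooled-data Bayes factors (the evidence-updating definition),
    so the chain-product identity holds by construction and what the pooled
    computations must get right is internal consistency.
    """
    studies = list(studies)
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if not studies:
        raise ValueError("at least one study is required")
    expected = _PAYLOAD_TYPES[design]
    for i, s in enumerate(studies):
        if not isinstance(s, expected):
            raise TypeError(
                f"study {i} has type {type(s).__name__}, expected "
                f"{expected.__name__} for design {design!r}"
            )
    if design == "binomial":
        return _chain_binomial(studies, prior or BetaPrior(1.0, 1.0), theta0)
    if design == "ttest":
        return _chain_ttest(studies, prior or EffectSizePrior())
    return _chain_contingency(studies, prior or DirichletPrior())
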