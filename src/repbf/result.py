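"""Shared Bayes factor result container.

All Bayes factors in this package are computed and stored on the log scale;
``bf10`` is derived from ``log_bf10`` so that the two are consistent by
construction even for extreme evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BayesFactorResult:
    """A Bayes factor BF10 comparing an alternative H1 against a null H0.

    Parameters
    ----------
    log_bf10
        Natural log of the evidence ratio p(d | H1) / p(d | H0).
    marginal_h1, marginal_h0
        Log prior-predictive (marginal likelihood) values under each
        hypothesis, when the computation path produces them; ``None`` when
        only the ratio is available (e.g. a pure Savage--Dickey evaluation).
    hypothesis_labels
        Short human-readable descriptors ``(null spec, alternative spec)``.
    method
        One of ``savage_dickey``, ``marginal_ratio``, ``quadrature``,
        ``closed_form``.
    numerical_error
        Nonnegative estimate of the absolute numerical error on ``bf10``
        (zero for exact closed forms).
    """

    log_bf10: float
    marginal_h1: float | None = None
    marginal_h0: float | None = None
    hypothesis_labels: tuple[str, str] = ("H0", "H1")
    method: str = "closed_form"
    numerical_error: float = 0.0

    _METHODS = ("savage_dickey", "marginal_ratio", "quadrature", "closed_form")

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_bf10):
            raise ValueError(f"log_bf10 must be finite, got {self.log_bf10}")
        if self.method not in self._METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.numerical_error < 0:
            raise ValueError("numerical_error must be nonnegative")
        if self.marginal_h1 is not None and self.marginal_h0 is not None:
            gap = abs((self.marginal_h1 - self.marginal_h0) - self.log_bf10)
            if gap > 1e-8 * max(1.0, abs(self.log_bf10)):
                raise ValueError(
                    "log_bf10 inconsistent with marginal_h1 - marginal_h0 "
                    f"(difference {gap:.3e})"
                )

    @property
    def bf10(self) -> float:
        return math.exp(self.log_bf10)

    @property
    def bf01(self) -> float:
        return math.exp(-self.log_bf10)

    @property
    def log_bf01(self) -> float:
        return -self.log_bf10

    @property
    def favored(self) -> str:
        """Label of the hypothesis the data favor (BF in its direction > 1)."""
        return self.hypothesis_labels[1] if self.log_bf10 >= 0 else self.hypothesis_labels[0]

    def to_dict(self) -> dict:
        return {
            "bf10": self.bf10,
            "bf01": self.bf01,
            "log_bf10": self.log_bf10,
            "marginal_h1": self.marginal_h1,
            "marginal_h0": self.marginal_h0,
            "hypothesis_labels": list(self.hypothesis_labels),
            "method": self.method,
            "numerical_error": self.numerical_error,
            "favored": self.favored,
        }
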