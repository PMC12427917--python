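"""Probability/odds arithmetic and sequential likelihood-ratio updating.

The engine's arithmetic core.  A disease probability is updated by a
diagnostic finding in three moves: convert probability to odds
(``odds = p / (1 - p)``), multiply the odds by the finding's likelihood
ratio, and convert back (``p = odds / (1 + odds)``).  Because likelihood
ratios act multiplicatively on the odds scale, an ordered sequence of
findings — history, biomarkers, ECG features — can be layered one step at
a time, and in full precision the result is order-invariant.

Probabilities are fractions in the open interval (0, 1) everywhere inside
the package; the percent scale appears only at I/O boundaries.  Degenerate
priors of exactly 0 or 1 are rejected rather than absorbed: a probability
pinned at an endpoint can never be updated again, and the whole point of
the framework is that the estimate stays refreshable as new data arrive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ProbabilityValue",
    "LikelihoodRatio",
    "EvidenceItem",
    "UpdateStep",
    "UpdateTrace",
    "FullPrecision",
    "PrintedCheckpoint",
    "prob_to_odds",
    "odds_to_prob",
    "apply_lr",
    "chain_update",
    "propagate_interval",
    "round_percent",
]


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------

def prob_to_odds(p: float) -> float:
    """Convert a probability fraction to odds, ``p / (1 - p)``.

    Parameters
    ----------
    p : float
        Probability in the open interval (0, 1).

    Returns
    -------
    float
        The corresponding odds, a positive real.

    Raises
    ------
    ValueError
        If ``p`` lies outside (0, 1).
    """
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"probability must lie strictly between 0 and 1, got {p!r}"
        )
    return p / (1.0 - p)


def odds_to_prob(o: float) -> float:
    """Convert odds to a probability fraction, ``o / (1 + o)``.

    Inverse of :func:`prob_to_odds` to within 1e-12.
    """
    if not o > 0.0:
        raise ValueError(f"odds must be positive, got {o!r}")
    return o / (1.0 + o)


def apply_lr(prior: float, lr: float) -> float:
    """Update a prior probability with a likelihood ratio on the odds scale.

    ``posterior = odds_to_prob(prob_to_odds(prior) * lr)``.  Strictly
    increasing in both arguments; the result stays inside (0, 1) for any
    positive finite ``lr``.
    """
    if not lr > 0.0:
        raise ValueError(f"likelihood ratio must be positive, got {lr!r}")
    if not (0.0 < prior < 1.0):
        raise ValueError(
            f"probability must lie strictly between 0 and 1, got {prior!r}"
        )
    if lr == 1.0:  # neutral evidence is exactly neutral, no round-trip noise
        return prior
    return odds_to_prob(prob_to_odds(prior) * lr)


def round_percent(p: float, decimals: int) -> float:
    """Round a probability fraction on the percent scale, half-up.

    Returns the fraction whose percent representation is ``p * 100``
    rounded to ``decimals`` decimal places with half-up tie-breaking
    (the convention used for printed clinical checkpoints: 55.5 -> 56,
    not banker's 55.5 -> 56 vs 56.5 -> 56).
    """
    quantum = Decimal(1).scaleb(-decimals)
    pct = Decimal(repr(p * 100.0)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(pct) / 100.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityValue:
    """A disease probability as a fraction in (0, 1), with an odds view."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(
                f"probability must lie strictly between 0 and 1, got {self.p!r}"
            )

    @property
    def odds(self) -> float:
        return prob_to_odds(self.p)

    @property
    def percent(self) -> float:
        return self.p * 100.0

    @classmethod
    def from_odds(cls, o: float) -> "ProbabilityValue":
        return cls(odds_to_prob(o))

    @classmethod
    def from_percent(cls, pct: float) -> "ProbabilityValue":
        return cls(pct / 100.0)


@dataclass(frozen=True)
class LikelihoodRatio:
    """A multiplicative evidence weight, optionally with a 95% interval.

    ``value`` is the point likelihood ratio; ``ci_low``/``ci_high`` bound
    it when a pooled interval (or a span of study estimates) is available.
    ``source`` carries the citation text so every number in an audit trail
    can be traced to its origin.
    """

    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0.0:
            raise ValueError(f"likelihood ratio must be positive, got {self.value!r}")
        has_low, has_high = self.ci_low is not None, self.ci_high is not None
        if has_low != has_high:
            raise ValueError("interval must supply both ci_low and ci_high")
        if has_low:
            if not (self.ci_low > 0.0 and self.ci_high > 0.0):
                raise ValueError("interval bounds must be positive")
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError(
                    f"interval [{self.ci_low}, {self.ci_high}] must bracket "
                    f"the point value {self.value}"
                )

    @property
    def has_interval(self) -> bool:
        return self.ci_low is not None


@dataclass(frozen=True)
class EvidenceItem:
    """One applicable finding: a label plus its likelihood ratio.

    ``direction`` is purely descriptive — "supports" for LR > 1,
    "refutes" for LR < 1; an LR of exactly 1 is neutral and accepts
    either label.
    """

    label: str
    lr: LikelihoodRatio
    direction: Literal["supports", "refutes"] | None = None

    def __post_init__(self) -> None:
        v = self.lr.value
        if self.direction is None:
            object.__setattr__(
                self, "direction", "supports" if v >= 1.0 else "refutes"
            )
        elif v > 1.0 and self.direction != "supports":
            raise ValueError(f"LR {v} > 1 is 'supports', not {self.direction!r}")
        elif v < 1.0 and self.direction != "refutes":
            raise ValueError(f"LR {v} < 1 is 'refutes', not {self.direction!r}")


@dataclass(frozen=True)
class UpdateStep:
    """One applied update: label, LR value, and the pre/post probabilities."""

    label: str
    lr_value: float
    pre: float
    post: float


# Rounding policies.  FullPrecision chains unrounded probabilities; the
# posterior then equals a single update by the product of all LRs.
# PrintedCheckpoint mimics published bedside arithmetic: at designated
# steps the output probability is rounded (half-up, percent scale) to a
# stated number of decimals before feeding the next step, and a step may
# force-carry a published value that differs from the recomputation within
# tolerance (read-off imprecision of graphical nomogram use).

@dataclass(frozen=True)
class FullPrecision:
    name: str = "full_precision"


@dataclass(frozen=True)
class PrintedCheckpoint:
    """Per-step rounding schedule for replaying printed update chains.

    ``step_decimals[k]`` is the number of percent-scale decimals to round
    step *k*'s output to, or ``None`` for no rounding at that step.
    ``step_overrides[k]``, when not ``None``, replaces step *k*'s carried
    output with a stated probability fraction (the rounded checkpoint is
    still recorded in the trace step for auditing).
    """

    step_decimals: tuple[int | None, ...]
    step_overrides: tuple[float | None, ...] | None = None
    name: str = "printed_checkpoint"


RoundingPolicy = FullPrecision | PrintedCheckpoint


@dataclass(frozen=True)
class UpdateTrace:
    """A fully audited chain of sequential likelihood-ratio updates."""

    prior: ProbabilityValue
    steps: tuple[UpdateStep, ...]
    posterior: ProbabilityValue
    rounding_policy: RoundingPolicy = field(default_factory=FullPrecision)

    @property
    def lr_product(self) -> float:
        return math.prod(s.lr_value for s in self.steps)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_update(
    prior: float,
    evidence: Sequence[EvidenceItem],
    policy: RoundingPolicy | None = None,
) -> UpdateTrace:
    """Apply an ordered sequence of evidence items to a prior probability.

    Under :class:`FullPrecision` the posterior is order-invariant and equals
    a single :func:`apply_lr` call with the product of all LR values (to
    within 1e-12).  Under :class:`PrintedCheckpoint` each step's output is
    rounded per the policy schedule before the next step sees it, which is
    how published bedside chains are actually computed.

    An empty evidence list yields a trace whose posterior equals the prior.
    """
    if policy is None:
        policy = FullPrecision()
    if isinstance(policy, PrintedCheckpoint):
        if len(policy.step_decimals) != len(evidence):
            raise ValueError(
                f"policy declares {len(policy.step_decimals)} steps but "
                f"{len(evidence)} evidence items were given"
            )
        if policy.step_overrides is not None and len(policy.step_overrides) != len(
            evidence
        ):
            raise ValueError("step_overrides length must match evidence length")

    prior_pv = ProbabilityValue(prior)
    steps: list[UpdateStep] = []
    current = prior
    for k, item in enumerate(evidence):
        post = apply_lr(current, item.lr.value)
        if isinstance(policy, PrintedCheckpoint):
            decimals = policy.step_decimals[k]
            if decimals is not None:
                post = round_percent(post, decimals)
            if policy.step_overrides is not None:
                override = policy.step_overrides[k]
                if override is not None:
                    post = override
        steps.append(UpdateStep(item.label, item.lr.value, current, post))
        current = post
    return UpdateTrace(
        prior=prior_pv,
        steps=tuple(steps),
        posterior=ProbabilityValue(current),
        rounding_policy=policy,
    )


# ---------------------------------------------------------------------------
# interval propagation
# ---------------------------------------------------------------------------

def propagate_interval(
    prior: float,
    evidence: Sequence[EvidenceItem],
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo 95% interval for a chained posterior from per-LR intervals.

    Each evidence item's LR is drawn independently on the log scale as
    Normal(log(value), sd) with ``sd = (log(ci_high) - log(ci_low)) / (2 * 1.96)``
    — the usual back-conversion of a reported 95% interval.  Draws are
    combined multiplicatively on the odds scale and the 2.5th/97.5th
    percentiles of the posterior distribution are returned.

    Independence across items is an approximation: correlated findings
    (colinear ECG signs, say) would require a joint model this package
    deliberately does not fit.

    Raises
    ------
    ValueError
        If ``n_draws`` < 1000 or any item lacks an interval (items are
        named in the message).
    """
    if n_draws < 1000:
        raise ValueError(f"n_draws must be at least 1000, got {n_draws}")
    missing = [item.label for item in evidence if not item.lr.has_interval]
    if missing:
        raise ValueError(
            "interval propagation requires a CI on every item; missing for: "
            + ", ".join(missing)
        )
    prior_odds = prob_to_odds(prior)
    rng = np.random.default_rng(seed)
    log_odds = np.full(n_draws, np.log(prior_odds))
    for item in evidence:
        mu = math.log(item.lr.value)
        sd = (math.log(item.lr.ci_high) - math.log(item.lr.ci_low)) / (2.0 * 1.96)
        log_odds += rng.normal(mu, sd, size=n_draws)
    posts = 1.0 / (1.0 + np.exp(-log_odds))
    lo, hi = np.percentile(posts, [2.5, 97.5])
    return float(lo), float(hi)
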