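"""Action tiers and classical test/treatment thresholds.

A posterior probability of occlusion maps onto pragmatic action tiers:
above the catheterization threshold (default 10%) immediate angiography
is on the table; above the fibrinolysis threshold (default 75%) lytic
therapy becomes defensible when angiography is unavailable.  Comparisons
are strictly greater-than — a posterior exactly at a threshold falls to
the lower tier.

The pragmatic cut-points honor the direction of the classical
threshold-of-testing analysis (Pauker & Kassirer), whose expressions are
implemented here so users can check the pragmatic targets against a
utility-based derivation.  Both tier names and report prose are
deliberately non-prescriptive: the framework is didactic, not a device.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Tier",
    "ThresholdPolicy",
    "ThresholdParameters",
    "ThresholdResult",
    "recommend",
    "pauker_kassirer_thresholds",
]


class Tier(enum.Enum):
    SURVEILLANCE = "surveillance"
    ACTIVATE_CATH = "activate_cath"
    ACTIVATE_CATH_AND_LYSIS_ELIGIBLE = "activate_cath_and_lysis_eligible"

    # ordering for monotonicity checks
    @property
    def rank(self) -> int:
        return list(Tier).index(self)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Posterior cut-points for escalation (strict > comparisons)."""

    cath_threshold: float = 0.10
    lysis_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.cath_threshold < self.lysis_threshold < 1.0:
            raise ValueError(
                "thresholds must satisfy 0 < cath < lysis < 1, got "
                f"{self.cath_threshold}, {self.lysis_threshold}"
            )


def recommend(posterior: float, policy: ThresholdPolicy | None = None) -> Tier:
    """Map a posterior probability to an action tier.

    Strictly-greater comparisons: a posterior exactly at a threshold
    stays in the lower tier.  Whether a published cut-point means > or >=
    is usually unstated; strict > is this package's documented choice.
    """
    if not 0.0 < posterior < 1.0:
        raise ValueError(f"posterior must lie in (0, 1), got {posterior}")
    policy = policy or ThresholdPolicy()
    if posterior > policy.lysis_threshold:
        return Tier.ACTIVATE_CATH_AND_LYSIS_ELIGIBLE
    if posterior > policy.cath_threshold:
        return Tier.ACTIVATE_CATH
    return Tier.SURVEILLANCE


@dataclass(frozen=True)
class ThresholdParameters:
    """Utilities for the threshold-of-testing analysis, on a common scale.

    ``brx`` — net benefit of treating a diseased patient; ``rrx`` — net
    harm of treating a non-diseased one; ``rt`` — intrinsic risk of the
    confirmatory test; ``sn``/``sp`` — that test's accuracy.
    """

    brx: float
    rrx: float
    rt: float
    sn: float
    sp: float

    def __post_init__(self) -> None:
        if self.brx <= 0:
            raise ValueError("net treatment benefit brx must be positive")
        for name in ("rrx", "rt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("sn", "sp"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ThresholdResult:
    """The three probability pivots of the classical analysis.

    Below ``testing`` neither testing nor treating is worthwhile; between
    ``testing`` and ``test_treatment`` the test can change management;
    above ``test_treatment`` one treats without further confirmation.
    ``no_test_treatment`` is the treat/no-treat pivot when the test is
    unavailable.  ``test_useful`` is False when the parameters make the
    test never worth its risk (negative numerator before clamping).
    """

    testing: float
    test_treatment: float
    no_test_treatment: float
    test_useful: bool


def pauker_kassirer_thresholds(params: ThresholdParameters) -> ThresholdResult:
    """Classical testing / test-treatment / treatment thresholds.

    Standard textbook forms, invariant to common rescaling of the
    utilities::

        no_test_treatment = Rrx / (Rrx + Brx)
        testing           = ((1-Sp)*Rrx + Rt) / ((1-Sp)*Rrx + Sn*Brx)
        test_treatment    = (Sp*Rrx - Rt) / (Sp*Rrx + (1-Sn)*Brx)

    Results are clamped to [0, 1].  With a risk-free perfect test the
    window is the whole axis (0, 1); an uninformative test collapses both
    thresholds onto the treat/no-treat pivot.
    """
    p = params
    no_test = p.rrx / (p.rrx + p.brx)
    fp_cost = (1.0 - p.sp) * p.rrx
    testing_num = fp_cost + p.rt
    testing_den = fp_cost + p.sn * p.brx
    tt_num = p.sp * p.rrx - p.rt
    tt_den = p.sp * p.rrx + (1.0 - p.sn) * p.brx
    test_useful = tt_num >= 0.0
    if testing_den <= 0.0 or tt_den <= 0.0:
        raise ValueError("degenerate parameters: threshold denominators vanish")
    clamp = lambda x: min(1.0, max(0.0, x))
    return ThresholdResult(
        testing=clamp(testing_num / testing_den),
        test_treatment=clamp(tt_num / tt_den),
        no_test_treatment=clamp(no_test),
        test_useful=test_useful,
    )
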