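"""The numeric evidence base: anchors, clinical LRs, test accuracy.

Three kinds of entries live in one human-editable YAML document:

* **anchors** — age-band baseline prevalences of occlusion MI (OMI) among
  ED chest-pain presentations, together with the pipeline that derives
  them (STEMI ED visit rate -> chest-pain prevalence -> OMI multiplier)
  so a user can audit or re-derive every row;
* **clinical_features** — pre-ECG likelihood ratios for chest-pain
  descriptors and history;
* **tests** — accuracy entries (ECG reading tiers, troponin strategies)
  given either as sensitivity/specificity pairs, from which LR+ = Sn/(1-Sp)
  and LR- = (1-Sn)/Sp are derived, or as directly stated LRs.

No probability or LR is hard-coded in package code; everything numeric
comes from the catalog file, so users can exchange their own priors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import LikelihoodRatio

__all__ = [
    "Catalog",
    "CatalogError",
    "TestCharacteristics",
    "DerivedAnchorRow",
    "load_catalog",
    "save_catalog",
    "default_catalog",
    "anchor_probability",
    "derive_anchor_table",
    "lr_from_accuracy",
    "lookup_clinical_lr",
    "lookup_test_lr",
    "validate_catalog",
]

logger = logging.getLogger(__name__)


class CatalogError(ValueError):
    """A catalog lookup or validation failure."""


# ---------------------------------------------------------------------------
# file schema (pydantic; unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LRSpec(_Strict):
    value: float = Field(gt=0)
    ci_low: float | None = Field(default=None, gt=0)
    ci_high: float | None = Field(default=None, gt=0)
    is_range: bool = False  # interval is a span of study estimates, point is its midpoint

    @model_validator(mode="after")
    def _check_interval(self) -> "LRSpec":
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("interval must supply both ci_low and ci_high")
        if self.ci_low is not None and not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] must bracket {self.value}"
            )
        return self

    def as_lr(self, label: str, source: str) -> LikelihoodRatio:
        return LikelihoodRatio(
            value=self.value,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            label=label,
            source=source,
        )


class AnchorBand(_Strict):
    label: str
    lower: int = Field(ge=0)
    upper: int | None = None  # exclusive; None = unbounded top band
    stemi_rate_per_10k: float = Field(gt=0)
    stemi_prevalence_percent: float = Field(gt=0)
    p_omi_female_percent: float = Field(gt=0, lt=100)
    p_omi_decimals: int = Field(ge=0)  # printed precision of the p_omi figure
    derivation_whitelisted: bool = False
    capped: bool = False
    note: str | None = None


class AnchorSection(_Strict):
    chest_pain_share: float = Field(gt=0, lt=1)
    omi_multiplier: float = Field(gt=0)
    male_odds_multiplier: float = Field(gt=0)
    cap_percent: float = Field(gt=0, lt=100)
    source: str = ""
    bands: list[AnchorBand]

    @model_validator(mode="after")
    def _check_bands(self) -> "AnchorSection":
        if not self.bands:
            raise ValueError("at least one anchor band required")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper is None or b.lower != a.upper:
                raise ValueError(
                    f"bands must be contiguous and ordered: {a.label} then {b.label}"
                )
            if b.p_omi_female_percent < a.p_omi_female_percent:
                raise ValueError("anchor probability must be non-decreasing with age")
        if self.bands[-1].upper is not None:
            raise ValueError("top band must be unbounded (upper: null)")
        return self


class ClinicalFeatureEntry(_Strict):
    id: str
    description: str
    lr_positive: LRSpec
    lr_negative: LRSpec
    source: str


class TestEntry(_Strict):
    id: str
    description: str
    sensitivity: float | None = Field(default=None, gt=0, le=1)
    specificity: float | None = Field(default=None, gt=0, le=1)
    lr_positive: LRSpec | None = None
    lr_negative: LRSpec | None = None
    source: str

    @model_validator(mode="after")
    def _check_forms(self) -> "TestEntry":
        has_acc = self.sensitivity is not None and self.specificity is not None
        if (self.sensitivity is None) != (self.specificity is None):
            raise ValueError("sensitivity and specificity must be given together")
        if not has_acc and (self.lr_positive is None or self.lr_negative is None):
            raise ValueError(
                "a test entry needs sensitivity/specificity or both stated LRs"
            )
        return self


class Catalog(_Strict):
    version: int
    anchors: AnchorSection
    clinical_features: list[ClinicalFeatureEntry]
    tests: list[TestEntry]

    def feature(self, feature_id: str) -> ClinicalFeatureEntry:
        for entry in self.clinical_features:
            if entry.id == feature_id:
                return entry
        raise CatalogError(
            f"unknown clinical feature {feature_id!r}; available: "
            + ", ".join(e.id for e in self.clinical_features)
        )

    def test(self, test_id: str) -> TestEntry:
        for entry in self.tests:
            if entry.id == test_id:
                return entry
        raise CatalogError(
            f"unknown test {test_id!r}; available: "
            + ", ".join(e.id for e in self.tests)
        )


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load and schema-validate a catalog file (default: the shipped one)."""
    if path is None:
        text = (resources.files("omibayes") / "data" / "catalog.yaml").read_text()
    else:
        text = Path(path).read_text()
    return Catalog.model_validate(yaml.safe_load(text))


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog back to YAML (round-trips through load_catalog)."""
    data = catalog.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


_DEFAULT: Catalog | None = None


def default_catalog() -> Catalog:
    """The shipped catalog, loaded once and cached."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_catalog()
    return _DEFAULT


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _band_for_age(catalog: Catalog, age: float) -> AnchorBand:
    bands = catalog.anchors.bands
    if age < bands[0].lower:
        logger.warning(
            "age %s below the youngest anchor band; applying the %s band",
            age,
            bands[0].label,
        )
        return bands[0]
    for band in bands:
        if band.upper is None or band.lower <= age < band.upper:
            if band.lower <= age:
                return band
    raise CatalogError(f"no anchor band covers age {age}")  # pragma: no cover


def anchor_probability(
    age: float,
    sex: Literal["female", "male"],
    catalog: Catalog | None = None,
) -> float:
    """Baseline P(OMI) for an ED chest-pain patient of given age and sex.

    The female anchor is read from the age band containing ``age``; the
    male value applies the catalog's odds-scale multiplier (1.3 by
    default) to the female anchor.  Ages below the youngest band map to
    that band with a logged warning rather than an error.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    catalog = catalog or default_catalog()
    band = _band_for_age(catalog, age)
    p_female = band.p_omi_female_percent / 100.0
    if sex == "female":
        return p_female
    odds = p_female / (1.0 - p_female)
    odds *= catalog.anchors.male_odds_multiplier
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class DerivedAnchorRow:
    """One age band pushed through the anchor derivation pipeline."""

    label: str
    stemi_rate_per_10k: float
    stemi_prevalence: float  # fraction
    p_omi: float  # fraction, after any cap
    capped: bool

    @property
    def display_percent(self) -> str:
        """p_omi on the percent scale at table precision.

        Sub-1% values print with two decimals, larger values with one;
        a capped value prints as stated (integer cap).
        """
        pct = self.p_omi * 100.0
        if self.capped:
            return f"{pct:g}"
        return f"{pct:.2f}" if pct < 1.0 else f"{pct:.1f}"


def derive_anchor_table(
    stemi_rates: dict[str, float],
    chest_pain_share: float = 0.05,
    omi_multiplier: float = 1.7,
    cap_percent: float = 25.0,
) -> list[DerivedAnchorRow]:
    """Run the anchor derivation pipeline over per-band STEMI ED rates.

    ``prevalence = rate / 10000 / chest_pain_share``;
    ``p_omi = prevalence * omi_multiplier``, with the top (last) band
    capped at ``cap_percent``.  Rounding to printed precision is a display
    concern (:attr:`DerivedAnchorRow.display_percent`), never applied to
    the returned fractions.
    """
    if not 0 < chest_pain_share < 1:
        raise ValueError(f"chest_pain_share must be in (0,1), got {chest_pain_share}")
    rows: list[DerivedAnchorRow] = []
    labels = list(stemi_rates)
    for i, label in enumerate(labels):
        rate = stemi_rates[label]
        if not rate > 0:
            raise ValueError(f"STEMI rate must be positive, got {rate} for {label!r}")
        prevalence = rate / 10_000.0 / chest_pain_share
        p_omi = prevalence * omi_multiplier
        capped = False
        if i == len(labels) - 1 and p_omi > cap_percent / 100.0:
            p_omi = cap_percent / 100.0
            capped = True
        rows.append(DerivedAnchorRow(label, rate, prevalence, p_omi, capped))
    return rows


# ---------------------------------------------------------------------------
# test characteristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity with the derived LR+, LR- and DOR.

    ``boundary`` flags perfect-accuracy edges: Sp == 1 gives an infinite
    LR+ and Sn == 1 gives LR- == 0 (and an infinite DOR).  These are
    legitimate summaries of a study that recorded no false positives (or
    negatives) but cannot be chained as multiplicative evidence, so they
    are flagged rather than silently propagated.
    """

    test_id: str
    sensitivity: float
    specificity: float
    lr_positive: float
    lr_negative: float
    dor: float
    boundary: bool
    source: str = ""


def lr_from_accuracy(
    sensitivity: float, specificity: float, test_id: str = "", source: str = ""
) -> TestCharacteristics:
    """Derive LR+, LR- and the diagnostic odds ratio from Sn and Sp.

    ``LR+ = Sn / (1 - Sp)``, ``LR- = (1 - Sn) / Sp``, ``DOR = LR+ / LR-``.
    A test more often right than wrong (Sn + Sp > 1) has LR+ > 1 and
    LR- < 1.
    """
    if not (0 < sensitivity <= 1):
        raise ValueError(f"sensitivity must be in (0, 1], got {sensitivity}")
    if not (0 < specificity <= 1):
        raise ValueError(f"specificity must be in (0, 1], got {specificity}")
    boundary = sensitivity == 1.0 or specificity == 1.0
    lr_pos = math.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = (1.0 - sensitivity) / specificity
    dor = math.inf if lr_neg == 0.0 else lr_pos / lr_neg
    return TestCharacteristics(
        test_id=test_id,
        sensitivity=sensitivity,
        specificity=specificity,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        dor=dor,
        boundary=boundary,
        source=source,
    )


# ---------------------------------------------------------------------------
# lookups
# ---------------------------------------------------------------------------

def lookup_clinical_lr(
    feature_id: str, present: bool, catalog: Catalog | None = None
) -> LikelihoodRatio:
    """The LR a clinical feature contributes, given presence or absence."""
    catalog = catalog or default_catalog()
    entry = catalog.feature(feature_id)
    spec = entry.lr_positive if present else entry.lr_negative
    suffix = "present" if present else "absent"
    return spec.as_lr(f"{entry.description} ({suffix})", entry.source)


def lookup_test_lr(
    test_id: str, positive: bool, catalog: Catalog | None = None
) -> LikelihoodRatio:
    """The LR a test result contributes.

    Stated LRs take precedence over Sn/Sp-derived ones (a source may print
    LRs that its own rounded accuracy figures do not exactly reproduce).
    A result direction for which neither a stated nor a finite derived LR
    exists (e.g. the negative branch of a 100%-sensitive test) raises
    :class:`CatalogError`.
    """
    catalog = catalog or default_catalog()
    entry = catalog.test(test_id)
    stated = entry.lr_positive if positive else entry.lr_negative
    suffix = "positive" if positive else "negative"
    label = f"{entry.description} ({suffix})"
    if stated is not None:
        return stated.as_lr(label, entry.source)
    tc = lr_from_accuracy(entry.sensitivity, entry.specificity, entry.id, entry.source)
    value = tc.lr_positive if positive else tc.lr_negative
    if not math.isfinite(value) or value == 0.0:
        raise CatalogError(
            f"test {test_id!r} has a boundary {suffix} LR ({value}); it cannot "
            "be chained multiplicatively — supply a stated LR instead"
        )
    return LikelihoodRatio(value=value, label=label, source=entry.source)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationRow:
    section: str
    key: str
    ok: bool
    whitelisted: bool
    message: str


def validate_catalog(catalog: Catalog | None = None) -> list[ValidationRow]:
    """Row-level consistency report for a catalog.

    Anchor rows are re-derived through the stated pipeline and compared to
    the stored figures at their printed precision (tolerance: half of the
    last printed digit).  Whitelisted rows (published figures that the
    pipeline does not reproduce) are reported as such, never silently
    passed.  Test entries get their DOR identity checked.
    """
    catalog = catalog or default_catalog()
    rows: list[ValidationRow] = []
    a = catalog.anchors
    derived = derive_anchor_table(
        {b.label: b.stemi_rate_per_10k for b in a.bands},
        chest_pain_share=a.chest_pain_share,
        omi_multiplier=a.omi_multiplier,
        cap_percent=a.cap_percent,
    )
    for band, der in zip(a.bands, derived):
        # prevalence column always prints two decimals
        prev_ok = abs(der.stemi_prevalence * 100.0 - band.stemi_prevalence_percent) <= 0.005
        tol = 0.5 * 10.0 ** (-band.p_omi_decimals)
        p_omi_ok = band.capped or (
            abs(der.p_omi * 100.0 - band.p_omi_female_percent) <= tol
        )
        ok = prev_ok and p_omi_ok
        msg = (
            f"derived prevalence {der.stemi_prevalence * 100.0:.3f}% vs stored "
            f"{band.stemi_prevalence_percent}%; derived P(OMI) "
            f"{der.p_omi * 100.0:.3f}% vs stored {band.p_omi_female_percent}%"
        )
        if band.capped:
            msg += " (capped)"
        if not ok and band.derivation_whitelisted:
            msg += " — whitelisted published discrepancy"
            logger.info("anchor band %s: %s", band.label, msg)
        rows.append(
            ValidationRow(
                "anchors", band.label, ok or band.derivation_whitelisted,
                not ok and band.derivation_whitelisted, msg,
            )
        )
    for entry in catalog.tests:
        if entry.sensitivity is not None:
            tc = lr_from_accuracy(entry.sensitivity, entry.specificity, entry.id)
            if math.isfinite(tc.dor) and tc.lr_negative > 0:
                ok = abs(tc.dor - tc.lr_positive / tc.lr_negative) <= 1e-9
                msg = f"DOR {tc.dor:.4g} == LR+/LR-"
            else:
                ok = True
                msg = "boundary accuracy (Sn or Sp == 1); DOR unbounded"
            rows.append(ValidationRow("tests", entry.id, ok, False, msg))
        else:
            rows.append(
                ValidationRow("tests", entry.id, True, False, "stated LRs only")
            )
    return rows
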