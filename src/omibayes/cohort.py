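"""Synthetic-cohort simulation and calibration of the chained posterior.

The updating engine multiplies likelihood ratios as if findings were
conditionally independent given disease status.  This module makes that
assumption testable: it generates cohorts *under* the framework's own
generative model (disease ~ Bernoulli(prevalence); each finding positive
with probability Sn in the diseased and 1-Sp in the non-diseased),
chains the posterior for every simulated patient, and measures how well
predicted probabilities match observed disease frequencies.

Under independence (rho = 0) the chained posterior is the exact
conditional probability, so the calibration slope on the logit scale is
1 up to Monte-Carlo error.  Setting rho > 0 couples the findings through
a Gaussian copula (one shared latent factor per patient, identical rho
in both disease classes) while the engine keeps multiplying LRs as if
independent — the resulting mis-calibration is the quantitative face of
the serial-multiplication caveat: colinear findings double-count
evidence and push posteriors toward the extremes.

Simulated probabilities here are single-number prevalences or anchor-band
draws; real cohorts have case-mix, spectrum and verification effects that
no part of this generator emulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import norm

from .catalog import Catalog, default_catalog
from .decision import ThresholdPolicy, Tier, recommend

__all__ = [
    "FindingSpec",
    "SimulationConfig",
    "CohortResult",
    "CalibrationReport",
    "simulate_cohort",
    "calibration_report",
    "policy_sweep",
]

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FindingSpec(_Strict):
    """One binary finding with enough information to simulate it.

    Three acceptable forms, in order of precedence:

    * ``sensitivity`` + ``specificity`` — used directly;
    * ``lr_positive`` + ``rate_nondiseased`` — the positivity rate in the
      non-diseased fixes Sp = 1 - rate, and Sn = LR+ * rate is solved from
      the LR (solved values are logged);
    * ``lr_positive`` + ``lr_negative`` — the pair determines Sn and Sp
      uniquely: Sp = (LR+ - 1)/(LR+ - LR-), Sn = LR+ * (1 - Sp), valid
      when LR+ > 1 > LR-.

    A finding that resolves to neither both Sn and Sp is a config error.
    """

    id: str
    sensitivity: float | None = Field(default=None, gt=0, lt=1)
    specificity: float | None = Field(default=None, gt=0, lt=1)
    lr_positive: float | None = Field(default=None, gt=0)
    lr_negative: float | None = Field(default=None, gt=0)
    rate_nondiseased: float | None = Field(default=None, gt=0, lt=1)

    def resolve(self) -> tuple[float, float]:
        """Return (sensitivity, specificity)."""
        if self.sensitivity is not None and self.specificity is not None:
            return self.sensitivity, self.specificity
        if self.lr_positive is not None and self.rate_nondiseased is not None:
            sp = 1.0 - self.rate_nondiseased
            sn = self.lr_positive * self.rate_nondiseased
            if not 0.0 < sn < 1.0:
                raise ValueError(
                    f"finding {self.id!r}: solved sensitivity {sn:.4f} outside "
                    "(0,1); lower rate_nondiseased or the LR"
                )
            logger.info(
                "finding %s: solved Sn=%.4f, Sp=%.4f from LR+=%.3g and "
                "non-diseased rate %.3g",
                self.id, sn, sp, self.lr_positive, self.rate_nondiseased,
            )
            return sn, sp
        if self.lr_positive is not None and self.lr_negative is not None:
            if not self.lr_positive > 1.0 > self.lr_negative:
                raise ValueError(
                    f"finding {self.id!r}: LR pair must satisfy LR+ > 1 > LR-"
                )
            sp = (self.lr_positive - 1.0) / (self.lr_positive - self.lr_negative)
            sn = self.lr_positive * (1.0 - sp)
            logger.info(
                "finding %s: solved Sn=%.4f, Sp=%.4f from LR pair (%.3g, %.3g)",
                self.id, sn, sp, self.lr_positive, self.lr_negative,
            )
            return sn, sp
        raise ValueError(
            f"finding {self.id!r} needs sensitivity+specificity, "
            "lr_positive+rate_nondiseased, or lr_positive+lr_negative"
        )

    def chained_lrs(self) -> tuple[float, float]:
        """(LR+, LR-) the engine multiplies with — consistent with the
        generating Sn/Sp so that calibration is exact under independence."""
        sn, sp = self.resolve()
        return sn / (1.0 - sp), (1.0 - sn) / sp


class SimulationConfig(_Strict):
    """Generative settings for one synthetic cohort."""

    n: int = Field(ge=1)
    prevalence: float | None = Field(default=None, gt=0, lt=1)
    demographic_mix: bool = False  # draw prevalence from the anchor table instead
    findings: list[FindingSpec]
    rho: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0
    cath_threshold: float = Field(default=0.10, gt=0, lt=1)
    lysis_threshold: float = Field(default=0.75, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.findings:
            raise ValueError("at least one finding required")
        if (self.prevalence is None) == (not self.demographic_mix):
            raise ValueError("give exactly one of prevalence or demographic_mix")
        if not self.cath_threshold < self.lysis_threshold:
            raise ValueError("cath_threshold must be below lysis_threshold")
        return self

    @property
    def policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(self.cath_threshold, self.lysis_threshold)


@dataclass(frozen=True)
class CohortResult:
    """Per-patient rows plus a summary recomputable from them."""

    config: SimulationConfig
    patients: pd.DataFrame  # disease, f_<id>..., prior, posterior, tier

    def summary(self) -> dict:
        df = self.patients
        diseased = df["disease"].astype(bool)
        activated = df["tier"] != Tier.SURVEILLANCE.value
        n_act = int(activated.sum())
        return {
            "n": len(df),
            "prevalence_observed": float(diseased.mean()),
            "activation_rate": float(activated.mean()),
            "activation_sensitivity": float(activated[diseased].mean())
            if diseased.any() else float("nan"),
            "activation_specificity": float((~activated[~diseased]).mean())
            if (~diseased).any() else float("nan"),
            "false_activation_fraction": float((~diseased[activated]).mean())
            if n_act else float("nan"),
            "missed_occlusion_rate": float((~activated[diseased]).mean())
            if diseased.any() else float("nan"),
            "mean_posterior": float(df["posterior"].mean()),
        }


def simulate_cohort(
    config: SimulationConfig, catalog: Catalog | None = None
) -> CohortResult:
    """Generate one cohort and chain every patient's posterior.

    Reproducible for a fixed config (seed included): the same config
    object always yields the same per-patient table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.demographic_mix:
        # equal weight per anchor band, 50/50 sex — an arbitrary but
        # documented default; real ED case-mix is not modeled
        from .catalog import anchor_probability

        catalog = catalog or default_catalog()
        bands = catalog.anchors.bands
        band_idx = rng.integers(0, len(bands), size=n)
        male = rng.random(n) < 0.5
        prior = np.array(
            [
                anchor_probability(
                    bands[b].lower, "male" if m else "female", catalog
                )
                for b, m in zip(band_idx, male)
            ]
        )
    else:
        prior = np.full(n, config.prevalence)

    disease = rng.random(n) < prior

    k = len(config.findings)
    sn = np.empty(k)
    sp = np.empty(k)
    lr_pos = np.empty(k)
    lr_neg = np.empty(k)
    for j, f in enumerate(config.findings):
        sn[j], sp[j] = f.resolve()
        lr_pos[j], lr_neg[j] = f.chained_lrs()

    # P(finding j positive | status), per patient
    p_pos = np.where(disease[:, None], sn[None, :], 1.0 - sp[None, :])
    if config.rho == 0.0:
        positive = rng.random((n, k)) < p_pos
    else:
        shared = rng.standard_normal(n)
        eps = rng.standard_normal((n, k))
        z = np.sqrt(config.rho) * shared[:, None] + np.sqrt(1.0 - config.rho) * eps
        positive = z < norm.ppf(p_pos)

    log_odds = np.log(prior / (1.0 - prior))
    log_odds = log_odds + np.where(
        positive, np.log(lr_pos)[None, :], np.log(lr_neg)[None, :]
    ).sum(axis=1)
    posterior = 1.0 / (1.0 + np.exp(-log_odds))

    policy = config.policy
    tier = np.where(
        posterior > policy.lysis_threshold,
        Tier.ACTIVATE_CATH_AND_LYSIS_ELIGIBLE.value,
        np.where(
            posterior > policy.cath_threshold,
            Tier.ACTIVATE_CATH.value,
            Tier.SURVEILLANCE.value,
        ),
    )

    data = {"disease": disease.astype(int), "prior": prior}
    for j, f in enumerate(config.findings):
        data[f"f_{f.id}"] = positive[:, j].astype(int)
    data["posterior"] = posterior
    data["tier"] = tier
    return CohortResult(config=config, patients=pd.DataFrame(data))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    """Binned reliability table plus a logit-scale calibration fit.

    ``slope``/``intercept`` come from the logistic regression of observed
    disease on logit(predicted posterior); perfect calibration gives
    slope 1 and intercept 0.  ``slope_ci`` is the Wald 95% interval.
    """

    table: pd.DataFrame  # bin, mean_posterior, observed_fraction, count
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


def calibration_report(result: CohortResult, n_bins: int = 10) -> CalibrationReport:
    """Bin predicted posteriors and fit the logit-scale calibration line.

    Bins partition [0, 1] into ``n_bins`` equal-width intervals; empty
    bins appear in the table with count 0 (observed fraction NaN), never
    dropped silently.
    """
    import statsmodels.api as sm

    df = result.patients
    if df.empty:
        raise ValueError("empty cohort")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(df["posterior"], edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_posterior": float(df["posterior"][mask].mean()) if count else float("nan"),
                "observed_fraction": float(df["disease"][mask].mean()) if count else float("nan"),
                "count": count,
            }
        )
    table = pd.DataFrame(rows)

    logit_p = np.log(df["posterior"] / (1.0 - df["posterior"]))
    X = sm.add_constant(logit_p.to_numpy())
    fit = sm.GLM(df["disease"].to_numpy(), X, family=sm.families.Binomial()).fit()
    ci = fit.conf_int()
    return CalibrationReport(
        table=table,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
    )


def policy_sweep(
    config: SimulationConfig,
    thresholds: list[float] | np.ndarray,
    catalog: Catalog | None = None,
) -> pd.DataFrame:
    """Operating characteristics of activation across a threshold grid.

    One cohort is simulated (so the grid is evaluated on common patients)
    and, per threshold t: activation rate P(posterior > t), sensitivity
    for occlusion P(posterior > t | disease), and false-activation
    fraction P(no disease | posterior > t).  Both rates are non-increasing
    in t.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds < 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in [0, 1)")
    result = simulate_cohort(config, catalog)
    df = result.patients
    diseased = df["disease"].astype(bool).to_numpy()
    post = df["posterior"].to_numpy()
    rows = []
    for t in thresholds:
        act = post > t
        n_act = int(act.sum())
        rows.append(
            {
                "threshold": float(t),
                "activation_rate": float(act.mean()),
                "sensitivity": float(act[diseased].mean()) if diseased.any() else float("nan"),
                "false_activation_fraction": float((~diseased[act]).mean()) if n_act else float("nan"),
            }
        )
    return pd.DataFrame(rows)
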