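"""Validation statistics for questionnaire-based exposure estimates.

The estimates are only meant to rank subjects by exposure, so agreement with
paired measurements is assessed by Spearman rank correlation.  Confidence
intervals use the Fisher z transform (half-width z_{1-a/2} / sqrt(n - 3),
back-transformed); correlations of two models validated against the *same*
measured vector are compared with Steiger's dependent-correlation z-test.
A variance-ratio F-test compares wattage spread between the model-building
and validation populations, and a simple threshold flag marks readings above
the 27 uT reference level for the 3 kHz - 10 MHz band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, PairingError, UnestimableError
from .exposure_model import ModelCoefficients, estimate_from_questionnaire
from .survey_io import QuestionnaireResponse

ICNIRP_PUBLIC_LIMIT_UT = 27.0
"""Public-exposure reference level (uT) for the 3 kHz - 10 MHz band."""


@dataclass(frozen=True)
class ValidationResult:
    """Spearman validation of one model against paired measurements."""

    model_id: Optional[int]
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self):
        if not (-1 - 1e-12 <= self.ci_low <= self.rho + 1e-12
                and self.rho <= self.ci_high + 1e-12 <= 1 + 1e-12):
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                f"rho = {self.rho}"
            )


def spearman_with_ci(
    estimates: Sequence[float],
    measurements: Sequence[float],
    model_id: Optional[int] = None,
    alpha: float = 0.05,
) -> ValidationResult:
    """Spearman rho with a Fisher-z confidence interval.

    Ties get average ranks; the p-value uses the t approximation.  Requires
    paired samples of n >= 4 with no missing values.
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(measurements, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"unpaired samples: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 4:
        raise DegenerateTestError(f"need n >= 4 paired values, got {n}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise DegenerateTestError("missing/non-finite values in paired samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateTestError("correlation undefined for a constant vector")
    sp = stats.spearmanr(x, y)
    rho = float(sp.statistic)
    p = float(sp.pvalue)
    if abs(rho) >= 1.0:
        ci_low = ci_high = rho
    else:
        half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
        z = math.atanh(rho)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return ValidationResult(model_id, rho, ci_low, ci_high, p, n)


def compare_correlations(
    result_a: ValidationResult,
    result_b: ValidationResult,
    rho_ab: float,
) -> tuple[float, float]:
    """Steiger's z-test for two dependent correlations sharing one variable.

    ``rho_ab`` is the (rank) correlation between the two estimate vectors;
    both results must come from the same n subjects against the same measured
    values.  Returns ``(z, two-sided p)``; z is antisymmetric in the two
    results.
    """
    if result_a.n != result_b.n:
        raise PairingError(
            f"results computed on different n: {result_a.n} vs {result_b.n}"
        )
    n = result_a.n
    r1, r2 = result_a.rho, result_b.rho
    if r1 == r2:
        return 0.0, 1.0
    rbar = (r1 + r2) / 2.0
    psi = rho_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - rho_ab**2)
    c = psi / (1 - rbar**2) ** 2
    z = (math.atanh(r1) - math.atanh(r2)) * math.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def variance_ratio_test(
    wattages_a: Sequence[float], wattages_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided variance-ratio F-test between two wattage samples.

    F is the larger sample variance over the smaller; p comes from the F
    distribution with the matching degrees of freedom, doubled and capped
    at 1.
    """
    a = np.asarray(wattages_a, dtype=float)
    b = np.asarray(wattages_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateTestError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise DegenerateTestError("zero variance in a sample; F undefined")
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return float(f), p


def guideline_flag(b_ut, limit_ut: float = ICNIRP_PUBLIC_LIMIT_UT):
    """True where flux density strictly exceeds the public reference level."""
    b = np.asarray(b_ut, dtype=float)
    if np.any(b < 0):
        raise ValueError("flux density must be >= 0")
    out = b > limit_ut
    return out if out.ndim else bool(out)


@dataclass
class ValidationReport:
    """Per-model validation plus all pairwise model comparisons."""

    results: list[ValidationResult]
    pairwise: list[dict]  # model_a, model_b, z, p
    estimates_by_model: dict[int, np.ndarray]
    measured: np.ndarray
    skipped_models: list[int]


def validate_survey(
    responses: Sequence[QuestionnaireResponse],
    coefs_by_model: Mapping[int, ModelCoefficients],
    **estimate_kwargs,
) -> ValidationReport:
    """Run the full validation stage on a survey with paired measurements.

    For each supplied model, every subject is estimated with that model alone;
    models whose covariates any subject lacks are skipped (noted in the
    report).  Spearman results and Steiger pairwise comparisons are computed
    against the shared measured vector.
    """
    if not responses:
        raise DegenerateTestError("empty survey")
    if any(r.measured_b_ut is None for r in responses):
        raise DegenerateTestError(
            "validation requires measured_b_ut for every subject"
        )
    measured = np.array([r.measured_b_ut for r in responses], dtype=float)
    estimates: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for model_id in sorted(coefs_by_model):
        try:
            est = [
                estimate_from_questionnaire(
                    r, {model_id: coefs_by_model[model_id]}, **estimate_kwargs
                )[0]
                for r in responses
            ]
        except UnestimableError:
            skipped.append(model_id)
            continue
        estimates[model_id] = np.asarray(est)
    results = [
        spearman_with_ci(est, measured, model_id=mid)
        for mid, est in estimates.items()
    ]
    by_id = {r.model_id: r for r in results}
    pairwise = []
    ids = sorted(estimates)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rho_ab = float(stats.spearmanr(estimates[a], estimates[b]).statistic)
            z, p = compare_correlations(by_id[a], by_id[b], rho_ab)
            pairwise.append({"model_a": a, "model_b": b, "z": z, "p": p})
    return ValidationReport(results, pairwise, estimates, measured, skipped)
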