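"""Dipole-decay models of the magnetic field around an induction cooker.

An induction cooker is approximated as a magnetic dipole at the hob center,
so flux density falls off with the cube of the distance to the evaluation
point.  Four nested models share the form

    B = (beta1 * mu * sqrt(W) + beta2 * (phi_c / 2)**2 + epsilon) / (4 pi r**3)

with r = sqrt(dh**2 + h**2) the radial distance (m) from the hob center to
the point of interest, W the rated wattage, phi_c the cookware diameter (m),
and B in microtesla.  sqrt(W) stands in for the coil current (power scales
with current squared through the load resistance); the squared cookware
radius adjusts for the loaded area of the pot bottom.  The numerator terms
present per model:

    model 1: beta1, beta2, epsilon     model 3: beta2, epsilon
    model 2: beta1, epsilon            model 4: epsilon

Model 4 is the pure-geometry fallback for questionnaires that report only a
distance.  With a negative beta2 the numerator can go negative for large
cookware; :func:`predict` returns the raw value (fitting needs unfloored
residuals) while :func:`estimate_from_questionnaire` floors reported
exposures at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .anthropometry import DEFAULT_TABLE_HEIGHT_M, height_above_table
from .errors import (
    FormatError,
    MissingVariableError,
    SingularityError,
    UnestimableError,
)
from .survey_io import QuestionnaireResponse

MU = 1.257e-6
"""Magnetic permeability constant as used in the field calibration.

Kept at the calibration's printed precision rather than free-space
4*pi*1e-7 = 1.25664e-6, for compatibility with the shipped coefficients."""

DEFAULT_HOB_OFFSET_M = 0.239
"""Mean horizontal distance (m) from hob center to cooktop edge."""

MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("beta1", "beta2", "epsilon"),
    2: ("beta1", "epsilon"),
    3: ("beta2", "epsilon"),
    4: ("epsilon",),
}

#: Device covariates each model needs beyond geometry.
MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: ("wattage_w", "cookware_diameter_m"),
    2: ("wattage_w",),
    3: ("cookware_diameter_m",),
    4: (),
}


@dataclass
class ModelCoefficients:
    """Coefficients (and optional fit diagnostics) for one dipole model.

    Exactly the model's own terms may be set: ``beta1`` for models 1-2,
    ``beta2`` for models 1 and 3, ``epsilon`` always.  ``stderr``/
    ``tvalues``/``pvalues`` are keyed by term name when produced by fitting.
    """

    model_id: int
    epsilon: float
    beta1: Optional[float] = None
    beta2: Optional[float] = None
    stderr: Optional[dict[str, float]] = None
    tvalues: Optional[dict[str, float]] = None
    pvalues: Optional[dict[str, float]] = None
    aic: Optional[float] = None
    rss: Optional[float] = None
    n_obs: Optional[int] = None
    loss_scale: Optional[str] = None

    def __post_init__(self):
        if self.model_id not in MODEL_TERMS:
            raise ValueError(f"model_id must be 1-4, got {self.model_id}")
        terms = MODEL_TERMS[self.model_id]
        if ("beta1" in terms) != (self.beta1 is not None):
            raise ValueError(
                f"model {self.model_id}: beta1 must be "
                f"{'set' if 'beta1' in terms else 'absent'}"
            )
        if ("beta2" in terms) != (self.beta2 is not None):
            raise ValueError(
                f"model {self.model_id}: beta2 must be "
                f"{'set' if 'beta2' in terms else 'absent'}"
            )

    @property
    def terms(self) -> tuple[str, ...]:
        return MODEL_TERMS[self.model_id]

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(getattr(self, t) for t in self.terms)

    def significant_terms(self, alpha: float = 0.05) -> dict[str, bool]:
        if self.pvalues is None:
            raise ValueError("no p-values attached; fit the model first")
        return {t: self.pvalues[t] < alpha for t in self.terms}


@dataclass(frozen=True)
class ExposureQuery:
    """Evaluation point and covariates for a single prediction.

    ``dh_m`` is the horizontal distance from the hob center, ``h_m`` the
    signed height above the cooking-table plane (both meters).
    """

    dh_m: float
    h_m: float
    wattage_w: Optional[float] = None
    cookware_diameter_m: Optional[float] = None

    def __post_init__(self):
        if self.dh_m < 0:
            raise ValueError(f"dh_m must be >= 0, got {self.dh_m}")
        if self.dh_m == 0 and self.h_m == 0:
            raise SingularityError("query sits at the hob center (dh = h = 0)")


def radial_distance(dh_m: float, h_m: float) -> float:
    """Radial distance r = sqrt(dh^2 + h^2) from the hob center (m)."""
    if dh_m == 0 and h_m == 0:
        raise SingularityError("radial distance undefined at the hob center")
    return math.hypot(dh_m, h_m)


def edge_to_center(d_edge_m: float, hob_offset_m: float) -> float:
    """Convert an edge-referenced distance to a hob-center distance (m).

    Campaign grids measure from the cooktop edge; the models are defined on
    distance from the hob center, so the household's hob offset is added.
    """
    if d_edge_m < 0 or hob_offset_m < 0:
        raise ValueError(
            f"distances must be non-negative, got d_edge={d_edge_m}, "
            f"offset={hob_offset_m}"
        )
    return d_edge_m + hob_offset_m


def numerator(coefs: ModelCoefficients, query: ExposureQuery, mu: float = MU) -> float:
    """Dipole-moment numerator of the model (can be negative)."""
    total = coefs.epsilon
    if coefs.beta1 is not None:
        if query.wattage_w is None:
            raise MissingVariableError(
                f"model {coefs.model_id} requires wattage_w"
            )
        total += coefs.beta1 * mu * math.sqrt(query.wattage_w)
    if coefs.beta2 is not None:
        if query.cookware_diameter_m is None:
            raise MissingVariableError(
                f"model {coefs.model_id} requires cookware_diameter_m"
            )
        total += coefs.beta2 * (query.cookware_diameter_m / 2.0) ** 2
    return total


def predict(coefs: ModelCoefficients, query: ExposureQuery, mu: float = MU) -> float:
    """Predicted flux density (uT) at the query point.

    Returns the raw model value; it is negative whenever the numerator is
    (possible for models 1 and 3 with large cookware).  Callers that report
    exposures should floor at zero; callers computing residuals must not.
    """
    r = radial_distance(query.dh_m, query.h_m)
    return numerator(coefs, query, mu) / (4.0 * math.pi * r**3)


def query_from_response(
    response: QuestionnaireResponse,
    *,
    default_hob_offset_m: float = DEFAULT_HOB_OFFSET_M,
    table_height_m: float = DEFAULT_TABLE_HEIGHT_M,
) -> ExposureQuery:
    """Geometry + covariates for a subject's usual cooking position.

    Self-reported hob-center distance is preferred; otherwise the edge
    distance plus a configured hob offset is used.
    """
    if response.dh_center_cm is not None:
        dh_m = response.dh_center_cm / 100.0
    elif response.d_edge_cm is not None:
        dh_m = edge_to_center(response.d_edge_cm / 100.0, default_hob_offset_m)
    else:  # pragma: no cover - blocked by QuestionnaireResponse invariant
        raise UnestimableError(f"subject {response.subject_id!r} reported no distance")
    return ExposureQuery(
        dh_m=dh_m,
        h_m=height_above_table(response.stature_cm, table_height_m),
        wattage_w=response.wattage_w,
        cookware_diameter_m=(
            None
            if response.cookware_diameter_cm is None
            else response.cookware_diameter_cm / 100.0
        ),
    )


def estimate_from_questionnaire(
    response: QuestionnaireResponse,
    coefs_by_model: Mapping[int, ModelCoefficients],
    *,
    default_hob_offset_m: float = DEFAULT_HOB_OFFSET_M,
    table_height_m: float = DEFAULT_TABLE_HEIGHT_M,
    mu: float = MU,
) -> tuple[float, int]:
    """Estimate a subject's exposure (uT) from questionnaire answers.

    The lowest-numbered model whose covariates are all answered (and whose
    coefficients are supplied) is used -- the fully adjusted model is
    preferred whenever wattage and cookware diameter are available, falling
    back to the pure-geometry model otherwise.  Negative raw predictions are
    floored at zero with a warning.  Returns ``(b_ut, model_used)``.
    """
    query = query_from_response(
        response,
        default_hob_offset_m=default_hob_offset_m,
        table_height_m=table_height_m,
    )
    for model_id in sorted(coefs_by_model):
        needed = MODEL_COVARIATES[model_id]
        if all(getattr(query, v) is not None for v in needed):
            b = predict(coefs_by_model[model_id], query, mu)
            if b < 0:
                warnings.warn(
                    f"subject {response.subject_id!r}: model {model_id} "
                    f"prediction {b:.4g} uT is negative; reporting 0",
                    stacklevel=2,
                )
                b = 0.0
            return b, model_id
    raise UnestimableError(
        f"subject {response.subject_id!r}: no supplied model's variables are "
        "all answered"
    )


def read_coefficients_csv(path) -> dict[int, ModelCoefficients]:
    """Read a coefficient table (columns model_id, beta1, beta2, epsilon[, aic])."""
    df = pd.read_csv(path)
    missing = [c for c in ("model_id", "epsilon") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    out: dict[int, ModelCoefficients] = {}
    for row in df.to_dict(orient="records"):
        mid = int(row["model_id"])

        def _opt(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        out[mid] = ModelCoefficients(
            model_id=mid,
            epsilon=float(row["epsilon"]),
            beta1=_opt("beta1"),
            beta2=_opt("beta2"),
            aic=_opt("aic"),
        )
    return out


def write_coefficients_csv(path, coefs_by_model: Mapping[int, ModelCoefficients]) -> None:
    rows = [
        {
            "model_id": c.model_id,
            "beta1": c.beta1,
            "beta2": c.beta2,
            "epsilon": c.epsilon,
            "aic": c.aic,
        }
        for _, c in sorted(coefs_by_model.items())
    ]
    pd.DataFrame(rows, columns=["model_id", "beta1", "beta2", "epsilon", "aic"]).to_csv(
        path, index=False
    )


def load_default_coefficients() -> dict[int, ModelCoefficients]:
    """Packaged coefficients from the published Phase-1 campaign fit."""
    ref = resources.files("cookfield") / "data/default_coefficients.csv"
    with resources.as_file(ref) as p:
        return read_coefficients_csv(p)
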