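"""Least-squares fitting of the dipole models to grid campaigns.

Each campaign reading becomes one design row pairing an
:class:`~cookfield.exposure_model.ExposureQuery` (hob-center geometry plus
device covariates) with the observed flux density.  Models are fitted by
iterative least squares (Levenberg-Marquardt via
``scipy.optimize.least_squares``); standard errors come from the linearized
Gauss-Newton covariance s^2 (J^T J)^-1, t-statistics use n - k degrees of
freedom, and models are ranked by Gaussian-likelihood AIC.

Two loss scales are available.  ``"natural"`` (default) minimizes squared
residuals in microtesla, mirroring the original campaign analysis.  ``"log"``
minimizes squared log-residuals, the maximum-likelihood choice when the
measurement error is multiplicative lognormal (which the campaign's GM/GSD
structure suggests).  AIC values are only comparable within one scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, LinkageError, MissingVariableError
from .exposure_model import (
    MODEL_TERMS,
    MU,
    ExposureQuery,
    ModelCoefficients,
    edge_to_center,
    radial_distance,
)
from .survey_io import GridMeasurement, HouseholdDevice

_COST_TOL = 1e-10
_MAX_NFEV = 10_000


@dataclass(frozen=True)
class DesignRow:
    """One fitting observation: a query and the measured flux density."""

    query: ExposureQuery
    b_ut: float


def build_design(
    measurements: Iterable[GridMeasurement],
    devices: Iterable[HouseholdDevice],
) -> list[DesignRow]:
    """Map campaign readings to model queries.

    Grid heights are already referenced to the cooktop plane, so they pass
    through unchanged; edge distances are shifted to hob-center distances by
    each household's hob offset.  Raises :class:`LinkageError` for readings
    whose household has no device covariates.
    """
    by_id = {d.household_id: d for d in devices}
    rows = []
    for m in measurements:
        dev = by_id.get(m.household_id)
        if dev is None:
            raise LinkageError(
                f"measurement references unknown household {m.household_id!r}"
            )
        rows.append(
            DesignRow(
                query=ExposureQuery(
                    dh_m=edge_to_center(m.d_cm / 100.0, dev.hob_offset_m),
                    h_m=m.h_cm / 100.0,
                    wattage_w=dev.wattage_w,
                    cookware_diameter_m=dev.cookware_diameter_m,
                ),
                b_ut=m.b_ut,
            )
        )
    return rows


def aic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC for a least-squares fit.

    ``k`` counts the model coefficients; the error variance adds one more
    parameter.  The Gaussian constant is included:

        AIC = n * (ln(2 pi rss / n) + 1) + 2 (k + 1)

    Only differences matter for ranking, so any fixed-constant convention
    gives the same model order; this one is stated so alternatives can be
    reconciled.  ``rss = 0`` returns ``-inf`` with a warning.
    """
    if n <= 0 or rss < 0:
        raise ValueError(f"need n > 0 and rss >= 0, got n={n}, rss={rss}")
    if rss == 0:
        warnings.warn("rss is exactly 0; AIC is -inf", stacklevel=2)
        return -math.inf
    return n * (math.log(2.0 * math.pi * rss / n) + 1.0) + 2.0 * (k + 1)


def _design_matrices(
    design: Sequence[DesignRow], model_id: int, mu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-term numerator columns C, geometry factor g = 1/(4 pi r^3), and y.

    Every model is linear in its coefficients: pred = (C @ theta) * g.
    """
    terms = MODEL_TERMS[model_id]
    n = len(design)
    cols = np.empty((n, len(terms)))
    g = np.empty(n)
    y = np.empty(n)
    for i, row in enumerate(design):
        q = row.query
        r = radial_distance(q.dh_m, q.h_m)
        g[i] = 1.0 / (4.0 * math.pi * r**3)
        y[i] = row.b_ut
        for j, t in enumerate(terms):
            if t == "beta1":
                if q.wattage_w is None:
                    raise MissingVariableError(
                        f"model {model_id} requires wattage_w for every design row"
                    )
                cols[i, j] = mu * math.sqrt(q.wattage_w)
            elif t == "beta2":
                if q.cookware_diameter_m is None:
                    raise MissingVariableError(
                        f"model {model_id} requires cookware_diameter_m for "
                        "every design row"
                    )
                cols[i, j] = (q.cookware_diameter_m / 2.0) ** 2
            else:
                cols[i, j] = 1.0
    return cols, g, y


def _default_init(
    C: np.ndarray, g: np.ndarray, y: np.ndarray, terms: tuple[str, ...]
) -> np.ndarray:
    """Starting point: a one-term pre-fit on the leading term, rest at zero.

    For the geometry-only model the robust median ratio is used instead so
    the iterative path is independent of the least-squares closed form.
    """
    x0 = np.zeros(len(terms))
    if terms == ("epsilon",):
        x0[0] = float(np.median(y / g))
    else:
        a = C[:, 0] * g
        x0[0] = float(a @ y / (a @ a))
    return x0


def fit_model(
    design: Sequence[DesignRow],
    model_id: int,
    init: Optional[Sequence[float]] = None,
    loss_scale: str = "natural",
    mu: float = MU,
) -> ModelCoefficients:
    """Fit one dipole model to a campaign design by least squares.

    Returns coefficients with standard errors, t, two-sided p (t-distribution,
    n - k df) and AIC attached.  Raises :class:`FitError` for underdetermined
    designs, non-convergence or a rank-deficient Jacobian.
    """
    if loss_scale not in ("natural", "log"):
        raise ValueError(f"loss_scale must be 'natural' or 'log', got {loss_scale!r}")
    terms = MODEL_TERMS[model_id]
    n, k = len(design), len(terms)
    if n <= k:
        raise FitError(
            f"model {model_id} has {k} free coefficients but only {n} design rows"
        )
    C, g, y = _design_matrices(design, model_id, mu)

    if loss_scale == "log":
        if np.any(y <= 0):
            raise FitError("log-scale loss requires strictly positive observations")
        logy = np.log(y)

        def fun(theta):
            p = (C @ theta) * g
            return np.log(np.clip(p, 1e-300, None)) - logy

        def jac(theta):
            p = np.clip((C @ theta) * g, 1e-300, None)
            return (C * g[:, None]) / p[:, None]

    else:

        def fun(theta):
            return (C @ theta) * g - y

        def jac(theta):
            return C * g[:, None]

    if init is not None:
        x0 = np.asarray(init, dtype=float)
    else:
        x0 = _default_init(C, g, y, terms)
        if loss_scale == "log" and np.any((C @ x0) * g <= 0):
            # fall back to the natural-scale linear solution, which keeps
            # predictions positive wherever the data support it
            x0 = np.linalg.lstsq(C * g[:, None], y, rcond=None)[0]

    res = optimize.least_squares(
        fun, x0, jac=jac, method="lm", ftol=_COST_TOL, xtol=_COST_TOL,
        gtol=_COST_TOL, max_nfev=_MAX_NFEV,
    )
    if not res.success:
        raise FitError(
            f"model {model_id} did not converge: {res.message} "
            f"(nfev={res.nfev}, cost={res.cost:.3g})"
        )

    resid = res.fun
    rss = float(resid @ resid)
    J = res.jac
    JTJ = J.T @ J
    if not np.all(np.isfinite(JTJ)) or np.linalg.cond(JTJ) > 1e14:
        raise FitError(f"model {model_id}: Jacobian is rank deficient")
    s2 = rss / (n - k)
    cov = s2 * np.linalg.inv(JTJ)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):
        tvals = res.x / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    fields = dict(zip(terms, (float(v) for v in res.x)))
    return ModelCoefficients(
        model_id=model_id,
        epsilon=fields["epsilon"],
        beta1=fields.get("beta1"),
        beta2=fields.get("beta2"),
        stderr=dict(zip(terms, (float(v) for v in se))),
        tvalues=dict(zip(terms, (float(v) for v in tvals))),
        pvalues=dict(zip(terms, (float(v) for v in pvals))),
        aic=aic(rss, n, k),
        rss=rss,
        n_obs=n,
        loss_scale=loss_scale,
    )


def fit_all_models(
    design: Sequence[DesignRow],
    loss_scale: str = "natural",
    mu: float = MU,
) -> list[ModelCoefficients]:
    """Fit models 1-4 and rank them by ascending AIC.

    Models that cannot be fitted (missing covariates, fitting failure) are
    skipped with a warning; the rest are still returned.
    """
    fits = []
    for model_id in (1, 2, 3, 4):
        try:
            fits.append(fit_model(design, model_id, loss_scale=loss_scale, mu=mu))
        except (FitError, MissingVariableError) as exc:
            warnings.warn(f"model {model_id} skipped: {exc}", stacklevel=2)
    fits.sort(key=lambda c: c.aic)
    return fits


def fit_report_rows(fits: Iterable[ModelCoefficients]) -> list[dict]:
    """Flatten fits into report rows (one row per coefficient)."""
    rows = []
    for rank, c in enumerate(fits, start=1):
        for t in c.terms:
            rows.append(
                {
                    "model_id": c.model_id,
                    "parameter": t,
                    "value": getattr(c, t),
                    "std_err": c.stderr[t] if c.stderr else None,
                    "t_value": c.tvalues[t] if c.tvalues else None,
                    "p_value": c.pvalues[t] if c.pvalues else None,
                    "aic": c.aic,
                    "aic_rank": rank,
                    "loss_scale": c.loss_scale,
                }
            )
    return rows
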