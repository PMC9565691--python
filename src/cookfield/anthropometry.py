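"""Stature-based body geometry for exposure estimation.

The exposure models evaluate the magnetic field at the height of the superior
iliac crest, a palpable surrogate for uterine position in pregnant women.
Since stature is routinely available from questionnaires while iliac-crest
height is not, a fixed linear conversion is applied:

    iliac crest height [m] = (stature [cm] * 0.6935 - 16.997) / 100

The model height coordinate ``h`` is the signed distance of the iliac crest
above the cooking-table surface, with the standard Japanese table height of
0.85 m as the population default (overridable per household).

The conversion constants are treated as fixed calibration values and are
never refitted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ILIAC_SLOPE = 0.6935
"""Slope of the stature (cm) -> iliac-crest height (cm) conversion."""

ILIAC_INTERCEPT_CM = 16.997
"""Intercept (cm) subtracted in the stature -> iliac-crest conversion."""

DEFAULT_TABLE_HEIGHT_M = 0.85
"""Standard cooking-table height (m), the JIS-typical value."""


def iliac_crest_height(stature_cm):
    """Height of the superior iliac crest (m) from standing height (cm).

    Accepts a scalar or array. Raises ``ValueError`` for non-positive stature.
    """
    stature = np.asarray(stature_cm, dtype=float)
    if np.any(stature <= 0):
        raise ValueError(f"stature must be positive (got {stature_cm!r})")
    out = (stature * ILIAC_SLOPE - ILIAC_INTERCEPT_CM) / 100.0
    return out if out.ndim else float(out)


def height_above_table(stature_cm, table_height_m: float = DEFAULT_TABLE_HEIGHT_M):
    """Signed height (m) of the iliac crest above the cooking-table surface.

    Negative values mean the crest sits below the cooktop plane.
    """
    return iliac_crest_height(stature_cm) - table_height_m


@dataclass(frozen=True)
class BodyGeometry:
    """Resolved vertical geometry for one subject."""

    stature_cm: float
    iliac_crest_m: float
    h_m: float

    @classmethod
    def from_stature(
        cls, stature_cm: float, table_height_m: float = DEFAULT_TABLE_HEIGHT_M
    ) -> "BodyGeometry":
        crest = iliac_crest_height(stature_cm)
        return cls(
            stature_cm=float(stature_cm),
            iliac_crest_m=crest,
            h_m=crest - table_height_m,
        )
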