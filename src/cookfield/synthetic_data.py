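"""Synthetic grid campaigns and questionnaire surveys.

The generators emulate the two-phase study design the pipeline expects:

* **Phase 1** (model building): households with wattages spread uniformly
  over the 1.5-3 kW catalogue levels, each measured on the canonical
  20-point grid (h in {-20,-10,0,10,20} cm by d in {0,10,20,30} cm);
* **Phase 2** (validation): subjects whose devices are biased toward 3 kW,
  with self-reported geometry and a paired "measured" exposure at
  iliac-crest height.

Flux densities are drawn as model prediction x LogNormal(0, ln GSD) -- i.e.
the model value is the *geometric* mean of the measurement distribution --
then floored at a small detection limit so downstream log transforms are
safe.  All randomness flows through one ``numpy`` Generator, so a seed fixes
the whole dataset.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np

from .anthropometry import height_above_table
from .config import SimulationConfig
from .exposure_model import (
    ExposureQuery,
    ModelCoefficients,
    edge_to_center,
    numerator,
    predict,
)
from .survey_io import (
    CANONICAL_D_CM,
    CANONICAL_H_CM,
    GridMeasurement,
    HouseholdDevice,
    QuestionnaireResponse,
)

#: The 20 canonical grid positions, in campaign-report order.
CANONICAL_GRID_POINTS: list[tuple[float, float]] = [
    (h, d) for h in sorted(CANONICAL_H_CM, reverse=True) for d in CANONICAL_D_CM
]


def _rng(seed, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    """Normal draws redrawn (not clipped) until all exceed ``low``."""
    out = rng.normal(mean, sd, size)
    while np.any(out <= low):
        bad = out <= low
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def generate_households(
    n: int,
    phase: int,
    seed: Optional[int] = None,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[HouseholdDevice]:
    """Draw device covariates for ``n`` households.

    Phase 1 spreads wattage uniformly over the catalogue levels; phase 2
    picks the top level with high probability (the validation population's
    bias), making its wattage variance strictly smaller by construction.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    cfg = config or SimulationConfig()
    gen = _rng(seed, rng)
    levels = np.asarray(cfg.wattage_levels, dtype=float)
    if phase == 1:
        wattage = gen.choice(levels, size=n)
    else:
        top = levels.max()
        rest = levels[levels < top]
        take_top = gen.random(n) < cfg.phase2_max_wattage_prob
        wattage = np.where(take_top, top, gen.choice(rest, size=n))
    offsets = _truncated_normal(
        gen, cfg.hob_offset_mean_m, cfg.hob_offset_sd_m, cfg.hob_offset_min_m, n
    )
    tables = gen.normal(cfg.table_height_mean_m, cfg.table_height_sd_m, n)
    diameters = gen.uniform(cfg.cookware_diameter_min_m, cfg.cookware_diameter_max_m, n)
    return [
        HouseholdDevice(
            household_id=f"H{phase}-{i:04d}",
            wattage_w=float(wattage[i]),
            cookware_diameter_m=float(diameters[i]),
            hob_offset_m=float(offsets[i]),
            table_height_m=float(tables[i]),
        )
        for i in range(n)
    ]


def generate_grid_campaign(
    devices: Sequence[HouseholdDevice],
    truth: ModelCoefficients,
    noise_gsd: float = 1.8,
    seed: Optional[int] = None,
    detection_floor_ut: float = 0.001,
    rng: Optional[np.random.Generator] = None,
) -> list[GridMeasurement]:
    """Simulate the canonical 20-point grid for each device.

    Each reading is the truth-model prediction at the grid point (edge
    distances shifted by the device's hob offset) times a lognormal noise
    multiplier, floored at the detection limit.  ``noise_gsd = 1`` gives the
    noiseless limit exactly.
    """
    if noise_gsd < 1:
        raise ValueError(f"noise_gsd must be >= 1, got {noise_gsd}")
    gen = _rng(seed, rng)
    sigma = math.log(noise_gsd)
    measurements = []
    for dev in devices:
        warned = False
        for h_cm, d_cm in CANONICAL_GRID_POINTS:
            q = ExposureQuery(
                dh_m=edge_to_center(d_cm / 100.0, dev.hob_offset_m),
                h_m=h_cm / 100.0,
                wattage_w=dev.wattage_w,
                cookware_diameter_m=dev.cookware_diameter_m,
            )
            b0 = predict(truth, q)
            if b0 < 0 and not warned:
                warnings.warn(
                    f"device {dev.household_id!r}: negative model numerator "
                    f"({numerator(truth, q):.4g}); draws floored at "
                    f"{detection_floor_ut} uT",
                    stacklevel=2,
                )
                warned = True
            b = max(b0 * float(gen.lognormal(0.0, sigma)), detection_floor_ut)
            measurements.append(GridMeasurement(dev.household_id, h_cm, d_cm, b))
    return measurements


def generate_phase2_survey(
    n: int,
    truth: ModelCoefficients,
    noise_gsd: float = 1.8,
    seed: Optional[int] = None,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[QuestionnaireResponse]:
    """Simulate a validation survey with paired measured exposures.

    Subjects get stature, an edge distance (truncated at zero), a hob-center
    distance (edge + their device's hob offset), and phase-2 device
    covariates.  The paired measurement is the truth model evaluated at the
    subject's iliac-crest height over the standard 0.85 m table -- the same
    geometry the estimator reconstructs from the questionnaire -- times
    lognormal noise, so the noiseless survey closes the loop exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if noise_gsd < 1:
        raise ValueError(f"noise_gsd must be >= 1, got {noise_gsd}")
    cfg = config or SimulationConfig()
    gen = _rng(seed, rng)
    devices = generate_households(n, 2, config=cfg, rng=gen)
    stature = _truncated_normal(gen, cfg.stature_mean_cm, cfg.stature_sd_cm, 120.0, n)
    d_edge = gen.normal(cfg.edge_distance_mean_cm, cfg.edge_distance_sd_cm, n)
    while np.any(d_edge < 0):
        bad = d_edge < 0
        d_edge[bad] = gen.normal(
            cfg.edge_distance_mean_cm, cfg.edge_distance_sd_cm, int(bad.sum())
        )
    sigma = math.log(noise_gsd)
    responses = []
    for i, dev in enumerate(devices):
        dh_center_cm = d_edge[i] + dev.hob_offset_m * 100.0
        q = ExposureQuery(
            dh_m=dh_center_cm / 100.0,
            h_m=height_above_table(stature[i]),
            wattage_w=dev.wattage_w,
            cookware_diameter_m=dev.cookware_diameter_m,
        )
        measured = max(
            predict(truth, q) * float(gen.lognormal(0.0, sigma)),
            cfg.detection_floor_ut,
        )
        responses.append(
            QuestionnaireResponse(
                subject_id=f"S-{i:04d}",
                stature_cm=float(stature[i]),
                dh_center_cm=float(dh_center_cm),
                d_edge_cm=float(d_edge[i]),
                cookware_diameter_cm=dev.cookware_diameter_m * 100.0,
                wattage_w=dev.wattage_w,
                measured_b_ut=measured,
            )
        )
    return responses
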