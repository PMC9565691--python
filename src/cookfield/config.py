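"""Simulation configuration: every generator distribution in one place.

Defaults encode the measured structure of the two home-visit campaigns: 45
model-building households with wattages spread over 1.5-3 kW, hob offsets of
23.9 (3.38) cm, table heights of 85.04 (0.89) cm; 30 validation subjects with
mean stature 158.3 cm, edge distances of 15.00 (11.19) cm, and a wattage
distribution biased toward 3 kW.  Stature SD and the cookware-diameter range
are population-plausible choices (not campaign-measured) and are exposed here
so sensitivity analyses can vary them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .exposure_model import ModelCoefficients


@dataclass
class SimulationConfig:
    seed: int = 0

    # campaign sizes
    n_households: int = 45
    n_subjects: int = 30

    # multiplicative measurement noise (geometric SD; 1 = noiseless)
    noise_gsd: float = 1.8
    detection_floor_ut: float = 0.001

    # device covariates
    wattage_levels: tuple = (1500.0, 2000.0, 2500.0, 3000.0)
    phase2_max_wattage_prob: float = 0.8
    hob_offset_mean_m: float = 0.239
    hob_offset_sd_m: float = 0.0338
    hob_offset_min_m: float = 0.10
    table_height_mean_m: float = 0.8504
    table_height_sd_m: float = 0.0089
    cookware_diameter_min_m: float = 0.14
    cookware_diameter_max_m: float = 0.28

    # subject geometry
    stature_mean_cm: float = 158.3
    stature_sd_cm: float = 5.5
    edge_distance_mean_cm: float = 15.00
    edge_distance_sd_cm: float = 11.19

    # generating ("truth") coefficients, default = published model-1 fit
    truth_model_id: int = 1
    truth_beta1: float = 10501.2
    truth_beta2: float = -28.8
    truth_epsilon: float = 0.173

    def truth_coefficients(self) -> ModelCoefficients:
        from .exposure_model import MODEL_TERMS

        terms = MODEL_TERMS[self.truth_model_id]
        return ModelCoefficients(
            model_id=self.truth_model_id,
            epsilon=self.truth_epsilon,
            beta1=self.truth_beta1 if "beta1" in terms else None,
            beta2=self.truth_beta2 if "beta2" in terms else None,
        )

    @classmethod
    def valid_keys(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        unknown = sorted(set(d) - set(cls.valid_keys()))
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(unknown)}; "
                f"valid keys: {', '.join(cls.valid_keys())}"
            )
        if "wattage_levels" in d:
            d = {**d, "wattage_levels": tuple(float(w) for w in d["wattage_levels"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config keys")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["wattage_levels"] = list(self.wattage_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
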