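"""Artificial-cohort growth rates from before/after size distributions.

The artificial-cohort method incubates a size-fractionated cohort and
compares its biomass distribution before and after incubation.  The growth
rate is

    g = ln(W_T / W_0) / T        [per day]

where W_0 and W_T are the mean individual carbon biomasses at the start and
end of the incubation and T is the incubation time in days.  Carbon biomass
is obtained from biovolume through a power law W = c * V^k; the constants
are taxon- and study-specific, so no default is shipped — the caller must
supply them (inventing constants here would be false precision).

A key property of g: any multiplicative bias b applied to both W_0 and W_T
cancels exactly, since ln(bW_T / bW_0) = ln(W_T / W_0).  Systematic
instrument error that scales all biovolume measurements by a constant
factor therefore does not bias the growth estimate — which is what makes
uncalibrated instrument biovolumes usable for growth work even when their
absolute scale is off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .calibration import CalibrationModel

__all__ = [
    "CarbonModel",
    "GrowthEstimate",
    "mean_carbon",
    "growth_rate",
    "cohort_growth",
]


class CarbonModel(NamedTuple):
    """Power-law biovolume-to-carbon conversion: W = c * V^k (ug C, V in um^3)."""

    c: float
    k: float


@dataclass(frozen=True)
class GrowthEstimate:
    """Growth rate with its inputs; satisfies g * T = ln(WT / W0) exactly."""

    g: float  # per day
    W0: float  # ug C, mean at start
    WT: float  # ug C, mean at end
    T: float  # days
    n0: int | None = None
    nT: int | None = None
    carbon_model: CarbonModel | None = None

    def to_json(self, path=None):
        payload = {
            "g_per_day": self.g,
            "W0": self.W0,
            "WT": self.WT,
            "T_days": self.T,
            "n0": self.n0,
            "nT": self.nT,
            "carbon_model": None
            if self.carbon_model is None
            else {"c": self.carbon_model.c, "k": self.carbon_model.k},
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _check_carbon_model(carbon_model) -> CarbonModel:
    if carbon_model is None:
        raise ValueError(
            "carbon model required: supply (c, k) for W = c * V^k; no default is shipped"
        )
    model = CarbonModel(*carbon_model)
    if model.c <= 0 or model.k <= 0:
        raise ValueError("carbon model constants c and k must be positive")
    return model


def mean_carbon(volumes, carbon_model: CarbonModel) -> float:
    """Mean individual carbon biomass (ug C) of a volume sample."""
    model = _check_carbon_model(carbon_model)
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume sample")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    return float(np.mean(model.c * v**model.k))


def growth_rate(W0: float, WT: float, T: float) -> GrowthEstimate:
    """Specific growth rate g = ln(WT / W0) / T, per day."""
    if W0 <= 0 or WT <= 0 or T <= 0:
        raise ValueError("W0, WT and T must be positive")
    return GrowthEstimate(g=math.log(WT / W0) / T, W0=W0, WT=WT, T=T)


def cohort_growth(
    volumes_t0,
    volumes_tT,
    T: float,
    carbon_model: CarbonModel,
    calibration_model: CalibrationModel | None = None,
) -> GrowthEstimate:
    """Growth rate of an artificial cohort from its biovolume samples.

    Optionally converts every instrument biovolume to microscopy-equivalent
    biovolume through ``calibration_model`` first, then maps volumes to
    carbon and takes g = ln(mean WT / mean W0) / T.
    """
    model = _check_carbon_model(carbon_model)
    v0 = np.asarray(volumes_t0, dtype=float)
    vT = np.asarray(volumes_tT, dtype=float)
    if v0.size == 0 or vT.size == 0:
        raise ValueError("both time points need at least one particle")
    if calibration_model is not None:
        v0 = calibration_model.apply(v0)
        vT = calibration_model.apply(vT)
    W0 = mean_carbon(v0, model)
    WT = mean_carbon(vT, model)
    base = growth_rate(W0, WT, T)
    return GrowthEstimate(
        g=base.g, W0=W0, WT=WT, T=T, n0=int(v0.size), nT=int(vT.size),
        carbon_model=model,
    )
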