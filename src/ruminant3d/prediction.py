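"""Published regression equations: partial-to-total conversion and
body-weight prediction.

All equation math is in SI units (m^3, m^2, m, kg).  Volumes are often
reported in litres at the I/O layer; the conversion (1 m^3 = 1000 L)
belongs there, never inside the equations — the total-volume intercept
(0.015) is only dimensionally sensible in m^3.

The body-weight equation is

    BW = 644 * TV + 408 * HW + 271 * WB - 199            [kg]

with TV the total body volume in m^3, HW the hip width in m (not the
withers height) and WB the buttocks width in m.  The partial-to-total
conversions are

    TV = 1.0704 * PV + 0.015                             [m^3]
    TS = 1.07   * PS + 0.94                              [m^2]

where PV/PS are the volume/surface of the body cut off at the shoulder
blades and the rump (head and neck excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "PredictionConfig",
    "DEFAULT_CONFIG",
    "total_volume_from_partial",
    "total_surface_from_partial",
    "predict_bw",
    "litres",
    "from_litres",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Equation coefficients.  Defaults are the published values and are
    immutable; a non-default instance is recorded in output metadata by
    the pipeline layer."""

    tv_slope: float = 1.0704
    tv_intercept_m3: float = 0.015
    ts_slope: float = 1.07
    ts_intercept_m2: float = 0.94
    bw_coeff_tv: float = 644.0  # kg per m^3
    bw_coeff_hw: float = 408.0  # kg per m
    bw_coeff_wb: float = 271.0  # kg per m
    bw_intercept: float = -199.0  # kg

    def is_default(self) -> bool:
        return self == PredictionConfig()


DEFAULT_CONFIG = PredictionConfig()

# plausibility envelope: twice the span of the published cohort means
_PLAUSIBLE = {"tv": (0.2, 1.6), "hw": (0.2, 1.2), "wb": (0.2, 1.1)}


def total_volume_from_partial(pv: float, config: PredictionConfig = DEFAULT_CONFIG) -> float:
    """Total body volume (m^3) from the partial volume cut off at the
    shoulder (m^3)."""
    if pv < 0:
        raise ValueError(f"partial volume must be >= 0, got {pv}")
    return config.tv_slope * pv + config.tv_intercept_m3


def total_surface_from_partial(ps: float, config: PredictionConfig = DEFAULT_CONFIG) -> float:
    """Total surface area (m^2) from the partial surface cut off at the
    shoulder tip (m^2)."""
    if ps < 0:
        raise ValueError(f"partial surface must be >= 0, got {ps}")
    return config.ts_slope * ps + config.ts_intercept_m2


def predict_bw(
    tv: float, hw: float, wb: float, config: PredictionConfig = DEFAULT_CONFIG
) -> float:
    """Body weight (kg) from total volume (m^3), hip width (m) and
    buttocks width (m).

    Emits a plausibility warning when an input is outside twice the
    envelope of typical adult-cow values, but still returns the
    equation value.
    """
    for name, val in (("tv", tv), ("hw", hw), ("wb", wb)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
        lo, hi = _PLAUSIBLE[name]
        if not (lo <= val <= hi):
            warnings.warn(
                f"{name} = {val:g} is outside the plausible range [{lo}, {hi}]; "
                "the predicted body weight may be meaningless",
                stacklevel=2,
            )
    return (
        config.bw_coeff_tv * tv
        + config.bw_coeff_hw * hw
        + config.bw_coeff_wb * wb
        + config.bw_intercept
    )


def litres(volume_m3: float) -> float:
    """Reporting-layer conversion m^3 -> L."""
    return 1000.0 * volume_m3


def from_litres(volume_l: float) -> float:
    """Reporting-layer conversion L -> m^3."""
    return volume_l / 1000.0
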