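"""In vitro-in vivo extrapolation of hepatocyte clearances.

Assay-scale intrinsic clearances (uL/min/1e6 cells) are scaled to
whole-liver, per-kg values with hepatocellularity and liver weight, then to
whole-body values (L/h) with body weight.
"""
from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterError


@dataclass(frozen=True)
class ScalingFactors:
    """hepatocellularity: 1e6 cells/g liver; liver_weight: g/kg body weight;
    body_weight: kg."""

    hepatocellularity: float = 120.0
    liver_weight: float = 40.0
    body_weight: float = 0.25

    def __post_init__(self):
        if min(self.hepatocellularity, self.liver_weight,
               self.body_weight) <= 0:
            raise ParameterError("scaling factors must be > 0")


def scale_to_per_kg(cl_u: float, factors: ScalingFactors = ScalingFactors()
                    ) -> float:
    """uL/min/1e6 cells -> mL/min/kg body weight."""
    if cl_u < 0:
        raise ParameterError("clearance must be >= 0")
    return cl_u * factors.hepatocellularity * factors.liver_weight / 1000.0


def per_kg_to_whole_body(cl_per_kg: float, body_weight: float = 0.25) -> float:
    """mL/min/kg -> L/h for a given body weight (kg)."""
    if cl_per_kg < 0:
        raise ParameterError("clearance must be >= 0")
    if body_weight <= 0:
        raise ParameterError("body weight must be > 0")
    return cl_per_kg * body_weight * 60.0 / 1000.0


def scale_to_whole_body(cl_u: float,
                        factors: ScalingFactors = ScalingFactors()) -> float:
    """uL/min/1e6 cells -> L/h in one composed step."""
    return per_kg_to_whole_body(scale_to_per_kg(cl_u, factors),
                                factors.body_weight)
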