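"""Instrument-guidance error budget for image-guided lesion resection.

The total guidance error of a navigated surgical instrument combines a
*visualization* error (how well the lesion/healthy-tissue boundary is
located in the model frame) with a *positioning* error (how precisely
the manipulator places the tool).  Components (all mm, root-mean-square
unless noted):

* delta_T — model data-representation error, the RSS of half the model's
  spatial resolution along each axis;
* delta_C — boundary-determination error (opaque input);
* delta_M — methodological error of the surgical-field centre (opaque);
* delta_V = delta_T + delta_C + delta_M — visualization error.  The
  three image-derived terms are treated as fully correlated, so they
  add linearly (the K = +1 limit of the correlated combination);
* delta_P — manipulator positioning error, the RSS of the per-axis
  mechanical errors, each of which is itself a linear sum of backlash,
  kinematic error, shaft twisting, support gap, clutch and thermal
  terms;
* delta_R = sqrt(delta_V^2 + delta_P^2) — total guidance error
  (visualization and mechanics are uncorrelated, K = 0).

Reference component values (``REFERENCE_COMPONENTS``) describe a model
built from radial sections at 0.5 mm lateral / 1 mm vertical
resolution; they yield delta_T = 0.61, delta_V = 2.24 and
delta_R = 2.27 mm at the 2-decimal display precision.  Displayed values
truncate (round toward zero) at 2 decimals; internal values keep full
precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import HemisurfError

__all__ = [
    "ErrorComponent",
    "BudgetReport",
    "REFERENCE_COMPONENTS",
    "AXIS_COMPONENT_NAMES",
    "combine_correlated",
    "representation_error",
    "visualization_error",
    "axis_positioning_error",
    "positioning_error",
    "total_guidance_error",
    "full_budget",
    "truncate2",
]

REFERENCE_COMPONENTS = {
    "delta_T_x": 0.25,
    "delta_T_y": 0.25,
    "delta_T_z": 0.5,
    "delta_C": 1.13,
    "delta_M": 0.5,
    "delta_P": 0.41,
}

AXIS_COMPONENT_NAMES = (
    "backlash",
    "kinematic",
    "shaft_twist",
    "support_gap",
    "clutch",
    "temperature",
)


@dataclass(frozen=True)
class ErrorComponent:
    name: str
    value: float  # mm, >= 0

    def __post_init__(self):
        if self.value < 0:
            raise HemisurfError(
                f"error component {self.name!r} must be >= 0, got {self.value}"
            )


def truncate2(value: float) -> float:
    """Truncate toward zero at 2 decimals — the display convention used
    throughout the budget report (0.6124 -> 0.61, 2.2796 -> 2.27)."""
    return math.trunc(value * 100 + 1e-9 * math.copysign(1, value)) / 100


def combine_correlated(d1: float, d2: float, K: float) -> float:
    """RMS combination of two errors with correlation K in [-1, 1]:
    sqrt(d1^2 + d2^2 + 2 K d1 d2)."""
    if d1 < 0 or d2 < 0:
        raise HemisurfError("error magnitudes must be >= 0")
    if not -1.0 <= K <= 1.0:
        raise HemisurfError(f"correlation coefficient must lie in [-1, 1], got {K}")
    s = d1 * d1 + d2 * d2 + 2.0 * K * d1 * d2
    return math.sqrt(max(s, 0.0))


def representation_error(dx: float, dy: float, dz: float) -> float:
    """RSS of the per-axis model resolution half-widths."""
    if min(dx, dy, dz) < 0:
        raise HemisurfError("resolution half-widths must be >= 0")
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def visualization_error(dT: float, dC: float, dM: float, rss: bool = False) -> float:
    """Visualization error: linear sum of the three image-derived terms.

    The terms are treated as fully correlated (K = +1), under which the
    pairwise RMS combination collapses to plain addition.  ``rss=True``
    switches to the uncorrelated RSS combination for sensitivity
    studies.
    """
    if min(dT, dC, dM) < 0:
        raise HemisurfError("visualization components must be >= 0")
    if rss:
        return math.sqrt(dT * dT + dC * dC + dM * dM)
    return dT + dC + dM


def axis_positioning_error(components) -> float:
    """Linear sum of the six mechanical error terms of one drive axis."""
    vals = [c.value if isinstance(c, ErrorComponent) else float(c) for c in components]
    if any(v < 0 for v in vals):
        raise HemisurfError("axis components must be >= 0")
    return float(sum(vals))


def positioning_error(d1: float, d2: float, d3: float) -> float:
    """RSS of the three per-axis mechanical errors."""
    if min(d1, d2, d3) < 0:
        raise HemisurfError("axis errors must be >= 0")
    return math.sqrt(d1 * d1 + d2 * d2 + d3 * d3)


def total_guidance_error(dV: float, dP: float) -> float:
    """Uncorrelated (K = 0) combination of visualization and positioning."""
    return combine_correlated(dV, dP, 0.0)


@dataclass(frozen=True)
class BudgetReport:
    """Chained error budget with full-precision and display accessors."""

    delta_T: float
    delta_V: float
    delta_P: float
    delta_R: float
    per_axis: tuple = None  # (dP1, dP2, dP3) when built from axis components
    inputs: dict = field(default_factory=dict)

    def display(self) -> dict:
        """Values truncated to the 2-decimal display precision."""
        out = {
            "delta_T": truncate2(self.delta_T),
            "delta_V": truncate2(self.delta_V),
            "delta_P": truncate2(self.delta_P),
            "delta_R": truncate2(self.delta_R),
        }
        if self.per_axis is not None:
            out["per_axis"] = tuple(truncate2(v) for v in self.per_axis)
        return out

    def to_dict(self) -> dict:
        return {
            "delta_T_mm": self.delta_T,
            "delta_V_mm": self.delta_V,
            "delta_P_mm": self.delta_P,
            "delta_R_mm": self.delta_R,
            "per_axis_mm": list(self.per_axis) if self.per_axis is not None else None,
            "inputs": dict(self.inputs),
        }

    def summary(self) -> str:
        d = self.display()
        lines = [
            "Instrument guidance error budget (mm)",
            "=" * 40,
            f"data representation  delta_T = {d['delta_T']:.2f}",
            f"visualization        delta_V = {d['delta_V']:.2f}",
            f"positioning          delta_P = {d['delta_P']:.2f}",
            f"total guidance       delta_R = {d['delta_R']:.2f}",
        ]
        return "\n".join(lines)


def read_components(path) -> dict:
    """Load named error components from a JSON file."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise HemisurfError("component file must be a JSON object of name: value")
    return {str(k): float(v) for k, v in data.items()}


def full_budget(values: dict = None, per_axis: dict = None,
                rss_visualization: bool = False) -> BudgetReport:
    """Chain the full budget from named components.

    ``values`` overrides entries of ``REFERENCE_COMPONENTS``; ``per_axis``
    optionally maps axis names to six mechanical components each, from
    which delta_P is derived (overriding any direct ``delta_P``).
    """
    comp = dict(REFERENCE_COMPONENTS)
    if values:
        unknown = set(values) - set(comp)
        if unknown:
            raise HemisurfError(f"unknown component(s): {sorted(unknown)}")
        comp.update({k: float(v) for k, v in values.items()})
    axes = None
    if per_axis is not None:
        if len(per_axis) != 3:
            raise HemisurfError("per_axis must name exactly 3 axes")
        axes = tuple(axis_positioning_error(v) for v in per_axis.values())
        comp["delta_P"] = positioning_error(*axes)
    dT = representation_error(comp["delta_T_x"], comp["delta_T_y"], comp["delta_T_z"])
    dV = visualization_error(dT, comp["delta_C"], comp["delta_M"], rss=rss_visualization)
    dP = comp["delta_P"]
    if dP < 0:
        raise HemisurfError("delta_P must be >= 0")
    dR = total_guidance_error(dV, dP)
    return BudgetReport(delta_T=dT, delta_V=dV, delta_P=dP, delta_R=dR,
                        per_axis=axes, inputs=comp)
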