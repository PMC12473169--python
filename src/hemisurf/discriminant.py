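"""Mahalanobis screening of resection parameters.

Each candidate parameter (skin elasticity, tumor volume, mass, density,
shape/size correction factor, ...) is summarized by its mean and
standard deviation in two states: normal (theta_0) and pathological
(theta_1).  The per-parameter spread is taken conservatively as
sigma_i = max(sigma_i(0), sigma_i(1)), and the separation between the
states is a diagonal Mahalanobis distance

    delta = sum_i (m_i(0) - m_i(1))^2 / sigma_i^2      (squared mode).

An 'as-printed' mode without the square — a signed, non-standard
variant found in some applied texts — is kept selectable for
comparison.  The probability of a wrong classification is bounded by

    P_err <= 1 - Phi(delta / 2),

with Phi either the standard normal CDF (default) or the Laplace
function Phi_0 = Phi - 1/2 used by some Slavic textbooks (under the
normal-CDF reading a bound above 0.5 is impossible for delta > 0, which
is why both conventions are exposed).

A packaged reference table reproduces the published five-parameter
screening outcome (state means, distances and bounds) as *data only*:
the standard deviations behind it were never published, so those
printed distances cannot be recomputed from the means and are not
regression targets for the formulas above.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import HemisurfError

__all__ = [
    "GroupStats",
    "DiscriminantResult",
    "ReferenceRow",
    "mahalanobis_delta",
    "error_probability_bound",
    "screen",
    "reference_screening_table",
    "read_group_stats",
]


@dataclass(frozen=True)
class GroupStats:
    """Per-parameter means/SDs in normal (0) and pathological (1) states."""

    names: tuple
    m0: np.ndarray
    m1: np.ndarray
    s0: np.ndarray
    s1: np.ndarray

    def __post_init__(self):
        m0 = np.asarray(self.m0, dtype=float)
        m1 = np.asarray(self.m1, dtype=float)
        s0 = np.asarray(self.s0, dtype=float)
        s1 = np.asarray(self.s1, dtype=float)
        names = tuple(str(n) for n in self.names)
        if not (len(names) == len(m0) == len(m1) == len(s0) == len(s1)):
            raise HemisurfError("GroupStats fields must have equal length")
        if len(names) == 0:
            raise HemisurfError("GroupStats needs at least one parameter")
        if np.any(s0 <= 0) or np.any(s1 <= 0):
            raise HemisurfError("standard deviations must be > 0")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "m1", m1)
        object.__setattr__(self, "s0", s0)
        object.__setattr__(self, "s1", s1)

    @property
    def sigma(self) -> np.ndarray:
        """Conservative per-parameter spread max(s0, s1)."""
        return np.maximum(self.s0, self.s1)


@dataclass(frozen=True)
class DiscriminantResult:
    delta: float
    p_err_bound: float
    mode: str
    phi_convention: str
    per_parameter: tuple = ()

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "p_err_bound": self.p_err_bound,
            "mode": self.mode,
            "phi_convention": self.phi_convention,
            "per_parameter": list(self.per_parameter),
        }


def mahalanobis_delta(g: GroupStats, mode: str = "squared") -> float:
    """Diagonal Mahalanobis separation between the two states.

    'squared' (default): sum of (m0 - m1)^2 / sigma^2 — nonnegative and
    additive over parameters.  'as-printed': signed sum of
    (m0 - m1) / sigma^2.
    """
    d = g.m0 - g.m1
    s2 = g.sigma**2
    if mode == "squared":
        return float(np.sum(d * d / s2))
    if mode == "as-printed":
        return float(np.sum(d / s2))
    raise HemisurfError(f"unknown mode {mode!r}")


def error_probability_bound(delta: float, phi_convention: str = "normal-cdf") -> float:
    """Upper bound on the decision-error probability, P <= 1 - Phi(delta/2)."""
    if phi_convention == "normal-cdf":
        if delta < 0:
            raise HemisurfError("delta must be >= 0 under the normal-cdf convention")
        return float(norm.sf(delta / 2.0))
    if phi_convention == "laplace":
        # Phi replaced by the Laplace function Phi - 1/2; capped into [0, 1]
        return float(np.clip(1.0 - (norm.cdf(delta / 2.0) - 0.5), 0.0, 1.0))
    raise HemisurfError(f"unknown phi convention {phi_convention!r}")


def screen(g: GroupStats, mode: str = "squared",
           phi_convention: str = "normal-cdf") -> DiscriminantResult:
    """Distance, error bound and per-parameter contributions for a group."""
    per = []
    for i, name in enumerate(g.names):
        sub = GroupStats(names=(name,), m0=g.m0[i : i + 1], m1=g.m1[i : i + 1],
                         s0=g.s0[i : i + 1], s1=g.s1[i : i + 1])
        per.append((name, mahalanobis_delta(sub, mode=mode)))
    delta = mahalanobis_delta(g, mode=mode)
    p = error_probability_bound(max(delta, 0.0) if mode == "as-printed" else delta,
                                phi_convention=phi_convention)
    return DiscriminantResult(delta=delta, p_err_bound=p, mode=mode,
                              phi_convention=phi_convention,
                              per_parameter=tuple(per))


@dataclass(frozen=True)
class ReferenceRow:
    label: str
    description: str
    theta0: float
    theta1: float
    delta: float  # reported distance (SDs behind it unpublished)
    p_err_bound: float  # reported bound


_REFERENCE_ROWS = (
    ReferenceRow("X1", "skin elasticity coefficient", 1.1, 0.8, 2.1, 0.81),
    ReferenceRow("X2", "tumor volume, mm^3", 4.0, 1.0, 2.5, 0.69),
    ReferenceRow("X3", "tumor weight, g", 0.0, 17.5, 6.40, 0.45),
    ReferenceRow("X4", "tumor density, g/mm^3", 11.0, 9.0, 7.3, 0.4),
    ReferenceRow("X5", "P shape/size correction factor", 0.67, 0.97, 8.11, 0.31),
)


def reference_screening_table() -> tuple:
    """The packaged five-parameter screening outcome, as reference data.

    Returns the rows (state means, reported distance, reported error
    bound).  The standard deviations behind the reported distances were
    not published, so the rows cannot be reproduced through
    :func:`mahalanobis_delta` and serve only as a loadable fixture.
    """
    return _REFERENCE_ROWS


def read_group_stats(path) -> GroupStats:
    """Load group statistics from JSON ({names, m0, m1, s0, s1}) or CSV
    (columns name, m0, m1, s0, s1)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        try:
            return GroupStats(names=tuple(data["names"]), m0=data["m0"],
                              m1=data["m1"], s0=data["s0"], s1=data["s1"])
        except KeyError as exc:
            raise HemisurfError(f"{path}: missing field {exc}") from exc
    with path.open(newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise HemisurfError(f"{path}: empty group-statistics file")
    try:
        return GroupStats(
            names=tuple(r["name"] for r in rows),
            m0=[float(r["m0"]) for r in rows],
            m1=[float(r["m1"]) for r in rows],
            s0=[float(r["s0"]) for r in rows],
            s1=[float(r["s1"]) for r in rows],
        )
    except (KeyError, ValueError) as exc:
        raise HemisurfError(f"{path}: need columns name,m0,m1,s0,s1") from exc
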