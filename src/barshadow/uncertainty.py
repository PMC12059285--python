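"""GUM-style uncertainty budget for the bar-shadow measurement.

Type-A components come from repeated observations (repeatability within a
session, reproducibility across sessions); Type-B from other knowledge,
here the finite stage sampling interval.  Components are combined by
root-sum-square into a combined standard uncertainty.  Following the
published convention, the combination is performed on the dip-center
deviations themselves (no 1/k sensitivity coefficient); propagation to
focus height is available as a clearly labeled extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import MeasurementGeometry, magnification_factor

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "type_a_from_repeats",
    "type_b_from_resolution",
    "combine",
    "focus_level_uncertainty",
    "session_budget",
]


@dataclass(frozen=True)
class UncertaintyComponent:
    """One named standard-uncertainty contribution in mm."""

    name: str
    utype: str  # "A" (statistical) or "B" (other knowledge)
    value_mm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.utype not in ("A", "B"):
            raise ValueError(f"utype must be 'A' or 'B', got {self.utype!r}")
        if self.value_mm < 0:
            raise ValueError("a standard uncertainty cannot be negative")


@dataclass(frozen=True)
class UncertaintyBudget:
    """A list of components and their root-sum-square combination."""

    components: tuple[UncertaintyComponent, ...]
    combined_mm: float

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "name": c.name,
                "utype": c.utype,
                "value_mm": c.value_mm,
                "provenance": c.provenance,
            }
            for c in self.components
        ]
        return rows


def type_a_from_repeats(
    values_mm: Sequence[float],
    mode: str = "sd",
    name: str = "repeatability",
    provenance: str = "",
) -> UncertaintyComponent:
    """Type-A standard uncertainty from repeated observations.

    ``mode="sd"`` (default) returns the sample standard deviation (n-1
    denominator), the literal reading of "estimated from their standard
    deviations"; ``mode="sd_of_mean"`` returns SD/sqrt(n) for when the
    reported quantity is the mean of the repeats.
    """
    values = np.asarray(values_mm, dtype=float)
    if values.size < 2:
        raise ValueError("Type-A estimation needs at least 2 observations")
    sd = float(np.std(values, ddof=1))
    if mode == "sd":
        value = sd
    elif mode == "sd_of_mean":
        value = sd / math.sqrt(values.size)
    else:
        raise ValueError(f"mode must be 'sd' or 'sd_of_mean', got {mode!r}")
    return UncertaintyComponent(
        name=name,
        utype="A",
        value_mm=value,
        provenance=provenance or f"{mode} of {values.size} observations",
    )


def type_b_from_resolution(
    interval_mm: float,
    model: str = "rectangular_half_interval",
    given_mm: Optional[float] = None,
    name: str = "measurement interval",
) -> UncertaintyComponent:
    """Type-B standard uncertainty from the stage sampling interval.

    ``rectangular_half_interval`` applies the standard rectangular model to a
    half-interval bound: ``(interval/2)/sqrt(3)``.  ``as_given`` passes an
    externally assigned value through unchanged (for reproducing published
    budgets whose derivation is not stated).
    """
    if interval_mm < 0:
        raise ValueError("interval_mm must be >= 0")
    if model == "rectangular_half_interval":
        value = (interval_mm / 2.0) / math.sqrt(3.0)
        provenance = f"rectangular, half-interval {interval_mm / 2.0:g} mm / sqrt(3)"
    elif model == "as_given":
        if given_mm is None:
            raise ValueError("model 'as_given' requires given_mm")
        value = float(given_mm)
        provenance = "assigned value (as given)"
    else:
        raise ValueError(f"unknown Type-B model {model!r}")
    if name == "measurement interval":
        name = f"measurement interval:{interval_mm:g} mm"
    return UncertaintyComponent(name=name, utype="B", value_mm=value, provenance=provenance)


def combine(components: Sequence[UncertaintyComponent]) -> UncertaintyBudget:
    """Root-sum-square combination of standard uncertainties.

    ``combined = sqrt(sum(u_i^2))``; always at least the largest single
    component and at most the arithmetic sum.
    """
    comps = tuple(components)
    if not comps:
        raise ValueError("cannot combine an empty component list")
    combined = math.sqrt(sum(c.value_mm**2 for c in comps))
    return UncertaintyBudget(components=comps, combined_mm=combined)


def focus_level_uncertainty(
    budget: UncertaintyBudget, geometry: MeasurementGeometry
) -> float:
    """Extension: propagate a dip-plane budget to focus height.

    Divides the combined standard uncertainty by the magnification factor
    ``k``, i.e. applies the sensitivity of the offset estimate to a
    dip-center deviation.  Not part of the published combination convention.
    """
    return budget.combined_mm / magnification_factor(geometry)


def session_budget(
    d1_by_session: Sequence[Sequence[float]],
    d2_by_session: Sequence[Sequence[float]],
    min_interval_mm: float = 0.1,
    type_a_mode: str = "sd",
    type_b_model: str = "rectangular_half_interval",
    type_b_given_mm: Optional[float] = None,
) -> UncertaintyBudget:
    """Build the standard six-row budget from per-session repeat centers.

    ``dX_by_session`` holds, per session, the per-repeat dip-center estimates
    (mm) for the upstream (d1) and downstream (d2) bar heights.
    Repeatability is the pooled within-session SD (RMS over sessions);
    reproducibility the SD over session means (included only when at least
    two sessions are available); the Type-B rows come from the finest stage
    interval via :func:`type_b_from_resolution`.
    """
    components: list[UncertaintyComponent] = []
    for label, sessions in (("d1", d1_by_session), ("d2", d2_by_session)):
        sessions = [np.asarray(s, dtype=float) for s in sessions]
        if not sessions:
            raise ValueError(f"no sessions for {label}")
        rep_vars = [float(np.var(s, ddof=1)) for s in sessions if s.size >= 2]
        if rep_vars:
            pooled = math.sqrt(sum(rep_vars) / len(rep_vars))
            value = pooled
            n_total = sum(s.size for s in sessions if s.size >= 2)
            if type_a_mode == "sd_of_mean":
                value = pooled / math.sqrt(n_total / len(rep_vars))
            elif type_a_mode != "sd":
                raise ValueError(f"type_a_mode must be 'sd' or 'sd_of_mean', got {type_a_mode!r}")
            components.append(
                UncertaintyComponent(
                    name=f"{label} (repeatability)",
                    utype="A",
                    value_mm=value,
                    provenance=f"pooled within-session {type_a_mode}, {len(rep_vars)} session(s)",
                )
            )
        if len(sessions) >= 2:
            means = [float(np.mean(s)) for s in sessions]
            components.append(
                type_a_from_repeats(
                    means,
                    mode=type_a_mode,
                    name=f"{label} (reproducibility)",
                    provenance=f"{type_a_mode} of {len(means)} session means",
                )
            )
    for label in ("d1", "d2"):
        components.append(
            type_b_from_resolution(
                min_interval_mm,
                model=type_b_model,
                given_mm=type_b_given_mm,
                name=f"{label} (measurement interval:{min_interval_mm:g} mm)",
            )
        )
    return combine(components)
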