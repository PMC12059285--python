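"""Projection geometry of the two-height bar-shadow method.

A thin metal bar suspended in the beam casts a shadow (a dip) in a lateral
beam profile recorded below it.  With the bar at an upstream height the dip
center seen at the acquisition plane is displaced by ``-a*(B+C)/A`` for a
lateral focal-spot offset ``a``; with the bar at a downstream height it is
displaced by ``-a*C/(A+B)``.  The difference of the two dip-center
deviations therefore isolates the focal-spot offset:

    a = (d2 - d1) / k,      k = (B + C)/A - C/(A + B)

where ``A`` is the focal-spot-to-upstream-bar distance, ``B`` the distance
between the two bar heights and ``C`` the distance from the downstream bar
to the plane where the profile is acquired (all in cm).  ``d1``/``d2`` are
the dip-center deviations (mm) at the acquisition plane and ``a`` the
focal-spot offset (mm) at target height.  For the Radixact geometry
(SAD 85 cm, B = 20.473 cm, C = 3.65 cm) the divisor ``k`` rounds to 0.33.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GeometryError",
    "MeasurementGeometry",
    "ScanAxis",
    "FocalSpotResult",
    "IEC_X",
    "IEC_Y",
    "UPSTREAM",
    "DOWNSTREAM",
    "RADIXACT",
    "PAPER_ROUNDED_DIVISOR",
    "magnification_factor",
    "shadow_offset",
    "estimate_focal_offset",
]

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

#: Rounded two-decimal divisor used in the published convenience form of the
#: inversion; the full-precision divisor is ``magnification_factor(geometry)``.
PAPER_ROUNDED_DIVISOR = 0.33


class GeometryError(ValueError):
    """Raised for non-physical distance stacks or degenerate geometry."""


@dataclass(frozen=True)
class MeasurementGeometry:
    """Source/bar/detector distance stack defining the projection magnification.

    Parameters
    ----------
    a_cm:
        Distance from the focal spot to the upstream bar position (cm).
    b_cm:
        Distance between the upstream and downstream bar positions (cm).
    c_cm:
        Distance from the downstream bar to the profile acquisition plane (cm).
    """

    a_cm: float
    b_cm: float
    c_cm: float

    def __post_init__(self) -> None:
        for name in ("a_cm", "b_cm", "c_cm"):
            value = getattr(self, name)
            if not (value > 0):
                raise GeometryError(f"{name} must be positive, got {value!r}")

    @classmethod
    def from_sad(
        cls, sad_cm: float = 85.0, b_cm: float = 20.473, c_cm: float = 3.65
    ) -> "MeasurementGeometry":
        """Build from source-axis distance, with the downstream bar at isocenter.

        ``A = SAD - B``; the defaults reproduce the Radixact setup
        (SAD 85 cm, two-turn roller travel 20.473 cm, 3.65 cm bar-to-chamber
        clearance).
        """
        return cls(a_cm=sad_cm - b_cm, b_cm=b_cm, c_cm=c_cm)

    @property
    def sad_cm(self) -> float:
        """Source-axis distance when the downstream bar sits at isocenter."""
        return self.a_cm + self.b_cm

    @property
    def total_cm(self) -> float:
        """Focal spot to acquisition plane distance A + B + C."""
        return self.a_cm + self.b_cm + self.c_cm


#: Default bore-type (Radixact) geometry: SAD 85 cm, B 20.473 cm, C 3.65 cm.
RADIXACT = MeasurementGeometry.from_sad()


@dataclass(frozen=True)
class ScanAxis:
    """A scan direction and the sign mapping stage coordinates to IEC axes.

    ``orientation_sign`` converts a displacement measured in the chamber-stage
    coordinate into the reported IEC coordinate; it is a configuration choice,
    not a physical constant.
    """

    name: str
    orientation_sign: int

    def __post_init__(self) -> None:
        if self.orientation_sign not in (+1, -1):
            raise ValueError(
                f"orientation_sign must be +1 or -1, got {self.orientation_sign!r}"
            )


IEC_X = ScanAxis("IEC_X", +1)
IEC_Y = ScanAxis("IEC_Y", -1)


@dataclass(frozen=True)
class FocalSpotResult:
    """Per-axis focal-spot offset with the dip deviations it came from.

    All lengths in mm; ``d1_mm``/``d2_mm`` are stage-plane dip-center
    deviations at the upstream/downstream bar heights, ``offset_mm`` the
    signed lateral focal-spot displacement at target height in the IEC frame.
    """

    axis: ScanAxis
    d1_mm: float
    d2_mm: float
    offset_mm: float
    combined_uncertainty_mm: Optional[float] = None


def magnification_factor(geometry: MeasurementGeometry) -> float:
    """Geometric sensitivity ``k = (B+C)/A - C/(A+B)`` of d2-d1 to the offset.

    Strictly positive for any valid geometry; for the default Radixact stack
    it evaluates to 0.33090... and rounds to 0.33.
    """
    a, b, c = geometry.a_cm, geometry.b_cm, geometry.c_cm
    return (b + c) / a - c / (a + b)


def shadow_offset(a_mm: float, level: str, geometry: MeasurementGeometry) -> float:
    """Forward model: dip-center deviation (mm) at the acquisition plane.

    The bar is assumed laterally centered on the reference axis; a focal-spot
    offset ``a_mm`` shifts its shadow to ``-a*(B+C)/A`` (upstream bar) or
    ``-a*C/(A+B)`` (downstream bar).  By construction
    ``shadow_offset(a, downstream) - shadow_offset(a, upstream) == a * k``.
    """
    a, b, c = geometry.a_cm, geometry.b_cm, geometry.c_cm
    if level == UPSTREAM:
        return -a_mm * (b + c) / a
    if level == DOWNSTREAM:
        return -a_mm * c / (a + b)
    raise ValueError(f"level must be {UPSTREAM!r} or {DOWNSTREAM!r}, got {level!r}")


def estimate_focal_offset(
    d1_mm: float,
    d2_mm: float,
    geometry: MeasurementGeometry = RADIXACT,
    axis: ScanAxis = IEC_X,
    divisor_mode: str = "full",
) -> FocalSpotResult:
    """Invert the projection: focal-spot offset from two dip-center deviations.

    Parameters
    ----------
    d1_mm, d2_mm:
        Dip-center deviations (mm, stage coordinates at the acquisition
        plane) with the bar at the upstream and downstream heights.
    geometry:
        Distance stack used for the magnification factor.
    axis:
        Scan axis; its ``orientation_sign`` maps the stage-frame result into
        the IEC frame.
    divisor_mode:
        ``"full"`` uses the full-precision magnification factor;
        ``"paper_rounded"`` uses the two-decimal divisor 0.33 so published
        two-decimal results reproduce digit for digit.
    """
    import math

    if not (math.isfinite(d1_mm) and math.isfinite(d2_mm)):
        raise ValueError("d1_mm and d2_mm must be finite")
    if divisor_mode == "full":
        k = magnification_factor(geometry)
    elif divisor_mode == "paper_rounded":
        k = PAPER_ROUNDED_DIVISOR
    else:
        raise ValueError(
            f"divisor_mode must be 'full' or 'paper_rounded', got {divisor_mode!r}"
        )
    if k == 0:
        raise GeometryError("degenerate geometry: magnification factor is zero")
    offset = axis.orientation_sign * (d2_mm - d1_mm) / k
    return FocalSpotResult(axis=axis, d1_mm=d1_mm, d2_mm=d2_mm, offset_mm=offset)
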