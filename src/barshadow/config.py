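"""Analysis configuration: validated blocks mirroring the module parameters.

Unknown keys are rejected with a clear message so typos in config files do
not silently fall back to defaults.  All defaults reproduce the bore-type
(Radixact) measurement setup, so a paper-like session analyzes with no
config at all.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .geometry import MeasurementGeometry, ScanAxis

__all__ = ["GeometryConfig", "AnalysisOptions", "UncertaintyOptions", "AnalysisConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    """Distance stack and stage-to-IEC sign conventions."""

    sad_cm: float = 85.0
    b_cm: float = 20.473
    c_cm: float = 3.65
    axis_sign_x: Literal[1, -1] = 1
    axis_sign_y: Literal[1, -1] = -1

    def measurement_geometry(self) -> MeasurementGeometry:
        return MeasurementGeometry.from_sad(self.sad_cm, self.b_cm, self.c_cm)

    def scan_axis(self, name: str) -> ScanAxis:
        if name == "IEC_X":
            return ScanAxis("IEC_X", self.axis_sign_x)
        if name == "IEC_Y":
            return ScanAxis("IEC_Y", self.axis_sign_y)
        raise ValueError(f"unknown axis {name!r} (expected IEC_X or IEC_Y)")


class AnalysisOptions(_Strict):
    """Dip-center estimator settings."""

    method: Literal["bracket_interp", "local_linear_fit"] = "local_linear_fit"
    window_halfwidth_mm: float = Field(default=1.0, gt=0)
    divisor_mode: Literal["full", "paper_rounded"] = "full"
    smooth_window: Optional[int] = None


class UncertaintyOptions(_Strict):
    """Budget construction settings."""

    type_a_mode: Literal["sd", "sd_of_mean"] = "sd"
    type_b_model: Literal["rectangular_half_interval", "as_given"] = (
        "rectangular_half_interval"
    )
    type_b_given_mm: Optional[float] = None
    propagate_to_focus: bool = False


class AnalysisConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)
    uncertainty: UncertaintyOptions = Field(default_factory=UncertaintyOptions)
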