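"""End-to-end analysis: profile files -> focal-spot offsets with uncertainty.

For every scanned axis the pipeline differentiates each profile, locates
the dip center, aggregates repeats within and across sessions, inverts the
projection geometry for the focal-spot offset, and assembles the
uncertainty budget.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .geometry import DOWNSTREAM, UPSTREAM, estimate_focal_offset, magnification_factor
from .io import read_profile
from .profile import ProfileError, find_dip_center
from .uncertainty import focus_level_uncertainty, session_budget

__all__ = ["AnalysisError", "AnalysisReport", "analyze"]

_AXES = ("IEC_X", "IEC_Y")
_LEVELS = (UPSTREAM, DOWNSTREAM)


class AnalysisError(RuntimeError):
    """Raised when a session cannot be analyzed; carries per-file diagnostics."""


@dataclass(frozen=True)
class AnalysisReport:
    """Per-axis results plus configuration and provenance."""

    axes: dict
    config: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"axes": self.axes, "config": self.config, "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = ["Bar-shadow focal-spot analysis", ""]
        for axis_name, result in self.axes.items():
            lines.append(f"{axis_name}:")
            for label in ("d1", "d2"):
                stats = result[label]
                line = (
                    f"  {label} ({'upstream' if label == 'd1' else 'downstream'}): "
                    f"{stats['mean_mm']:+.3f} mm"
                )
                if stats["sd_mm"] is not None:
                    line += f"  (SD {stats['sd_mm']:.3f} mm, n={stats['n_repeats']})"
                lines.append(line)
            line = f"  focal-spot offset: {result['offset_mm']:+.3f} mm"
            if result["combined_standard_uncertainty_mm"] is not None:
                line += f"  (u = {result['combined_standard_uncertainty_mm']:.3f} mm)"
            lines.append(line)
            lines.append("  uncertainty budget:")
            for row in result["budget"]:
                lines.append(
                    f"    {row['name']:<40s} Type {row['utype']}  {row['value_mm']:.3f} mm"
                )
            lines.append(
                f"    {'Combined standard uncertainty':<40s}         "
                f"{result['combined_standard_uncertainty_mm']:.3f} mm"
            )
            lines.append("")
        lines.append(
            "Positions are chamber-stage coordinates at the acquisition plane; "
            "the plane-to-focus magnification is absorbed in the geometric divisor."
        )
        return "\n".join(lines) + "\n"


def _collect_paths(inputs: Union[str, Path, Iterable[Union[str, Path]]]) -> list[Path]:
    if isinstance(inputs, (str, Path)):
        root = Path(inputs)
        if root.is_dir():
            return sorted(p for p in root.glob("*.csv"))
        return [root]
    return [Path(p) for p in inputs]


def analyze(
    inputs: Union[str, Path, Iterable[Union[str, Path]]],
    config: Optional[AnalysisConfig] = None,
) -> AnalysisReport:
    """Analyze a session directory (or explicit file list) of profile CSVs.

    Each profile must carry ``axis`` (IEC_X/IEC_Y) and ``level``
    (upstream/downstream) metadata; ``session`` defaults to 1.  Every
    requested axis needs at least one profile per level.  File-level parse or
    dip-detection failures are collected and reported together in an
    :class:`AnalysisError`.
    """
    config = config or AnalysisConfig()
    paths = _collect_paths(inputs)
    if not paths:
        raise AnalysisError("no profile files found")

    centers: dict[str, dict[str, dict[str, list[float]]]] = {}
    min_interval = np.inf
    diagnostics: list[str] = []
    for path in paths:
        try:
            profile = read_profile(path)
            axis = profile.metadata.get("axis")
            level = profile.metadata.get("level")
            if axis not in _AXES:
                raise ProfileError(f"missing or unknown axis metadata {axis!r}")
            if level not in _LEVELS:
                raise ProfileError(f"missing or unknown level metadata {level!r}")
            session = profile.metadata.get("session", "1")
            estimate = find_dip_center(
                profile,
                window_halfwidth_mm=config.analysis.window_halfwidth_mm,
                method=config.analysis.method,
                smooth_window=config.analysis.smooth_window,
            )
        except (ValueError, OSError) as exc:
            diagnostics.append(f"{path.name}: {exc}")
            continue
        min_interval = min(min_interval, float(np.min(np.diff(profile.positions_mm))))
        centers.setdefault(axis, {}).setdefault(level, {}).setdefault(session, []).append(
            estimate.center_mm
        )
    if diagnostics:
        raise AnalysisError(
            "analysis failed for {} file(s):\n  {}".format(
                len(diagnostics), "\n  ".join(diagnostics)
            )
        )

    geometry = config.geometry.measurement_geometry()
    axes_out: dict[str, dict] = {}
    for axis_name in _AXES:
        if axis_name not in centers:
            continue
        by_level = centers[axis_name]
        for level in _LEVELS:
            if level not in by_level:
                raise AnalysisError(f"{axis_name}: no {level} profile present")
        level_stats = {}
        per_session: dict[str, list[list[float]]] = {}
        for label, level in (("d1", UPSTREAM), ("d2", DOWNSTREAM)):
            sessions = [by_level[level][k] for k in sorted(by_level[level])]
            per_session[label] = sessions
            session_means = [float(np.mean(s)) for s in sessions]
            all_values = np.array([v for s in sessions for v in s])
            sd = float(np.std(all_values, ddof=1)) if all_values.size >= 2 else None
            level_stats[label] = {
                "mean_mm": float(np.mean(session_means)),
                "sd_mm": sd,
                "sd_of_mean_mm": (sd / float(np.sqrt(all_values.size))) if sd is not None else None,
                "n_repeats": int(all_values.size),
                "n_sessions": len(sessions),
                "session_means_mm": session_means,
            }
        budget = session_budget(
            per_session["d1"],
            per_session["d2"],
            min_interval_mm=float(min_interval),
            type_a_mode=config.uncertainty.type_a_mode,
            type_b_model=config.uncertainty.type_b_model,
            type_b_given_mm=config.uncertainty.type_b_given_mm,
        )
        combined = budget.combined_mm
        if config.uncertainty.propagate_to_focus:
            combined = focus_level_uncertainty(budget, geometry)
        result = estimate_focal_offset(
            level_stats["d1"]["mean_mm"],
            level_stats["d2"]["mean_mm"],
            geometry,
            axis=config.geometry.scan_axis(axis_name),
            divisor_mode=config.analysis.divisor_mode,
        )
        axes_out[axis_name] = {
            "d1": level_stats["d1"],
            "d2": level_stats["d2"],
            "offset_mm": result.offset_mm,
            "combined_standard_uncertainty_mm": combined,
            "uncertainty_at_focus": bool(config.uncertainty.propagate_to_focus),
            "divisor": (
                0.33
                if config.analysis.divisor_mode == "paper_rounded"
                else magnification_factor(geometry)
            ),
            "budget": budget.to_rows(),
        }
    if not axes_out:
        raise AnalysisError("no analyzable axis found in inputs")

    config_json = config.model_dump_json()
    provenance = {
        "inputs": [p.name for p in paths],
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "package_version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(
        axes=axes_out, config=json.loads(config_json), provenance=provenance
    )
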