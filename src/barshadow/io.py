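"""File I/O: profile CSVs, budget tables, configuration files.

Profile format: plain CSV with a ``position_mm,current`` header (optionally
``position_mm,current,current_sd``), preceded by ``# key: value`` metadata
comment lines (axis, level, session, ...).  The reader tolerates comma or
tab delimiters and sorts shuffled rows with a warning; the writer emits
commas and ``repr``-precision floats so read/write round-trips are lossless.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .profile import BeamProfile

__all__ = [
    "ParseError",
    "read_profile",
    "write_profile",
    "read_budget_components",
    "write_budget_components",
    "load_config",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A profile or budget file could not be parsed; names file and line."""


def write_profile(profile: BeamProfile, path: PathLike) -> None:
    """Write a profile as metadata comments + CSV rows."""
    path = Path(path)
    lines = []
    for key, value in profile.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append(f"# n_samples_per_point: {profile.n_samples_per_point}")
    has_sd = profile.current_sd is not None
    lines.append("position_mm,current,current_sd" if has_sd else "position_mm,current")
    for i in range(len(profile)):
        # repr of Python floats is shortest-exact, so round-trips are lossless
        row = f"{float(profile.positions_mm[i])!r},{float(profile.currents[i])!r}"
        if has_sd:
            row += f",{float(profile.current_sd[i])!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: PathLike) -> BeamProfile:
    """Parse a profile CSV, tolerating tab delimiters and shuffled rows.

    Shuffled (non-increasing) rows are sorted with a warning; a duplicated
    position or a malformed row raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    rows: list[tuple[float, ...]] = []
    row_lines: list[int] = []
    header_seen = False
    n_cols = 2
    n_samples = 5

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            continue
        sep = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(sep)]
        if not header_seen:
            if fields[0] != "position_mm" or len(fields) < 2 or fields[1] != "current":
                raise ParseError(
                    f"{path.name}:{lineno}: expected header 'position_mm,current[,current_sd]', "
                    f"got {line!r}"
                )
            n_cols = len(fields)
            header_seen = True
            continue
        if len(fields) != n_cols:
            raise ParseError(
                f"{path.name}:{lineno}: expected {n_cols} fields, got {len(fields)}: {line!r}"
            )
        try:
            rows.append(tuple(float(f) for f in fields))
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: malformed row {line!r} ({exc})") from None
        row_lines.append(lineno)

    if not header_seen:
        raise ParseError(f"{path.name}: missing 'position_mm,current' header")
    if len(rows) < 3:
        raise ParseError(f"{path.name}: only {len(rows)} data rows (need at least 3)")

    positions = [r[0] for r in rows]
    seen: dict[float, int] = {}
    for pos, lineno in zip(positions, row_lines):
        if pos in seen:
            raise ParseError(
                f"{path.name}:{lineno}: duplicated position {pos:g} mm "
                f"(first seen on line {seen[pos]})"
            )
        seen[pos] = lineno
    if any(b <= a for a, b in zip(positions, positions[1:])):
        warnings.warn(
            f"{path.name}: positions not increasing; rows sorted by position",
            stacklevel=2,
        )
        rows.sort(key=lambda r: r[0])

    if "n_samples_per_point" in metadata:
        try:
            n_samples = int(metadata.pop("n_samples_per_point"))
        except ValueError:
            raise ParseError(f"{path.name}: non-integer n_samples_per_point") from None

    return BeamProfile(
        positions_mm=[r[0] for r in rows],
        currents=[r[1] for r in rows],
        n_samples_per_point=n_samples,
        current_sd=[r[2] for r in rows] if n_cols == 3 else None,
        metadata=metadata,
    )


def read_budget_components(path: PathLike):
    """Read an uncertainty-component table (name,utype,value_mm,provenance)."""
    from .uncertainty import UncertaintyComponent

    frame = pd.read_csv(path)
    required = {"name", "utype", "value_mm"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(
            f"{Path(path).name}: missing column(s) {', '.join(sorted(missing))}"
        )
    if "provenance" not in frame.columns:
        frame["provenance"] = ""
    frame["provenance"] = frame["provenance"].fillna("")
    try:
        return [
            UncertaintyComponent(
                name=str(row["name"]),
                utype=str(row["utype"]).strip(),
                value_mm=float(row["value_mm"]),
                provenance=str(row["provenance"]),
            )
            for _, row in frame.iterrows()
        ]
    except ValueError as exc:
        raise ParseError(f"{Path(path).name}: {exc}") from None


def write_budget_components(components, path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "name": c.name,
                "utype": c.utype,
                "value_mm": c.value_mm,
                "provenance": c.provenance,
            }
            for c in components
        ]
    ).to_csv(path, index=False)


def load_config(path: PathLike):
    """Load an analysis configuration from a YAML (or flat key-value) file."""
    from .config import AnalysisConfig

    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParseError(f"{Path(path).name}: config must be a mapping")
    return AnalysisConfig.model_validate(raw)
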