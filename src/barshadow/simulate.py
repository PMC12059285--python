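"""Forward simulation of bar-shadow measurement sessions.

Generates the synthetic counterpart of a stepwise ionization-chamber scan
under a suspended metal bar: straight rays from a blurred focal spot are
traced through a finite cylinder, attenuated with a single effective
attenuation coefficient, averaged over the chamber aperture, and sampled on
the nonuniform stage schedule with multiplicative electrometer noise.  A
session generator emits complete two-axis, two-height repeat/reproducibility
studies with a ground-truth manifest, so the whole analysis chain can be
exercised without hardware.

Coordinate frame (cm): ``x`` along the scan direction, ``y`` along the bar
axis (horizontal, perpendicular to the scan), ``z`` depth from the focal
spot toward the chamber; the acquisition plane sits at ``z = A + B + C``.
The bar axis lies at depth ``A`` (upstream) or ``A + B`` (downstream), so
the dip center is the point projection of the bar axis through the source
and the projection-inversion formula applies exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple
import warnings

import numpy as np

from .geometry import (
    DOWNSTREAM,
    IEC_X,
    IEC_Y,
    RADIXACT,
    UPSTREAM,
    MeasurementGeometry,
    ScanAxis,
)
from .profile import BeamProfile

__all__ = [
    "BarSpec",
    "SourceSpec",
    "DetectorSpec",
    "SamplingSchedule",
    "cylinder_path_length",
    "ray_path_length",
    "bar_shadow_center",
    "simulate_profile",
    "generate_session",
    "session_from_manifest",
    "MANIFEST_NAME",
]

MANIFEST_NAME = "manifest.json"

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BarSpec:
    """Suspended metal bar: 14.5 cm long, 0.5 cm diameter by default.

    ``attenuation_per_cm`` is a single effective linear attenuation
    coefficient for the 6 MV beam (generic metal, no spectral model).
    """

    length_cm: float = 14.5
    diameter_cm: float = 0.5
    attenuation_per_cm: float = 0.4

    def __post_init__(self) -> None:
        if not (self.length_cm > 0 and self.diameter_cm > 0 and self.attenuation_per_cm > 0):
            raise ValueError("bar dimensions and attenuation must be positive")
        if not self.diameter_cm < self.length_cm:
            raise ValueError("bar diameter must be smaller than its length")

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0


@dataclass(frozen=True)
class SourceSpec:
    """Focal spot: ground-truth lateral offset plus a Gaussian intensity blur.

    ``offset_mm`` is the true lateral focal displacement in the stage frame
    (the quantity the analysis should recover).  ``fwhm_mm`` is the focal
    spot size used for blurring; the dip center is first-order insensitive to
    it.  ``sad_cm`` is the nominal machine source-axis distance.
    """

    offset_mm: float = 0.0
    fwhm_mm: float = 1.0
    sad_cm: float = 85.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


@dataclass(frozen=True)
class DetectorSpec:
    """Chamber/electrometer model: lateral averaging aperture and noise.

    Each stage position is read ``samples_per_point`` times (default 5, as in
    the stepwise protocol) with independent multiplicative Gaussian noise of
    coefficient of variation ``noise_cv``; the stored reading is the sample
    mean.
    """

    aperture_mm: float = 2.0
    noise_cv: float = 0.002
    samples_per_point: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.aperture_mm < 0:
            raise ValueError("aperture_mm must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.samples_per_point < 1:
            raise ValueError("samples_per_point must be >= 1")


@dataclass(frozen=True)
class SamplingSchedule:
    """Contiguous stage segments (start_mm, end_mm, interval_mm).

    The default reproduces the measurement schedule: 1 mm steps over
    +/-(5-10) mm, 0.2 mm over +/-(1-5) mm and 0.1 mm over the central
    +/-1 mm.
    """

    segments: Tuple[Tuple[float, float, float], ...] = (
        (-10.0, -5.0, 1.0),
        (-5.0, -1.0, 0.2),
        (-1.0, 1.0, 0.1),
        (1.0, 5.0, 0.2),
        (5.0, 10.0, 1.0),
    )

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        prev_end = None
        for start, end, interval in self.segments:
            if not interval > 0:
                raise ValueError(f"interval must be positive, got {interval}")
            if not end > start:
                raise ValueError(f"segment ({start}, {end}) must be increasing")
            if prev_end is not None and start != prev_end:
                raise ValueError("segments must be contiguous")
            prev_end = end
        object.__setattr__(self, "segments", tuple(tuple(map(float, s)) for s in self.segments))

    def positions_mm(self) -> np.ndarray:
        """All stage positions, each segment half-open plus the final endpoint."""
        parts = [np.arange(s, e, i) for s, e, i in self.segments]
        parts.append(np.array([self.segments[-1][1]]))
        return np.round(np.concatenate(parts), 9)

    @property
    def min_interval_mm(self) -> float:
        return min(i for _, _, i in self.segments)


def cylinder_path_length(
    start: np.ndarray,
    end: np.ndarray,
    center: Sequence[float],
    axis: Sequence[float],
    radius_cm: float,
    half_length_cm: float,
) -> np.ndarray:
    """Exact intersection length of straight segments with a finite cylinder.

    ``start``/``end`` are broadcastable arrays of shape (..., 3) in cm;
    ``center`` and ``axis`` define the cylinder (any orientation).  Returns
    the in-cylinder chord length (cm), 0 where the segment misses.  Total
    geometric function: no error cases.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    start, end = np.broadcast_arrays(start, end)
    center = np.asarray(center, dtype=float)
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)

    d = end - start
    seg_len = np.linalg.norm(d, axis=-1)
    safe_len = np.where(seg_len > 0, seg_len, 1.0)
    u = d / safe_len[..., None]

    v = start - center
    uw = np.tensordot(u, w, axes=([-1], [0]))
    vw = np.tensordot(v, w, axes=([-1], [0]))
    ur = u - uw[..., None] * w
    vr = v - vw[..., None] * w

    a = np.einsum("...i,...i->...", ur, ur)
    b = 2.0 * np.einsum("...i,...i->...", ur, vr)
    c = np.einsum("...i,...i->...", vr, vr) - radius_cm**2

    # radial constraint a t^2 + b t + c <= 0
    parallel = a < 1e-14
    disc = b**2 - 4.0 * a * c
    safe_a = np.where(parallel, 1.0, a)
    sqrt_disc = np.sqrt(np.clip(disc, 0.0, None))
    t_rad_lo = np.where(parallel, np.where(c <= 0, -np.inf, np.inf), (-b - sqrt_disc) / (2 * safe_a))
    t_rad_hi = np.where(parallel, np.where(c <= 0, np.inf, -np.inf), (-b + sqrt_disc) / (2 * safe_a))
    miss = (~parallel) & (disc <= 0)
    t_rad_lo = np.where(miss, np.inf, t_rad_lo)
    t_rad_hi = np.where(miss, -np.inf, t_rad_hi)

    # axial constraint |vw + t uw| <= h
    axial_parallel = np.abs(uw) < 1e-14
    safe_uw = np.where(axial_parallel, 1.0, uw)
    t1 = (-half_length_cm - vw) / safe_uw
    t2 = (half_length_cm - vw) / safe_uw
    t_ax_lo = np.minimum(t1, t2)
    t_ax_hi = np.maximum(t1, t2)
    inside_axial = np.abs(vw) <= half_length_cm
    t_ax_lo = np.where(axial_parallel, np.where(inside_axial, -np.inf, np.inf), t_ax_lo)
    t_ax_hi = np.where(axial_parallel, np.where(inside_axial, np.inf, -np.inf), t_ax_hi)

    t_lo = np.maximum(np.maximum(t_rad_lo, t_ax_lo), 0.0)
    t_hi = np.minimum(np.minimum(t_rad_hi, t_ax_hi), seg_len)
    return np.clip(t_hi - t_lo, 0.0, None)


def _bar_depth_cm(level: str, geometry: MeasurementGeometry) -> float:
    if level == UPSTREAM:
        return geometry.a_cm
    if level == DOWNSTREAM:
        return geometry.a_cm + geometry.b_cm
    raise ValueError(f"level must be {UPSTREAM!r} or {DOWNSTREAM!r}, got {level!r}")


def ray_path_length(
    source_x_mm: float,
    plane_x_mm: float,
    level: str,
    bar_center_mm: float,
    geometry: MeasurementGeometry = RADIXACT,
    bar: BarSpec = BarSpec(),
    bar_axis: Sequence[float] = (0.0, 1.0, 0.0),
) -> float:
    """Path length (cm) inside the bar for one source-to-plane ray.

    The ray starts at the focal height at lateral position ``source_x_mm``
    and ends at the acquisition plane at ``plane_x_mm``.  The bar axis passes
    through ``(bar_center_mm, 0, depth(level))`` with direction ``bar_axis``
    (default horizontal, perpendicular to the scan; any orientation is
    accepted).
    """
    depth = _bar_depth_cm(level, geometry)
    start = np.array([source_x_mm / 10.0, 0.0, 0.0])
    end = np.array([plane_x_mm / 10.0, 0.0, geometry.total_cm])
    return float(
        cylinder_path_length(
            start,
            end,
            center=(bar_center_mm / 10.0, 0.0, depth),
            axis=bar_axis,
            radius_cm=bar.radius_cm,
            half_length_cm=bar.length_cm / 2.0,
        )
    )


def bar_shadow_center(
    source_offset_mm: float,
    bar_center_mm: float,
    level: str,
    geometry: MeasurementGeometry = RADIXACT,
) -> float:
    """Stage position (mm) where the bar axis projects from the source."""
    depth = _bar_depth_cm(level, geometry)
    total = geometry.total_cm
    return source_offset_mm + (bar_center_mm - source_offset_mm) * total / depth


def _source_nodes(source: SourceSpec, n_nodes: int = 21):
    """Gauss-Hermite nodes/weights averaging over the focal-spot Gaussian."""
    if source.fwhm_mm == 0 or n_nodes == 1:
        return np.array([source.offset_mm]), np.array([1.0])
    sigma = source.fwhm_mm * _FWHM_TO_SIGMA
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    return source.offset_mm + np.sqrt(2.0) * sigma * nodes, weights / np.sqrt(np.pi)


def _aperture_nodes(aperture_mm: float, n_nodes: int = 11):
    """Midpoint nodes averaging uniformly over the chamber aperture."""
    if aperture_mm == 0 or n_nodes == 1:
        return np.array([0.0]), np.array([1.0])
    edges = np.linspace(-aperture_mm / 2.0, aperture_mm / 2.0, n_nodes + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return mids, np.full(n_nodes, 1.0 / n_nodes)


def transmission(
    positions_mm: np.ndarray,
    source: SourceSpec,
    level: str,
    bar_center_mm: float,
    detector: DetectorSpec,
    geometry: MeasurementGeometry = RADIXACT,
    bar: BarSpec = BarSpec(),
    n_source_nodes: int = 21,
    n_aperture_nodes: int = 11,
) -> np.ndarray:
    """Noiseless relative transmission at each stage position.

    Averages ``exp(-mu * path)`` over the focal-spot Gaussian (>= 21
    Gauss-Hermite nodes) and the chamber aperture (>= 11 uniform nodes).
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    depth = _bar_depth_cm(level, geometry)
    s_nodes, s_weights = _source_nodes(source, n_source_nodes)
    a_nodes, a_weights = _aperture_nodes(detector.aperture_mm, n_aperture_nodes)

    # rays: (n_pos, n_src, n_ap)
    start = np.zeros((1, s_nodes.size, 1, 3))
    start[..., 0] = (s_nodes / 10.0)[None, :, None]
    end = np.zeros((positions_mm.size, 1, a_nodes.size, 3))
    end[..., 0] = (positions_mm[:, None] + a_nodes[None, :])[:, None, :] / 10.0
    end[..., 2] = geometry.total_cm

    path = cylinder_path_length(
        start,
        end,
        center=(bar_center_mm / 10.0, 0.0, depth),
        axis=(0.0, 1.0, 0.0),
        radius_cm=bar.radius_cm,
        half_length_cm=bar.length_cm / 2.0,
    )
    t = np.exp(-bar.attenuation_per_cm * path)
    return np.einsum("psa,s,a->p", t, s_weights, a_weights)


def simulate_profile(
    source: SourceSpec,
    level: str,
    bar_center_mm: float = 0.0,
    detector: DetectorSpec = DetectorSpec(),
    schedule: SamplingSchedule = SamplingSchedule(),
    geometry: MeasurementGeometry = RADIXACT,
    bar: BarSpec = BarSpec(),
    rng: Optional[np.random.Generator] = None,
    open_field_level: float = 1.0,
    metadata: Optional[dict] = None,
) -> BeamProfile:
    """Simulate one stepwise chamber scan and return it as a profile.

    The open field is modeled as flat over the scanned central region (the
    analysis uses only the central dip, so no penumbra model is included).
    Readings carry multiplicative Gaussian noise of CV ``detector.noise_cv``
    per electrometer sample, averaged over ``detector.samples_per_point``
    samples; with ``noise_cv == 0`` the profile is exactly deterministic.
    """
    positions = schedule.positions_mm()
    if np.max(np.abs(positions)) > 50.0:
        warnings.warn(
            "schedule extends beyond +/-50 mm; the flat open-field model is "
            "unrealistic outside the central field region",
            stacklevel=2,
        )
    tbar = transmission(
        positions, source, level, bar_center_mm, detector, geometry, bar
    )
    readings = open_field_level * tbar
    current_sd = None
    if detector.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(detector.seed)
        eps = rng.normal(0.0, detector.noise_cv, size=(positions.size, detector.samples_per_point))
        samples = readings[:, None] * (1.0 + eps)
        readings = samples.mean(axis=1)
        if detector.samples_per_point > 1:
            current_sd = samples.std(axis=1, ddof=1)
    meta = {"level": level}
    if metadata:
        meta.update(metadata)
    return BeamProfile(
        positions_mm=positions,
        currents=readings,
        n_samples_per_point=detector.samples_per_point,
        current_sd=current_sd,
        metadata=meta,
    )


def generate_session(
    true_offset_x_mm: float,
    true_offset_y_mm: float,
    n_repeats: int,
    n_sessions: int,
    seed: int,
    out_dir: str | Path,
    geometry: MeasurementGeometry = RADIXACT,
    bar: BarSpec = BarSpec(),
    detector: DetectorSpec = DetectorSpec(),
    schedule: SamplingSchedule = SamplingSchedule(),
    source_fwhm_mm: float = 1.0,
    session_sd_mm: float = 0.08,
    axes: Tuple[ScanAxis, ScanAxis] = (IEC_X, IEC_Y),
    open_field_level: float = 1.0,
) -> dict:
    """Emit a full synthetic measurement study and its ground-truth manifest.

    Writes ``2 axes x 2 levels x n_repeats x n_sessions`` profile CSVs plus
    ``manifest.json`` into ``out_dir``.  The injected IEC-frame offsets are
    converted to the stage frame with each axis' orientation sign, so the
    analysis pipeline (which applies the same sign) recovers the injected
    values.  Between-session reproducibility is modeled as a Normal(0,
    ``session_sd_mm``) lateral shift of the bar per session, common to both
    heights (the bar is realigned once per session).  All randomness derives
    from ``seed`` through a fixed spawn order, so identical calls reproduce
    byte-identical files.

    Raises ``FileExistsError`` if any target file already exists.
    """
    from .io import write_profile  # deferred: io imports profile only

    if n_repeats < 1 or n_sessions < 1:
        raise ValueError("n_repeats and n_sessions must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = {axes[0].name: float(true_offset_x_mm), axes[1].name: float(true_offset_y_mm)}
    ss = np.random.SeedSequence(seed)
    shift_rng = np.random.default_rng(ss.spawn(1)[0])
    session_shift_mm = shift_rng.normal(0.0, session_sd_mm, size=n_sessions)

    n_profiles = len(axes) * n_sessions * 2 * n_repeats
    children = ss.spawn(n_profiles)
    child_iter = iter(children)

    files = []
    for axis in axes:
        stage_offset = axis.orientation_sign * truth[axis.name]
        source = SourceSpec(offset_mm=stage_offset, fwhm_mm=source_fwhm_mm, sad_cm=geometry.sad_cm)
        for sess in range(n_sessions):
            bar_center = float(session_shift_mm[sess])
            for level in (UPSTREAM, DOWNSTREAM):
                tbar = transmission(
                    schedule.positions_mm(), source, level, bar_center, detector, geometry, bar
                )
                base = open_field_level * tbar
                for rep in range(n_repeats):
                    rng = np.random.default_rng(next(child_iter))
                    if detector.noise_cv > 0:
                        eps = rng.normal(
                            0.0, detector.noise_cv, size=(base.size, detector.samples_per_point)
                        )
                        samples = base[:, None] * (1.0 + eps)
                        readings = samples.mean(axis=1)
                        sd = samples.std(axis=1, ddof=1) if detector.samples_per_point > 1 else None
                    else:
                        readings, sd = base, None
                    profile = BeamProfile(
                        positions_mm=schedule.positions_mm(),
                        currents=readings,
                        n_samples_per_point=detector.samples_per_point,
                        current_sd=sd,
                        metadata={
                            "axis": axis.name,
                            "level": level,
                            "session": str(sess + 1),
                            "repeat": str(rep + 1),
                        },
                    )
                    name = f"{axis.name}_{level}_s{sess + 1:02d}_r{rep + 1:02d}.csv"
                    path = out / name
                    if path.exists():
                        raise FileExistsError(f"output file already exists: {path}")
                    write_profile(profile, path)
                    files.append(name)

    manifest = {
        "format": "barshadow-session/1",
        "seed": int(seed),
        "true_offset_x_mm": float(true_offset_x_mm),
        "true_offset_y_mm": float(true_offset_y_mm),
        "n_repeats": int(n_repeats),
        "n_sessions": int(n_sessions),
        "session_sd_mm": float(session_sd_mm),
        "source_fwhm_mm": float(source_fwhm_mm),
        "open_field_level": float(open_field_level),
        "geometry": {"a_cm": geometry.a_cm, "b_cm": geometry.b_cm, "c_cm": geometry.c_cm},
        "bar": {
            "length_cm": bar.length_cm,
            "diameter_cm": bar.diameter_cm,
            "attenuation_per_cm": bar.attenuation_per_cm,
        },
        "detector": {
            "aperture_mm": detector.aperture_mm,
            "noise_cv": detector.noise_cv,
            "samples_per_point": detector.samples_per_point,
        },
        "schedule": [list(s) for s in schedule.segments],
        "axis_signs": {axis.name: axis.orientation_sign for axis in axes},
        "session_shift_mm": [float(s) for s in session_shift_mm],
        "files": files,
    }
    manifest_path = out / MANIFEST_NAME
    if manifest_path.exists():
        raise FileExistsError(f"output file already exists: {manifest_path}")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def session_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-run :func:`generate_session` from a stored manifest.

    With the recorded seed and specs the regenerated profile files are
    byte-identical to the originals (determinism contract).
    """
    manifest = json.loads(Path(manifest_path).read_text())
    axes = tuple(
        ScanAxis(name, sign) for name, sign in manifest["axis_signs"].items()
    )
    return generate_session(
        true_offset_x_mm=manifest["true_offset_x_mm"],
        true_offset_y_mm=manifest["true_offset_y_mm"],
        n_repeats=manifest["n_repeats"],
        n_sessions=manifest["n_sessions"],
        seed=manifest["seed"],
        out_dir=out_dir,
        geometry=MeasurementGeometry(**manifest["geometry"]),
        bar=BarSpec(**manifest["bar"]),
        detector=DetectorSpec(**manifest["detector"]),
        schedule=SamplingSchedule(tuple(tuple(s) for s in manifest["schedule"])),
        source_fwhm_mm=manifest["source_fwhm_mm"],
        session_sd_mm=manifest["session_sd_mm"],
        axes=axes,
        open_field_level=manifest["open_field_level"],
    )
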