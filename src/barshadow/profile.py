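"""Dip-center analysis of measured beam profiles.

The center of the bar shadow is defined as the position where the derivative
of the recorded current with respect to stage position crosses zero.  The
derivative is taken with a three-point central difference that is exact for
linear data on arbitrary (nonuniform) grids; the zero crossing is located
either by linear interpolation between the bracketing samples or by a local
least-squares line through all derivative samples in a window around the
current minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ProfileError",
    "NoDipError",
    "InvalidDipError",
    "BeamProfile",
    "DerivativeProfile",
    "DipCenterEstimate",
    "RepeatStatistics",
    "differentiate_profile",
    "find_dip_center",
    "aggregate_repeats",
]


class ProfileError(ValueError):
    """Raised for profiles violating the container invariants."""


class NoDipError(ProfileError):
    """The derivative has no zero crossing inside the search window."""


class InvalidDipError(ProfileError):
    """A zero crossing exists but does not correspond to a current minimum."""


@dataclass
class BeamProfile:
    """Ordered (position, current) samples from one stepwise chamber scan.

    Positions are stage coordinates (mm) at the acquisition plane relative to
    the reference (isocenter projection); currents are relative readings on an
    arbitrary positive scale.  ``current_sd`` optionally carries the per-point
    standard deviation of the ``n_samples_per_point`` electrometer samples
    averaged into each reading (diagnostic only; the dip estimator ignores it).
    """

    positions_mm: np.ndarray
    currents: np.ndarray
    n_samples_per_point: int = 5
    current_sd: Optional[np.ndarray] = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.positions_mm.ndim != 1 or self.currents.ndim != 1:
            raise ProfileError("positions and currents must be 1-D")
        if self.positions_mm.size != self.currents.size:
            raise ProfileError(
                f"length mismatch: {self.positions_mm.size} positions vs "
                f"{self.currents.size} currents"
            )
        if self.positions_mm.size < 3:
            raise ProfileError("a profile needs at least 3 samples")
        if not np.all(np.diff(self.positions_mm) > 0):
            raise ProfileError("positions must be strictly increasing")
        if not np.all(self.currents > 0):
            raise ProfileError("currents must be strictly positive")
        if self.current_sd is not None:
            self.current_sd = np.asarray(self.current_sd, dtype=float)
            if self.current_sd.shape != self.currents.shape:
                raise ProfileError("current_sd must match currents in length")
        self.metadata = dict(self.metadata)

    def __len__(self) -> int:
        return int(self.positions_mm.size)


@dataclass(frozen=True)
class DerivativeProfile:
    """Current change per mm at the interior samples of a profile."""

    positions_mm: np.ndarray
    derivative: np.ndarray


@dataclass(frozen=True)
class DipCenterEstimate:
    """Zero-crossing position of the profile derivative.

    ``residual`` is the RMS deviation of the in-window derivative samples
    from the local line (``local_linear_fit``) or 0.0 for ``bracket_interp``,
    normalized by the largest in-window derivative magnitude.
    """

    center_mm: float
    method: str
    window_halfwidth_mm: float
    residual: float


@dataclass(frozen=True)
class RepeatStatistics:
    """Mean, sample SD (n-1) and SD of the mean over repeated estimates."""

    mean_mm: float
    sd_mm: float
    sd_of_mean_mm: float
    n: int


def differentiate_profile(profile: BeamProfile) -> DerivativeProfile:
    """Three-point central difference of current per distance.

    At each interior sample ``i`` the derivative is the slope of the secant
    through its neighbours, ``(c[i+1]-c[i-1])/(x[i+1]-x[i-1])``, which is
    valid on nonuniform grids and exact for linear data.  Endpoints are
    dropped.
    """
    x = profile.positions_mm
    c = profile.currents
    if x.size < 3:
        raise ProfileError("differentiation needs at least 3 samples")
    deriv = (c[2:] - c[:-2]) / (x[2:] - x[:-2])
    return DerivativeProfile(positions_mm=x[1:-1].copy(), derivative=deriv)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    # simple centered boxcar; endpoints use the available shrunken window
    if window % 2 != 1 or window < 3:
        raise ValueError("smooth_window must be an odd integer >= 3")
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo = max(0, i - half)
        hi = min(values.size, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def find_dip_center(
    profile: BeamProfile,
    window_halfwidth_mm: float = 1.0,
    method: str = "local_linear_fit",
    smooth_window: Optional[int] = None,
) -> DipCenterEstimate:
    """Locate the shadow center as the derivative zero crossing near the dip.

    The search window is centered on the minimum-current sample, which must
    lie strictly inside the scanned range.  With ``bracket_interp`` the
    negative-to-positive derivative sign change nearest the minimum is found
    and the root linearly interpolated between the bracketing samples; with
    ``local_linear_fit`` (default) a least-squares line through every
    derivative sample in the window supplies the root ``-intercept/slope``.
    Both are deterministic.  An optional centered moving average of the
    currents (``smooth_window`` points, off by default) can be applied before
    differentiation.

    Raises
    ------
    NoDipError
        If the derivative never changes sign from negative to positive inside
        the window.
    InvalidDipError
        If the fitted derivative slope is not positive (no current minimum),
        or the root falls outside the window.
    """
    if method not in ("bracket_interp", "local_linear_fit"):
        raise ValueError(f"unknown method {method!r}")
    if not window_halfwidth_mm > 0:
        raise ValueError("window_halfwidth_mm must be positive")

    work = profile
    if smooth_window is not None:
        work = BeamProfile(
            positions_mm=profile.positions_mm,
            currents=_moving_average(profile.currents, smooth_window),
            n_samples_per_point=profile.n_samples_per_point,
            metadata=profile.metadata,
        )

    i_min = int(np.argmin(work.currents))
    if i_min == 0 or i_min == len(work) - 1:
        raise NoDipError("minimum current lies on the scan boundary; no dip")
    x0 = work.positions_mm[i_min]

    dprof = differentiate_profile(work)
    in_window = np.abs(dprof.positions_mm - x0) <= window_halfwidth_mm
    if int(in_window.sum()) < 4:
        raise ProfileError(
            f"window +/-{window_halfwidth_mm} mm around {x0:g} mm holds only "
            f"{int(in_window.sum())} derivative samples (need >= 4)"
        )
    xs = dprof.positions_mm[in_window]
    gs = dprof.derivative[in_window]

    if method == "bracket_interp":
        center = _bracket_root(xs, gs, x0)
        residual = 0.0
    else:
        slope, intercept = np.polyfit(xs, gs, 1)
        if slope <= 0:
            raise InvalidDipError(
                "derivative is not increasing through the window; no minimum"
            )
        center = -intercept / slope
        scale = np.max(np.abs(gs))
        resid = gs - (slope * xs + intercept)
        residual = float(np.sqrt(np.mean(resid**2)) / scale) if scale > 0 else 0.0

    if not (xs[0] <= center <= xs[-1]):
        raise InvalidDipError(
            f"estimated center {center:.4g} mm falls outside the search window"
        )
    return DipCenterEstimate(
        center_mm=float(center),
        method=method,
        window_halfwidth_mm=float(window_halfwidth_mm),
        residual=float(residual),
    )


def _bracket_root(xs: np.ndarray, gs: np.ndarray, x0: float) -> float:
    """Root of the nearest negative-to-positive sign change to ``x0``."""
    candidates = []
    for i in range(xs.size - 1):
        g0, g1 = gs[i], gs[i + 1]
        if g0 == 0.0 and g1 > 0.0:
            candidates.append(float(xs[i]))
        elif g0 < 0.0 <= g1:
            root = xs[i] - g0 * (xs[i + 1] - xs[i]) / (g1 - g0)
            candidates.append(float(root))
    if not candidates:
        raise NoDipError("no negative-to-positive derivative crossing in window")
    return min(candidates, key=lambda r: abs(r - x0))


def aggregate_repeats(
    estimates: Sequence[DipCenterEstimate | float],
) -> RepeatStatistics:
    """Mean, sample SD and SD of the mean of repeated dip-center estimates.

    Accepts either :class:`DipCenterEstimate` objects or bare center values
    in mm.  Requires at least two repeats.
    """
    centers = np.array(
        [e.center_mm if isinstance(e, DipCenterEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    if centers.size < 2:
        raise ValueError("aggregation needs at least 2 estimates")
    sd = float(np.std(centers, ddof=1))
    return RepeatStatistics(
        mean_mm=float(np.mean(centers)),
        sd_mm=sd,
        sd_of_mean_mm=sd / float(np.sqrt(centers.size)),
        n=int(centers.size),
    )
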