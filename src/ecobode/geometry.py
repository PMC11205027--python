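"""Cochlear geometry from CT-slice landmarks.

This module turns a small set of manually selected landmarks on an axial
CT slice of an implanted cochlea — the cochlear center, the round window
(RW), and ordered points along the electrode array — into the two x-axes
every downstream plot shares:

* per-contact **insertion depth** in mm, measured as arc length along the
  array trajectory from the round window, and
* per-contact **angular insertion depth** (AID) in degrees, the unwrapped
  polar angle about the cochlear center measured from the center→RW ray.

The trajectory is a cubic spline through ``[round_window, *array_points]``
(not-a-knot boundary, knot-index parameterization), densely resampled so
that the chordal sum approximates arc length.  Contact depths follow from
the apical contact's depth and the array's known inter-contact span; AIDs
are linearly interpolated between the basal and apical contact angles.

Coordinates are image coordinates scaled to mm via ``scale_mm_per_px``;
the insertion rotation sense (left vs right ear, y-up vs y-down images)
is auto-detected from the landmarks, so no ear-side flag is needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import GeometryError, InputError

__all__ = [
    "Point2D",
    "CochlearLandmarks",
    "Trajectory",
    "ElectrodeGeometry",
    "overlay_slices",
    "fit_trajectory",
    "apical_insertion_depth",
    "electrode_depths",
    "point_angles",
    "electrode_aids",
    "monitoring_axis",
]

#: Maximum distance (mm) between the apical landmark and the nearest
#: trajectory sample before the landmarks are declared inconsistent.
APICAL_MATCH_TOL_MM = 0.1


@dataclass(frozen=True)
class Point2D:
    """A point in the slice plane, in mm (or px before calibration)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class CochlearLandmarks:
    """User-selected landmarks describing one implanted cochlea.

    ``array_points`` are ordered basal-most first, apical-most last and
    must include the basal and apical electrode contacts as their first
    and last entries.  ``scale_mm_per_px`` calibrates raw pixel
    coordinates; use 1.0 when the coordinates are already in mm.
    """

    center: Point2D
    round_window: Point2D
    array_points: tuple[Point2D, ...]
    scale_mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "array_points", tuple(self.array_points))
        if len(self.array_points) < 2:
            raise InputError("need at least 2 points along the electrode array")
        if self.scale_mm_per_px <= 0:
            raise InputError("scale_mm_per_px must be positive")
        if _same_point(self.center, self.round_window):
            raise GeometryError("cochlear center coincides with the round window")
        chain = (self.round_window, *self.array_points)
        for i in range(len(chain) - 1):
            if _same_point(chain[i], chain[i + 1]):
                raise GeometryError(
                    f"degenerate knots: consecutive landmark points {i} and {i + 1} coincide"
                )

    def to_mm(self) -> "CochlearLandmarks":
        """Return a copy with coordinates scaled to mm (scale becomes 1)."""
        if self.scale_mm_per_px == 1.0:
            return self
        s = self.scale_mm_per_px
        scale = lambda p: Point2D(p.x * s, p.y * s)  # noqa: E731
        return CochlearLandmarks(
            center=scale(self.center),
            round_window=scale(self.round_window),
            array_points=tuple(scale(p) for p in self.array_points),
            scale_mm_per_px=1.0,
        )


def _same_point(a: Point2D, b: Point2D, tol: float = 1e-12) -> bool:
    return abs(a.x - b.x) <= tol and abs(a.y - b.y) <= tol


@dataclass(frozen=True)
class Trajectory:
    """Densely sampled electrode-array curve starting at the round window.

    ``points`` has shape (n_samples, 2) in mm; ``cumulative_arc_length``
    holds the chordal arc length from the first sample, non-decreasing
    with ``cumulative_arc_length[0] == 0``.
    """

    points: np.ndarray
    cumulative_arc_length: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        cum = np.asarray(self.cumulative_arc_length, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) != len(cum):
            raise InputError("trajectory points/arc-length shape mismatch")
        if cum[0] != 0 or np.any(np.diff(cum) < 0):
            raise GeometryError("cumulative arc length must start at 0 and be non-decreasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cumulative_arc_length", cum)

    @property
    def total_length(self) -> float:
        return float(self.cumulative_arc_length[-1])


@dataclass
class ElectrodeGeometry:
    """Per-contact axes shared by every plot.

    Arrays are ordered apical-most first (contact 1), matching the
    convention that the apical contact has the largest insertion depth
    and AID.  ``tonotopic_freq_hz`` is filled by the tonotopy stage and
    may be ``None`` until then.
    """

    insertion_depth_mm: np.ndarray
    insertion_angle_deg: np.ndarray
    tonotopic_freq_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.insertion_depth_mm, dtype=float)
        a = np.asarray(self.insertion_angle_deg, dtype=float)
        if d.shape != a.shape or d.ndim != 1 or len(d) < 2:
            raise InputError("depth/angle vectors must be 1-D, equal length >= 2")
        if np.any(np.diff(d) >= 0):
            raise GeometryError("insertion depths must strictly decrease apical -> basal")
        if np.any(d < 0):
            raise GeometryError("insertion depths must be non-negative")
        if np.any(np.diff(a) > 0):
            raise GeometryError("insertion angles must be non-increasing apical -> basal")
        self.insertion_depth_mm = d
        self.insertion_angle_deg = a
        if self.tonotopic_freq_hz is not None:
            f = np.asarray(self.tonotopic_freq_hz, dtype=float)
            if f.shape != d.shape:
                raise InputError("tonotopic_freq_hz length mismatch")
            self.tonotopic_freq_hz = f

    @property
    def n_contacts(self) -> int:
        return len(self.insertion_depth_mm)

    def with_frequencies(self, freqs: np.ndarray) -> "ElectrodeGeometry":
        return replace(self, tonotopic_freq_hz=np.asarray(freqs, dtype=float))

    def depth_angle_fit(self) -> tuple[float, float]:
        """Least-squares linear map depth→angle, ``angle = m*depth + c``.

        Exact whenever angles were produced by linear interpolation over
        the (arithmetic) depth sequence, which is how both axis routes
        construct them.
        """
        m, c = np.polyfit(self.insertion_depth_mm, self.insertion_angle_deg, 1)
        return float(m), float(c)


# ---------------------------------------------------------------------------
# slice overlay
# ---------------------------------------------------------------------------

def overlay_slices(
    images: Sequence[np.ndarray], combiner: str = "max"
) -> np.ndarray:
    """Combine equal-shape grayscale slices into one image.

    Electrode contacts are hyperdense (bright) in CT, so the default
    per-pixel maximum keeps every contact that is visible in any slice
    visible in the overlay.  ``combiner`` may be ``"max"`` (default),
    ``"min"`` or ``"mean"``.
    """
    if len(images) == 0:
        raise InputError("overlay_slices needs at least one image")
    arrays = [np.asarray(im) for im in images]
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise InputError(
                f"image {i} has shape {a.shape}, expected {shape}: all slices must match"
            )
    stack = np.stack(arrays)
    if combiner == "max":
        return stack.max(axis=0)
    if combiner == "min":
        return stack.min(axis=0)
    if combiner == "mean":
        return stack.mean(axis=0).astype(arrays[0].dtype)
    raise InputError(f"unknown combiner {combiner!r}; use max, min or mean")


# ---------------------------------------------------------------------------
# trajectory and depths
# ---------------------------------------------------------------------------

def fit_trajectory(
    landmarks: CochlearLandmarks,
    n_samples: int = 10**6,
    parameterization: str = "index",
) -> Trajectory:
    """Fit a cubic-spline trajectory through the RW and array landmarks.

    The spline interpolates x and y separately as one-dimensional
    functions of the knot parameter (not-a-knot boundary conditions) and
    is evaluated at ``n_samples`` equally spaced parameter values; the
    cumulative arc length is the running sum of consecutive chord
    lengths.

    ``parameterization`` is ``"index"`` (knot number, the default) or
    ``"chord"`` (cumulative chord length between knots), the latter
    being more robust to very uneven landmark spacing.
    """
    lm = landmarks.to_mm()
    knots = np.array(
        [lm.round_window.as_array()] + [p.as_array() for p in lm.array_points]
    )
    n_knots = len(knots)
    if n_samples < 10 * n_knots:
        raise InputError(
            f"n_samples={n_samples} too small; need at least 10 x {n_knots} knots"
        )
    if parameterization == "index":
        t = np.arange(n_knots, dtype=float)
    elif parameterization == "chord":
        chords = np.hypot(*np.diff(knots, axis=0).T)
        t = np.concatenate([[0.0], np.cumsum(chords)])
    else:
        raise InputError(f"unknown parameterization {parameterization!r}")
    sx = CubicSpline(t, knots[:, 0])
    sy = CubicSpline(t, knots[:, 1])
    tt = np.linspace(t[0], t[-1], n_samples)
    pts = np.column_stack([sx(tt), sy(tt)])
    seg = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return Trajectory(points=pts, cumulative_arc_length=cum)


def apical_insertion_depth(
    trajectory: Trajectory,
    apical_point: Point2D,
    tol_mm: float = APICAL_MATCH_TOL_MM,
) -> float:
    """Arc length from the round window to the apical contact (mm).

    The apical contact's depth is read off at the trajectory sample
    nearest ``apical_point`` (which should be the last landmark knot,
    already in mm).  A nearest-sample distance above ``tol_mm`` means
    the landmark does not lie on the fitted curve and raises
    :class:`GeometryError`.
    """
    target = apical_point.as_array()
    d2 = np.sum((trajectory.points - target) ** 2, axis=1)
    idx = int(np.argmin(d2))
    dist = math.sqrt(d2[idx])
    if dist > tol_mm:
        raise GeometryError(
            f"apical point is {dist:.3f} mm from the trajectory (tolerance {tol_mm} mm); "
            "landmarks are inconsistent"
        )
    return float(trajectory.cumulative_arc_length[idx])


def electrode_depths(apical_depth: float, spec) -> np.ndarray:
    """Per-contact insertion depths from the apical depth and array span.

    Contacts are equally spaced along the array, so depth of contact i
    (1 = apical) is ``apical_depth - (i-1) * array_length / (n-1)``.  If
    that puts the basal contact at negative depth — which happens when
    the basal contact sits at the round window and the 2-D arc length
    slightly underestimates the array span — the axis is corrected so
    the apical contact is at ``array_length`` and the basal contact at
    exactly 0, keeping equal spacing.
    """
    n = spec.n_contacts
    length = spec.array_length_mm
    if apical_depth <= 0:
        raise InputError(f"apical depth must be positive, got {apical_depth}")
    if n < 2:
        raise InputError("need at least 2 contacts")
    if length <= 0:
        raise InputError("array length must be positive")
    depths = apical_depth - np.arange(n) * (length / (n - 1))
    if depths[-1] < 0:
        depths = np.linspace(length, 0.0, n)
    return depths


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def point_angles(landmarks: CochlearLandmarks) -> np.ndarray:
    """Unwrapped insertion angle (deg) of each array landmark.

    Angles are measured about the cochlear center from the center→RW
    ray, in the direction of insertion, and unwrapped basal→apical so
    the sequence is non-decreasing and may exceed 360°.  The rotation
    sense (clockwise vs counter-clockwise in image coordinates, i.e.
    left vs right ear or y-down rasters) is inferred from the net signed
    rotation of the array knots, so the result is invariant under
    rotation, translation and mirror reflection of all landmarks.
    """
    lm = landmarks.to_mm()
    c = lm.center.as_array()
    ref = lm.round_window.as_array() - c
    pts = np.array([p.as_array() for p in lm.array_points]) - c
    radii = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(radii < 1e-9):
        raise GeometryError("an array landmark coincides with the cochlear center")
    # signed angle of each knot relative to the center->RW ray, in (-180, 180]
    raw = np.degrees(
        np.arctan2(
            pts[:, 0] * ref[1] - pts[:, 1] * ref[0],  # negative cross => ccw positive below
            pts[:, 0] * ref[0] + pts[:, 1] * ref[1],
        )
    )
    raw = -raw  # atan2(cross, dot) with cross = ref x p gives ccw-positive angles
    # rotation sense: net signed advance along the knot chain
    inc = np.diff(raw)
    inc = (inc + 180.0) % 360.0 - 180.0
    net = inc.sum() + _wrap_half(raw[0])
    sense = 1.0 if net >= 0 else -1.0
    ang = sense * raw
    ang[0] = ang[0] % 360.0
    # unwrap: add 360 whenever the basal->apical sequence would decrease
    for i in range(1, len(ang)):
        while ang[i] < ang[i - 1]:
            ang[i] += 360.0
    return ang


def _wrap_half(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def electrode_aids(
    basal_angle: float, apical_angle: float, n_contacts: int
) -> np.ndarray:
    """Per-contact AIDs, linearly interpolated apical→basal.

    Returns ``n_contacts`` equally spaced angles from ``apical_angle``
    (contact 1) down to ``basal_angle`` (contact n).
    """
    if basal_angle < 0:
        raise InputError("basal angle must be >= 0")
    if apical_angle < basal_angle:
        raise InputError(
            f"apical angle ({apical_angle}) must be >= basal angle ({basal_angle})"
        )
    if n_contacts < 1:
        raise InputError("need at least one contact")
    return np.linspace(apical_angle, basal_angle, n_contacts)


def landmark_geometry(
    landmarks: CochlearLandmarks,
    spec,
    n_samples: int = 10**6,
    parameterization: str = "index",
) -> ElectrodeGeometry:
    """Full imaging route: landmarks → per-contact depths and AIDs.

    Convenience composition of :func:`fit_trajectory`,
    :func:`apical_insertion_depth`, :func:`electrode_depths`,
    :func:`point_angles` and :func:`electrode_aids`.  Tonotopic
    frequencies are left unset; the tonotopy stage fills them.
    """
    lm = landmarks.to_mm()
    traj = fit_trajectory(lm, n_samples=n_samples, parameterization=parameterization)
    apical = apical_insertion_depth(traj, lm.array_points[-1])
    depths = electrode_depths(apical, spec)
    angles = point_angles(lm)
    aids = electrode_aids(angles[0], angles[-1], spec.n_contacts)
    return ElectrodeGeometry(insertion_depth_mm=depths, insertion_angle_deg=aids)


# ---------------------------------------------------------------------------
# insertion-monitoring axis
# ---------------------------------------------------------------------------

def monitoring_axis(
    geometry: ElectrodeGeometry,
    markers: Sequence[tuple[float, int]],
    samples: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Map insertion-monitoring timestamps to (depth mm, AID deg).

    During insertion the apical contact records while the surgeon marks
    the instant each contact j enters the cochlea.  At that instant the
    recording electrode sits at depth ``depth[1] - depth[j]`` (the fixed
    arc distance between the apical contact and contact j, taken from
    the sweep axes).  Sample depths are linearly interpolated in time
    between markers and linearly extrapolated before the first marker,
    clamped at 0 mm; AIDs follow the sweep axes' linear depth↔angle map,
    clamped at 0°.

    ``markers`` is a time-ordered list of ``(time_s, contact_index)``
    with contact 1 = apical.  Returns arrays aligned with ``samples``.
    """
    markers = list(markers)
    if len(markers) < 2:
        raise InputError("need at least 2 insertion markers to fix the time axis")
    times = np.array([t for t, _ in markers], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise InputError("marker times must be strictly increasing")
    idx = np.array([j for _, j in markers], dtype=int)
    if np.any(idx < 1) or np.any(idx > geometry.n_contacts):
        raise InputError("marker contact index out of range")
    d = geometry.insertion_depth_mm
    marker_depths = d[0] - d[idx - 1]

    samples = np.asarray(samples, dtype=float)
    # piecewise-linear in time with extrapolation from the end segments
    depth = np.interp(samples, times, marker_depths)
    slope0 = (marker_depths[1] - marker_depths[0]) / (times[1] - times[0])
    before = samples < times[0]
    depth[before] = marker_depths[0] + slope0 * (samples[before] - times[0])
    slope1 = (marker_depths[-1] - marker_depths[-2]) / (times[-1] - times[-2])
    after = samples > times[-1]
    depth[after] = marker_depths[-1] + slope1 * (samples[after] - times[-1])

    t_zero = times[0] - marker_depths[0] / slope0 if slope0 > 0 else times[0]
    out_of_range = (samples < t_zero - 1e-9) | (samples > times[-1] + 1e-9)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} monitoring sample(s) outside the "
            "[extrapolated start, last marker] window; depths clamped",
            stacklevel=2,
        )
    depth = np.clip(depth, 0.0, None)

    m, c = geometry.depth_angle_fit()
    aid = np.clip(m * depth + c, 0.0, None)
    return depth, aid
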