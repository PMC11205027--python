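"""Synthetic cochleae, recordings and audiograms with analytic ground truth.

No public imaging or ECochG dataset accompanies this problem, so every
stage is validated against generated data whose true geometry is known
in closed form.  The cochlea stand-in is an Archimedean spiral
``r(θ) = r0 - b·θ`` about the cochlear center with the round window at
θ = 0: its arc length has the exact antiderivative

    s(θ) = [F(r0) - F(r0 - bθ)] / b,   F(u) = (u·√(u²+b²) + b²·asinh(u/b)) / 2,

so contact depths and polar angles are available without numerical
error, and the pipeline's recovery of them can be measured honestly.
The default spiral decays gently (the per-contact AID axis is a linear
interpolation between the end contacts, which is exact on a circle and
degrades with radial decay — see the methods note).

ECochG amplitude courses follow the two canonical insertion patterns
(monotone rise to completion; raised-cosine mid-insertion bump with
matching ends) plus a flat control, with linear phase delay along the
array.  Audiograms are flat or high-frequency-sloping with the
no-response substitution applied at the audiometer's limits.

All randomness flows through one explicitly passed seed; equal seeds
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .audiology import CLINICAL_FREQS_HZ, Audiogram
from .ecochg import EcochgMeasurement
from .errors import GeometryError, InputError
from .geometry import CochlearLandmarks, ElectrodeGeometry, Point2D

__all__ = [
    "SpiralModel",
    "generate_geometry",
    "generate_measurement",
    "generate_audiogram",
    "generate_slice_images",
]


@dataclass(frozen=True)
class SpiralModel:
    """Archimedean spiral stand-in for an imaged cochlea.

    Defaults give ~16 mm of arc over 1.5 turns with a gently decaying
    radius (r 1.72 → 1.68 mm), the regime in which the per-contact AID
    interpolation of the axis pipeline is a faithful approximation.
    """

    center: Point2D = field(default_factory=lambda: Point2D(0.0, 0.0))
    r0_mm: float = 1.72
    b_mm_per_rad: float = 0.004
    theta_max_rad: float = 10.0
    handedness: str = "ccw"  # direction of insertion in image coordinates

    def __post_init__(self) -> None:
        if self.theta_max_rad <= 0:
            raise InputError("theta_max must be positive")
        if self.b_mm_per_rad < 0:
            raise InputError("radius decay b must be >= 0")
        if self.r0_mm - self.b_mm_per_rad * self.theta_max_rad <= 0:
            raise GeometryError("radius reaches zero before theta_max")

    def radius(self, theta: float) -> float:
        return self.r0_mm - self.b_mm_per_rad * theta

    def arc_length(self, theta) -> np.ndarray | float:
        """Exact arc length from θ=0 (round window), in mm."""
        theta = np.asarray(theta, dtype=float)
        b = self.b_mm_per_rad
        if b == 0:
            s = self.r0_mm * theta
        else:
            F = lambda u: 0.5 * (u * np.sqrt(u * u + b * b) + b * b * np.arcsinh(u / b))  # noqa: E731
            s = (F(self.r0_mm) - F(self.r0_mm - b * theta)) / b
        return float(s) if np.ndim(theta) == 0 else s

    def theta_at_arc(self, s: float) -> float:
        """Invert :meth:`arc_length` (bisection on the closed form)."""
        if not 0 <= s <= self.arc_length(self.theta_max_rad) + 1e-12:
            raise GeometryError(f"arc length {s} mm outside the spiral extent")
        if s == 0:
            return 0.0
        return brentq(lambda t: self.arc_length(t) - s, 0.0, self.theta_max_rad, xtol=1e-12)

    def point_at(self, theta: float) -> Point2D:
        """Cartesian position; RW direction is +x, handedness sets the turn sense."""
        sign = 1.0 if self.handedness == "ccw" else -1.0
        r = self.radius(theta)
        return Point2D(
            self.center.x + r * math.cos(sign * theta),
            self.center.y + r * math.sin(sign * theta),
        )


def generate_geometry(
    model: SpiralModel,
    spec,
    apical_theta_rad: float = 9.4,
    n_landmarks: int = 17,
    noise_sd_mm: float = 0.0,
    seed: int | None = None,
    scale_mm_per_px: float = 1.0,
) -> tuple[CochlearLandmarks, ElectrodeGeometry]:
    """Place an electrode array on the spiral and emit landmarks + truth.

    The apical contact sits at polar angle ``apical_theta_rad``; the
    remaining contacts are spaced back from it at equal *arc* intervals
    of ``array_length / (n-1)``.  Landmarks are ``n_landmarks`` points
    equally spaced in arc length from the basal to the apical contact
    (both included), with optional isotropic Gaussian coordinate noise.
    Ground truth: depths are the exact arc lengths from the RW, AIDs the
    exact polar angles in degrees.  ``scale_mm_per_px`` converts the
    emitted landmark coordinates to pixels, exercising calibration.
    """
    if apical_theta_rad > model.theta_max_rad:
        raise InputError("apical_theta exceeds the spiral extent")
    if n_landmarks < 4:
        raise InputError("need at least 4 landmarks")
    n = spec.n_contacts
    s_apical = model.arc_length(apical_theta_rad)
    spacing = spec.array_length_mm / (n - 1)
    s_contacts = s_apical - spacing * np.arange(n)  # apical-first
    if s_contacts[-1] < 0:
        raise GeometryError(
            f"array span {spec.array_length_mm} mm exceeds the available arc "
            f"({s_apical:.2f} mm) — basal contact would sit outside the cochlea"
        )
    theta_contacts = np.array([model.theta_at_arc(s) for s in s_contacts])
    truth = ElectrodeGeometry(
        insertion_depth_mm=s_contacts,
        insertion_angle_deg=np.degrees(theta_contacts),
    )

    rng = np.random.default_rng(seed)
    s_landmarks = np.linspace(s_contacts[-1], s_apical, n_landmarks)
    pts = []
    for s in s_landmarks:
        p = model.point_at(model.theta_at_arc(s))
        x, y = p.x, p.y
        if noise_sd_mm > 0:
            x += rng.normal(0.0, noise_sd_mm)
            y += rng.normal(0.0, noise_sd_mm)
        pts.append(Point2D(x / scale_mm_per_px, y / scale_mm_per_px))
    rw = model.point_at(0.0)
    landmarks = CochlearLandmarks(
        center=Point2D(model.center.x / scale_mm_per_px, model.center.y / scale_mm_per_px),
        round_window=Point2D(rw.x / scale_mm_per_px, rw.y / scale_mm_per_px),
        array_points=tuple(pts),
        scale_mm_per_px=scale_mm_per_px,
    )
    return landmarks, truth


def generate_measurement(
    pattern: str,
    n_sites: int = 11,
    peak_db: float = 20.0,
    noise_sd_db: float = 0.0,
    seed: int | None = None,
    site_refs=None,
    label: str | None = None,
    stimulus_freq_hz: float = 500.0,
    phase_delay_total_deg: float = 180.0,
) -> EcochgMeasurement:
    """Synthesize an ECochG series with a known insertion-amplitude shape.

    ``pattern``: ``"A"`` — monotone rise from 0 to ``peak_db`` at
    completion; ``"C"`` — raised-cosine bump peaking at ``peak_db``
    mid-insertion with equal (zero) ends; ``"flat"`` — constant 0 dB.
    Phases accumulate a linear delay of ``phase_delay_total_deg`` along
    the course.  Gaussian amplitude/phase noise is added per site.
    """
    if n_sites < 5:
        raise InputError("need at least 5 sites")
    frac = np.linspace(0.0, 1.0, n_sites)
    if pattern == "A":
        amps = peak_db * frac
    elif pattern == "C":
        amps = peak_db * 0.5 * (1.0 - np.cos(2.0 * np.pi * frac))
    elif pattern == "flat":
        amps = np.zeros(n_sites)
    else:
        raise InputError(f"unknown pattern {pattern!r}; use A, C or flat")
    phases = -phase_delay_total_deg * frac
    rng = np.random.default_rng(seed)
    if noise_sd_db > 0:
        amps = amps + rng.normal(0.0, noise_sd_db, n_sites)
        phases = phases + rng.normal(0.0, 2.0 * noise_sd_db, n_sites)
    if site_refs is None:
        site_refs = list(range(1, n_sites + 1))
    return EcochgMeasurement(
        label=label or f"synthetic {pattern} pattern",
        site_refs=list(site_refs),
        amplitudes_db=amps,
        phases_deg=phases,
        stimulus_freq_hz=stimulus_freq_hz,
    )


def generate_audiogram(
    shape: str = "ski_slope",
    base_level_db: float = 40.0,
    slope_db_per_octave: float = 15.0,
    seed: int | None = None,
    timepoint: str = "preoperative",
    audiometer_max_db: float = 110.0,
    jitter_sd_db: float = 0.0,
) -> Audiogram:
    """Synthesize an audiogram over the clinical frequency set.

    ``flat`` holds ``base_level_db`` everywhere; ``ski_slope`` rises by
    ``slope_db_per_octave`` above 500 Hz, emulating typical
    high-frequency hearing loss.  Thresholds exceeding the audiometer's
    maximum output are flagged no-response and substituted with
    max + 5 dB; thresholds are rounded to the clinical 5 dB step.
    """
    if shape not in ("flat", "ski_slope"):
        raise InputError(f"unknown audiogram shape {shape!r}")
    rng = np.random.default_rng(seed)
    thresholds: dict[int, float] = {}
    no_resp: dict[int, bool] = {}
    amax = {f: audiometer_max_db for f in CLINICAL_FREQS_HZ}
    for f in CLINICAL_FREQS_HZ:
        level = base_level_db
        if shape == "ski_slope" and f > 500:
            level += slope_db_per_octave * math.log2(f / 500.0)
        if jitter_sd_db > 0:
            level += rng.normal(0.0, jitter_sd_db)
        level = 5.0 * round(level / 5.0)
        if level > audiometer_max_db:
            no_resp[f] = True
            level = audiometer_max_db + 5.0  # re-applied by the Audiogram invariant
        thresholds[f] = level
    return Audiogram(
        timepoint=timepoint, thresholds=thresholds, no_response=no_resp, audiometer_max=amax
    )


def generate_slice_images(
    points_px,
    shape: tuple[int, int] = (64, 64),
    radius_px: int = 2,
    n_slices: int = 2,
    value: int = 255,
) -> list[np.ndarray]:
    """Small labeled-blob slice images for overlay testing.

    Round-robins bright disks at ``points_px`` (x, y) across
    ``n_slices`` dark 8-bit images, so only the overlay shows them all.
    """
    images = [np.zeros(shape, dtype=np.uint8) for _ in range(n_slices)]
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (x, y) in enumerate(points_px):
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= radius_px**2
        images[i % n_slices][disk] = value
    return images
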