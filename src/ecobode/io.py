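"""Interchange formats: landmark JSON, axes CSV, image files.

The axes CSV (one row per contact: ``contact_index, insertion_depth_mm,
insertion_angle_deg, tonotopic_freq_hz``; contact 1 = apical-most) is the
hand-off between the geometry stages and the renderer, so axes can also
be produced or audited outside this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ParseError
from .geometry import CochlearLandmarks, ElectrodeGeometry, Point2D

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_axes_csv",
    "write_axes_csv",
    "read_image",
    "write_image",
]


def read_landmarks(path: str | Path) -> CochlearLandmarks:
    """Read landmark JSON: scale_mm_per_px, center, round_window, array_points.

    Coordinates are raw pixel positions (basal→apical order for
    array_points); the scale factor calibrates them to mm downstream.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return CochlearLandmarks(
            center=Point2D(*map(float, data["center"])),
            round_window=Point2D(*map(float, data["round_window"])),
            array_points=tuple(Point2D(*map(float, p)) for p in data["array_points"]),
            scale_mm_per_px=float(data["scale_mm_per_px"]),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing or malformed field ({exc})") from exc


def write_landmarks(landmarks: CochlearLandmarks, path: str | Path) -> None:
    data = {
        "scale_mm_per_px": landmarks.scale_mm_per_px,
        "center": [landmarks.center.x, landmarks.center.y],
        "round_window": [landmarks.round_window.x, landmarks.round_window.y],
        "array_points": [[p.x, p.y] for p in landmarks.array_points],
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def write_axes_csv(geometry: ElectrodeGeometry, path: str | Path) -> None:
    """One row per contact, apical contact first (contact_index 1)."""
    df = pd.DataFrame(
        {
            "contact_index": np.arange(1, geometry.n_contacts + 1),
            "insertion_depth_mm": geometry.insertion_depth_mm,
            "insertion_angle_deg": geometry.insertion_angle_deg,
            "tonotopic_freq_hz": (
                geometry.tonotopic_freq_hz
                if geometry.tonotopic_freq_hz is not None
                else np.full(geometry.n_contacts, np.nan)
            ),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_axes_csv(path: str | Path) -> ElectrodeGeometry:
    df = pd.read_csv(path)
    required = {"contact_index", "insertion_depth_mm", "insertion_angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.sort_values("contact_index")
    freqs = None
    if "tonotopic_freq_hz" in df.columns and not df["tonotopic_freq_hz"].isna().any():
        freqs = df["tonotopic_freq_hz"].to_numpy(dtype=float)
    return ElectrodeGeometry(
        insertion_depth_mm=df["insertion_depth_mm"].to_numpy(dtype=float),
        insertion_angle_deg=df["insertion_angle_deg"].to_numpy(dtype=float),
        tonotopic_freq_hz=freqs,
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF slice as a 2-D array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_image(array: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(array).astype(np.uint8)).save(path)
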