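"""Greenwood frequency–position map for the cochlear duct.

The Greenwood function relates position along the basilar membrane to
characteristic frequency,

    F(x) = A * (10**(a * x) - k),

with x the *proportional* distance from the apex (x = 0 at the apex,
x = 1 at the base).  This package measures electrode position as
insertion depth d from the base (round window), so x = (L - d) / L with
L the cochlear duct length.  The proportional form is used so that an
individually measured L rescales the map without touching A, a, k.

Default constants are the standard human values A = 165.4 Hz, a = 2.1,
k = 0.88 with a default duct length of 36.2 mm; all four can be
overridden via :meth:`GreenwoodParams.from_yaml` for non-human or
individualized maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError, RangeError

__all__ = ["GreenwoodParams", "greenwood_frequency", "greenwood_depth"]

#: Default cochlear duct length in mm.
DEFAULT_DUCT_LENGTH_MM = 36.2


@dataclass(frozen=True)
class GreenwoodParams:
    """Constants of the Greenwood map (proportional-distance form)."""

    A: float = 165.4  # frequency scale, Hz
    a: float = 2.1  # exponent slope per unit proportional distance
    k: float = 0.88  # integration constant
    L: float = DEFAULT_DUCT_LENGTH_MM  # cochlear duct length, mm

    def __post_init__(self) -> None:
        if self.A <= 0 or self.a <= 0 or self.L <= 0:
            raise InputError("Greenwood A, a and L must be positive")
        if not 0 <= self.k < 1:
            raise InputError("Greenwood k must lie in [0, 1)")

    @property
    def apex_frequency(self) -> float:
        """Lowest mappable frequency, at the apex: A * (1 - k)."""
        return self.A * (1.0 - self.k)

    @property
    def base_frequency(self) -> float:
        """Highest mappable frequency, at the base: A * (10**a - k)."""
        return self.A * (10.0**self.a - self.k)

    def with_duct_length(self, L: float) -> "GreenwoodParams":
        return replace(self, L=L)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GreenwoodParams":
        """Load constants from a YAML mapping with keys A, a, k, L."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {key: float(data[key]) for key in ("A", "a", "k", "L") if key in data}
        return cls(**kwargs)


def greenwood_frequency(
    depth_from_base_mm, params: GreenwoodParams = GreenwoodParams()
):
    """Characteristic frequency (Hz) at insertion depth d from the base.

    Strictly decreasing in depth: deeper contacts sit more apically and
    see lower frequencies.  ``depth_from_base_mm`` may be a scalar or
    array; values must lie in [0, L].
    """
    d = np.asarray(depth_from_base_mm, dtype=float)
    if np.any(d < -1e-9) or np.any(d > params.L + 1e-9):
        raise RangeError(
            f"depth outside [0, {params.L}] mm: {d[(d < -1e-9) | (d > params.L + 1e-9)]}"
        )
    x = (params.L - d) / params.L  # proportional distance from apex
    f = params.A * (10.0 ** (params.a * x) - params.k)
    return float(f) if np.isscalar(depth_from_base_mm) else f


def greenwood_depth(freq_hz, params: GreenwoodParams = GreenwoodParams()):
    """Insertion depth d (mm from base) whose characteristic frequency is ``freq_hz``.

    Exact closed-form inverse of :func:`greenwood_frequency`:
    d = L - (L / a) * log10(F / A + k).
    """
    f = np.asarray(freq_hz, dtype=float)
    lo, hi = params.apex_frequency, params.base_frequency
    if np.any(f < lo * (1 - 1e-12)) or np.any(f > hi * (1 + 1e-12)):
        raise RangeError(
            f"frequency outside the Greenwood range [{lo:.2f}, {hi:.2f}] Hz"
        )
    x = np.log10(f / params.A + params.k) / params.a
    d = params.L * (1.0 - x)
    d = np.clip(d, 0.0, params.L)
    return float(d) if np.isscalar(freq_hz) else d
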