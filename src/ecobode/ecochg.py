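"""ECochG measurement model, parsing and insertion-pattern analysis.

A measurement is one labeled series of extracted first-harmonic (F0)
responses — amplitude in dB re 1 µV and phase in degrees relative to the
acoustic stimulus — recorded either at intracochlear contacts (an
electrode *sweep*, possibly covering every second contact) or at
timestamps during insertion (*insertion monitoring*, recorded from the
apical contact).  Waveform-level processing (FFT extraction, DIF/SUM
curves) is out of scope: this module consumes already-extracted values.

Amplitudes at or below 0 dB re 1 µV are conventionally read as "no
cochlear-microphonic response"; a measurement whose sites are all
subthreshold has its phase curve suppressed by the renderer, since phase
is meaningless without a response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

__all__ = [
    "EcochgMeasurement",
    "InsertionPattern",
    "read_measurement",
    "write_measurement",
    "subthreshold_mask",
    "classify_insertion_pattern",
    "unwrap_phase",
]

#: Amplitude floor (dB re 1 uV) below which no CM response is assumed.
RESPONSE_FLOOR_DB = 0.0


@dataclass
class EcochgMeasurement:
    """One labeled ECochG recording series.

    ``site_refs`` are contact indices (sweeps) or timestamps in seconds
    (insertion monitoring); they must be unique within a measurement and
    are kept in file/recording order.
    """

    label: str
    site_refs: list[float]
    amplitudes_db: np.ndarray
    phases_deg: np.ndarray
    stimulus_freq_hz: float = 500.0
    stimulus_level_db: float | None = None

    def __post_init__(self) -> None:
        self.amplitudes_db = np.asarray(self.amplitudes_db, dtype=float)
        self.phases_deg = np.asarray(self.phases_deg, dtype=float)
        n = len(self.site_refs)
        if self.amplitudes_db.shape != (n,) or self.phases_deg.shape != (n,):
            raise InputError("site_refs, amplitudes and phases must have equal length")
        if len(set(self.site_refs)) != n:
            raise InputError(f"duplicate site_ref in measurement {self.label!r}")
        if not np.all(np.isfinite(self.amplitudes_db)):
            raise InputError("non-finite amplitude")
        if not np.all(np.isfinite(self.phases_deg)):
            raise InputError("non-finite phase")

    @property
    def n_sites(self) -> int:
        return len(self.site_refs)

    @property
    def is_monitoring(self) -> bool:
        """Heuristic: non-integer site refs are insertion-monitoring timestamps."""
        return any(float(r) != int(r) for r in self.site_refs)


def read_measurement(path: str | Path, label: str | None = None) -> EcochgMeasurement:
    """Read a measurement CSV.

    Format: optional ``# key: value`` metadata lines (label,
    stimulus_freq_hz, stimulus_level_db) followed by a header and rows
    ``site_ref, amplitude_db_re_1uV, phase_deg``.  Rows are preserved in
    file order; parse failures name the offending row.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
        elif line.strip():
            data_lines.append(line)
    if not data_lines:
        raise ParseError(f"{path}: no data rows")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(data_lines)))
    required = {"site_ref", "amplitude_db_re_1uV", "phase_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    site_refs: list[float] = []
    seen: set[float] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        try:
            ref = float(row.site_ref)
            float(row.amplitude_db_re_1uV)
            float(row.phase_deg)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric value in row {i}: {exc}") from exc
        if ref in seen:
            raise ParseError(f"{path}: duplicate site_ref {row.site_ref} in row {i}")
        seen.add(ref)
        site_refs.append(ref)
    return EcochgMeasurement(
        label=label or meta.get("label", path.stem),
        site_refs=site_refs,
        amplitudes_db=df["amplitude_db_re_1uV"].to_numpy(dtype=float),
        phases_deg=df["phase_deg"].to_numpy(dtype=float),
        stimulus_freq_hz=float(meta.get("stimulus_freq_hz", 500.0)),
        stimulus_level_db=(
            float(meta["stimulus_level_db"]) if "stimulus_level_db" in meta else None
        ),
    )


def write_measurement(m: EcochgMeasurement, path: str | Path) -> None:
    """Write a measurement in the CSV format read by :func:`read_measurement`."""
    lines = [f"# label: {m.label}", f"# stimulus_freq_hz: {m.stimulus_freq_hz:g}"]
    if m.stimulus_level_db is not None:
        lines.append(f"# stimulus_level_db: {m.stimulus_level_db:g}")
    lines.append("site_ref,amplitude_db_re_1uV,phase_deg")
    for ref, amp, ph in zip(m.site_refs, m.amplitudes_db, m.phases_deg):
        ref_str = f"{int(ref)}" if float(ref) == int(ref) else f"{ref:.6g}"
        lines.append(f"{ref_str},{amp:.6g},{ph:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def subthreshold_mask(
    m: EcochgMeasurement, floor_db: float = RESPONSE_FLOOR_DB
) -> tuple[np.ndarray, bool]:
    """Flag sites with no CM response (amplitude <= ``floor_db``).

    Returns ``(mask, all_subthreshold)``; when every site is flagged the
    renderer omits the measurement's phase curve entirely.
    """
    mask = m.amplitudes_db <= floor_db
    return mask, bool(mask.all())


@dataclass(frozen=True)
class InsertionPattern:
    """Harris-style insertion amplitude pattern with its evidence."""

    type: str  # "A" | "C" | "other"
    start_amp: float
    end_amp: float
    max_amp: float
    max_position_fraction: float


def classify_insertion_pattern(
    amplitudes_db,
    similar_tol_db: float = 3.0,
    rise_min_db: float = 6.0,
    end_window: float = 0.2,
) -> InsertionPattern:
    """Classify an insertion-monitoring amplitude course.

    Type A: overall rise from insertion start to completion — the end
    exceeds the start by at least ``rise_min_db`` and the maximum falls
    in the final ``end_window`` fraction of the insertion.  Type C:
    start and end amplitudes similar (within ``similar_tol_db``) with a
    mid-insertion maximum exceeding both ends by at least
    ``rise_min_db``.  Anything else (including the further Harris shapes
    not modeled here) is ``other``.  Invariant under adding a constant
    to all amplitudes.
    """
    amps = np.asarray(amplitudes_db, dtype=float)
    if amps.ndim != 1 or len(amps) < 5:
        raise InputError("pattern classification needs at least 5 ordered amplitudes")
    start, end = float(amps[0]), float(amps[-1])
    imax = int(np.argmax(amps))
    max_amp = float(amps[imax])
    frac = imax / (len(amps) - 1)
    kind = "other"
    if end - start >= rise_min_db and frac >= 1.0 - end_window:
        kind = "A"
    elif (
        abs(end - start) <= similar_tol_db
        and max_amp - start >= rise_min_db
        and max_amp - end >= rise_min_db
        and end_window <= frac <= 1.0 - end_window
    ):
        kind = "C"
    return InsertionPattern(
        type=kind,
        start_amp=start,
        end_amp=end,
        max_amp=max_amp,
        max_position_fraction=frac,
    )


def unwrap_phase(phases_deg, period: float = 360.0) -> np.ndarray:
    """Unwrap a phase sequence so adjacent jumps lie in (-period/2, period/2].

    Display aid only (off by default in the renderer — recorded phases
    are plotted as-is).  The first value is kept; every output differs
    from its input by an exact integer multiple of ``period``.
    """
    p = np.asarray(phases_deg, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise InputError("need at least 2 phases to unwrap")
    out = p.copy()
    for i in range(1, len(p)):
        delta = p[i] - out[i - 1]
        # shift into (-period/2, period/2]
        wrapped = -((-delta + period / 2) % period - period / 2)
        out[i] = out[i - 1] + wrapped
    return out
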