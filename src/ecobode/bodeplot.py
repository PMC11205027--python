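"""Two-panel Bode-style rendering of ECochG data on tonotopic axes.

The figure places every curve on a shared logarithmic frequency axis
(low frequencies left, so insertion angle *decreases* left to right and
the panels read right-to-left in insertion order):

* upper panel — ECochG F0 amplitudes (left y-axis, dB re 1 µV, with a
  horizontal no-response reference line at 0 dB) overlaid with the pre-
  and postoperative audiograms (right y-axis, dB HL, increasing
  downward per audiometric convention);
* lower panel — ECochG phases (° re stimulus) on the same x-axis.

A secondary x-axis on top shows the insertion angle, derived from the
geometry's linear depth↔angle map composed with the Greenwood inverse,
so the two x-axes are mutually consistent by construction.  Measurements
whose amplitudes are all subthreshold carry no interpretable phase and
are omitted from the lower panel.

SVG output is deterministic (fixed hash salt, no embedded date) so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .audiology import Audiogram
from .ecochg import EcochgMeasurement, subthreshold_mask
from .errors import InputError
from .geometry import ElectrodeGeometry, monitoring_axis
from .tonotopy import GreenwoodParams, greenwood_depth, greenwood_frequency

__all__ = [
    "MeasurementStyle",
    "BodePlotSpec",
    "PlacedCurve",
    "place_on_axes",
    "phase_panel_curves",
    "render",
]

#: Octave-spaced tick frequencies for the audiometric x-axis (Hz).
FREQ_TICKS_HZ = (125, 250, 500, 1000, 2000, 4000, 8000, 16000)


@dataclass
class MeasurementStyle:
    """A measurement plus how to draw it.

    ``markers`` (time s, contact index) is required for
    insertion-monitoring measurements so their timestamps can be mapped
    onto the sweep axes.
    """

    measurement: EcochgMeasurement
    color: str = "C0"
    linestyle: str = "-"
    marker: str = "o"
    markers: Sequence[tuple[float, int]] | None = None


@dataclass
class BodePlotSpec:
    """Everything needed to render one figure."""

    geometry: ElectrodeGeometry
    measurements: list[MeasurementStyle] = field(default_factory=list)
    audiogram_pre: Audiogram | None = None
    audiogram_post: Audiogram | None = None
    greenwood: GreenwoodParams = field(default_factory=GreenwoodParams)
    title: str = ""
    reference_line_db: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry.tonotopic_freq_hz is None:
            raise InputError("geometry must carry tonotopic frequencies; run the tonotopy stage")
        if not self.measurements and self.audiogram_pre is None and self.audiogram_post is None:
            raise InputError("nothing to plot: no measurements and no audiograms")


@dataclass
class PlacedCurve:
    """One measurement resolved to x positions on the shared axes."""

    label: str
    freq_hz: np.ndarray
    amplitudes_db: np.ndarray
    phases_deg: np.ndarray
    all_subthreshold: bool
    style: MeasurementStyle


def place_on_axes(spec: BodePlotSpec) -> list[PlacedCurve]:
    """Resolve every measurement's sites to frequencies on the shared axis.

    Sweep sites land at their contact's tonotopic frequency; monitoring
    timestamps go through :func:`~ecobode.geometry.monitoring_axis` to a
    depth, then through Greenwood to a frequency.  Placement of one
    curve never depends on the others.
    """
    geom = spec.geometry
    freqs = geom.tonotopic_freq_hz
    placed: list[PlacedCurve] = []
    for style in spec.measurements:
        m = style.measurement
        if m.is_monitoring:
            if style.markers is None:
                raise InputError(
                    f"measurement {m.label!r} has timestamp sites but no insertion markers"
                )
            depths, _aid = monitoring_axis(geom, style.markers, m.site_refs)
            x = greenwood_frequency(np.clip(depths, 0.0, spec.greenwood.L), spec.greenwood)
        else:
            x = np.empty(m.n_sites)
            for i, ref in enumerate(m.site_refs):
                contact = int(ref)
                if not 1 <= contact <= geom.n_contacts:
                    raise InputError(
                        f"measurement {m.label!r}: site_ref {contact} has no geometry entry "
                        f"(contacts 1..{geom.n_contacts})"
                    )
                x[i] = freqs[contact - 1]
        _, all_sub = subthreshold_mask(m)
        placed.append(
            PlacedCurve(
                label=m.label,
                freq_hz=np.asarray(x, dtype=float),
                amplitudes_db=m.amplitudes_db,
                phases_deg=m.phases_deg,
                all_subthreshold=all_sub,
                style=style,
            )
        )
    return placed


def phase_panel_curves(placed: Sequence[PlacedCurve]) -> list[PlacedCurve]:
    """Curves the lower (phase) panel draws.

    A measurement whose amplitudes are all at or below the response
    floor has no interpretable phase, so its phase curve is suppressed.
    """
    return [c for c in placed if not c.all_subthreshold]


def _angle_of_freq(freq, spec: BodePlotSpec):
    """Insertion angle for an axis frequency via Greenwood + depth↔angle map."""
    m, c = spec.geometry.depth_angle_fit()
    f = np.clip(
        np.asarray(freq, dtype=float),
        spec.greenwood.apex_frequency,
        spec.greenwood.base_frequency,
    )
    return m * greenwood_depth(f, spec.greenwood) + c


def render(
    spec: BodePlotSpec,
    out_path: str | Path,
    log_frequency: bool = True,
) -> Path:
    """Render the two-panel figure and write it to ``out_path``.

    Format follows the file suffix; ``.svg`` (default choice) is
    byte-reproducible.  Returns the written path.
    """
    placed = place_on_axes(spec)
    with plt.rc_context({"svg.hashsalt": "ecobode"}):
        fig, (ax_amp, ax_phase) = plt.subplots(
            2, 1, sharex=True, figsize=(9, 7), height_ratios=[2, 1]
        )
        if log_frequency:
            ax_amp.set_xscale("log")
        lo = spec.greenwood.apex_frequency
        hi = spec.greenwood.base_frequency
        ax_amp.set_xlim(max(lo, 100.0), min(hi, 16000.0))

        # amplitude curves, left y-axis
        for curve in placed:
            ax_amp.plot(
                curve.freq_hz,
                curve.amplitudes_db,
                color=curve.style.color,
                linestyle=curve.style.linestyle,
                marker=curve.style.marker,
                markersize=3,
                label=curve.label,
            )
        ax_amp.axhline(
            spec.reference_line_db, color="0.4", linewidth=0.8, linestyle=":"
        )
        ax_amp.set_ylabel("ECochG amplitude (dB re 1 µV)")

        # audiograms, right y-axis, dB HL increasing downward
        ax_hl = ax_amp.twinx()
        for audiogram, color, label in (
            (spec.audiogram_pre, "0.35", "audiogram (pre)"),
            (spec.audiogram_post, "0.65", "audiogram (post)"),
        ):
            if audiogram is None:
                continue
            fs = sorted(audiogram.thresholds)
            ax_hl.plot(
                fs,
                [audiogram.thresholds[f] for f in fs],
                color=color,
                marker="x",
                linewidth=1.2,
                label=label,
            )
        ax_hl.set_ylim(130, -10)  # audiometric convention: loss grows downward
        ax_hl.set_ylabel("hearing level (dB HL)")

        # secondary x-axis: insertion angle, consistent with the frequency axis
        ax_angle = ax_amp.secondary_xaxis("top")
        tick_freqs = [f for f in FREQ_TICKS_HZ if ax_amp.get_xlim()[0] <= f <= ax_amp.get_xlim()[1]]
        ax_angle.set_xticks(tick_freqs)
        ax_angle.set_xticklabels(
            [f"{a:.0f}" for a in _angle_of_freq(tick_freqs, spec)]
        )
        ax_angle.set_xlabel("insertion angle (°)")

        # phase panel; all-subthreshold measurements carry no phase
        for curve in phase_panel_curves(placed):
            ax_phase.plot(
                curve.freq_hz,
                curve.phases_deg,
                color=curve.style.color,
                linestyle=curve.style.linestyle,
                marker=curve.style.marker,
                markersize=3,
                label=curve.label,
            )
        ax_phase.set_ylabel("phase (° re stimulus)")
        ax_phase.set_xlabel("frequency (Hz)")
        ax_phase.set_xticks([f for f in FREQ_TICKS_HZ if f >= 125])
        ax_phase.set_xticklabels(
            [f"{f/1000:g}k" if f >= 1000 else f"{f}" for f in FREQ_TICKS_HZ if f >= 125]
        )

        if spec.title:
            fig.suptitle(spec.title)
        handles, labels = ax_amp.get_legend_handles_labels()
        h2, l2 = ax_hl.get_legend_handles_labels()
        if handles or h2:
            ax_amp.legend(handles + h2, labels + l2, fontsize=8, loc="lower left")
        fig.tight_layout()
        out_path = Path(out_path)
        fig.savefig(out_path, metadata=_stable_metadata(out_path))
        plt.close(fig)
    return out_path


def _stable_metadata(path: Path) -> dict | None:
    """Strip volatile metadata so identical inputs give identical bytes."""
    suffix = path.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None
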