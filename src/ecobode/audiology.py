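"""Audiograms, pure-tone averages and hearing preservation.

Air-conduction thresholds are taken at the clinical frequency set
0.25–8 kHz.  Where no response was obtained at the audiometer's maximum
output, the threshold is recorded as that maximum plus 5 dB.  Hearing
preservation after implantation follows the HEARRING group's relative
scale,

    HP% = (1 - (PTA_post - PTA_pre) / (PTA_max - PTA_pre)) * 100,

where PTA_max is the maximum measurable pure-tone average; 100% means
complete preservation and 0% total loss of residual hearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

__all__ = [
    "CLINICAL_FREQS_HZ",
    "PTA_FREQS_HZ",
    "Audiogram",
    "HearingPreservation",
    "compute_pta",
    "hearing_preservation",
]

#: Clinical air-conduction test frequencies (Hz).
CLINICAL_FREQS_HZ = (250, 500, 1000, 2000, 3000, 4000, 6000, 8000)

#: Frequencies entering the pure-tone average (0.25-2 kHz).
PTA_FREQS_HZ = (250, 500, 1000, 2000)

#: Added to the audiometer's maximum output when there is no response.
NO_RESPONSE_MARGIN_DB = 5.0


@dataclass
class Audiogram:
    """One ear's air-conduction thresholds at one timepoint.

    ``thresholds`` maps frequency (Hz) to threshold (dB HL).  For
    frequencies flagged in ``no_response``, the stored threshold is
    forced to ``audiometer_max + 5`` (enforced at construction, so the
    invariant cannot drift).
    """

    timepoint: str  # "preoperative" | "postoperative"
    thresholds: dict[int, float]
    no_response: dict[int, bool] = field(default_factory=dict)
    audiometer_max: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in ("preoperative", "postoperative"):
            raise InputError(
                f"timepoint must be pre- or postoperative, got {self.timepoint!r}"
            )
        for f in self.thresholds:
            if f not in CLINICAL_FREQS_HZ:
                raise InputError(
                    f"{f} Hz is not a clinical audiometric frequency {CLINICAL_FREQS_HZ}"
                )
        for f, flag in self.no_response.items():
            if flag:
                if f not in self.audiometer_max:
                    raise InputError(
                        f"no-response at {f} Hz requires the audiometer's max output"
                    )
                self.thresholds[f] = self.audiometer_max[f] + NO_RESPONSE_MARGIN_DB

    @classmethod
    def from_csv(cls, path: str | Path, timepoint: str) -> "Audiogram":
        """Read ``frequency_hz, threshold_db_hl, no_response, audiometer_max_db_hl``."""
        df = pd.read_csv(path)
        required = {"frequency_hz", "threshold_db_hl"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        thresholds, no_resp, amax = {}, {}, {}
        for row in df.itertuples(index=False):
            f = int(row.frequency_hz)
            thresholds[f] = float(row.threshold_db_hl)
            if hasattr(row, "no_response"):
                no_resp[f] = bool(row.no_response)
            if hasattr(row, "audiometer_max_db_hl") and not pd.isna(
                row.audiometer_max_db_hl
            ):
                amax[f] = float(row.audiometer_max_db_hl)
        return cls(
            timepoint=timepoint,
            thresholds=thresholds,
            no_response=no_resp,
            audiometer_max=amax,
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "frequency_hz": f,
                "threshold_db_hl": self.thresholds[f],
                "no_response": int(self.no_response.get(f, False)),
                "audiometer_max_db_hl": self.audiometer_max.get(f, np.nan),
            }
            for f in sorted(self.thresholds)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def pta_max(self, freqs: Iterable[int] = PTA_FREQS_HZ) -> float:
        """Maximum measurable PTA: mean of (audiometer max + 5) over ``freqs``."""
        freqs = list(freqs)
        missing = [f for f in freqs if f not in self.audiometer_max]
        if missing:
            raise InputError(f"audiometer max output missing at {missing} Hz")
        return float(
            np.mean([self.audiometer_max[f] + NO_RESPONSE_MARGIN_DB for f in freqs])
        )


def compute_pta(
    audiogram: Audiogram | Mapping[int, float],
    freqs: Iterable[int] = PTA_FREQS_HZ,
) -> float:
    """Pure-tone average (dB HL): arithmetic mean over ``freqs``.

    No-response frequencies contribute their substituted value
    (audiometer max + 5 dB), already applied by :class:`Audiogram`.
    """
    thresholds = (
        audiogram.thresholds if isinstance(audiogram, Audiogram) else audiogram
    )
    freqs = list(freqs)
    missing = [f for f in freqs if f not in thresholds]
    if missing:
        raise InputError(f"audiogram is missing threshold(s) at {missing} Hz")
    return float(np.mean([thresholds[f] for f in freqs]))


@dataclass(frozen=True)
class HearingPreservation:
    """HEARRING hearing-preservation result."""

    pta_pre: float
    pta_post: float
    pta_max: float
    hp_percent: float
    band: str  # complete | partial | minimal | loss


def _hp_band(hp: float) -> str:
    if hp == 0:
        return "loss"
    if hp < 25:
        return "minimal"
    if hp <= 75:
        return "partial"
    return "complete"


def hearing_preservation(
    pta_pre: float, pta_post: float, pta_max: float
) -> HearingPreservation:
    """HEARRING hearing-preservation percentage and band.

    Clamped to [0, 100]; band cut-offs: complete > 75, partial 25–75
    (boundaries inclusive), minimal (0, 25), loss = 0.
    """
    if pta_max <= pta_pre:
        raise InputError(
            f"PTA max ({pta_max}) must exceed the preoperative PTA ({pta_pre}); "
            "hearing preservation is undefined otherwise"
        )
    hp = (1.0 - (pta_post - pta_pre) / (pta_max - pta_pre)) * 100.0
    hp = float(np.clip(hp, 0.0, 100.0))
    return HearingPreservation(
        pta_pre=pta_pre,
        pta_post=pta_post,
        pta_max=pta_max,
        hp_percent=hp,
        band=_hp_band(hp),
    )
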