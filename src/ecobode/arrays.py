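"""Electrode-array registry and standardized x-axes.

When postoperative imaging is unavailable, per-contact axes are built
from the manufacturer's array geometry instead: contact depths from the
array's average apical insertion depth and inter-contact span, AIDs
scaled linearly down from the array's average angular insertion depth
to 0° at the round window, and tonotopic frequencies via Greenwood.

The registry ships as an editable YAML file.  Numeric entries are
nominal values with a provenance note and MUST be verified against the
manufacturer's datasheet before clinical interpretation; placeholder
entries (``default_apical_depth_mm: null``) require the user to supply
geometry and cannot produce axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import GeometryError, InputError, LookupError_
from .geometry import ElectrodeGeometry, electrode_depths
from .tonotopy import DEFAULT_DUCT_LENGTH_MM, GreenwoodParams, greenwood_frequency

__all__ = ["ElectrodeArraySpec", "load_registry", "lookup_spec", "standard_axes"]


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """Geometry of one commercial electrode array.

    ``array_length_mm`` is the basal-most to apical-most *contact*
    distance (the active span), not the overall lead length.
    ``default_apical_depth_mm`` / ``default_aid_deg`` are population
    averages used only for standardized axes.
    """

    name: str
    manufacturer: str
    n_contacts: int
    array_length_mm: float
    default_apical_depth_mm: float | None = None
    default_aid_deg: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_contacts < 2:
            raise InputError("an electrode array needs at least 2 contacts")
        if self.array_length_mm <= 0:
            raise InputError("array_length_mm must be positive")
        if self.default_apical_depth_mm is not None and self.default_apical_depth_mm <= 0:
            raise InputError("default_apical_depth_mm must be positive")
        if self.default_aid_deg is not None and self.default_aid_deg <= 0:
            raise InputError("default_aid_deg must be positive")


def load_registry(path: str | Path | None = None) -> dict[str, ElectrodeArraySpec]:
    """Load the array registry (bundled YAML by default), keyed by name."""
    if path is None:
        text = (
            resources.files("ecobode").joinpath("data/array_registry.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text)
    registry: dict[str, ElectrodeArraySpec] = {}
    for entry in entries:
        spec = ElectrodeArraySpec(
            name=entry["name"],
            manufacturer=entry.get("manufacturer", ""),
            n_contacts=int(entry["n_contacts"]),
            array_length_mm=float(entry["array_length_mm"]),
            default_apical_depth_mm=(
                None
                if entry.get("default_apical_depth_mm") is None
                else float(entry["default_apical_depth_mm"])
            ),
            default_aid_deg=(
                None
                if entry.get("default_aid_deg") is None
                else float(entry["default_aid_deg"])
            ),
            source=entry.get("source", ""),
        )
        registry[spec.name] = spec
    return registry


def lookup_spec(
    name: str, registry: dict[str, ElectrodeArraySpec] | None = None
) -> ElectrodeArraySpec:
    """Fetch a named array spec, matching case-insensitively."""
    if registry is None:
        registry = load_registry()
    wanted = name.strip().casefold()
    for spec in registry.values():
        if spec.name.casefold() == wanted:
            return spec
    available = ", ".join(sorted(registry))
    raise LookupError_(f"unknown electrode array {name!r}; available: {available}")


def standard_axes(
    spec: ElectrodeArraySpec,
    duct_length_mm: float = DEFAULT_DUCT_LENGTH_MM,
    greenwood: GreenwoodParams | None = None,
) -> ElectrodeGeometry:
    """Standardized per-contact axes from manufacturer geometry alone.

    Depths come from :func:`~ecobode.geometry.electrode_depths` applied
    to the array's average apical depth; AIDs scale the average AID
    linearly with depth down to 0° at the round window (a documented
    convention — the angle origin is the RW); frequencies follow from
    Greenwood at the given duct length.
    """
    if spec.default_apical_depth_mm is None or spec.default_aid_deg is None:
        raise InputError(
            f"array {spec.name!r} is a placeholder entry without average geometry; "
            "supply default_apical_depth_mm and default_aid_deg"
        )
    if spec.default_apical_depth_mm > duct_length_mm:
        raise GeometryError(
            f"average apical depth {spec.default_apical_depth_mm} mm exceeds the "
            f"cochlear duct length {duct_length_mm} mm"
        )
    params = (greenwood or GreenwoodParams()).with_duct_length(duct_length_mm)
    depths = electrode_depths(spec.default_apical_depth_mm, spec)
    apical_depth = depths[0]
    aids = spec.default_aid_deg * depths / apical_depth
    freqs = greenwood_frequency(depths, params)
    return ElectrodeGeometry(
        insertion_depth_mm=depths, insertion_angle_deg=aids, tonotopic_freq_hz=freqs
    )
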