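"""Exception hierarchy.

Every error raised by this package derives from :class:`EcobodeError`, so
callers (and the CLI) can distinguish domain failures from programming
errors.  Subclasses carry a stable ``exit_code`` used by the command line.
"""


class EcobodeError(Exception):
    """Base class for all domain errors."""

    exit_code = 1


class InputError(EcobodeError, ValueError):
    """Invalid user-supplied value (wrong range, missing field, bad shape)."""

    exit_code = 2


class GeometryError(EcobodeError, ValueError):
    """Landmark/trajectory geometry is degenerate or inconsistent."""

    exit_code = 3


class ParseError(EcobodeError, ValueError):
    """A data file could not be parsed; message names the offending row."""

    exit_code = 4


class LookupError_(EcobodeError, KeyError):
    """Unknown registry entry; message lists what is available."""

    exit_code = 5


class RangeError(EcobodeError, ValueError):
    """A value lies outside the domain of a map (e.g. Greenwood)."""

    exit_code = 6
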