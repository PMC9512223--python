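"""Exception hierarchy.

Every error raised by the library derives from :class:`HipForceError`, so
callers (and the CLI) can catch one type and print a single-line diagnostic.
"""


class HipForceError(Exception):
    """Base class for all hipforce errors."""


class RampRangeError(HipForceError, ValueError):
    """Ramp inclination outside the supported 0-70 degree range."""


class UndefinedDirectionError(HipForceError, ValueError):
    """Direction angle requested for an identically-zero force vector."""


class CalibrationError(HipForceError, ValueError):
    """Calibration table is malformed (missing/extra anchors, bad values)."""


class EmptyInputError(HipForceError, ValueError):
    """An operation that requires at least one record received none."""


class PersonDataError(HipForceError, ValueError):
    """Subject data file cannot be parsed (missing columns, empty file)."""
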