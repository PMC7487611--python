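"""Exception hierarchy.

Validation failures (bad specs, malformed cohort files, inconsistent
parameters) raise :class:`ValidationError`; unexpected runtime conditions
(numerical breakdown, failed calibration) raise :class:`RuntimeFailure`.
The CLI maps these to exit codes 2 and 3 respectively.
"""


class PathsemError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PathsemError, ValueError):
    """Input failed a structural or value check."""


class RuntimeFailure(PathsemError, RuntimeError):
    """A computation could not be completed."""
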