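"""Exception hierarchy shared across the package."""


class OligotrajError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OligotrajError):
    """Input file cannot be parsed in the expected format."""


class ConfigurationError(OligotrajError):
    """Run configuration is inconsistent with the system (missing roles,
    missing inhibitor, infeasible geometry, ...)."""


class TopologyError(OligotrajError):
    """Trajectory data does not match the system topology."""


class DataError(OligotrajError):
    """Trajectory data is internally inconsistent (e.g. non-monotonic times)."""


class ValidationError(OligotrajError, ValueError):
    """Invalid argument value."""


class EmptyResultError(OligotrajError):
    """An analysis was asked for on a selection with no qualifying data."""
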