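"""Exception hierarchy shared across the pipeline."""


class PupilVRError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(PupilVRError):
    """Invalid configuration value; names the offending field."""

    exit_code = 2


class DataError(PupilVRError):
    """Invalid or insufficient data."""

    exit_code = 3


class FormatError(DataError):
    """Malformed input file (missing column, bad enum, non-uniform grid)."""
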