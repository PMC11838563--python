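"""Exception types used across the package."""


class AllelertError(Exception):
    """Base class for errors raised by allelert."""


class ConfigError(AllelertError, ValueError):
    """Invalid configuration or simulation parameters."""


class GridMismatchError(AllelertError, ValueError):
    """Two profiles are not on the same bin grid."""


class StateError(AllelertError, ValueError):
    """A profile is in the wrong normalization state for an operation."""


class FastqFormatError(AllelertError, ValueError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index
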