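"""Exception hierarchy shared across the toolkit."""


class StopinError(Exception):
    """Base class for all toolkit errors."""


class FormatError(StopinError):
    """Malformed input file (FASTA/GFF3/TSV)."""


class AlphabetError(StopinError):
    """Sequence contains characters outside A/C/G/T/N."""


class CoordinateError(StopinError):
    """Interval arithmetic violation or out-of-bounds access."""


class LookupError_(StopinError):
    """Unknown gene, isoform, or chromosome identifier."""


class DesignError(StopinError):
    """A design constraint cannot be satisfied."""


class StateError(StopinError):
    """A genome is not in the state an operation requires (e.g. the guide
    site is already destroyed, or the cassette is absent)."""
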