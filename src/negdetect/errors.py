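"""Exception hierarchy shared across the package."""


class NegdetectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NegdetectError):
    """A file or raster does not conform to the expected format."""


class ValidationError(NegdetectError):
    """Parsed content violates a declared invariant."""


class ConsistencyError(NegdetectError):
    """Cross-references between records do not line up (e.g. unknown image id)."""


class CapacityError(NegdetectError):
    """A resource pool is too small for the requested assignment."""


class UndefinedMetricError(NegdetectError):
    """A metric or derived quantity is undefined for the given counts."""


class SpecError(NegdetectError):
    """A generator or profile specification is internally inconsistent."""
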