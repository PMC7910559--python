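class HvkitError(Exception):
    """Base class for user-facing errors."""


class MetadataError(HvkitError):
    """A trace file is missing or corrupts required header metadata."""


class ProtocolError(HvkitError):
    """A voltage protocol is inconsistent with the data or with itself."""


class FitError(HvkitError):
    """A fit could not be performed or did not converge."""


class NoRiseError(FitError):
    """An activation fit was requested on a trace with no detectable rise."""
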