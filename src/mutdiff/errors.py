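"""Exception hierarchy shared across the package."""


class MutDiffError(Exception):
    """Base class for all package-specific errors."""


class DataError(MutDiffError):
    """Malformed, inconsistent, or missing input data."""
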