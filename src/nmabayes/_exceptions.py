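"""Exception hierarchy."""


class NMAError(Exception):
    """Base class for all package errors."""


class DataError(NMAError):
    """Invalid or inconsistent arm-level data."""


class DisconnectedNetworkError(DataError):
    """The evidence network is not connected."""


class ModelError(NMAError):
    """Invalid model specification or parameter state."""


class DiagnosticError(NMAError):
    """A convergence diagnostic could not be computed."""
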