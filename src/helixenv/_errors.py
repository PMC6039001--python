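class HelixenvError(Exception):
    """Base class for all package errors."""


class InputError(HelixenvError):
    """Malformed or inconsistent input data (exit code 2 in the CLI)."""


class SizingError(InputError):
    """A chain is too short to hold the requested helices/flanks."""


class DegenerateDataError(HelixenvError):
    """Statistic undefined for the given data (zero variance, singular
    covariance, group too small)."""
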