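"""Exception hierarchy shared across the package."""


class FrailtykitError(Exception):
    """Base class for all package errors."""


class CatalogError(FrailtykitError):
    """Invalid deficit catalog: schema violation, duplicate ids, failed invariants."""


class ConfigurationError(FrailtykitError):
    """Pipeline or simulation configuration problem detected before computation."""


class DataError(FrailtykitError):
    """Input data violates a documented contract (bad level, negative time, ...)."""


class FitError(FrailtykitError):
    """Model or distribution fit failed (non-convergence, separation, zero events)."""


class EmptySampleError(FrailtykitError):
    """An operation requiring a non-empty (or large-enough) sample received none."""
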