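"""Exception hierarchy.

All package errors derive from :class:`BrushLcaError` so callers can catch
one base class; subclasses distinguish validation, registry, configuration,
coverage and numerical-solve failures.
"""


class BrushLcaError(Exception):
    """Base class for all errors raised by brushlca."""


class DomainError(BrushLcaError, ValueError):
    """A quantity is outside its physical domain (e.g. negative mass)."""


class RegistryError(BrushLcaError, KeyError):
    """Duplicate or unknown impact-category id."""


class ConfigurationError(BrushLcaError, ValueError):
    """Invalid run configuration or scenario override."""


class CoverageError(BrushLcaError, ValueError):
    """A demanded or consumed product flow has no producing process."""


class InventorySolveError(BrushLcaError, ValueError):
    """The technology matrix is singular or ill-conditioned."""


class MissingFactorError(BrushLcaError, KeyError):
    """A nonzero elementary flow has no characterization-factor row."""


class ValidationError(BrushLcaError, ValueError):
    """A file or table violates its schema."""
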