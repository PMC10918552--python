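"""Exception hierarchy shared across the toolkit.

Configuration errors mean the *call* was wrong (bad parameters, missing
fields, inconsistent variant/config); validation errors mean the *data*
was wrong. The CLI maps the former to exit code 2 and the latter to 1.
"""


class FcaError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(FcaError):
    """Invalid parameters, missing fields/flags, variant-config mismatch."""


class ValidationError(FcaError):
    """Input data violates a layer or network invariant."""


class CRSError(ValidationError):
    """Layer uses a geographic (lat/lon) CRS; distance math needs a projected one."""


class IntegrityError(FcaError):
    """Cross-object identity mismatch (e.g. result does not cover every demand id)."""


class DomainError(FcaError):
    """Mathematically undefined request (empty network, k > distinct values, ...)."""
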