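"""Exception hierarchy for healthnet.

Every stage raises a subclass of :class:`HealthNetError`, so callers can
catch a single type at the pipeline boundary while still distinguishing
schema problems from model preconditions.
"""


class HealthNetError(Exception):
    """Base class for all healthnet errors."""


class ConfigurationError(HealthNetError):
    """An unrecognized option value (regime, mode, fixture name, ...)."""


class InvalidSizeError(HealthNetError):
    """A table or network is too small for the requested operation."""


class DegenerateGeometryError(HealthNetError):
    """Two provinces share coordinates, producing a zero distance."""


class SchemaError(HealthNetError):
    """A file violates the documented CSV schema (missing column,
    non-numeric cell, asymmetric distances, duplicated name, ...)."""


class UndefinedCoefficientError(HealthNetError):
    """Both provinces of a pair lack tertiary hospitals (R_i + R_j == 0),
    so the gravity coefficient K_ij is undefined."""


class ZeroEconomicDistanceError(HealthNetError):
    """Two provinces have identical GDP per capita; the gravity model
    divides by (g_i - g_j) and is undefined."""


class InvalidDistanceError(HealthNetError):
    """A non-positive inter-capital distance was supplied for a pair."""


class PipelineError(HealthNetError):
    """A pipeline stage failed; the message names the stage."""
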