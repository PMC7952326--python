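"""Exception hierarchy for eamkit.

All errors raised by the package derive from :class:`EamkitError` so callers
can catch package failures with one clause; specific subclasses distinguish
usage errors from data/topology problems (the CLI maps these to exit codes).
"""


class EamkitError(Exception):
    """Base class for all eamkit errors."""


class MissingDataError(EamkitError):
    """A required block (electric, surface, rfindex, field) is absent."""


class PointNotFoundError(EamkitError, KeyError):
    """A clinical point id was not found in the study."""


class TopologyError(EamkitError):
    """The mesh violates a topological precondition (non-manifold edge,
    non-orientable surface, ...)."""


class IntegrityError(EamkitError):
    """A container or export failed validation (shape mismatch, truncated
    array, inconsistent manifest)."""


class SchemaError(IntegrityError):
    """A container declares a schema version this build does not support."""
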