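"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`LdphaseError`
so callers can catch the package's failures with a single except clause.
"""


class LdphaseError(Exception):
    """Base class for all ldphase errors."""


class ConfigurationError(LdphaseError):
    """An invalid configuration value; the message names the offending field."""


class StructuralError(LdphaseError):
    """Incompatible inputs, e.g. marker maps that do not match."""


class QCError(LdphaseError):
    """A quality-control precondition failed (zero samples, empty intersection)."""


class UndefinedLDError(LdphaseError):
    """LD is undefined for this pair (a monomorphic locus or a fixed margin)."""


class UndefinedSignError(LdphaseError):
    """Composite D has no defined sign (tau = 0: every sample double-heterozygous)."""


class ConvergenceError(LdphaseError):
    """An iterative procedure failed to converge within its iteration budget."""
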