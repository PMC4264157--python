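"""Exception types shared across the package."""


class VTMapError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(VTMapError, ValueError):
    """An argument violates a documented precondition."""


class InvalidSpecError(VTMapError, ValueError):
    """A simulation or mechanism specification is internally inconsistent."""


class NoDeflectionError(VTMapError):
    """No usable deflection was found in the analysis window."""


class InsufficientDataError(VTMapError):
    """Not enough complexes/beats to compute the requested measurement."""


class UndefinedSiteError(VTMapError):
    """A site cannot be classified (e.g. zero pre-occlusion voltage)."""


class UndefinedTestError(VTMapError):
    """A contingency test is undefined for the given table (zero margin)."""
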