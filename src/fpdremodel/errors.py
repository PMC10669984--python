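"""Exception hierarchy for fpdremodel.

All package errors derive from :class:`FPDRemodelError` so callers (and the
CLI) can map failure classes to exit codes without matching on messages.
"""


class FPDRemodelError(Exception):
    """Base class for all fpdremodel errors."""


class MeshFormatError(FPDRemodelError):
    """Unreadable, truncated or otherwise malformed mesh file."""


class InputError(FPDRemodelError):
    """Semantically invalid input (empty mesh, missing file, bad geometry)."""


class ParameterError(FPDRemodelError):
    """A numeric parameter outside its documented range."""


class DetectionError(FPDRemodelError):
    """Connector detection could not produce a usable result."""


class SolverError(FPDRemodelError):
    """The area-matching search failed (unreachable target, broken bracket)."""
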