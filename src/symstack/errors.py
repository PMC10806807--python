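"""Exception hierarchy for symstack.

All data-level failures derive from :class:`SymstackError` so the CLI can
map them to a single exit code distinct from usage errors.
"""


class SymstackError(Exception):
    """Base class for all symstack data/validation errors."""


class OperatorError(SymstackError):
    """Invalid affine operator (not a proper rotation, bad matrix shape...)."""


class DegenerateOperatorError(OperatorError):
    """Operator has neither rotation nor translation; no screw axis exists."""


class CorrespondenceError(SymstackError):
    """Monomers cannot be put into atom correspondence."""


class InsufficientInputError(SymstackError):
    """Fewer monomers/atoms than the operation requires."""


class PoseError(SymstackError):
    """Invalid ligand pose (empty, duplicate coordinates, non-finite...)."""


class PlaneFitError(SymstackError):
    """Ring selection is degenerate (collinear or too few atoms)."""


class ParameterError(SymstackError):
    """Missing or invalid van der Waals parameters."""


class SingularGeometryError(SymstackError):
    """Zero interatomic distance encountered where an energy is required."""


class BackendError(SymstackError):
    """External energy backend failed or returned a malformed reply."""


class MetricError(SymstackError):
    """Enrichment metric is undefined for the given inputs."""


class FileFormatError(SymstackError):
    """Unparseable or structurally invalid input file."""
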