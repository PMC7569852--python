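"""Exception hierarchy for the solver pipeline.

Every public operation raises one of these instead of bare ValueError so
callers (and the CLI) can distinguish bad parameters from bad geometry,
solver breakdown, or corrupted state/files.
"""


class RdfemError(Exception):
    """Base class for all package errors."""


class ParameterError(RdfemError):
    """Invalid argument values or mismatched dimensions."""


class GeometryError(RdfemError):
    """Unusable reactor geometry: empty, disconnected, or degenerate."""


class SolverError(RdfemError):
    """Linear-solver breakdown (e.g. a non-SPD system handed to CG)."""


class StateError(RdfemError):
    """Concentration state violates its invariants (negative, non-finite)."""


class ParseError(RdfemError):
    """Malformed on-disk artifact; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line
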