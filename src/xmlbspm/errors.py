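"""Exception hierarchy for the xmlbspm package."""


class BspmError(Exception):
    """Base class for all xmlbspm errors."""


class BspmParseError(BspmError):
    """Malformed XML input; carries the line/column when known."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class BspmSchemaError(BspmError):
    """Well-formed XML that violates the XML-BSPM structure; names the path."""

    def __init__(self, message: str, path: str = ""):
        self.path = path
        if path:
            message = f"{path}: {message}"
        super().__init__(message)


class BspmValidationError(BspmError):
    """A document failed validation where a valid document was required."""


class EquationSyntaxError(BspmError):
    """Derived-lead equation text could not be parsed; carries the offset."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class EquationEvalError(BspmError):
    """A derived-lead equation could not be evaluated (missing reference,
    division by zero, length mismatch)."""


class CyclicDependencyError(EquationEvalError):
    """Calculated leads form a reference cycle."""

    def __init__(self, cycle: list[int]):
        self.cycle = cycle
        chain = " -> ".join(str(c) for c in cycle)
        super().__init__(f"cyclic calc-lead dependency: {chain}")


class DiagramError(BspmError):
    """No usable torso diagram could be resolved for the document."""


class MapError(BspmError):
    """Invalid map request (time out of range, empty window, degenerate
    electrode geometry)."""
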