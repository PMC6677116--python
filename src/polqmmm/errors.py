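"""Exception hierarchy for polqmmm."""


class PolQmmmError(Exception):
    """Base class for all package errors."""


class ParseError(PolQmmmError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(PolQmmmError):
    """Input violates a structural invariant (asymmetric bonds, traced quadrupole...)."""


class PartitionError(PolQmmmError):
    """Invalid QM/MM partition (PB atom without an MM neighbor, PB-PB bond...)."""


class ParameterLookupError(PolQmmmError, LookupError):
    """A valence/nonbonded parameter tuple could not be resolved."""

    def __init__(self, kind, type_tuple):
        super().__init__(f"no {kind} parameters for type tuple {tuple(type_tuple)}")
        self.kind = kind
        self.type_tuple = tuple(type_tuple)


class DegenerateFrameError(PolQmmmError):
    """Local multipole frame is degenerate (collinear defining atoms)."""


class ConvergenceError(PolQmmmError):
    """Iterative solver failed to converge; carries the residual history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []
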