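"""Exception hierarchy for the serochip pipeline."""


class SerochipError(Exception):
    """Base class for all serochip errors."""


class GPRFormatError(SerochipError):
    """A spot-level results file does not conform to the expected dialect."""


class LayoutValidationError(SerochipError):
    """An array scan violates a structural invariant (e.g. duplicate grid position)."""


class CalibrationError(SerochipError):
    """Autofluorescence calibration cannot proceed (e.g. no mock arrays)."""


class DesignError(SerochipError):
    """A simulation or study design is infeasible or inconsistent."""


class AnalysisError(SerochipError):
    """A statistical operation is undefined for the given input (e.g. zero variance)."""
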