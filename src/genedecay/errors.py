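"""Exception hierarchy shared across the pipeline stages."""


class GenedecayError(Exception):
    """Base class for all package errors."""


class AlignmentError(GenedecayError):
    """Malformed alignment (unequal row lengths, duplicate ids, ...)."""


class FrameError(AlignmentError):
    """Reference sequence does not define a valid reading frame."""


class TreeError(GenedecayError):
    """Unparseable or inconsistent species tree."""


class ManifestError(GenedecayError):
    """Species manifest inconsistent with the alignment or tree."""


class SaturationError(GenedecayError):
    """Observed proportion of differences beyond the correctable range."""


class InsufficientDataError(GenedecayError):
    """Too little usable data survives sanitization."""


class ConvergenceError(GenedecayError):
    """Optimizer failed to converge; carries the best fit found so far."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
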