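"""Exception hierarchy for the nichecast pipeline."""


class NichecastError(Exception):
    """Base class for all nichecast errors."""


class GridFormatError(NichecastError):
    """A raster file violates the ESRI ASCII grid format."""


class TruncationError(GridFormatError):
    """A raster file holds fewer/more values than its header declares."""


class AlignmentError(NichecastError):
    """Two rasters or stacks that must share geometry do not."""


class SpecificationError(NichecastError):
    """A synthetic-data specification is unsatisfiable."""


class EmptyInputError(NichecastError):
    """An input collection is empty after validation/filtering."""


class SelectionError(NichecastError):
    """Model selection has no valid candidate to choose from."""


class ConvergenceError(NichecastError):
    """The solver failed to converge; carries the objective trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
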