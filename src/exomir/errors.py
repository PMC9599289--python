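"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`ExomirError`
so callers can catch one type at pipeline boundaries.
"""


class ExomirError(Exception):
    """Base class for all errors raised by exomir."""


class ValidationError(ExomirError, ValueError):
    """An input violates a documented invariant (shape, range, uniqueness)."""


class UnknownSymbolError(ExomirError, KeyError):
    """A gene or mature-miR symbol is absent from the matrix/annotation table."""


class UnknownStageError(ExomirError, KeyError):
    """A tumor-stage label outside the recognized set {I, II, III, IV}."""


class UnknownSampleError(ExomirError, KeyError):
    """A sample_id absent from a Cq table."""


class ControlFailedError(ExomirError):
    """A normalization control assay is entirely non-detect in a sample."""

    def __init__(self, sample_id: str, assay: str):
        self.sample_id = sample_id
        self.assay = assay
        super().__init__(
            f"control assay {assay!r} has no detected well in sample {sample_id!r}; "
            "sample excluded from quantification"
        )


class EmptyResultError(ExomirError):
    """A pipeline stage produced zero candidates."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} yielded zero candidates")
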