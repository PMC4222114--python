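"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`VitisnpError`
so callers can catch the whole family with one clause.
"""


class VitisnpError(Exception):
    """Base class for all vitisnp errors."""


class AlphabetError(VitisnpError):
    """A sequence symbol falls outside the accepted IUB consensus alphabet."""


class AlignmentError(VitisnpError):
    """Sequences within one marker alignment disagree in length, or records
    are otherwise structurally invalid (e.g. duplicate ids)."""


class MetadataError(VitisnpError):
    """Accession metadata is missing, malformed or inconsistent with the
    sequence data."""


class UndefinedDistanceError(VitisnpError):
    """A pairwise distance is undefined (K2P log argument non-positive or no
    comparable sites) where a defined value is required."""


class SimulationConfigError(VitisnpError):
    """A synthetic-data configuration is internally unsatisfiable."""


class StageError(VitisnpError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
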