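"""Exception hierarchy for the tgxddi package.

Every error raised deliberately by the package derives from
:class:`TgxDdiError`, so callers can catch package failures with a single
``except`` clause while still distinguishing the failure mode.
"""


class TgxDdiError(Exception):
    """Base class for all tgxddi errors."""


class FormatError(TgxDdiError):
    """Malformed input file (CSV or RCC); the message names the offending location."""


class PairingError(TgxDdiError):
    """A treated sample has no concurrent solvent control in its (lab, batch)."""


class DegenerateSampleError(TgxDdiError):
    """A sample cannot be normalized (e.g. all housekeeping counts are zero)."""


class AlignmentError(TgxDdiError):
    """Gene identifiers of a profile do not match the fitted model."""


class DegenerateModelError(TgxDdiError):
    """A fitted model is unusable (e.g. zero pooled standard deviation with s0 = 0)."""


class DegenerateSeparationError(TgxDdiError):
    """The two classes are indistinguishable on the axis a method relies on."""


class InsufficientReplicatesError(TgxDdiError):
    """Fewer than the required number of replicate sample calls."""


class NoCallError(TgxDdiError):
    """No concentration-level call survives exclusion; no chemical call can be made."""


class LabelingError(TgxDdiError):
    """A called compound is missing from the truth-standard labels."""


class NoOverlapError(TgxDdiError):
    """Two laboratories share no commonly tested, conclusively called compound."""


class InsufficientDataError(TgxDdiError):
    """Too few shared genes (or labs) for a correlation analysis."""


class DegenerateAssayError(TgxDdiError):
    """MTT control absorbance does not exceed the blank."""


class UndefinedCoefficientError(TgxDdiError):
    """Chance agreement equals 1; the agreement coefficient is undefined."""
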