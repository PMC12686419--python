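"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`VBDGError`,
so callers (and the CLI) can distinguish data/validation problems from bugs.
"""


class VBDGError(Exception):
    """Base class for all errors raised by vbdg."""


class ValidationError(VBDGError, ValueError):
    """Invalid input values or malformed records."""


class InvalidLabelError(ValidationError):
    """A diagnosis label is empty or blank."""


class InvalidThresholdError(ValidationError):
    """A rank threshold is not a positive integer."""


class DuplicateRecordError(ValidationError):
    """The same (case, condition) pair appears more than once."""


class ReferentialError(ValidationError):
    """A record points at a case id that does not exist in the cohort."""


class IncompleteDesignError(ValidationError):
    """A matched design is missing (case, condition) combinations.

    Paired tests assume complete matched data; missing cells are never
    silently imputed.
    """


class IncompleteMetadataError(ValidationError):
    """Cases lack a label for the requested stratification variable."""


class UnknownKeyError(VBDGError, KeyError):
    """Lookup of an unknown condition id, case id or threshold."""


class NoDiscordanceError(VBDGError):
    """Both discordant cells are zero: the conditional odds ratio is undefined."""


class ReconstructionError(VBDGError):
    """No integer paired table satisfies the requested marginal constraints."""


class SimulationSpecError(ValidationError):
    """A simulation specification is internally inconsistent."""
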