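"""Exception hierarchy for mthia."""


class MthiaError(Exception):
    """Base class for all mthia errors."""


class VariantParseError(MthiaError, ValueError):
    """A variant label could not be parsed; the message names the offending token."""


class RangeError(MthiaError, ValueError):
    """A coordinate falls outside the 16S gene span."""


class CalibrationError(MthiaError, ValueError):
    """Double-numbered fixture rows disagree on the rRNA/mtDNA offset."""


class InputError(MthiaError, ValueError):
    """Malformed or inconsistent user input (sequences, ids, statuses...)."""


class StructureParseError(MthiaError, ValueError):
    """A coordinate file could not be parsed."""


class ResidueLookupError(MthiaError, KeyError):
    """A chain/residue/atom address does not exist in the model."""


class DegenerateSuperpositionError(MthiaError, ValueError):
    """Fewer than three atom pairs remain during the fit-prune cycle."""


class SpecError(MthiaError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
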