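"""Exception hierarchy for the model-preparation pipeline."""


class MemprepError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MemprepError):
    """Input structure file could not be parsed."""


class TooShortError(MemprepError):
    """Chain has too few usable residues."""


class ContractError(MemprepError):
    """An operation was called outside its documented contract."""


class NoTMFoundError(MemprepError):
    """No window passes the transmembrane-segment thresholds.

    The protein may be the water-soluble form of a conditionally
    membrane-bound family (e.g. scramblases, BCL-2-like regulators).
    """


class AllTrimmedError(MemprepError):
    """No confident run exists; terminal trimming would remove everything."""


class InfeasibleWindowError(MemprepError):
    """No tiling fragment window fully contains the TM segment."""


class AlignmentFailedError(MemprepError):
    """Too few alignable residue pairs to superpose."""
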