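"""Exception hierarchy for contract violations across the pipeline."""


class RareSpliceError(Exception):
    """Base class for all package-specific errors."""


class AmbiguousCountError(RareSpliceError):
    """More than one integer allele count is consistent with a rounded frequency."""


class DegenerateTableError(RareSpliceError):
    """A 2x2 allele table has a zero margin, so association statistics are undefined."""


class TooFewStudiesError(RareSpliceError):
    """Meta-analysis requires at least two studies."""


class MissingDirectionError(RareSpliceError):
    """A study lacks the effect direction needed for the weighted-Z combination."""


class NoCompleteSamplesError(RareSpliceError):
    """No sample has complete genotype data at both sites of a pair."""


class EmptyGroupError(RareSpliceError):
    """A required sample group is empty after filtering."""


class NoClassifiedReadsError(RareSpliceError):
    """No read received an unambiguous isoform call."""
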