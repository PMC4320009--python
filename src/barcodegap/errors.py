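"""Exception hierarchy for the barcodegap package.

Every stage raises a subclass of :class:`BarcodeGapError` so callers can
trap pipeline failures without catching unrelated exceptions.
"""


class BarcodeGapError(Exception):
    """Base class for all package errors."""


class ParseError(BarcodeGapError):
    """Malformed input file (bad FASTA, illegal character, empty input)."""


class AlignmentError(BarcodeGapError):
    """Sequences violate alignment invariants (unequal lengths, bad ids)."""


class MetadataError(BarcodeGapError):
    """Specimen table problems: duplicate ids, missing columns, cross-reference gaps."""


class ConfigError(BarcodeGapError):
    """Invalid configuration value (unknown genetic code, bad threshold, unknown preset)."""


class SaturatedDistanceError(BarcodeGapError):
    """K2P log argument non-positive; the pair is too divergent for the model.

    Carries the offending pair so the caller can report which specimens
    saturated.
    """

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class EmptyComparisonError(BarcodeGapError):
    """No sites left to compare after gap/ambiguity exclusion."""


class UndefinedStatisticError(BarcodeGapError):
    """Statistic undefined for the given input (e.g. haplotype diversity at n<2)."""


class LabelingError(BarcodeGapError):
    """A specimen/haplotype label is missing or refers to an unknown group."""


class TrivialTreeError(BarcodeGapError):
    """Fewer than three taxa: no informative unrooted topology exists."""


class AssemblyError(BarcodeGapError):
    """Delimitation inputs disagree (inconsistent id sets between stages)."""


class ScenarioError(BarcodeGapError):
    """Simulation scenario invalid (saturating divergence, bad sample sizes)."""
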