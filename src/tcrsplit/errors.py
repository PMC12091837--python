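"""Exception hierarchy.

Every error raised by the library derives from :class:`TcrSplitError`, so the
CLI can catch one type and exit with a categorized message.
"""


class TcrSplitError(Exception):
    """Base class for all tcrsplit errors."""


class SchemaError(TcrSplitError):
    """Input table is missing a mapped column or is otherwise malformed."""


class EmptyDatasetError(TcrSplitError):
    """An operation received or produced a dataset with no usable records."""


class AlphabetError(TcrSplitError):
    """A sequence contains a residue outside the 20-letter amino-acid alphabet
    (or outside the substitution matrix alphabet)."""


class InfeasibleError(TcrSplitError):
    """A sampling request cannot be satisfied (e.g. more negatives than
    non-positive combinations, or too few peptides to fill split budgets)."""


class InfeasibleBandError(InfeasibleError):
    """The eligible in-band peptide pool was exhausted before a split budget
    was reached."""


class StructureFormatError(TcrSplitError):
    """A PDB file could not be parsed."""


class EmptyStructureError(StructureFormatError):
    """A PDB file contains no usable C-alpha atoms."""


class DegenerateStructureError(TcrSplitError):
    """Too few paired C-alpha atoms survive for a meaningful superposition."""


class NoOverlapError(DegenerateStructureError):
    """The optimal sequence alignment of two peptides has no match columns."""


class UndefinedMetricError(TcrSplitError):
    """An evaluation metric is undefined on the given input (e.g. AUROC with a
    single label class)."""
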