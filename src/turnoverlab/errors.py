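"""Exception hierarchy for turnoverlab.

All package-specific failures derive from :class:`TurnoverLabError` so callers
can catch one base class at pipeline boundaries.
"""


class TurnoverLabError(Exception):
    """Base class for all turnoverlab errors."""


class SequenceError(TurnoverLabError):
    """A sequence contains residues outside the 20-letter canonical alphabet,
    or is otherwise malformed."""


class PanelError(TurnoverLabError):
    """Invalid allele panel: parse failure, duplicate names, unknown locus."""


class GenotypeError(TurnoverLabError):
    """A donor genotype references alleles missing from the panel, or lists
    more than two alleles at one locus."""


class UnquantifiablePeptideError(TurnoverLabError):
    """No mass isotopomer channel shifts enough between the unlabeled and
    fully-labeled envelope to quantify fractional synthesis."""


class FitError(TurnoverLabError):
    """A model fit could not be performed (too few points, degenerate
    degrees of freedom, empty search range)."""


class ConfigError(TurnoverLabError):
    """Invalid simulation or pipeline configuration."""
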