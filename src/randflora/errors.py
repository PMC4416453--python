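"""Exception hierarchy shared across the package."""


class RandfloraError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RandfloraError, ValueError):
    """A numerical argument lies outside the domain of a birth-death formula.

    The message always names the offending field.
    """


class ConditioningError(RandfloraError, RuntimeError):
    """Rejection sampling failed to meet a survival condition within the cap."""


class NoSurvivorsError(RandfloraError, RuntimeError):
    """An ensemble produced no replicate satisfying the requested condition."""


class TreeError(RandfloraError, ValueError):
    """Base class for chronogram validation failures."""


class MissingBranchLengthError(TreeError):
    """A non-root edge lacks a branch length."""


class UnrootedTreeError(TreeError):
    """The input tree is unrooted (or has a basal polytomy)."""


class UltrametricityError(TreeError):
    """Root-to-tip path lengths spread beyond the configured tolerance."""


class LabelError(TreeError, KeyError):
    """Requested tip labels are absent from the chronogram."""


class TableError(RandfloraError, ValueError):
    """A lineage or stage table failed validation; messages are row-addressed."""
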