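"""Exception and warning types shared across the package."""


class NeoError(Exception):
    """Base class for all package errors."""


class HierarchyParseError(NeoError):
    """Malformed hierarchy CSV; the message names the offending line."""


class DuplicateConceptError(NeoError):
    """The same CUI (or the same child-parent row) appears more than once."""


class DanglingParentError(NeoError):
    """A row references a parent CUI that resolves to no concept."""


class CycleError(NeoError):
    """The parent graph contains a cycle; the message lists one cycle."""


class MultiRootError(NeoError):
    """More than one parentless concept where exactly one root is required."""


class MissingConceptError(NeoError, KeyError):
    """A queried concept id is not present in the hierarchy."""


class LexiconConflictError(NeoError):
    """One normalized term maps to two different CUIs."""


class EmptyInputError(NeoError, ValueError):
    """An operation that needs at least one element received none."""


class SkippedPairWarning(UserWarning):
    """A concept pair could not be resolved in both hierarchies and was skipped."""
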