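"""Exception hierarchy for dagalign.

All errors derive from :class:`DagAlignError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
mirror the failure modes of the individual layers (parsing, validation,
path handling, factored-distribution support).
"""


class DagAlignError(Exception):
    """Base class for all dagalign errors."""


class FormatError(DagAlignError):
    """A file failed to parse as the expected format."""


class ConsistencyError(DagAlignError):
    """Inputs that must agree (sequence sets, leaf labels) do not."""


class ContractError(DagAlignError):
    """An operation was called with arguments violating its contract."""


class CodingError(DagAlignError):
    """A column cannot be coded (e.g. consists entirely of gaps)."""


class PathError(DagAlignError):
    """A column-code sequence is not a valid source-to-sink path."""


class SupportError(DagAlignError):
    """A pair-factored probability was requested for an unobserved adjacency."""


class SizeError(DagAlignError):
    """An enumeration would exceed the requested cap."""
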