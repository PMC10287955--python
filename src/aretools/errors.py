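"""Exception hierarchy shared across the toolkit.

Two families matter for the CLI exit-code contract:

* :class:`ValidationError` (and plain ``ValueError``) -- bad usage or bad
  input values; the CLI maps these to exit code 1.
* :class:`DataError` -- structurally valid input that is inconsistent with
  itself or with a previously computed artifact (stale rewrite plan,
  unpaired qPCR wells, ...); the CLI maps these to exit code 2.
"""


class ValidationError(ValueError):
    """Invalid input value or precondition violation (CLI exit 1)."""


class AlphabetConflictError(ValidationError):
    """A record mixes T and U, or contradicts the declared alphabet."""


class InvalidResidueError(ValidationError):
    """A character outside the accepted nucleotide alphabet."""


class FastaParseError(ValidationError):
    """Malformed FASTA input."""


class EmptyInputError(ValidationError):
    """A file or record set that must be nonempty is empty."""


class DataError(Exception):
    """Internally inconsistent data (CLI exit 2)."""


class UnmappedMotifError(DataError):
    """A stabilizing hit whose motif has no replacement-map entry."""


class StalePlanError(DataError):
    """A rewrite plan applied to a sequence that changed since planning."""


class EditMismatchError(DataError):
    """A residue edit whose expected base differs from the sequence."""


class PairingError(DataError):
    """A (time, replicate) well missing either target or reference Ct."""


class NonConvergenceError(DataError):
    """Iterative destabilization failed to reach a fixed point."""


class NonDecayWarning(UserWarning):
    """Fit input whose initial slope is not consistent with decay."""
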