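"""Exception hierarchy.

Error classes map onto CLI exit codes: input/validation problems
(:class:`InputError` subclasses) exit 2, an inference that cannot be
completed (:class:`CannotInferError`) exits 3.
"""


class RestoreError(Exception):
    """Base class for all errors raised by this package."""


class InputError(RestoreError):
    """A problem with user-supplied input (file, table, or configuration)."""


class FormatError(InputError):
    """A file does not have the expected structure (missing columns, bad header)."""


class IntegrityError(InputError):
    """A table violates an invariant: negative/non-finite intensities,
    duplicate (sample_id, cell_id), empty table."""


class ConfigError(InputError):
    """A pair configuration or run configuration is invalid."""


class DegenerateInputError(InputError):
    """Numerically degenerate input (e.g. an all-zero intensity matrix)."""


class TooFewCellsError(InputError):
    """Not enough cells for the requested operation."""


class NoPositiveCellsError(RestoreError):
    """The two-group split found no credible reference-positive population.

    Markers without positive cells in a sample carry no signal to
    normalize; the split is reported as unreliable rather than returning
    arbitrary labels.
    """


class CannotInferError(RestoreError):
    """No mutually exclusive target yielded a usable background estimate."""


class UndefinedStatisticError(RestoreError):
    """A statistic is undefined for the given input (e.g. zero-variance
    composition vector, zero-mean counts)."""
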