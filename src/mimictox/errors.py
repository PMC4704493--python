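"""Exception hierarchy.

Data-quality problems (bad files, violated invariants, degenerate inputs)
derive from :class:`DataError`; configuration mistakes derive from
:class:`ConfigError`.  The CLI maps these to exit codes 1 and 2.
"""


class MimictoxError(Exception):
    """Base class for all package errors."""


class ConfigError(MimictoxError):
    """Invalid configuration or parameters."""


class DataError(MimictoxError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A required column or field is missing from an input table."""


class IntegrityError(DataError):
    """Duplicate keys or internally inconsistent records."""


class ParseError(DataError):
    """A cell could not be parsed; carries row/column location."""


class DegenerateDataError(DataError):
    """An operation is undefined on this input (zero median, constant
    column, empty group, ...)."""


class AnnotationGapError(DataError):
    """Records reference mimics absent from the annotation table."""

    def __init__(self, missing_ids):
        self.missing_ids = sorted(missing_ids)
        super().__init__(
            "mimics missing from annotations: " + ", ".join(self.missing_ids)
        )


class NonConvergenceError(MimictoxError):
    """Affinity propagation reached max_iter without a stable exemplar set.

    Carries the last message matrices so callers can inspect or restart.
    """

    def __init__(self, message, responsibility=None, availability=None,
                 n_iterations=None):
        super().__init__(message)
        self.responsibility = responsibility
        self.availability = availability
        self.n_iterations = n_iterations
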