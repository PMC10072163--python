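"""Exception hierarchy for metseg."""


class MetSegError(Exception):
    """Base class for all metseg errors."""


class FormatError(MetSegError):
    """A file does not conform to the expected dialect (missing columns,
    unparseable fields). Carries the offending line number where known."""


class ValidationError(MetSegError):
    """A value or object violates a contract (out-of-range input, overlapping
    bands, unknown label, band missing from the map, ...)."""


class EmptyDataError(MetSegError):
    """An operation received no usable data (no bins on the arm, empty class,
    empty region list)."""


class QcFailError(MetSegError):
    """Sample failed the sequencing quality-control gate."""

    def __init__(self, failures):
        self.failures = tuple(failures)
        super().__init__("QC failed: " + "; ".join(self.failures))
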