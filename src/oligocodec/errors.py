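"""Exception types shared across the codec layers."""


class OligocodecError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OligocodecError, ValueError):
    """A code-geometry or configuration parameter is out of range."""


class InvalidInputError(OligocodecError, ValueError):
    """An input value violates an operation's precondition."""


class InvalidConfigError(OligocodecError, ValueError):
    """A codec configuration is internally inconsistent."""


class AlphabetError(InvalidInputError):
    """A sequence contains symbols outside the expected alphabet."""


class LengthParityError(InvalidInputError):
    """A nucleotide string has odd length where pairs are required
    (usually the footprint of an uncorrected indel)."""


class DecodeError(OligocodecError):
    """A bit/byte stream could not be decoded (truncation, corruption)."""


class PartialRecoveryError(OligocodecError):
    """Some oligo indices could not be recovered from the pool.

    Carries ``missing`` (sorted index list) and, when available, the full
    decode ``report``.
    """

    def __init__(self, missing, report=None):
        self.missing = sorted(missing)
        self.report = report
        super().__init__(f"unrecovered oligo indices: {self.missing}")


class IntegrityError(OligocodecError):
    """The reassembled payload failed its whole-payload checksum."""

    def __init__(self, message="payload checksum mismatch", report=None):
        self.report = report
        super().__init__(message)
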