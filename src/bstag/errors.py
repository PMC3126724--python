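"""Exception and warning types shared across the toolkit."""


class BstagError(Exception):
    """Base class for all toolkit errors."""


class InvalidSequenceError(BstagError, ValueError):
    """A nucleotide string violates an alphabet or length precondition."""


class ScaffoldViolationError(BstagError, ValueError):
    """A 16-nt tag deviates from the configured scaffold outside position 8.

    Carries the offending 1-based positions in ``positions``.
    """

    def __init__(self, positions, message=None):
        self.positions = tuple(positions)
        super().__init__(
            message or f"scaffold violation at position(s) {list(self.positions)}"
        )


class TmGapError(BstagError, ValueError):
    """Core-primer Tm is too close to the tag Tm for two-stage labeling."""

    def __init__(self, core_tm, tag_tm, min_gap):
        self.core_tm = core_tm
        self.tag_tm = tag_tm
        self.min_gap = min_gap
        super().__init__(
            f"Tm gap {core_tm - tag_tm:.1f} degC below required {min_gap:.1f} degC "
            f"(core {core_tm:.1f}, tag {tag_tm:.1f}); risk of insufficient amplification"
        )


class NoDestabilizerError(BstagError, ValueError):
    """No G/C available in the allowed window upstream of the SNP base."""


class DesignError(BstagError, ValueError):
    """An oligo design request cannot be satisfied on the given template."""


class SwapRejectedError(BstagError, ValueError):
    """A dye swap would violate panel invariants; the panel is unchanged."""


class FastaParseError(BstagError, ValueError):
    """Malformed FASTA input; carries the 1-based line number when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MarkerTableError(BstagError, ValueError):
    """One or more rows of a marker table failed to parse.

    ``row_errors`` maps 1-based data-row numbers to messages; all row
    failures are collected before raising so a sheet is reported once.
    """

    def __init__(self, row_errors):
        self.row_errors = dict(row_errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in sorted(self.row_errors.items()))
        super().__init__(f"marker table errors: {lines}")


class SelfPrimingWarning(UserWarning):
    """A primer core contains the tag's 3'-terminal seed (self-priming risk)."""
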