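"""Exception hierarchy for the breakpoint model and its I/O layers."""


class SvBreaksError(Exception):
    """Base class for all package-specific errors."""


class DuplicateId(SvBreaksError):
    """Two breakends in one set share an id."""

    def __init__(self, bnd_id: str):
        self.id = bnd_id
        super().__init__(f"duplicate breakend id: {bnd_id!r}")


class DanglingPartner(SvBreaksError):
    """A breakend names a partner id that is not in the set."""

    def __init__(self, partner_id: str, bnd_id: str = ""):
        self.id = partner_id
        super().__init__(
            f"breakend {bnd_id!r} names partner {partner_id!r} which is not in the set"
        )


class AsymmetricPartner(SvBreaksError):
    """Partner links are not reciprocal (A.partner = B but B.partner != A)."""

    def __init__(self, bnd_id: str):
        self.id = bnd_id
        super().__init__(f"partner link through {bnd_id!r} is not reciprocal")


class MismatchedInsert(SvBreaksError):
    """The two mates of a pair disagree on the stored inserted sequence."""

    def __init__(self, bnd_id: str):
        self.id = bnd_id
        super().__init__(f"mates of pair containing {bnd_id!r} carry different insert_seq")


class UnknownId(SvBreaksError):
    """Lookup of a breakend id that does not exist."""

    def __init__(self, bnd_id: str):
        self.id = bnd_id
        super().__init__(f"no breakend with id {bnd_id!r}")


class MalformedAlt(SvBreaksError):
    """ALT string is not a parseable breakend allele."""


class MissingEnd(SvBreaksError):
    """Symbolic DEL/DUP/INV record without END or SVLEN."""


class NegativeSpan(SvBreaksError):
    """Symbolic record with END < POS."""


class InvertedInterval(SvBreaksError):
    """Confidence interval with CI[0] > CI[1]."""


class MalformedRow(SvBreaksError):
    """Unparseable BEDPE row; carries the 1-based line number."""

    def __init__(self, line_no: int, reason: str):
        self.line_no = line_no
        super().__init__(f"BEDPE line {line_no}: {reason}")


class UnsupportedCombination(SvBreaksError):
    """Requested rendering cannot express an event type."""


class ContigTooSmall(SvBreaksError):
    """Simulated events cannot be placed without overlap."""
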