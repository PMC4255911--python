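"""Exception hierarchy shared by all kbmine modules."""


class KbmineError(Exception):
    """Base class for all kbmine errors."""


class ParseError(KbmineError, ValueError):
    """Raised when an input document (OBO, TSV, GMT, descriptor text) is malformed."""


class ValidationError(KbmineError, ValueError):
    """Raised when an argument or data structure violates a documented contract."""


class UnknownEntityError(KbmineError, KeyError):
    """Raised when a curie / node id is looked up but not present.

    Subclasses KeyError for idiomatic handling, but str() gives a readable
    message naming the missing identifier.
    """

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return self.args[0] if self.args else ""
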