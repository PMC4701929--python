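"""Exception and warning types shared across the package."""


class SWCError(ValueError):
    """Base class for problems with SWC content."""


class SWCParseError(SWCError):
    """A line of an SWC file could not be parsed (wrong column count,
    non-numeric field, non-positive radius)."""


class SWCStructureError(SWCError):
    """The records do not form a single valid tree (no root, multiple
    roots, dangling parent reference, cycle, duplicate ids)."""


class RemodWarning(UserWarning):
    """Non-fatal diagnostic raised while selecting or editing dendrites,
    e.g. an empty selection or an action skipped because of pre-existing
    structural constraints."""
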