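"""Exception hierarchy for lyticpred.

All package-raised errors derive from :class:`LyticPredError` so callers can
catch one type at the CLI boundary.
"""


class LyticPredError(Exception):
    """Base class for all lyticpred errors."""


class ParseError(LyticPredError):
    """A file could not be parsed (FASTA, PSSM, ss2, manifest)."""


class ValidationError(LyticPredError):
    """Parsed content violates a domain invariant (alphabet, lengths, ids)."""


class DomainError(LyticPredError):
    """An operation was called outside its mathematical domain (e.g. lag >= L)."""


class ConfigError(LyticPredError):
    """Invalid or incomplete configuration (missing table entry, bad mode)."""


class InputError(LyticPredError):
    """A required input (profile, track, class) is missing or degenerate."""
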