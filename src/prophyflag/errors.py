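"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Input data or configuration violates a documented invariant."""


class LexiconError(ValidationError):
    """The antimicrobial lexicon is malformed (alias collision, empty, ...)."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns/keys."""
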