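"""Exception types shared across the pipeline stages."""


class DgscoreError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(DgscoreError):
    """A configuration value violates its documented constraints."""


class InputError(DgscoreError):
    """Malformed or inconsistent input data."""


class DegenerateSplitError(DgscoreError):
    """A median split produced an empty group (all scores identical)."""
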