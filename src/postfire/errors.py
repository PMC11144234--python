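"""Exception hierarchy shared across the package."""


class PostfireError(Exception):
    """Base class for all package errors."""


class InputError(PostfireError):
    """Invalid argument values or incompatible inputs (shapes, ranges)."""


class FormatError(PostfireError):
    """Unreadable or ambiguous file content."""


class ConfigError(PostfireError):
    """Inconsistent configuration (e.g. image size vs. network depth)."""


class TrainingError(PostfireError):
    """Optimization failed (divergence, empty clusters after retries)."""
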