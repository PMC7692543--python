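"""Exception hierarchy for coccogate."""


class CoccogateError(Exception):
    """Base class for all coccogate errors."""


class InvalidParameterError(CoccogateError, ValueError):
    """A parameter value violates an operation's precondition."""


class InvalidInputError(CoccogateError, ValueError):
    """Input data (image, record table) is malformed or unusable."""


class FeatureUndefinedError(CoccogateError):
    """A morphometric feature is undefined for the given mask (e.g. empty)."""


class ConfigError(CoccogateError, ValueError):
    """A gate configuration failed validation; the message names the field."""


class GalleryReadError(CoccogateError, IOError):
    """One or more gallery rows could not be read; message lists the rows."""
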