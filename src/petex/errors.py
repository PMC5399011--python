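"""Package-level exception types."""


class PetexError(Exception):
    """Base class for all errors raised by petex."""


class ValidationError(PetexError):
    """An input violated a documented precondition or invariant."""


class VolumeIOError(PetexError):
    """A volume file could not be read or written."""
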