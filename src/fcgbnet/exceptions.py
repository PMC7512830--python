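"""Exception types raised by fcgbnet."""


class FcgbnetError(ValueError):
    """Base class for all fcgbnet-specific errors."""


class DegenerateSignalError(FcgbnetError):
    """A channel window has zero energy, so its correlation is undefined."""


class DegenerateGraphError(FcgbnetError):
    """All edge weights of a connectivity matrix are zero; entropy is undefined."""


class UnconnectableGraphError(FcgbnetError):
    """No binarization threshold yields a connected graph (some node pair is
    joined only by zero-weight paths)."""
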