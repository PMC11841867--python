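"""Exception hierarchy for panelseg."""


class PanelSegError(Exception):
    """Base class for all panelseg errors."""


class UnsupportedFormatError(PanelSegError):
    """Input image has a channel count / bit depth the framework does not handle."""


class DegenerateCropError(PanelSegError):
    """A border trim or crop would leave no interior pixels."""


class WrongBranchError(PanelSegError):
    """A segmenter was invoked on an image class it does not handle."""


class PackingError(PanelSegError):
    """A synthetic montage specification cannot be laid out on its canvas."""
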