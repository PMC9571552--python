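"""Exception hierarchy for urivar."""


class UrivarError(Exception):
    """Base class for all errors raised by urivar."""


class PanelFormatError(UrivarError):
    """A BED panel file could not be parsed or failed validation."""


class CountsFormatError(UrivarError):
    """A counts table could not be parsed or failed validation."""


class PanelMismatchError(UrivarError):
    """A sample does not cover the panel it is being analysed against."""


class CalibrationError(UrivarError):
    """The anomaly-score cutoff could not be calibrated to the target."""


class VcfFormatError(UrivarError):
    """A VCF file could not be parsed."""
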