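"""Exception hierarchy shared across the package."""


class AphidVisionError(Exception):
    """Base class for all package-specific errors."""


class SpectrumFormatError(AphidVisionError, ValueError):
    """Malformed spectral input (non-monotone grid, missing cells, bad values)."""


class RangeError(AphidVisionError, ValueError):
    """A requested wavelength grid lies outside the spectrum's support."""


class InputError(AphidVisionError, ValueError):
    """Invalid argument values (bad weights, unknown labels, out-of-range peaks)."""


class ComputationError(AphidVisionError, ArithmeticError):
    """A numerical contract was violated (zero denominator, zero variance)."""


class FitError(AphidVisionError, RuntimeError):
    """A model fit failed to converge or the data make it unidentifiable."""


class GenerationError(AphidVisionError, RuntimeError):
    """The synthetic generator produced an invalid trap or leaf."""
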