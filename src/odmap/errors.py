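"""Exception hierarchy shared across the analysis modules."""


class OdmapError(Exception):
    """Base class for all package errors."""


class ParameterError(OdmapError, ValueError):
    """A generator or analysis parameter is out of its valid range."""


class ValidationError(OdmapError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class NoRoiError(OdmapError):
    """No region of interest can be defined (e.g. all-zero response map)."""


class DegeneratePixelError(OdmapError):
    """ODI is undefined at one or more ROI pixels (C + I <= 0)."""

    def __init__(self, pixels):
        self.pixels = list(pixels)
        super().__init__(
            f"C+I <= 0 at {len(self.pixels)} ROI pixel(s): {self.pixels[:10]}"
        )


class NoEpspError(OdmapError):
    """No EPSP onset crossing found after the stimulus."""


class NoRateIncreaseError(OdmapError):
    """Post-stimulus event rate does not exceed the spontaneous rate.

    The spontaneous-correction formula divides by (post_freq - pre_freq);
    cells without a rate increase are excluded rather than estimated.
    """
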