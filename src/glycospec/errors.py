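"""Exception hierarchy for spectral operations."""


class GlycospecError(Exception):
    """Base class for all package errors."""


class SpectrumKindError(GlycospecError, TypeError):
    """An operation received a spectrum of the wrong kind (e.g. absorbance where
    percent transmittance was required)."""


class SpectrumDomainError(GlycospecError, ValueError):
    """A spectrum value is outside the physically meaningful domain of an
    operation (e.g. %T <= 0, negative absorbance for inversion)."""


class GridAlignmentError(GlycospecError, ValueError):
    """Two spectra that must share a wavelength grid do not."""


class WavelengthRangeError(GlycospecError, ValueError):
    """A requested wavelength, band or grid falls outside the span of a
    spectrum (no extrapolation is ever performed)."""


class CompositionError(GlycospecError, ValueError):
    """Invalid solution composition (fractions, concentrations, path length)."""


class DegenerateAnchorError(GlycospecError, ValueError):
    """A reference anchor falls where the relative spectrum is non-positive,
    so no finite scale factor exists."""
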