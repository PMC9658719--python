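"""Reference-anchored ("theoretical") route to the HbA1c absorption spectrum.

The idea: a transmittance measurement of a dissolved chromophore, after
solvent subtraction, yields an absorbance spectrum that is *proportional* to
the molar absorption coefficient spectrum — the proportionality constant
k' = k * c * d bundles the unknown normalization factor k of the recorded
transmittance with concentration and path length, and is never identified.
Because only ratios between wavelengths matter,

    eps(lambda2) = A(lambda2) / A(lambda1) * eps(lambda1),

a single literature anchor (lambda1, eps1) pins the whole relative spectrum
to absolute M^-1 cm^-1 units, and the result is invariant under any positive
rescaling of the input absorbance.

With several anchors the per-anchor scale factors are combined by geometric
mean (scale factors compose multiplicatively); mutually inconsistent anchors
are a data-quality signal and trigger a warning when per-anchor scales
disagree by more than 1%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DegenerateAnchorError
from .spectra import (
    Spectrum,
    SpectrumKind,
    percent_transmittance_to_absorbance,
    restrict_band,
    subtract_absorbance,
)

__all__ = [
    "ReferenceAnchor",
    "component_absorbance",
    "anchor_scale_factor",
    "scale_spectrum_to_anchors",
    "run_theoretical_pipeline",
    "DEFAULT_ANCHORS",
]

logger = logging.getLogger(__name__)

AnchorPolicy = Literal["single", "geometric_mean"]

#: Fractional disagreement between per-anchor scale factors above which a
#: data-quality warning is logged.
ANCHOR_CONSISTENCY_TOL = 0.01


@dataclass(frozen=True)
class ReferenceAnchor:
    """A literature (wavelength, epsilon) pair used to fix absolute units.

    ``epsilon`` is in M^-1 cm^-1 and must be positive; the wavelength must
    lie within the span of the spectrum the anchor is applied to.
    """

    wavelength_nm: float
    epsilon: float

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"anchor epsilon must be positive, got {self.epsilon!r}")
        if not self.wavelength_nm > 0:
            raise ValueError("anchor wavelength must be positive")


#: Literature anchors for HbA1c at 535 and 593 nm (M^-1 cm^-1).
DEFAULT_ANCHORS: tuple[ReferenceAnchor, ReferenceAnchor] = (
    ReferenceAnchor(535.0, 710_888.0),
    ReferenceAnchor(593.0, 322_197.0),
)


def component_absorbance(sol_T: Spectrum, solvent_T: Spectrum) -> Spectrum:
    """Absorbance of the solute: convert both %T spectra and subtract.

    A_component = (2 - log10 %T_solution) - (2 - log10 %T_solvent),
    pointwise on a shared grid. Any common multiplicative normalization of
    the two transmittance spectra cancels in the difference.
    """
    a_sol = percent_transmittance_to_absorbance(sol_T)
    a_solvent = percent_transmittance_to_absorbance(solvent_T)
    return subtract_absorbance(a_sol, a_solvent)


def anchor_scale_factor(rel: Spectrum, anchor: ReferenceAnchor) -> float:
    """Scale (M^-1 cm^-1 per absorbance unit) that maps ``rel`` onto the anchor.

    The relative spectrum is evaluated at the anchor wavelength by the same
    linear interpolation used everywhere else; it must be positive there.
    """
    val = float(rel.value_at(anchor.wavelength_nm)[0])
    if not val > 0:
        raise DegenerateAnchorError(
            f"relative absorbance at the {anchor.wavelength_nm:g} nm anchor is {val:g}; "
            "a positive value is required to form a scale factor"
        )
    return anchor.epsilon / val


def scale_spectrum_to_anchors(
    rel: Spectrum,
    anchors: Sequence[ReferenceAnchor],
    policy: AnchorPolicy = "geometric_mean",
) -> Spectrum:
    """Rescale a relative absorbance spectrum to absolute molar absorption.

    policy="single" uses the first anchor's scale, so the output passes
    through that anchor exactly (up to interpolation off-grid).
    policy="geometric_mean" (default) combines all anchors by geometric mean
    of their scale factors. Negative relative values are scaled through and
    flagged, never clipped — clipping would distort ratios where absorbance
    is small.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("at least one reference anchor is required")
    scales = [anchor_scale_factor(rel, a) for a in anchors]
    if len(scales) > 1:
        spread = max(scales) / min(scales) - 1.0
        if spread > ANCHOR_CONSISTENCY_TOL:
            logger.warning(
                "anchor scale factors disagree by %.2f%% (anchors at %s nm); "
                "the input spectrum and the anchors are mutually inconsistent",
                100 * spread,
                [a.wavelength_nm for a in anchors],
            )
    if policy == "single":
        scale = scales[0]
    elif policy == "geometric_mean":
        scale = math.exp(float(np.mean(np.log(scales))))
    else:
        raise ValueError(f"unknown anchor policy {policy!r}")
    out = rel.with_values(rel.values * scale, SpectrumKind.MOLAR_ABSORPTION)
    if np.any(out.values < 0):
        out.meta["negative_values"] = True
    return out


def run_theoretical_pipeline(
    sol_T: Spectrum,
    solvent_T: Spectrum,
    anchors: Sequence[ReferenceAnchor] = DEFAULT_ANCHORS,
    band: tuple[float, float] = (450.0, 700.0),
    policy: AnchorPolicy = "geometric_mean",
) -> Spectrum:
    """End-to-end anchor-rescaling route over the reporting band.

    component_absorbance -> restrict_band -> scale_spectrum_to_anchors.
    Anchors outside the band still work as long as they lie inside the band
    (they are evaluated on the restricted spectrum).
    """
    rel = restrict_band(component_absorbance(sol_T, solvent_T), *band)
    return scale_spectrum_to_anchors(rel, anchors, policy=policy)
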