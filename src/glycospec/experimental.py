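"""Concentration-series ("experimental") route to the HbA1c absorption spectrum.

Beer-Lambert, A(lambda) = eps_sol(lambda) * c * d, makes the absorbance at
each wavelength a line through the origin in c*d. A dilution series of the
same solution therefore determines eps_sol(lambda) as the slope of a
no-intercept least-squares fit across the series — every concentration
contributes, and the zero intercept the physics demands is enforced rather
than estimated.

The measured solution is a mixture of glycated (HbA1c) and non-glycated
hemoglobin with glycated molar fraction f, so

    eps_sol = f * eps_HbA1c + (1 - f) * eps_non,

which inverts exactly to

    eps_HbA1c = (eps_sol - (1 - f) * eps_non) / f.

The non-glycated reference spectrum eps_non must come from the literature
(a synthetic stand-in ships with the package; see :mod:`glycospec.synthetic`).

The glycated fractions of the two assay-control levels are derived at run
time from their certified concentrations: level 1 has 0.228 mmol/L HbA1c in
9.43 mmol/L total hemoglobin, level 2 has 0.488 mmol/L in 7.44 mmol/L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CompositionError, GridAlignmentError, WavelengthRangeError
from .spectra import Spectrum, SpectrumKind, average_replicates, restrict_band

__all__ = [
    "SolutionComposition",
    "ConcentrationSeries",
    "PeakReport",
    "epsilon_solution_from_series",
    "hba1c_fraction",
    "level_fraction",
    "correct_for_nonglycated",
    "find_q_band_peaks",
    "run_experimental_pipeline",
    "LEVEL_CONCENTRATIONS_MMOL_L",
]

#: Certified (HbA1c, total hemoglobin) concentrations in mmol/L for the two
#: bilevel assay-control solutions; glycated fractions are always computed
#: from these, never stored as decimals.
LEVEL_CONCENTRATIONS_MMOL_L: dict[str, tuple[float, float]] = {
    "level1": (0.228, 9.43),
    "level2": (0.488, 7.44),
}


def hba1c_fraction(c_hba1c: float, c_total: float) -> float:
    """Glycated molar fraction f = c_HbA1c / c_total, with 0 < f <= 1."""
    if not (c_hba1c > 0 and c_total > 0):
        raise CompositionError("concentrations must be positive")
    if c_hba1c > c_total:
        raise CompositionError(
            f"HbA1c concentration {c_hba1c:g} exceeds total hemoglobin {c_total:g}"
        )
    return c_hba1c / c_total


def level_fraction(level: str) -> float:
    """Glycated fraction of a named assay-control level ('level1' or 'level2')."""
    try:
        c_a1c, c_tot = LEVEL_CONCENTRATIONS_MMOL_L[level]
    except KeyError:
        raise KeyError(
            f"unknown level {level!r}; known: {sorted(LEVEL_CONCENTRATIONS_MMOL_L)}"
        ) from None
    return hba1c_fraction(c_a1c, c_tot)


@dataclass(frozen=True)
class SolutionComposition:
    """One measured cuvette: total hemoglobin molarity, glycated fraction, path.

    ``c_total_mol_l`` is the as-supplied hemoglobin molarity (mol/L);
    ``glycated_fraction`` is f in (0, 1]; ``path_cm`` the cuvette length.
    """

    c_total_mol_l: float
    glycated_fraction: float
    path_cm: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.c_total_mol_l > 0:
            raise CompositionError("total concentration must be positive")
        if not 0 < self.glycated_fraction <= 1:
            raise CompositionError(
                f"glycated fraction must be in (0, 1], got {self.glycated_fraction!r}"
            )
        if not self.path_cm > 0:
            raise CompositionError("path length must be positive")


@dataclass(frozen=True)
class ConcentrationSeries:
    """A dilution series: (composition, absorbance spectrum) pairs.

    All members share the glycated fraction, path length and wavelength
    grid, and differ only in total concentration (distinct when > 1 member).
    """

    members: tuple[tuple[SolutionComposition, Spectrum], ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError("a concentration series needs at least one member")
        comps = [m[0] for m in members]
        specs = [m[1] for m in members]
        f0, d0 = comps[0].glycated_fraction, comps[0].path_cm
        if any(c.glycated_fraction != f0 or c.path_cm != d0 for c in comps):
            raise CompositionError("series members must share glycated fraction and path")
        concs = [c.c_total_mol_l for c in comps]
        if len(members) > 1 and len(set(concs)) != len(concs):
            raise CompositionError("series concentrations must be distinct")
        for s in specs:
            if s.kind is not SpectrumKind.ABSORBANCE:
                raise GridAlignmentError("series spectra must be absorbance")
            if not s.same_grid(specs[0]):
                raise GridAlignmentError("series spectra must share one grid")

    @property
    def glycated_fraction(self) -> float:
        return self.members[0][0].glycated_fraction

    @property
    def path_cm(self) -> float:
        return self.members[0][0].path_cm

    @property
    def concentrations_mol_l(self) -> np.ndarray:
        return np.array([c.c_total_mol_l for c, _ in self.members])

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.members[0][1].wavelengths_nm


@dataclass(frozen=True)
class PeakReport:
    """Detected absorption peaks, ordered by wavelength."""

    peaks: tuple[tuple[float, float], ...]  # (wavelength_nm, epsilon)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple((float(w), float(e)) for w, e in self.peaks))
        wl = [w for w, _ in self.peaks]
        if wl != sorted(wl):
            raise ValueError("peaks must be ordered by wavelength")

    @property
    def wavelengths_nm(self) -> tuple[float, ...]:
        return tuple(w for w, _ in self.peaks)

    @property
    def epsilons(self) -> tuple[float, ...]:
        return tuple(e for _, e in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def epsilon_solution_from_series(series: ConcentrationSeries) -> Spectrum:
    """Per-wavelength molar absorption of the whole solution from the series.

    At each wavelength the slope of the no-intercept OLS fit of absorbance
    against c_total * d over all series members is returned:

        eps_sol(lambda) = sum_i x_i A_i(lambda) / sum_i x_i^2,  x_i = c_i d.

    A single-member series degenerates to eps_sol = A / (c d) exactly. The
    per-wavelength root-mean-square residual of the fit is attached as the
    spectrum's dispersion.
    """
    x = series.concentrations_mol_l * series.path_cm  # (n,)
    A = np.vstack([s.values for _, s in series.members])  # (n, m)
    sxx = float(np.dot(x, x))
    slope = (x @ A) / sxx
    resid = A - np.outer(x, slope)
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return Spectrum(
        series.wavelengths_nm.copy(),
        slope,
        SpectrumKind.MOLAR_ABSORPTION,
        dispersion=rms,
        meta={"n_concentrations": len(series.members)},
    )


def epsilon_solution_by_averaging(series: ConcentrationSeries) -> Spectrum:
    """Alternative estimator: mean over members of A/(c d) per wavelength.

    Provided for comparison with the no-intercept OLS; it weights dilute,
    noisier members equally with concentrated ones.
    """
    x = series.concentrations_mol_l * series.path_cm
    A = np.vstack([s.values for _, s in series.members])
    eps = np.mean(A / x[:, None], axis=0)
    return Spectrum(series.wavelengths_nm.copy(), eps, SpectrumKind.MOLAR_ABSORPTION)


def correct_for_nonglycated(eps_sol: Spectrum, eps_non: Spectrum, f: float) -> Spectrum:
    """Remove the non-glycated hemoglobin contribution from a mixture spectrum.

    eps_HbA1c = (eps_sol - (1 - f) * eps_non) / f, the exact inverse of the
    molar-fraction mixture eps_sol = f*eps_HbA1c + (1-f)*eps_non. Negative
    outputs (noise, or an inconsistent eps_non) are preserved and flagged.
    """
    if not 0 < f <= 1:
        raise CompositionError(f"glycated fraction must be in (0, 1], got {f!r}")
    if not eps_sol.same_grid(eps_non):
        raise GridAlignmentError("eps_sol and eps_non must share a wavelength grid")
    vals = (eps_sol.values - (1.0 - f) * eps_non.values) / f
    out = eps_sol.with_values(vals, SpectrumKind.MOLAR_ABSORPTION)
    if np.any(vals < 0):
        out.meta["negative_values"] = True
    return out


def find_q_band_peaks(
    eps: Spectrum,
    window: tuple[float, float] = (500.0, 600.0),
    n_peaks: int = 2,
    min_separation_nm: float = 10.0,
) -> PeakReport:
    """Report the strongest strict local maxima in a wavelength window.

    Hemoglobin's visible Q-bands are two peaks ~34 nm apart between 500 and
    600 nm; the default minimum separation of 10 nm suppresses noise-split
    doublets without merging the true pair. Maxima are strict (plateaus do
    not count); among equal heights the lower wavelength wins. If fewer
    maxima exist than requested, a shorter report is returned with a warning.
    Detection is invariant under positive rescaling of the spectrum.
    """
    lo, hi = window
    if not lo < hi:
        raise WavelengthRangeError("peak window must satisfy lo < hi")
    sub = restrict_band(eps, lo, hi)
    if len(sub) < 3:
        raise WavelengthRangeError("need at least 3 samples inside the peak window")
    lam, v = sub.wavelengths_nm, sub.values
    interior = np.arange(1, len(v) - 1)
    is_max = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    cand = interior[is_max]
    # sort by height desc, then wavelength asc, then greedily enforce separation
    order = sorted(cand, key=lambda i: (-v[i], lam[i]))
    chosen: list[int] = []
    for i in order:
        if all(abs(lam[i] - lam[j]) >= min_separation_nm for j in chosen):
            chosen.append(i)
        if len(chosen) == n_peaks:
            break
    if len(chosen) < n_peaks:
        warnings.warn(
            f"found {len(chosen)} peak(s) in [{lo:g}, {hi:g}] nm, fewer than the "
            f"{n_peaks} requested",
            stacklevel=2,
        )
    chosen.sort(key=lambda i: lam[i])
    return PeakReport(tuple((lam[i], v[i]) for i in chosen))


def run_experimental_pipeline(
    replicate_series: Sequence[ConcentrationSeries],
    eps_non: Spectrum,
    f: float | None = None,
    band: tuple[float, float] = (450.0, 700.0),
    window: tuple[float, float] = (500.0, 600.0),
) -> tuple[Spectrum, PeakReport]:
    """End-to-end experimental route.

    Replicate absorbance spectra are averaged per concentration first, then
    the no-intercept slope gives eps_sol, the glycated-fraction correction
    isolates eps_HbA1c, the result is restricted to the reporting band, and
    the Q-band peaks are located.

    Parameters
    ----------
    replicate_series
        One ConcentrationSeries per replicate run, all structurally identical
        (same concentrations, fraction, path, grid).
    eps_non
        Non-glycated hemoglobin molar absorption reference, on (or covering)
        the same grid.
    f
        Glycated fraction override; defaults to the series' own fraction.
    """
    if not replicate_series:
        raise ValueError("at least one replicate series is required")
    base = replicate_series[0]
    n_conc = len(base.members)
    averaged_members = []
    for j in range(n_conc):
        comps = {rs.members[j][0] for rs in replicate_series}
        if len(comps) != 1:
            raise CompositionError("replicate series must share compositions member-wise")
        mean_spec = average_replicates([rs.members[j][1] for rs in replicate_series])
        averaged_members.append((base.members[j][0], mean_spec))
    series = ConcentrationSeries(tuple(averaged_members))
    eps_sol = epsilon_solution_from_series(series)
    if f is None:
        f = series.glycated_fraction
    if not eps_non.same_grid(eps_sol):
        from .spectra import resample_to_grid

        eps_non = resample_to_grid(eps_non, eps_sol.wavelengths_nm)
    eps_a1c = correct_for_nonglycated(eps_sol, eps_non, f)
    eps_a1c = restrict_band(eps_a1c, *band)
    peaks = find_q_band_peaks(eps_a1c, window=window)
    return eps_a1c, peaks
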