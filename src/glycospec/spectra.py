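"""Wavelength-indexed spectra and Beer-Lambert transmittance/absorbance math.

A :class:`Spectrum` is a strictly increasing wavelength grid (nm) with values
of a declared kind:

``percent_transmittance``
    %T = 100 * I/I0, dimensionless, in (0, 100] (zero excluded so absorbance
    stays finite).
``absorbance``
    A = -log10(T) = 2 - log10(%T), dimensionless.
``molar_absorption``
    epsilon, in M^-1 cm^-1 (per mole of species as supplied, per cm of path).

All binary operations require identical grids; :func:`resample_to_grid`
(linear interpolation, no extrapolation) is the single sanctioned alignment
path, so there is exactly one interpolation convention in the package.

The common (base-10) logarithm is used throughout: the identity
``A = 2 - log10(%T)`` holds only in base 10.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GridAlignmentError,
    SpectrumDomainError,
    SpectrumKindError,
    WavelengthRangeError,
)

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "WavelengthGrid",
    "percent_transmittance_to_absorbance",
    "absorbance_to_percent_transmittance",
    "resample_to_grid",
    "subtract_absorbance",
    "average_replicates",
    "restrict_band",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


class SpectrumKind(str, Enum):
    """What the values of a spectrum measure."""

    PERCENT_TRANSMITTANCE = "percent_transmittance"
    ABSORBANCE = "absorbance"
    MOLAR_ABSORPTION = "molar_absorption"

    @property
    def units(self) -> str:
        return "M^-1 cm^-1" if self is SpectrumKind.MOLAR_ABSORPTION else "dimensionless"


def _as_kind(kind: "SpectrumKind | str") -> SpectrumKind:
    return kind if isinstance(kind, SpectrumKind) else SpectrumKind(kind)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: wavelengths in nm with values of one kind.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing, finite, positive wavelengths (nm). At least 2.
    values
        Same length as ``wavelengths_nm``; finite. For percent transmittance,
        each value must lie in (0, 100].
    kind
        One of :class:`SpectrumKind` (or its string value).
    dispersion
        Optional per-wavelength sample standard deviation (attached by
        :func:`average_replicates`).
    meta
        Free-form flags, e.g. ``{"negative_values": True}`` on difference
        spectra.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    dispersion: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", _as_kind(self.kind))
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D and the same length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.kind is SpectrumKind.PERCENT_TRANSMITTANCE:
            bad = vals <= 0
            # %T > 100 only admissible on flagged inversions of negative absorbance
            if not self.meta.get("transmittance_above_100"):
                bad = bad | (vals > 100)
            if np.any(bad):
                lam = wl[bad][0]
                raise SpectrumDomainError(
                    f"percent transmittance must lie in (0, 100]; offending value "
                    f"{vals[bad][0]!r} at {lam:g} nm"
                )
        if self.dispersion is not None:
            disp = np.asarray(self.dispersion, dtype=float)
            if disp.shape != vals.shape:
                raise ValueError("dispersion must match the value array shape")
            object.__setattr__(self, "dispersion", disp)

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def value_at(self, wavelength_nm: float | Sequence[float]) -> np.ndarray:
        """Linearly interpolated value(s) at the given wavelength(s).

        Raises :class:`WavelengthRangeError` outside the spectrum span —
        extrapolation is never performed.
        """
        lam = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        lo, hi = self.span
        out = (lam < lo) | (lam > hi)
        if np.any(out):
            raise WavelengthRangeError(
                f"wavelength(s) {lam[out].tolist()} outside spectrum span [{lo:g}, {hi:g}] nm"
            )
        return np.interp(lam, self.wavelengths_nm, self.values)

    def with_values(self, values: np.ndarray, kind: "SpectrumKind | str | None" = None,
                    **meta) -> "Spectrum":
        """A copy with new values (and optionally a new kind / extra meta)."""
        return Spectrum(
            self.wavelengths_nm.copy(),
            np.asarray(values, dtype=float),
            _as_kind(kind) if kind is not None else self.kind,
            meta={**self.meta, **meta},
        )

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and bool(np.array_equal(self.wavelengths_nm, other.wavelengths_nm))
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths_nm, "value": self.values})
        if self.dispersion is not None:
            df["sd"] = self.dispersion
        return df


@dataclass(frozen=True)
class WavelengthGrid:
    """A regular wavelength grid [start, stop] nm with the given step.

    The generated grid is strictly increasing and covers the interval
    inclusively within one step.
    """

    start_nm: float
    stop_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm > 0 and self.stop_nm > 0 and self.step_nm > 0):
            raise ValueError("grid bounds and step must be positive")
        if not self.start_nm < self.stop_nm:
            raise ValueError("grid start must be below stop")

    def wavelengths(self) -> np.ndarray:
        n = int(np.floor((self.stop_nm - self.start_nm) / self.step_nm + 1e-9)) + 1
        return self.start_nm + self.step_nm * np.arange(n)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def _require_kind(s: Spectrum, kind: SpectrumKind, op: str) -> None:
    if s.kind is not kind:
        raise SpectrumKindError(f"{op} requires a {kind.value} spectrum, got {s.kind.value}")


def percent_transmittance_to_absorbance(s: Spectrum) -> Spectrum:
    """Convert %T to absorbance: A = 2 - log10(%T), pointwise.

    A = 0 at %T = 100 and grows as transmittance falls; the %T domain
    (0, 100] guarantees A >= 0 and finite.
    """
    _require_kind(s, SpectrumKind.PERCENT_TRANSMITTANCE, "percent_transmittance_to_absorbance")
    return s.with_values(2.0 - np.log10(s.values), SpectrumKind.ABSORBANCE)


def absorbance_to_percent_transmittance(s: Spectrum, allow_negative: bool = False) -> Spectrum:
    """Convert absorbance to %T = 100 * 10**(-A).

    Negative absorbance implies %T > 100 (more light out than in), which is
    unphysical for a direct measurement; it is rejected unless
    ``allow_negative`` is set, in which case the result carries
    ``meta["transmittance_above_100"] = True``. Difference spectra can dip
    slightly negative under noise, which is the intended use of the flag.
    """
    _require_kind(s, SpectrumKind.ABSORBANCE, "absorbance_to_percent_transmittance")
    neg = s.values < 0
    if np.any(neg) and not allow_negative:
        lam = s.wavelengths_nm[neg][0]
        raise SpectrumDomainError(
            f"negative absorbance {s.values[neg][0]:g} at {lam:g} nm implies %T > 100; "
            "pass allow_negative=True to permit it"
        )
    pct = 100.0 * np.power(10.0, -s.values)
    meta = dict(s.meta)
    if np.any(neg):
        meta["transmittance_above_100"] = True
    return Spectrum(s.wavelengths_nm.copy(), pct, SpectrumKind.PERCENT_TRANSMITTANCE, meta=meta)


def resample_to_grid(s: Spectrum, grid: "WavelengthGrid | np.ndarray") -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation).

    Grid points that coincide with input wavelengths reproduce the stored
    values exactly; the kind is preserved.
    """
    lam = grid.wavelengths() if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    lo, hi = s.span
    if lam[0] < lo or lam[-1] > hi:
        raise WavelengthRangeError(
            f"target grid [{lam[0]:g}, {lam[-1]:g}] nm overhangs the spectrum span "
            f"[{lo:g}, {hi:g}] nm by "
            f"{max(lo - lam[0], 0):g} nm (low) / {max(lam[-1] - hi, 0):g} nm (high)"
        )
    vals = np.interp(lam, s.wavelengths_nm, s.values)
    return Spectrum(lam, vals, s.kind, meta=dict(s.meta))


def subtract_absorbance(minuend: Spectrum, subtrahend: Spectrum) -> Spectrum:
    """Pointwise absorbance difference (solution minus solvent/background).

    Both spectra must already share a grid (resample first). Negative values
    in the difference are preserved and flagged via
    ``meta["negative_values"]``.
    """
    _require_kind(minuend, SpectrumKind.ABSORBANCE, "subtract_absorbance")
    _require_kind(subtrahend, SpectrumKind.ABSORBANCE, "subtract_absorbance")
    if not minuend.same_grid(subtrahend):
        raise GridAlignmentError("subtract_absorbance requires identical wavelength grids")
    diff = minuend.values - subtrahend.values
    out = minuend.with_values(diff)
    if np.any(diff < 0):
        out.meta["negative_values"] = True
    return out


def average_replicates(replicates: Iterable[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra with sample sd attached.

    The dispersion is the n-1 sample standard deviation (zero when n = 1).
    Replicates must agree in grid and kind. Absorbance-domain averaging is
    the convention here because Beer-Lambert is linear in absorbance.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("average_replicates needs at least one replicate")
    first = reps[0]
    for r in reps[1:]:
        if r.kind is not first.kind:
            raise GridAlignmentError("replicates must share one spectrum kind")
        if not r.same_grid(first):
            raise GridAlignmentError("replicates must share one wavelength grid")
    stack = np.vstack([r.values for r in reps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros_like(mean)
    # where all replicates agree exactly, the mean is that value and sd is 0
    # (guards the idempotence invariant against summation rounding)
    same = np.ptp(stack, axis=0) == 0
    mean[same] = stack[0, same]
    sd[same] = 0.0
    return Spectrum(first.wavelengths_nm.copy(), mean, first.kind, dispersion=sd,
                    meta={"n_replicates": len(reps)})


def restrict_band(s: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Keep only samples with lo <= lambda <= hi (order preserved)."""
    if not lo_nm < hi_nm:
        raise ValueError("band limits must satisfy lo < hi")
    mask = (s.wavelengths_nm >= lo_nm) & (s.wavelengths_nm <= hi_nm)
    if not np.any(mask):
        raise WavelengthRangeError(
            f"band [{lo_nm:g}, {hi_nm:g}] nm does not intersect the spectrum span "
            f"[{s.span[0]:g}, {s.span[1]:g}] nm"
        )
    disp = s.dispersion[mask] if s.dispersion is not None else None
    return Spectrum(s.wavelengths_nm[mask], s.values[mask], s.kind, dispersion=disp,
                    meta=dict(s.meta))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
# Plain-text interchange: header `wavelength_nm,value`, one sample per row,
# optional leading `# kind: <kind>` comment. Written with 9 significant
# digits so that write -> read round-trips bit-stably at float32-beating
# precision.

def write_spectrum_csv(s: Spectrum, path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind: {s.kind.value}\n")
        fh.write("wavelength_nm,value\n")
        for lam, v in zip(s.wavelengths_nm, s.values):
            fh.write(f"{lam:.9g},{v:.9g}\n")


def read_spectrum_csv(path: "str | Path", kind: "SpectrumKind | str | None" = None) -> Spectrum:
    """Read a spectrum from the package CSV dialect.

    The kind is taken from the ``# kind:`` header comment; an explicit
    ``kind`` argument overrides it and is required if the comment is absent.
    """
    text = Path(path).read_text(encoding="utf-8")
    file_kind: SpectrumKind | None = None
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if payload.lower().startswith("kind:"):
                file_kind = SpectrumKind(payload.split(":", 1)[1].strip())
            continue
        if stripped:
            body_lines.append(line)
    resolved = _as_kind(kind) if kind is not None else file_kind
    if resolved is None:
        raise ValueError(f"{path}: no '# kind:' header and no kind argument given")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if list(df.columns[:2]) != ["wavelength_nm", "value"]:
        raise ValueError(f"{path}: expected header 'wavelength_nm,value', got {list(df.columns)}")
    return Spectrum(df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float), resolved)
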