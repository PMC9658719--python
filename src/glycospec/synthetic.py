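"""Synthetic hemoglobin-like spectra and measurement simulation.

The raw laboratory spectra behind this kind of study are rarely deposited,
so every pipeline stage here is exercised against a forward model that is
fully known and invertible:

* **epsilon spectra** are sums of Gaussian bands plus an optional
  exponentially declining background. Gaussians are a deliberate stand-in —
  they reproduce the two visible Q-band peaks (~545 and ~579 nm) and give
  exact peak locations for recovery tests, but claim nothing about real
  hemoglobin line shapes.
* **measurements** follow Beer-Lambert: A = [f*eps_a1c + (1-f)*eps_non]*c*d
  plus additive Gaussian noise in the absorbance domain, converted to
  percent transmittance, optionally multiplied by a normalization factor k
  (emulating auto-scaled spectrometer output).
* **error-grid point clouds** with exact per-zone counts are produced by
  rejection sampling inside each zone's region.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream; identical seeds give bit-identical
outputs.

Default study conditions mirror the assay-control design the pipeline
targets: five total-hemoglobin concentrations 0.03-0.07 mmol/L, 1 cm
cuvettes, three replicate measurements, glycated fractions derived from the
certified level-1/level-2 concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ega import DEFAULT_POLICY, EGAPoint, ZonePolicy, assign_zone
from .errors import CompositionError
from .experimental import ConcentrationSeries, SolutionComposition, level_fraction
from .spectra import Spectrum, SpectrumKind, WavelengthGrid

__all__ = [
    "GaussianBand",
    "BandModel",
    "NoiseModel",
    "gaussian_band_spectrum",
    "level1_band_model",
    "level2_band_model",
    "nonglycated_band_model",
    "load_nonglycated_reference",
    "SimulatedMeasurements",
    "DEFAULT_CONCENTRATIONS_MOL_L",
    "DEFAULT_GRID",
    "simulate_measurement_series",
    "simulate_level_dataset",
    "simulate_ega_points",
]

#: Total-hemoglobin dilution series (mol/L): 0.03, 0.04, 0.05, 0.06, 0.07 mmol/L.
DEFAULT_CONCENTRATIONS_MOL_L: tuple[float, ...] = (3e-5, 4e-5, 5e-5, 6e-5, 7e-5)

#: Default wavelength grid: full visible-range spectrometer span, 1 nm step.
DEFAULT_GRID = WavelengthGrid(300.0, 1100.0, 1.0)


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (nm), Gaussian sd width (nm), peak amplitude
    (M^-1 cm^-1)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 300.0 <= self.center_nm <= 1100.0:
            raise ValueError("band center must lie within 300-1100 nm")
        if not self.width_nm > 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be nonnegative")


@dataclass(frozen=True)
class BandModel:
    """A sum of Gaussian bands plus an optional declining exponential baseline.

    eps(lambda) = sum_b amp_b * exp(-(lambda - center_b)^2 / (2 width_b^2))
                  + baseline_amplitude * exp(-lambda / baseline_decay_nm)
    """

    bands: tuple[GaussianBand, ...]
    baseline_amplitude: float = 0.0
    baseline_decay_nm: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.baseline_amplitude < 0 or self.baseline_decay_nm <= 0:
            raise ValueError("baseline amplitude must be >= 0 and decay > 0")

    def __call__(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        eps = np.zeros_like(lam)
        for b in self.bands:
            eps += b.amplitude * np.exp(-((lam - b.center_nm) ** 2) / (2 * b.width_nm**2))
        if self.baseline_amplitude:
            eps += self.baseline_amplitude * np.exp(-lam / self.baseline_decay_nm)
        return eps


@dataclass(frozen=True)
class NoiseModel:
    """Additive zero-mean Gaussian noise in the absorbance domain.

    ``sd`` is in absorbance units; ``seed`` drives one reproducible stream.
    """

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")


def gaussian_band_spectrum(model: BandModel, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Evaluate a band model on a grid as a molar absorption spectrum."""
    lam = grid.wavelengths()
    return Spectrum(lam, model(lam), SpectrumKind.MOLAR_ABSORPTION)


# ---------------------------------------------------------------------------
# fixture band models
# ---------------------------------------------------------------------------
# Q-band centers follow the two observed visible peaks (545/579 nm for the
# level-1 control, 544/577 nm for level 2); amplitudes are fixture choices
# placing the corrected peak epsilon in the 4e5-9e5 M^-1 cm^-1 range the
# method reports. The broad declining baseline sketches the red tail of the
# Soret region.

def level1_band_model() -> BandModel:
    """Level-1-like HbA1c model: Q-bands at 545 and 579 nm."""
    return BandModel(
        bands=(
            GaussianBand(545.0, 10.0, 7.9e5),
            GaussianBand(579.0, 11.0, 6.9e5),
        ),
        baseline_amplitude=1.5e6,
        baseline_decay_nm=120.0,
    )


def level2_band_model() -> BandModel:
    """Level-2-like HbA1c model: Q-bands at 544 and 577 nm."""
    return BandModel(
        bands=(
            GaussianBand(544.0, 10.0, 4.9e5),
            GaussianBand(577.0, 11.0, 4.6e5),
        ),
        baseline_amplitude=1.2e6,
        baseline_decay_nm=120.0,
    )


def nonglycated_band_model() -> BandModel:
    """Synthetic non-glycated (oxyhemoglobin-like) reference model.

    Q-bands at 541/576 nm with per-heme-scale amplitudes and a background
    rising toward the blue. A stand-in for a literature reference table,
    not a measured hemoglobin spectrum.
    """
    return BandModel(
        bands=(
            GaussianBand(541.0, 9.0, 1.30e4),
            GaussianBand(576.0, 10.0, 1.25e4),
        ),
        baseline_amplitude=2.8e6,
        baseline_decay_nm=80.0,
    )


def load_nonglycated_reference() -> Spectrum:
    """Load the packaged synthetic non-glycated hemoglobin reference spectrum.

    This CSV fixture is generated from :func:`nonglycated_band_model` on the
    default 300-1100 nm, 1 nm grid. It is synthetic: for scientific use,
    substitute a literature molar absorption table for non-glycated
    hemoglobin in the same CSV dialect.
    """
    from importlib.resources import files

    from .spectra import read_spectrum_csv

    path = files("glycospec").joinpath("data", "nonglycated_hb_synthetic.csv")
    return read_spectrum_csv(str(path))


# ---------------------------------------------------------------------------
# measurement simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedMeasurements:
    """Output of :func:`simulate_measurement_series`, ground truth attached.

    ``replicate_series`` are the (noisy) absorbance dilution series, one per
    replicate — the experimental route's input. ``transmittance_replicates``
    hold the matching percent-transmittance spectra (normalization factor
    applied), and ``solvent_transmittance`` the solvent blank on the same
    grid — the theoretical route's input.
    """

    replicate_series: tuple[ConcentrationSeries, ...]
    transmittance_replicates: tuple[tuple[Spectrum, ...], ...]
    solvent_transmittance: Spectrum
    eps_a1c: Spectrum
    eps_non: Spectrum
    glycated_fraction: float
    concentrations_mol_l: tuple[float, ...]
    path_cm: float
    noise: NoiseModel
    normalization: float


def _to_transmittance(absorbance: np.ndarray, k: float) -> tuple[np.ndarray, dict]:
    pct = 100.0 * np.power(10.0, -absorbance) * k
    meta: dict = {}
    if np.any(pct > 100):
        meta["transmittance_above_100"] = True
    return pct, meta


def simulate_measurement_series(
    eps_a1c: Spectrum,
    eps_non: Spectrum,
    f: float,
    concentrations_mol_l: Sequence[float] = DEFAULT_CONCENTRATIONS_MOL_L,
    path_cm: float = 1.0,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    normalization: float = 1.0,
    solvent_absorbance: Spectrum | None = None,
) -> SimulatedMeasurements:
    """Forward-simulate a dilution-series measurement campaign.

    For each replicate and concentration c,

        A(lambda) = [f*eps_a1c + (1-f)*eps_non](lambda) * c * d + noise,

    is produced as an absorbance spectrum; the matching percent
    transmittance is 100*10^-(A + A_solvent) multiplied by the
    ``normalization`` factor k (applied to the solvent blank too, emulating
    an auto-normalizing spectrometer). ``solvent_absorbance`` defaults to a
    zero spectrum (water is transparent across the visible band).
    """
    if not 0 < f <= 1:
        raise CompositionError(f"glycated fraction must be in (0, 1], got {f!r}")
    concs = tuple(float(c) for c in concentrations_mol_l)
    if len(set(concs)) != len(concs) or any(c <= 0 for c in concs):
        raise CompositionError("concentrations must be positive and distinct")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if not normalization > 0:
        raise ValueError("normalization factor must be positive")
    if not eps_a1c.same_grid(eps_non):
        raise CompositionError("eps_a1c and eps_non must share a grid")
    lam = eps_a1c.wavelengths_nm
    eps_mix = f * eps_a1c.values + (1.0 - f) * eps_non.values
    a_solvent = (
        np.zeros_like(lam) if solvent_absorbance is None else solvent_absorbance.values
    )
    if solvent_absorbance is not None and not solvent_absorbance.same_grid(eps_a1c):
        raise CompositionError("solvent spectrum must share the epsilon grid")

    rng = np.random.default_rng(noise.seed)
    series_out = []
    trans_out = []
    for _ in range(replicates):
        members = []
        trans_members = []
        for c in concs:
            a = eps_mix * c * path_cm
            if noise.sd > 0:
                a = a + rng.normal(0.0, noise.sd, size=lam.size)
            comp = SolutionComposition(c_total_mol_l=c, glycated_fraction=f, path_cm=path_cm)
            members.append((comp, Spectrum(lam.copy(), a, SpectrumKind.ABSORBANCE)))
            pct, meta = _to_transmittance(a + a_solvent, normalization)
            trans_members.append(
                Spectrum(lam.copy(), pct, SpectrumKind.PERCENT_TRANSMITTANCE, meta=meta)
            )
        series_out.append(ConcentrationSeries(tuple(members)))
        trans_out.append(tuple(trans_members))

    pct_w, meta_w = _to_transmittance(a_solvent, normalization)
    solvent_T = Spectrum(lam.copy(), pct_w, SpectrumKind.PERCENT_TRANSMITTANCE, meta=meta_w)
    return SimulatedMeasurements(
        replicate_series=tuple(series_out),
        transmittance_replicates=tuple(trans_out),
        solvent_transmittance=solvent_T,
        eps_a1c=eps_a1c,
        eps_non=eps_non,
        glycated_fraction=f,
        concentrations_mol_l=concs,
        path_cm=path_cm,
        noise=noise,
        normalization=normalization,
    )


def simulate_level_dataset(
    level: str = "level1",
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    grid: WavelengthGrid = DEFAULT_GRID,
    normalization: float = 1.0,
) -> SimulatedMeasurements:
    """Convenience: simulate a full level-1-like or level-2-like campaign."""
    model = level1_band_model() if level == "level1" else level2_band_model()
    eps_a1c = gaussian_band_spectrum(model, grid)
    eps_non = gaussian_band_spectrum(nonglycated_band_model(), grid)
    return simulate_measurement_series(
        eps_a1c,
        eps_non,
        f=level_fraction(level),
        noise=noise,
        replicates=replicates,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# error-grid point clouds
# ---------------------------------------------------------------------------

_REF_RANGE = (4.0, 12.0)
_MAX_REJECT = 10_000


def _normalize_mix(zone_mix: dict, n: int) -> dict[str, int]:
    vals = list(zone_mix.values())
    if any(v < 0 for v in vals):
        raise ValueError("zone mix entries must be nonnegative")
    if all(float(v).is_integer() for v in vals) and sum(vals) == n:
        return {z: int(zone_mix.get(z, 0)) for z in ("A", "B", "C")}
    if sum(vals) > 1 + 1e-9:
        raise ValueError("zone mix must be counts summing to n or proportions summing to <= 1")
    counts = {z: int(round(n * float(zone_mix.get(z, 0)))) for z in ("A", "B", "C")}
    counts["A"] += n - sum(counts.values())  # remainder absorbed by zone A
    return counts


def simulate_ega_points(
    n: int,
    zone_mix: dict,
    policy: ZonePolicy = DEFAULT_POLICY,
    seed: int = 0,
) -> list[EGAPoint]:
    """Generate n reference/estimate pairs with exact per-zone counts.

    ``zone_mix`` maps zone labels to counts (summing to n) or proportions
    (summing to <= 1, remainder assigned to zone A). Points are drawn by
    rejection sampling inside each zone's region under ``policy``; an
    infeasible request (e.g. a zone emptied by a degenerate policy) raises
    after a bounded number of rejections. The point list is shuffled so zone
    order carries no information.
    """
    counts = _normalize_mix(zone_mix, n)
    rng = np.random.default_rng(seed)
    tol = policy.zone_a_rel_tol
    points: list[EGAPoint] = []
    for zone, count in counts.items():
        for _ in range(count):
            for _attempt in range(_MAX_REJECT):
                ref = float(rng.uniform(*_REF_RANGE))
                if zone == "A":
                    est = float(rng.uniform(ref * (1 - tol), ref * (1 + tol)))
                elif zone == "B":
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    est = ref * (1.0 + side * (tol + float(rng.uniform(0.02, 0.5))))
                else:  # C: normal <-> diabetes crossing
                    if rng.random() < 0.5:
                        ref = float(rng.uniform(_REF_RANGE[0], policy.cut_normal - 0.1))
                        est = float(rng.uniform(policy.cut_diabetes + 0.3,
                                                policy.cut_diabetes + 4.0))
                    else:
                        ref = float(rng.uniform(policy.cut_diabetes + 0.3,
                                                policy.cut_diabetes + 4.0))
                        est = float(rng.uniform(_REF_RANGE[0], policy.cut_normal - 0.1))
                if est <= 0:
                    continue
                p = EGAPoint(reference=ref, estimate=est)
                if assign_zone(p, policy) == zone:
                    points.append(p)
                    break
            else:
                raise ValueError(
                    f"could not place a zone-{zone} point under the given policy "
                    f"after {_MAX_REJECT} attempts (infeasible mix?)"
                )
    rng.shuffle(points)  # type: ignore[arg-type]
    return list(points)
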