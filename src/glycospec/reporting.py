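"""Wavelength lookup tables, spectrum comparison, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import Spectrum

__all__ = ["ComparisonTable", "lookup_epsilon", "compare_spectra", "write_manifest"]


def lookup_epsilon(eps: Spectrum, wavelengths_nm: Sequence[float]) -> list[tuple[float, float]]:
    """Molar absorption at the requested wavelengths (linear interpolation).

    Values are reported rounded to one decimal, the conventional printed
    precision for large molar absorption coefficients; out-of-span requests
    raise rather than extrapolate.
    """
    out = []
    for lam in wavelengths_nm:
        val = float(eps.value_at(lam)[0])
        out.append((float(lam), round(val, 1)))
    return out


@dataclass(frozen=True)
class ComparisonTable:
    """Row-per-wavelength comparison of two molar absorption spectra.

    ``rows`` are (wavelength_nm, eps_1, eps_2, relative_difference) with
    relative difference |e1 - e2| / max(e1, e2) — symmetric in the two
    methods. ``max_rel_diff`` / ``mean_rel_diff`` summarize the rows.
    """

    rows: tuple[tuple[float, float, float, float], ...]
    max_rel_diff: float
    mean_rel_diff: float

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "wavelength_nm": w,
                    "epsilon_method_1": e1,
                    "epsilon_method_2": e2,
                    "relative_difference": rd,
                }
                for w, e1, e2, rd in self.rows
            ],
            "max_relative_difference": self.max_rel_diff,
            "mean_relative_difference": self.mean_rel_diff,
        }


def compare_spectra(
    e1: Spectrum, e2: Spectrum, wavelengths_nm: Sequence[float]
) -> ComparisonTable:
    """Tabulate two epsilon spectra at given wavelengths with relative differences."""
    rows = []
    for lam in wavelengths_nm:
        v1 = float(e1.value_at(lam)[0])
        v2 = float(e2.value_at(lam)[0])
        denom = max(abs(v1), abs(v2))
        rd = 0.0 if denom == 0 else abs(v1 - v2) / denom
        rows.append((float(lam), v1, v2, rd))
    rel = [r[3] for r in rows]
    return ComparisonTable(
        rows=tuple(rows),
        max_rel_diff=float(np.max(rel)) if rel else 0.0,
        mean_rel_diff=float(np.mean(rel)) if rel else 0.0,
    )


def _sha256(path: "str | Path") -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: "str | Path",
    config: dict,
    input_paths: Sequence["str | Path"] = (),
    output_paths: Sequence["str | Path"] = (),
    seed: int | None = None,
) -> dict:
    """Write a JSON run manifest: config echo, input checksums, version, seed.

    Two runs with identical config, inputs and seed produce manifests that
    are identical except for the timestamp, so a manifest plus the inputs
    reproduces the run.
    """
    from . import __version__

    manifest = {
        "package": "glycospec",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in input_paths},
        "outputs": [str(p) for p in output_paths],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
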