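"""Three-zone Clarke-style error-grid analysis on the NGSP HbA1c scale.

Estimated HbA1c values are compared against reference values point by point
and binned into three clinical-consequence zones:

* **A** — estimate within a relative tolerance (default 20%, inclusive) of
  the reference: clinically accurate.
* **C** — the estimate crosses the normal/diabetes divide relative to the
  reference (a normal subject estimated diabetic, or vice versa): errors
  that would drive unnecessary treatment or dangerous non-treatment.
* **B** — everything else: benign errors outside tolerance.

NGSP diagnostic categories: normal < 5.7%, prediabetes 5.7-6.4% (both ends
inclusive), diabetes > 6.4%.

Zone percentages are reported as 100*count/total rounded half-up to two
decimals (so 14/19 -> 73.68, 16/19 -> 84.21).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

__all__ = [
    "Category",
    "Zone",
    "EGAPoint",
    "ZonePolicy",
    "EGASummary",
    "classify_ngsp",
    "assign_zone",
    "summarize_zones",
]

Category = Literal["normal", "prediabetes", "diabetes"]
Zone = Literal["A", "B", "C"]

ZONES: tuple[Zone, ...] = ("A", "B", "C")


@dataclass(frozen=True)
class EGAPoint:
    """One reference/estimate pair, both in NGSP % and positive."""

    reference: float
    estimate: float

    def __post_init__(self) -> None:
        import math

        for name in ("reference", "estimate"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} HbA1c must be finite and positive, got {v!r}")


@dataclass(frozen=True)
class ZonePolicy:
    """Zone geometry: relative zone-A tolerance and NGSP category cutpoints.

    ``cut_normal`` and ``cut_diabetes`` are the NGSP % cutpoints: values
    below ``cut_normal`` are normal, values above ``cut_diabetes`` are
    diabetes, the closed interval between is prediabetes.
    """

    zone_a_rel_tol: float = 0.20
    cut_normal: float = 5.7
    cut_diabetes: float = 6.4

    def __post_init__(self) -> None:
        if not 0 < self.zone_a_rel_tol < 1:
            raise ValueError("zone-A tolerance must be in (0, 1)")
        if not self.cut_normal < self.cut_diabetes:
            raise ValueError("category cutpoints must be strictly increasing")


DEFAULT_POLICY = ZonePolicy()


@dataclass(frozen=True)
class EGASummary:
    """Zone counts and half-up two-decimal percentages for a point set."""

    counts: dict[Zone, int]
    percentages: dict[Zone, float]
    n: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("zone counts must sum to the number of points")


def classify_ngsp(value: float, policy: ZonePolicy = DEFAULT_POLICY) -> Category:
    """NGSP diagnostic category of an HbA1c value (%).

    normal below 5.7, prediabetes in the closed band [5.7, 6.4],
    diabetes above 6.4.
    """
    if not value > 0:
        raise ValueError(f"HbA1c must be positive, got {value!r}")
    if value < policy.cut_normal:
        return "normal"
    if value <= policy.cut_diabetes:
        return "prediabetes"
    return "diabetes"


def assign_zone(p: EGAPoint, policy: ZonePolicy = DEFAULT_POLICY) -> Zone:
    """Zone of one point: A on relative agreement, C on a normal/diabetes
    category crossing in either direction, otherwise B.

    The zone-A test |estimate - reference| <= tol * reference is inclusive
    and scale-invariant. Every point lands in exactly one zone.
    """
    if abs(p.estimate - p.reference) <= policy.zone_a_rel_tol * p.reference:
        return "A"
    ref_cat = classify_ngsp(p.reference, policy)
    est_cat = classify_ngsp(p.estimate, policy)
    crossing = {ref_cat, est_cat} == {"normal", "diabetes"}
    return "C" if crossing else "B"


def _pct_half_up(count: int, total: int) -> float:
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_zones(
    points: Sequence[EGAPoint], policy: ZonePolicy = DEFAULT_POLICY
) -> EGASummary:
    """Zone counts and percentages over a non-empty point set."""
    points = list(points)
    if not points:
        raise ValueError("summarize_zones needs at least one point")
    counts: dict[Zone, int] = {z: 0 for z in ZONES}
    for p in points:
        counts[assign_zone(p, policy)] += 1
    n = len(points)
    percentages = {z: _pct_half_up(c, n) for z, c in counts.items()}
    return EGASummary(counts=counts, percentages=percentages, n=n)
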