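"""Closed-form immunoassay statistics.

Three small formulas used to quantify the in vivo consequences of antigen
presentation:

* specific cytotoxicity of an in vivo CTL killing assay,
  ``100 * (1 - (x/y) / (a/b))``, from pulsed/unpulsed target-cell event
  counts in antigen-primed (x, y) and naive (a, b) animals;
* ellipsoid tumor volume ``0.5 * D * d**2`` from caliper diameters;
* delayed-type hypersensitivity response as the thickness delta
  (after - before challenge).
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CytotoxicityCounts",
    "TumorMeasurement",
    "specific_cytotoxicity",
    "tumor_volume",
    "dth_response",
]


@dataclass
class CytotoxicityCounts:
    """Event counts of the in vivo CTL assay.

    x: pulsed (CellTrace-high) events in the antigen-primed animal;
    y: unpulsed (CellTrace-low) events in the primed animal;
    a: pulsed events in the naive animal;
    b: unpulsed events in the naive animal.
    """

    x: int
    y: int
    a: int
    b: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "a", "b"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"event count {name} must be non-negative, got {v}")


@dataclass
class TumorMeasurement:
    """Caliper measurement: D the longer, d the shorter diameter (mm)."""

    D: float
    d: float

    def __post_init__(self) -> None:
        if self.d < 0 or self.D < 0:
            raise ValueError("diameters must be non-negative")
        if self.d > self.D:
            raise ValueError(
                f"shorter diameter d={self.d} exceeds longer D={self.D}; "
                "axis labels are likely swapped"
            )


def specific_cytotoxicity(c: CytotoxicityCounts) -> float:
    """Percent specific cytotoxicity: 100 * (1 - (x/y)/(a/b)).

    The pulsed/unpulsed ratio in the primed animal is normalized by the
    same ratio in the naive animal, so the statistic is invariant to
    proportional rescaling of (x, y) or of (a, b). Negative values (more
    pulsed targets surviving in the primed animal than expected) are
    returned as-is, not clamped.
    """
    for name in ("y", "a", "b"):
        if getattr(c, name) == 0:
            raise ZeroDivisionError(
                f"count {name} is zero: the cytotoxicity ratio is undefined"
            )
    return 100.0 * (1.0 - (c.x / c.y) / (c.a / c.b))


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid tumor volume in mm^3: 0.5 * D * d^2."""
    return 0.5 * m.D * m.d**2


def dth_response(thickness_after: float, thickness_before: float) -> float:
    """DTH response: footpad/ear thickness after minus before challenge (mm).

    Negative deltas are returned as-is; callers may flag them.
    """
    if thickness_after < 0 or thickness_before < 0:
        raise ValueError("thickness measurements must be non-negative")
    return thickness_after - thickness_before
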