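"""USAF-1951 resolution-target arithmetic and field-of-view bookkeeping.

The USAF-1951 chart encodes spatial frequency as
``f = 2**(group + (element - 1)/6)`` line pairs per millimetre; six elements
span one octave. The single-bar line width (half the line-pair period) in
micrometres is ``500 / f``. Displayed values are rounded half-up to two
decimals, the convention used on printed target tables; full precision is
retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


def round_display(value: float, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` decimals (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def usaf_frequency(group: int, element: int) -> float:
    """Spatial frequency in line pairs / mm of a USAF-1951 group/element."""
    if not 1 <= element <= 6:
        raise ValueError(f"element must be in [1, 6], got {element}")
    return 2.0 ** (group + (element - 1) / 6.0)


def usaf_line_width(group: int, element: int) -> float:
    """Single-bar line width in micrometres: 500 / frequency."""
    return 500.0 / usaf_frequency(group, element)


def fov_area(width_cm: float, height_cm: float) -> float:
    """Field-of-view area in cm^2."""
    if width_cm <= 0 or height_cm <= 0:
        raise ValueError("field-of-view dimensions must be positive")
    return width_cm * height_cm


@dataclass(frozen=True)
class ResolutionSpec:
    """A resolved USAF-1951 reading: group/element with derived quantities."""

    group: int
    element: int
    frequency: float  # lp/mm
    line_width: float  # μm

    @classmethod
    def from_group_element(cls, group: int, element: int) -> "ResolutionSpec":
        f = usaf_frequency(group, element)
        return cls(group=group, element=element, frequency=f, line_width=500.0 / f)


@dataclass(frozen=True)
class FieldOfView:
    width_cm: float
    height_cm: float
    area_cm2: float

    @classmethod
    def from_dimensions(cls, width_cm: float, height_cm: float) -> "FieldOfView":
        return cls(width_cm, height_cm, fov_area(width_cm, height_cm))


def resolution_table(groups=range(-2, 8)):
    """Group/element table of frequencies (lp/mm) and line widths (μm).

    Returns a pandas DataFrame with display-rounded columns alongside the
    full-precision values.
    """
    import pandas as pd

    rows = []
    for g in groups:
        for e in range(1, 7):
            spec = ResolutionSpec.from_group_element(g, e)
            rows.append(
                {
                    "group": g,
                    "element": e,
                    "frequency_lp_per_mm": spec.frequency,
                    "line_width_um": spec.line_width,
                    "frequency_display": round_display(spec.frequency),
                    "line_width_display": round_display(spec.line_width),
                }
            )
    return pd.DataFrame(rows)
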