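"""Signed fold-regulation algebra.

Expression changes are linear ratios (treated/reference or tumor/normal);
published panels print them in one of two dialects:

* ``ratio`` — the ratio itself (always positive; 0.91 means mild
  down-regulation).
* ``signed`` — fold-regulation: a ratio r >= 1 is printed as r, a ratio
  r < 1 as -1/r, so that "down 4-fold" reads -4.00 rather than 0.25.

All arithmetic (in particular panel averaging) happens on the linear ratio
scale; the dialect is purely a presentation concern.  Legacy signed tables
occasionally print magnitudes below 1 (for example -0.88): these are read
as ratio = 1/|v| — i.e. the reciprocal convention applied uniformly even
when the resulting ratio exceeds 1.  Such values are accepted on input and
never produced on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

Dialect = Literal["ratio", "signed"]

_ROUNDTRIP_TOL = 1e-12


@dataclass(frozen=True)
class FoldRegulation:
    """A fold change in one of the two printed dialects."""

    value: float
    dialect: Dialect = "signed"

    def __post_init__(self) -> None:
        if self.dialect not in ("ratio", "signed"):
            raise ValueError(f"unknown dialect: {self.dialect!r}")
        if not math.isfinite(self.value):
            raise ValueError("fold-regulation must be finite")
        if self.dialect == "ratio" and self.value <= 0:
            raise ValueError("ratio-dialect fold-regulation must be positive")
        if self.dialect == "signed" and self.value == 0:
            raise ValueError("signed-dialect fold-regulation cannot be 0")

    @property
    def magnitude(self) -> float:
        return abs(self.value)


def from_ratio(r: float, dialect: Dialect = "signed") -> FoldRegulation:
    """Express a linear expression ratio in the requested dialect.

    Parameters
    ----------
    r : positive float
        Linear expression ratio; 1.0 means no change.
    dialect : {"signed", "ratio"}
        ``ratio`` returns r unchanged; ``signed`` returns r for r >= 1
        and -1/r for r < 1.
    """
    if not (r > 0) or not math.isfinite(r):
        raise ValueError(f"expression ratio must be a positive finite number, got {r}")
    if dialect == "ratio":
        return FoldRegulation(r, "ratio")
    if dialect == "signed":
        return FoldRegulation(r if r >= 1 else -1.0 / r, "signed")
    raise ValueError(f"unknown dialect: {dialect!r}")


def to_ratio(v: FoldRegulation | float, dialect: Dialect | None = None) -> float:
    """Recover the linear expression ratio from a dialect value.

    For the signed dialect the reciprocal convention is applied to every
    negative value, including legacy magnitudes below 1: -0.88 maps to
    ratio 1/0.88 (the only reading consistent with published averages).
    Positive signed values are the ratio itself.
    """
    if isinstance(v, FoldRegulation):
        value, dialect = v.value, v.dialect
    else:
        value = float(v)
        if dialect is None:
            raise ValueError("dialect required when passing a bare number")
    if dialect == "ratio":
        if value <= 0:
            raise ValueError("ratio-dialect value must be positive")
        return value
    if dialect == "signed":
        if value == 0:
            raise ValueError("signed-dialect value cannot be 0")
        return value if value > 0 else 1.0 / abs(value)
    raise ValueError(f"unknown dialect: {dialect!r}")


def average_fold_regulation(
    values: Iterable[FoldRegulation | float],
    out_dialect: Dialect = "signed",
    in_dialect: Dialect | None = None,
) -> FoldRegulation:
    """Ratio-scale average of fold regulations (panel "Average FC").

    Converts every input to a linear ratio, takes the arithmetic mean, and
    re-expresses the mean in ``out_dialect``.  For concordant negatives
    this behaves like a harmonic mean of the magnitudes, e.g. averaging
    -5.68 and -4.08 gives -2/(1/5.68 + 1/4.08) = -4.749.
    """
    ratios = [to_ratio(v, in_dialect) for v in values]
    if not ratios:
        raise ValueError("cannot average an empty list of fold regulations")
    return from_ratio(sum(ratios) / len(ratios), out_dialect)


@dataclass(frozen=True)
class ReportRounding:
    """Report rendering precision (published tables print 2 decimals)."""

    decimals: int = 2

    def __post_init__(self) -> None:
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")


def render_report_value(
    v: FoldRegulation | float, rounding: ReportRounding | int = ReportRounding()
) -> str:
    """Render a value with half-up rounding at the report precision."""
    if isinstance(rounding, int):
        rounding = ReportRounding(rounding)
    value = v.value if isinstance(v, FoldRegulation) else float(v)
    quantum = Decimal(1).scaleb(-rounding.decimals)
    return str(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
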