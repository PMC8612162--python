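"""Absolute copy-number quantification from qPCR standard curves.

A standard curve regresses the threshold cycle (CT) on log10 template
copies over a dilution series; the amplification efficiency E follows
from the slope as ``E = 10**(-1/slope) - 1`` (E = 1 is perfect
per-cycle doubling, slope ≈ -3.3219).  Unknowns are quantified by
inverting the curve.  Because cDNA preparations still contain genomic
rDNA, rRNA copy numbers are obtained by subtracting the rDNA copies
measured on the DNA-only template from the combined cDNA+DNA count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ribotraits.errors import InsufficientDataError, InvalidInputError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "efficiency_from_slope",
    "copies_from_ct",
    "ct_from_copies",
    "rrna_by_subtraction",
]

#: slope of an ideal (100% efficient) standard curve, CT per log10 copies
IDEAL_SLOPE = -1.0 / math.log10(2.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR standard curve: CT = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n: int = 0

    @property
    def valid(self) -> bool:
        """True when the slope is negative (more template → earlier CT)."""
        return self.slope < 0

    @property
    def efficiency_in_range(self) -> bool:
        """True when E lies in the conventional 90–120% QC window."""
        return 0.9 <= self.efficiency <= 1.2


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10**(-1/slope) - 1 from a curve slope.

    E is the per-cycle fold increase minus one: 1.0 means perfect
    doubling.  Only negative slopes are meaningful.
    """
    if slope >= 0:
        raise InvalidInputError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    log10_copies: Sequence[float],
    ct: Sequence[float],
    replicates: Sequence[int] | None = None,
    average_replicates: bool = True,
) -> StandardCurve:
    """Fit a standard curve by OLS of CT on log10 copies.

    Parameters
    ----------
    log10_copies, ct : sequences of equal length
        Dilution-series points; at least three distinct dilutions.
    replicates : optional sequence of replicate labels
        When given and ``average_replicates`` is true, replicate CTs at
        the same dilution are averaged before fitting (the default for
        triplicate plates).
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("log10_copies and ct must have equal length")
    if average_replicates:
        # collapse replicate CTs measured at the same dilution
        uniq = np.unique(x)
        y = np.array([y[x == u].mean() for u in uniq])
        x = uniq
        del replicates
    if np.unique(x).size < 3:
        raise InsufficientDataError(
            f"standard curve needs >= 3 dilution points, got {np.unique(x).size}"
        )
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        warnings.warn(
            f"standard curve slope {slope:.3g} is non-negative: invalid curve",
            stacklevel=2,
        )
        eff = math.nan
    else:
        eff = efficiency_from_slope(slope)
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=eff,
        n=int(x.size),
    )


def ct_from_copies(copies: float, curve: StandardCurve) -> float:
    """Predicted CT for a template amount (forward evaluation of the curve)."""
    if copies <= 0:
        raise InvalidInputError(f"copies must be positive, got {copies}")
    return curve.slope * math.log10(copies) + curve.intercept


def copies_from_ct(ct: float, curve: StandardCurve) -> float:
    """Template copies for an observed CT (inverse of the standard curve)."""
    if not curve.valid:
        raise InvalidInputError("cannot invert a curve with non-negative slope")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def rrna_by_subtraction(total_cdna_sample: float, rdna: float) -> tuple[float, bool]:
    """rRNA copies from a combined cDNA+rDNA count and the matched rDNA count.

    Returns ``(rRNA, clamped)``: the difference ``total - rdna``, clamped
    at zero.  ``clamped`` is True when the measured total fell below the
    rDNA count (possible with noisy biological samples), in which case a
    warning is emitted.
    """
    if total_cdna_sample < 0 or rdna < 0:
        raise InvalidInputError(
            f"copy counts must be non-negative, got total={total_cdna_sample}, rdna={rdna}"
        )
    diff = total_cdna_sample - rdna
    if diff < 0:
        warnings.warn(
            f"cDNA+rDNA total {total_cdna_sample} < rDNA {rdna}; clamping rRNA to 0",
            stacklevel=2,
        )
        return 0.0, True
    return float(diff), False
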