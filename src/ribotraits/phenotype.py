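"""Cell geometry and growth-rate computations.

Fixed ciliate cells (and their macronuclei) are treated as prolate
spheroids: volume ``(pi/6) * L * W**2`` with length the major axis and
width both minor axes.  Cell volume is converted to the equivalent
spherical diameter (ESD), the diameter of a sphere of the same volume,
which is the size variable the allometric relations are expressed in.
Maximum growth rate is the steepest log-phase slope of ln(abundance)
against time, in d^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ribotraits.errors import InvalidInputError, UndefinedRateError

__all__ = [
    "Stage",
    "CellRecord",
    "GrowthCurve",
    "spheroid_volume",
    "esd_from_volume",
    "nc_ratio",
    "max_growth_rate",
]


class Stage(str, Enum):
    """Life cycle stage of a ciliate cell."""

    LAG = "lag"
    LOG = "log"
    PLATEAU = "plateau"
    UNSTABLE_CYST = "unstable_cyst"
    RESTING_CYST = "resting_cyst"


def spheroid_volume(length: float, width: float) -> float:
    """Volume of a prolate spheroid cell, in μm³.

    Parameters
    ----------
    length : float
        Major axis in μm.
    width : float
        Minor axis in μm (assumed equal in both minor directions).

    Returns
    -------
    float
        ``(pi/6) * length * width**2``.
    """
    if length <= 0 or width <= 0:
        raise InvalidInputError(
            f"spheroid dimensions must be positive, got length={length}, width={width}"
        )
    return (math.pi / 6.0) * length * width * width


def esd_from_volume(cv: float) -> float:
    """Equivalent spherical diameter (μm) of a cell of volume ``cv`` (μm³).

    Inverse of the sphere volume formula: ``ESD = (6 CV / pi)**(1/3)``.
    """
    if cv <= 0:
        raise InvalidInputError(f"cell volume must be positive, got {cv}")
    return (6.0 * cv / math.pi) ** (1.0 / 3.0)


def nc_ratio(mv: float, cv: float) -> float:
    """Nucleocytoplasmic ratio MV/CV (dimensionless fraction).

    A macronucleus at least as large as its cell is biologically
    implausible; such inputs return the raw ratio with a warning rather
    than an error, so suspect rows can be inspected downstream.
    """
    if mv <= 0 or cv <= 0:
        raise InvalidInputError(f"volumes must be positive, got mv={mv}, cv={cv}")
    if mv >= cv:
        warnings.warn(
            f"macronuclear volume {mv} >= cell volume {cv}: biologically implausible",
            stacklevel=2,
        )
    return mv / cv


@dataclass(frozen=True)
class CellRecord:
    """One cell's phenotypic state.

    ``length``/``width`` are optional fixed-specimen axes in μm; when both
    are given, ``cell_volume`` must equal the spheroid formula applied to
    them.  ``macronuclear_volume`` (μm³) is optional (not measurable for
    every stage).
    """

    species: str
    stage: Stage
    temperature: float
    cell_volume: float
    length: Optional[float] = None
    width: Optional[float] = None
    macronuclear_volume: Optional[float] = None
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise InvalidInputError(
                f"cell volume must be positive, got {self.cell_volume}"
            )
        stage = Stage(self.stage)
        object.__setattr__(self, "stage", stage)
        if self.length is not None and self.width is not None:
            expected = spheroid_volume(self.length, self.width)
            if not math.isclose(expected, self.cell_volume, rel_tol=1e-6):
                raise InvalidInputError(
                    f"cell volume {self.cell_volume} inconsistent with spheroid "
                    f"volume {expected:.6g} from length={self.length}, width={self.width}"
                )
        if (
            self.macronuclear_volume is not None
            and self.macronuclear_volume >= self.cell_volume
        ):
            warnings.warn(
                f"macronuclear volume {self.macronuclear_volume} >= cell volume "
                f"{self.cell_volume} for {self.species}/{stage.value}",
                stacklevel=2,
            )

    @property
    def esd(self) -> float:
        """Equivalent spherical diameter in μm."""
        return esd_from_volume(self.cell_volume)

    @property
    def nc_ratio(self) -> Optional[float]:
        """MV/CV, or None when the macronuclear volume is unknown."""
        if self.macronuclear_volume is None:
            return None
        return self.macronuclear_volume / self.cell_volume


@dataclass(frozen=True)
class GrowthCurve:
    """Cell abundance (cells·ml⁻¹) over time (days) for one culture."""

    times: tuple
    abundances: tuple
    temperature: float
    species: str = ""

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        abundances = tuple(float(a) for a in self.abundances)
        if len(times) != len(abundances):
            raise InvalidInputError("times and abundances must have equal length")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidInputError("times must be strictly increasing")
        if any(a < 0 for a in abundances):
            raise InvalidInputError("abundances must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "abundances", abundances)


def max_growth_rate(curve: GrowthCurve, window: int = 3) -> float:
    """Maximum specific growth rate r (d⁻¹) from a growth curve.

    Slides a window of ``window`` consecutive positive-abundance points
    along the curve, fits ln(abundance) against time by least squares
    within each window, and returns the steepest slope — the log-phase
    rate.  The window shrinks to the number of available points when the
    curve is shorter than ``window`` (two points give the exact two-point
    rate).
    """
    if window < 2:
        raise InvalidInputError(f"window must be >= 2, got {window}")
    pos = [(t, a) for t, a in zip(curve.times, curve.abundances) if a > 0]
    if len(pos) < 2:
        raise UndefinedRateError(
            "growth rate undefined: fewer than two positive abundances"
        )
    t = np.array([p[0] for p in pos])
    ln_a = np.log([p[1] for p in pos])
    w = min(window, len(pos))
    best = -math.inf
    for i in range(len(pos) - w + 1):
        slope = stats.linregress(t[i : i + w], ln_a[i : i + w]).slope
        best = max(best, slope)
    return best


def mean_growth_rates(
    curves: Sequence[GrowthCurve], window: int = 3
) -> tuple[float, float]:
    """Mean ± standard error of max growth rate over replicate curves."""
    rates = np.array([max_growth_rate(c, window=window) for c in curves])
    se = rates.std(ddof=1) / math.sqrt(len(rates)) if len(rates) > 1 else 0.0
    return float(rates.mean()), float(se)
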