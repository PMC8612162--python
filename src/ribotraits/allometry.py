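"""Log-log power-law fits linking ribotype copy numbers to cell size.

Per-cell 18S rDNA and rRNA copy numbers scale with cell volume (CV),
equivalent spherical diameter (ESD) and macronuclear volume (MV) as
power laws, fitted here as ordinary least squares on log10-transformed
values: ``log10(y) = slope * log10(x) + intercept``.

Because CV = (π/6)·ESD³, a fit against CV converts exactly to a fit
against ESD (slope ×3, intercept shifted by slope·log10(π/6)), and a
per-cell relation extends to an idealized population of N identical
cells by adding a +log10(N) term.  The ratio of two fits on the same
predictor is itself a power law with subtracted coefficients — the
route by which the size-expected total rRNA/rDNA ratio used in the
dormancy estimator is derived.

:func:`table1_registry` exposes the reference Colpoda-derived
coefficients as published, without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from ribotraits.errors import ContractError, InvalidInputError

__all__ = [
    "LOG10_PI_OVER_6",
    "PowerLawFit",
    "RibotypeRecord",
    "fit_power_law",
    "cv_fit_to_esd_fit",
    "percell_to_population",
    "ratio_fit",
    "predict",
    "table1_registry",
]

#: log10(π/6): the additive constant of the exact CV ↔ ESD conversion
LOG10_PI_OVER_6 = math.log10(math.pi / 6.0)

#: allowed axis labels for fits
RESPONSE_LABELS = frozenset(
    {
        "rDNA_CNPC",
        "rRNA_CNPC",
        "rDNA_total",
        "rRNA_total",
        "rRNA_total/rDNA_total",
        "rRNA_CNPC/rDNA_CNPC",
        "MV",
        "nc_ratio",
        "otu_count",
    }
)
PREDICTOR_LABELS = frozenset({"CV", "ESD", "MV", "rDNA_CNPC", "rRNA_CNPC"})


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted (or published) log10-log10 linear relation.

    ``log10(response) = slope * log10(predictor) + intercept``, plus an
    optional ``+ log10(N)`` population term.  ``slope`` is the power-law
    exponent on the original scale.
    """

    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: Optional[float] = None
    p_value: Optional[float] = None
    n: Optional[int] = None
    includes_population_term: bool = False

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTOR_LABELS:
            raise ContractError(f"unknown predictor label {self.predictor!r}")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ContractError(f"r_squared out of [0, 1]: {self.r_squared}")

    def equation(self) -> str:
        """Human-readable form of the fitted equation."""
        pop = "log10(N) + " if self.includes_population_term else ""
        return (
            f"log10({self.response}) = {pop}{self.slope:g} log10({self.predictor})"
            f" {'+' if self.intercept >= 0 else '-'} {abs(self.intercept):g}"
        )


@dataclass(frozen=True)
class RibotypeRecord:
    """Per-cell rDNA and rRNA copy numbers tied to a phenotyped cell."""

    cell: object  # phenotype.CellRecord
    rdna_cnpc: float
    rrna_cnpc: float

    def __post_init__(self) -> None:
        if self.rdna_cnpc < 0 or self.rrna_cnpc < 0:
            raise InvalidInputError("copy numbers must be non-negative")

    @property
    def rrna_rdna_ratio(self) -> Optional[float]:
        """rRNA/rDNA copy-number ratio, undefined when rDNA is zero."""
        if self.rdna_cnpc == 0:
            return None
        return self.rrna_cnpc / self.rdna_cnpc


def fit_power_law(
    x: Sequence[float],
    y: Sequence[float],
    predictor: str = "CV",
    response: str = "rDNA_CNPC",
) -> PowerLawFit:
    """OLS fit of log10(y) on log10(x).

    Both variables must be strictly positive; offending row indices are
    reported.  Returns the exponent (slope), intercept, R², the slope
    t-test p-value and n.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise InvalidInputError("x and y must have equal length")
    bad = np.nonzero((xv <= 0) | (yv <= 0) | ~np.isfinite(xv) | ~np.isfinite(yv))[0]
    if bad.size:
        raise InvalidInputError(
            f"non-positive or non-finite values at rows {bad.tolist()}"
        )
    if xv.size < 3:
        raise InvalidInputError(f"power-law fit needs n >= 3, got {xv.size}")
    res = stats.linregress(np.log10(xv), np.log10(yv))
    r2 = float(res.rvalue) ** 2
    pval = float(res.pvalue)
    if math.isnan(r2):  # zero-variance response: flat line, no fit quality
        r2, pval = 0.0, 1.0
    return PowerLawFit(
        response=response,
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=pval,
        n=int(xv.size),
    )


def cv_fit_to_esd_fit(fit: PowerLawFit) -> PowerLawFit:
    """Re-express a CV-based fit on the ESD axis, exactly.

    Substituting CV = (π/6)·ESD³ into ``a·log10(CV) + b`` gives slope
    3a and intercept ``b + a·log10(π/6)``.
    """
    if fit.predictor != "CV":
        raise ContractError(f"fit predictor must be CV, got {fit.predictor!r}")
    return replace(
        fit,
        predictor="ESD",
        slope=3.0 * fit.slope,
        intercept=fit.intercept + fit.slope * LOG10_PI_OVER_6,
    )


def percell_to_population(fit: PowerLawFit) -> PowerLawFit:
    """Extend a per-cell fit to the total of N identical cells.

    Coefficients are unchanged; a ``+log10(N)`` term is recorded and the
    per-cell (``*_CNPC``) response label becomes a ``*_total`` label.
    """
    if fit.includes_population_term:
        raise ContractError("fit already includes the population term")
    response = fit.response.replace("_CNPC", "_total")
    return replace(fit, response=response, includes_population_term=True)


def ratio_fit(numerator: PowerLawFit, denominator: PowerLawFit) -> PowerLawFit:
    """Power law for the ratio of two responses on the same predictor.

    On a log scale a ratio subtracts: the resulting slope and intercept
    are the coefficient differences.  When both inputs are
    population-level, the +log10(N) terms cancel and the ratio is
    per-capita again.
    """
    if numerator.predictor != denominator.predictor:
        raise ContractError(
            f"predictor mismatch: {numerator.predictor!r} vs {denominator.predictor!r}"
        )
    if numerator.includes_population_term != denominator.includes_population_term:
        raise ContractError("both fits must be per-cell or both population-level")
    return PowerLawFit(
        response=f"{numerator.response}/{denominator.response}",
        predictor=numerator.predictor,
        slope=numerator.slope - denominator.slope,
        intercept=numerator.intercept - denominator.intercept,
        includes_population_term=False,
    )


def predict(fit: PowerLawFit, x: float, n: Optional[float] = None) -> float:
    """Forward-evaluate a fit: ``10**(intercept + slope*log10(x))``, ×N.

    ``n`` is required exactly when the fit carries the population term.
    """
    if x <= 0:
        raise InvalidInputError(f"predictor value must be positive, got {x}")
    if fit.includes_population_term:
        if n is None:
            raise ContractError("population-level fit requires the cell abundance n")
        scale = float(n)
    else:
        if n is not None:
            raise ContractError("per-cell fit does not take a population size")
        scale = 1.0
    return scale * 10.0 ** (fit.intercept + fit.slope * math.log10(x))


def table1_registry() -> Dict[int, PowerLawFit]:
    """Published Colpoda-derived allometric relations, as printed.

    Keys are the reference equation numbers.  Relations 1–10 link copy
    numbers to CV, ESD or MV; relation 7 is the derived size-expected
    total rRNA/rDNA ratio that anchors the dormancy estimator.
    Coefficients are stored exactly as published (the published
    ESD-basis intercepts 0.396 and 3.43 are rounded forms of the exact
    transforms 0.3964 and 3.4255).
    """
    reg: Dict[int, PowerLawFit] = {
        1: PowerLawFit("rDNA_CNPC", "CV", 0.76, 0.61, 0.91, 0.001, 20),
        2: PowerLawFit("rDNA_CNPC", "ESD", 2.28, 0.396, 0.91, 0.001, 20),
        3: PowerLawFit("rDNA_total", "ESD", 2.28, 0.396, 0.91, 0.001, 20, True),
        4: PowerLawFit("rRNA_CNPC", "CV", 1.24, 1.69, 0.37, 0.005, 20),
        5: PowerLawFit("rRNA_CNPC", "CV", 0.87, 3.67, 0.84, 0.001, 16),
        6: PowerLawFit("rRNA_total", "ESD", 2.61, 3.43, 0.84, 0.001, 16, True),
        8: PowerLawFit("rDNA_CNPC", "MV", 0.90, 1.44, 0.93, 0.001, 16),
        9: PowerLawFit("rRNA_CNPC", "MV", 1.70, 2.28, 0.50, 0.002, 16),
        10: PowerLawFit("rRNA_CNPC", "MV", 1.05, 4.47, 0.83, 0.001, 12),
    }
    reg[7] = ratio_fit(reg[6], reg[3])
    return dict(sorted(reg.items()))
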