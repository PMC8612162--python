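"""Synthetic data generators with the statistical structure the analysis assumes.

Each generator is deterministic under a fixed seed and mirrors one
input class of the pipeline:

* :func:`gen_cells` — per-cell trait + ribotype tables: stage-specific
  log-normal cell volumes, power-law rDNA/rRNA–CV coupling with
  multiplicative log-normal noise, and the drastic (2–4 orders of
  magnitude) rRNA collapse of resting cysts;
* :func:`gen_population` — mixed vegetative/resting-cyst populations of
  known cyst fraction, the validation harness for the dormancy
  estimator;
* :func:`gen_dilution_series` — qPCR dilution series at a stated
  amplification efficiency with Gaussian CT noise, in triplicate;
* :func:`gen_variant_pool` — denoised single-cell variant pools: a
  dominant variant, minor variants at known divergences from the
  template, and optional error singletons emulating residual
  post-denoising substitution errors;
* :func:`gen_growth_dataset` and :func:`gen_power_law_sample` —
  recovery harnesses for the growth-rate models and the allometric
  fits.

Default :class:`SpeciesProfile` instances encode the published
per-stage trait means of the two Colpoda species at 18°C; template
sequences are random with a fixed seed (no real 18S sequence is
required).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ribotraits.allometry import (
    PowerLawFit,
    cv_fit_to_esd_fit,
    predict,
    ratio_fit,
)
from ribotraits.dormancy import PopulationPool
from ribotraits.errors import InsufficientDataError, InvalidInputError
from ribotraits.phenotype import Stage, spheroid_volume
from ribotraits.variants import Variant, VariantPool

__all__ = [
    "SpeciesProfile",
    "default_profiles",
    "random_template",
    "gen_cells",
    "gen_population",
    "gen_dilution_series",
    "gen_variant_pool",
    "gen_growth_dataset",
    "gen_power_law_sample",
    "DEFAULT_GROWTH_DESIGN",
]

ALPHABET = np.array(list("ACGT"))


def random_template(length: int = 373, seed: int = 0) -> str:
    """Random ACGT template of V4-like length, deterministic under seed."""
    if length < 100:
        raise InvalidInputError(f"template length must be >= 100 nt, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(ALPHABET, size=length))


@dataclass(frozen=True)
class SpeciesProfile:
    """Generating parameters for one species at one temperature.

    ``stage_cv_means`` are geometric-mean cell volumes (μm³) per life
    cycle stage; ``rdna_fit``/``rrna_fit`` are CV-based per-cell power
    laws for *vegetative* copy numbers; resting cysts keep the rDNA law
    but have their rRNA multiplied by ``cyst_rrna_suppression``.
    ``variant_divergences`` are true biological divergences of minor
    variants from the template (residual sequencing error is added
    separately by :func:`gen_variant_pool`).
    """

    name: str
    temperature: float
    stage_cv_means: Dict[Stage, float]
    rdna_fit: PowerLawFit
    rrna_fit: PowerLawFit
    cyst_rrna_suppression: float
    cv_log10_sd: float = 0.08
    mv_coefficient: float = 0.14
    mv_exponent: float = 0.83
    template_sequence: str = ""
    variant_divergences: Tuple[float, ...] = ()
    dominant_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.cyst_rrna_suppression < 1.0:
            raise InvalidInputError("cyst_rrna_suppression must lie in (0, 1)")
        if any(not 0.0 < d <= 0.15 for d in self.variant_divergences):
            raise InvalidInputError("variant divergences must lie in (0, 0.15]")
        if not 0.0 < self.dominant_fraction <= 1.0:
            raise InvalidInputError("dominant_fraction must lie in (0, 1]")

    def ratio_baseline(self) -> PowerLawFit:
        """ESD-based power law for the vegetative rRNA/rDNA ratio.

        Derived exactly from the profile's own generating fits, so the
        dormancy estimator run with this baseline is consistent with
        :func:`gen_population` output.
        """
        return ratio_fit(
            cv_fit_to_esd_fit(self.rrna_fit), cv_fit_to_esd_fit(self.rdna_fit)
        )


def default_profiles() -> Dict[str, SpeciesProfile]:
    """Reference profiles for the two soil Colpoda species at 18°C.

    Stage cell-volume means and the log-phase/resting-cyst copy numbers
    follow the published per-stage values (e.g. C. inflata: lag-phase
    CV ≈ 2.14e5 μm³, log-phase rRNA 1.3e8 vs resting-cyst 3.1e4
    copies).  Suppression factors are chosen so the generated
    resting-cyst rRNA matches those printed cyst values given each
    species' cyst size.
    """
    rdna = PowerLawFit("rDNA_CNPC", "CV", 0.76, 0.61)
    rrna = PowerLawFit("rRNA_CNPC", "CV", 0.87, 3.67)
    steinii = SpeciesProfile(
        name="Colpoda_steinii",
        temperature=18.0,
        stage_cv_means={
            Stage.LAG: 1.28e4,
            Stage.LOG: 1.1e4,
            Stage.PLATEAU: 6.0e3,
            Stage.UNSTABLE_CYST: 5.3e3,
            Stage.RESTING_CYST: 2.0e3,
        },
        rdna_fit=rdna,
        rrna_fit=rrna,
        cyst_rrna_suppression=1.0e-2,
        template_sequence=random_template(373, seed=11),
        variant_divergences=(0.03, 0.10),
        dominant_fraction=0.92,
    )
    inflata = SpeciesProfile(
        name="Colpoda_inflata",
        temperature=18.0,
        stage_cv_means={
            Stage.LAG: 2.14e5,
            Stage.LOG: 1.2e5,
            Stage.PLATEAU: 6.5e4,
            Stage.UNSTABLE_CYST: 2.1e4,
            Stage.RESTING_CYST: 2.0e4,
        },
        rdna_fit=rdna,
        rrna_fit=rrna,
        cyst_rrna_suppression=1.2e-3,
        template_sequence=random_template(374, seed=12),
        variant_divergences=(0.02, 0.04),
        dominant_fraction=0.95,
    )
    return {steinii.name: steinii, inflata.name: inflata}


def gen_cells(
    profile: SpeciesProfile,
    n_per_stage: int = 5,
    noise_sd_log10: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell trait + ribotype table for one species/temperature.

    CV is log-normal around each stage mean; MV, rDNA and rRNA follow
    their generating power laws with multiplicative log-normal noise
    (``noise_sd_log10`` on the log10 scale; 0 puts every point exactly
    on the laws).  Resting-cyst rRNA is additionally multiplied by the
    profile's suppression factor.
    """
    if n_per_stage < 1:
        raise InvalidInputError("n_per_stage must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for stage, cv_mean in profile.stage_cv_means.items():
        log_cv = rng.normal(math.log10(cv_mean), profile.cv_log10_sd, n_per_stage)
        cv = 10.0**log_cv
        mv = (
            profile.mv_coefficient
            * cv**profile.mv_exponent
            * 10.0 ** rng.normal(0.0, noise_sd_log10, n_per_stage)
        )
        rdna = np.array([predict(profile.rdna_fit, c) for c in cv]) * 10.0 ** rng.normal(
            0.0, noise_sd_log10, n_per_stage
        )
        rrna = np.array([predict(profile.rrna_fit, c) for c in cv]) * 10.0 ** rng.normal(
            0.0, noise_sd_log10, n_per_stage
        )
        if stage is Stage.RESTING_CYST:
            rrna = rrna * profile.cyst_rrna_suppression
        for i in range(n_per_stage):
            rows.append(
                {
                    "species": profile.name,
                    "stage": stage.value,
                    "temperature": profile.temperature,
                    "cell_volume": cv[i],
                    "macronuclear_volume": mv[i],
                    "rdna_cnpc": rdna[i],
                    "rrna_cnpc": rrna[i],
                    "replicate": f"{stage.value}_{i + 1}",
                }
            )
    return pd.DataFrame(rows)


def gen_population(
    profile: SpeciesProfile,
    n_cells: int = 1000,
    cyst_fraction: float = 0.0,
    esd: float = 20.0,
    noise_sd_log10: float = 0.0,
    seed: int = 0,
) -> Tuple[PopulationPool, float]:
    """Mixed vegetative/resting-cyst population with a known cyst fraction.

    Every cell has the vegetative ESD; vegetative cells contribute rDNA
    and rRNA per the profile's generating laws, cysts contribute equal
    rDNA but rRNA suppressed by the profile factor.  Per-cell
    multiplicative log-normal noise is optional.  Returns the pooled
    totals and the realized (integer-cell) cyst fraction.
    """
    if not 0.0 <= cyst_fraction <= 1.0:
        raise InvalidInputError(f"cyst fraction {cyst_fraction} outside [0, 1]")
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    cv = spheroid_volume(esd, esd)  # sphere of diameter esd
    rdna_pc = predict(profile.rdna_fit, cv)
    rrna_pc = predict(profile.rrna_fit, cv)
    n_cyst = int(round(cyst_fraction * n_cells))
    n_veg = n_cells - n_cyst

    def noisy(base: float, n: int) -> float:
        if n == 0:
            return 0.0
        if noise_sd_log10 == 0.0:
            return base * n
        return float(np.sum(base * 10.0 ** rng.normal(0.0, noise_sd_log10, n)))

    rdna_total = noisy(rdna_pc, n_veg) + noisy(rdna_pc, n_cyst)
    rrna_veg = noisy(rrna_pc, n_veg)
    rrna_rc = noisy(rrna_pc * profile.cyst_rrna_suppression, n_cyst)
    pool = PopulationPool(
        esd=esd,
        rdna_total=rdna_total,
        rrna_total=rrna_veg + rrna_rc,
        n_cells=n_cells,
    )
    return pool, n_cyst / n_cells


def gen_dilution_series(
    true_efficiency: float = 1.0,
    log10_copies: Sequence[float] = (3.0, 4.0, 5.0, 6.0, 7.0),
    ct_noise_sd: float = 0.1,
    intercept: float = 38.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR dilution series: CT = intercept − log10(copies)/log10(1+E) + noise.

    One row per reaction; ``replicates`` reactions per dilution point
    (triplicate by default, matching standard plate practice).
    """
    if not 0.8 <= true_efficiency <= 1.2:
        raise InvalidInputError(
            f"efficiency {true_efficiency} outside the plausible [0.8, 1.2]"
        )
    pts = list(log10_copies)
    if len(pts) < 3:
        raise InsufficientDataError(
            f"dilution series needs >= 3 points, got {len(pts)}"
        )
    slope = -1.0 / math.log10(1.0 + true_efficiency)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        for lc in pts:
            ct = intercept + slope * lc + rng.normal(0.0, ct_noise_sd)
            rows.append({"log10_copies": lc, "ct": ct, "replicate": rep})
    return pd.DataFrame(rows)


def _mutate(
    sequence: str, n_subs: int, rng: np.random.Generator, forbidden: set | None = None
) -> str:
    """Substitute ``n_subs`` distinct positions (outside ``forbidden``)."""
    seq = list(sequence)
    candidates = [i for i in range(len(seq)) if not forbidden or i not in forbidden]
    positions = rng.choice(len(candidates), size=n_subs, replace=False)
    for p in positions:
        i = candidates[p]
        seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


def gen_variant_pool(
    profile: SpeciesProfile,
    pool_type: str = "rDNA",
    read_depth: int = 2000,
    substitution_error_rate: float = 0.0,
    seed: int = 0,
    cell_id: str = "cell_1",
) -> VariantPool:
    """Denoised single-cell variant pool.

    The dominant variant (the template) carries ``dominant_fraction`` of
    the reads; the remainder is split evenly among minor variants
    substituted at ``round(d * L)`` positions for each divergence ``d``
    in the profile.  When ``substitution_error_rate`` > 0, error
    singletons are added: reads derived from the most divergent variant
    with ``round(rate * L)`` extra substitutions, so the *apparent*
    maximum divergence exceeds the true one by the error rate — the
    situation :func:`ribotraits.variants.corrected_divergence` undoes.
    The pool's ``residual_error_rate`` records the rate.
    """
    template = profile.template_sequence or random_template(373, seed=seed + 1)
    length = len(template)
    if length < 100:
        raise InvalidInputError("template must be >= 100 nt")
    rng = np.random.default_rng(seed)
    divergences = sorted(profile.variant_divergences)
    n_error = (
        int(round(read_depth * substitution_error_rate)) if substitution_error_rate else 0
    )
    dom_count = int(round(profile.dominant_fraction * read_depth))
    remainder = read_depth - dom_count - n_error
    variants = [Variant(template, max(dom_count, 1), "dominant")]
    minor_seqs = []
    if divergences:
        per_minor = max(remainder // len(divergences), 1)
        mutated_positions: set = set()
        for j, d in enumerate(divergences):
            n_subs = int(round(d * length))
            seq = _mutate(template, n_subs, rng)
            minor_seqs.append(seq)
            variants.append(Variant(seq, per_minor, f"minor_{j + 1}"))
    if n_error:
        # error singletons branch off the most divergent true variant at
        # fresh positions, inflating the apparent maximum divergence by
        # exactly the residual error rate
        source = minor_seqs[-1] if minor_seqs else template
        diff_positions = {i for i, (a, b) in enumerate(zip(template, source)) if a != b}
        n_extra = int(round(substitution_error_rate * length))
        n_singletons = min(n_error, 5)
        reads_per_singleton = n_error // n_singletons
        for k in range(n_singletons):
            seq = _mutate(source, n_extra, rng, forbidden=diff_positions)
            count = reads_per_singleton if k < n_singletons - 1 else (
                n_error - reads_per_singleton * (n_singletons - 1)
            )
            variants.append(Variant(seq, max(count, 1), f"error_{k + 1}"))
    return VariantPool(
        cell_id=cell_id,
        pool_type=pool_type,
        variants=tuple(variants),
        residual_error_rate=substitution_error_rate,
    )


#: 12-point design mirroring the reference data structure: four species ×
#: temperatures, t spanning 16–28 °C, the trait spanning > 2 decades
DEFAULT_GROWTH_DESIGN: Tuple[Tuple[float, float], ...] = (
    (16.0, 3.3),
    (21.0, 3.5),
    (25.0, 3.7),
    (28.0, 3.9),
    (16.0, 4.1),
    (21.0, 4.3),
    (25.0, 4.5),
    (18.0, 4.7),
    (28.0, 4.9),
    (16.0, 5.1),
    (21.0, 5.3),
    (25.0, 5.5),
)


def gen_growth_dataset(
    coef_t: float,
    coef_x: float,
    intercept: float,
    design: Sequence[Tuple[float, float]] = DEFAULT_GROWTH_DESIGN,
    noise_sd_log10: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Growth-rate dataset from a known model: log10 r = a·t + b·log10 x + c.

    ``design`` is a sequence of (temperature, log10 predictor) pairs;
    Gaussian noise is added on the log10 rate scale.
    """
    design = list(design)
    if len(design) < 4:
        raise InvalidInputError("design needs >= 4 points")
    t = np.array([d[0] for d in design])
    log_x = np.array([d[1] for d in design])
    mat = np.column_stack([np.ones_like(t), t, log_x])
    if np.linalg.matrix_rank(mat) < 3:
        raise InvalidInputError("collinear design: t and log10 x must both vary")
    rng = np.random.default_rng(seed)
    log_r = (
        coef_t * t
        + coef_x * log_x
        + intercept
        + rng.normal(0.0, noise_sd_log10, len(design))
    )
    return pd.DataFrame(
        {"temperature": t, "predictor": 10.0**log_x, "growth_rate": 10.0**log_r}
    )


def gen_power_law_sample(
    slope: float,
    intercept: float,
    n: int = 200,
    noise_sd_log10: float = 0.25,
    log10_x_range: Tuple[float, float] = (2.5, 5.5),
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample (x, y) from a log10 power law with Gaussian log10 noise on y.

    ``log10_x_range`` defaults to the full cell-size span from resting
    cysts (~3e2 μm³) to the largest lag-phase cells (~3e5 μm³).
    """
    if n < 3:
        raise InvalidInputError("sample size must be >= 3")
    rng = np.random.default_rng(seed)
    log_x = rng.uniform(*log10_x_range, n)
    log_y = slope * log_x + intercept + rng.normal(0.0, noise_sd_log10, n)
    return 10.0**log_x, 10.0**log_y
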