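"""File-format readers/writers, run configuration and the pipeline driver.

Tabular inputs are UTF-8 CSV/TSV with a header row; variant sequences
come as FASTA with read counts in a ``>id;size=N`` header suffix or a
sidecar TSV.  All numeric outputs are JSON with stable key ordering and
embed the seed and a configuration hash, so reruns are reproducible and
diffable.  Units are fixed throughout: volumes μm³, lengths μm,
temperatures °C, rates d⁻¹.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from ribotraits import allometry, dormancy, qpcr, synthetic
from ribotraits.allometry import PowerLawFit, RibotypeRecord, fit_power_law
from ribotraits.errors import InvalidInputError, SchemaError
from ribotraits.phenotype import CellRecord, Stage
from ribotraits.variants import Variant, VariantPool

__all__ = [
    "RunConfig",
    "read_trait_table",
    "read_variant_fasta",
    "write_fit_json",
    "run_pipeline",
]

logger = logging.getLogger("ribotraits")

_SIZE_RE = re.compile(r";size=(\d+)")

MANDATORY_TRAIT_COLUMNS = ("species", "stage", "temperature", "cell_volume")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a pipeline run (YAML/JSON serialisable)."""

    output_dir: str
    seed: int = 0
    trait_table: Optional[str] = None
    variant_fasta: Optional[str] = None
    thresholds: Tuple[float, ...] = ()
    rarefaction_depth: int = 1600
    baseline_slope: float = 0.33
    baseline_intercept: float = 3.034
    stages: Tuple[str, ...] = ("simulate", "fit-allometry", "estimate-cysts")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if any(not 0.80 <= t <= 1.00 for t in self.thresholds):
            raise InvalidInputError("identity thresholds must lie in [0.80, 1.00]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc


def read_trait_table(
    path: str | Path, strict: bool = True
) -> List[Tuple[CellRecord, Optional[RibotypeRecord]]]:
    """Read a per-cell trait (± ribotype) table.

    Mandatory columns: species, stage, temperature, cell_volume.
    Optional: length, width, macronuclear_volume, rdna_cnpc, rrna_cnpc,
    replicate (missing values as empty cells).  Invalid rows are
    reported with their 1-based data line numbers; with ``strict`` they
    raise, otherwise they are skipped with a warning.
    """
    df = _read_table(path)
    missing = [c for c in MANDATORY_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records: List[Tuple[CellRecord, Optional[RibotypeRecord]]] = []
    problems: List[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            def opt(col: str) -> Optional[float]:
                return (
                    float(row[col])
                    if col in df.columns and pd.notna(row[col])
                    else None
                )

            cell = CellRecord(
                species=str(row["species"]),
                stage=Stage(str(row["stage"])),
                temperature=float(row["temperature"]),
                cell_volume=float(row["cell_volume"]),
                length=opt("length"),
                width=opt("width"),
                macronuclear_volume=opt("macronuclear_volume"),
                replicate=str(row.get("replicate", "")),
            )
            ribo = None
            if opt("rdna_cnpc") is not None and opt("rrna_cnpc") is not None:
                ribo = RibotypeRecord(
                    cell=cell, rdna_cnpc=opt("rdna_cnpc"), rrna_cnpc=opt("rrna_cnpc")
                )
            records.append((cell, ribo))
        except (ValueError, InvalidInputError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        message = f"{path}: {len(problems)} invalid rows: " + "; ".join(problems)
        if strict:
            raise InvalidInputError(message)
        warnings.warn(message, stacklevel=2)
    return records


def read_variant_fasta(
    path: str | Path,
    counts: Optional[str | Path] = None,
    pool_type: str = "rDNA",
    cell_id: Optional[str] = None,
    residual_error_rate: float = 0.0,
) -> VariantPool:
    """Read a single cell's variant pool from FASTA.

    Read counts come from a ``;size=N`` suffix in each header, or from a
    sidecar TSV (columns: variant_id, count).  A record with neither
    defaults to count 1 with a warning.  Lowercase sequences are
    uppercased silently; any non-ACGT character is an error naming the
    offending record.
    """
    path = Path(path)
    sidecar: Dict[str, int] = {}
    if counts is not None:
        ctab = pd.read_csv(counts, sep="\t")
        sidecar = dict(zip(ctab.iloc[:, 0].astype(str), ctab.iloc[:, 1].astype(int)))
    variants = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not re.fullmatch(r"[ACGT]+", seq or ""):
            raise InvalidInputError(
                f"{path}: record {rec.id!r} contains non-ACGT characters"
            )
        m = _SIZE_RE.search(rec.description)
        vid = rec.id.split(";")[0]
        if m:
            count = int(m.group(1))
        elif vid in sidecar:
            count = sidecar[vid]
        else:
            warnings.warn(
                f"{path}: record {rec.id!r} has no size annotation; count = 1",
                stacklevel=2,
            )
            count = 1
        variants.append(Variant(sequence=seq, count=count, variant_id=vid))
    if not variants:
        raise SchemaError(f"{path}: no FASTA records")
    return VariantPool(
        cell_id=cell_id or path.stem,
        pool_type=pool_type,
        variants=tuple(variants),
        residual_error_rate=residual_error_rate,
    )


def write_fit_json(fit, path: str | Path, extra: Optional[dict] = None) -> None:
    """Write a fit summary (dataclass) as sorted-key JSON."""
    payload = asdict(fit)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def run_pipeline(config: RunConfig) -> Dict[str, dict]:
    """Run the configured stages in order and write JSON outputs.

    ``simulate`` generates a per-cell table (written as CSV);
    ``fit-allometry`` fits the rDNA–CV and rRNA–CV power laws on the
    trait table (simulated or supplied); ``estimate-cysts`` estimates
    the cyst fraction of a simulated mixed population.  Every output
    embeds the seed and config hash.  Returns the report dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    report: Dict[str, dict] = {"meta": meta}
    profile = synthetic.default_profiles()["Colpoda_steinii"]
    table: Optional[pd.DataFrame] = None

    for stage in config.stages:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            table = synthetic.gen_cells(profile, n_per_stage=10, seed=config.seed)
            table.to_csv(out / "simulated_cells.csv", index=False)
            report["simulate"] = {"n_cells": int(len(table))}
        elif stage == "fit-allometry":
            if table is None:
                if config.trait_table is None:
                    raise InvalidInputError(
                        "fit-allometry needs a trait table or a prior simulate stage"
                    )
                records = read_trait_table(config.trait_table)
                table = pd.DataFrame(
                    {
                        "cell_volume": [c.cell_volume for c, r in records if r],
                        "rdna_cnpc": [r.rdna_cnpc for _, r in records if r],
                        "rrna_cnpc": [r.rrna_cnpc for _, r in records if r],
                    }
                )
            fits = {}
            for response in ("rdna_cnpc", "rrna_cnpc"):
                fit = fit_power_law(
                    table["cell_volume"],
                    table[response],
                    predictor="CV",
                    response="rDNA_CNPC" if response == "rdna_cnpc" else "rRNA_CNPC",
                )
                fits[response] = asdict(fit)
            (out / "allometry_fits.json").write_text(
                json.dumps({**meta, "fits": fits}, sort_keys=True, indent=2) + "\n"
            )
            report["fit-allometry"] = fits
        elif stage == "estimate-cysts":
            pool, true_f = synthetic.gen_population(
                profile, n_cells=1000, cyst_fraction=0.3, seed=config.seed
            )
            baseline = PowerLawFit(
                "rRNA_total/rDNA_total",
                "ESD",
                config.baseline_slope,
                config.baseline_intercept,
            )
            est = dormancy.cyst_fraction(pool, baseline)
            result = {
                "cyst_fraction": est.fraction,
                "raw": est.raw,
                "clamped": est.clamped,
                "true_fraction_simulated": true_f,
            }
            (out / "cyst_estimate.json").write_text(
                json.dumps({**meta, **result}, sort_keys=True, indent=2) + "\n"
            )
            report["estimate-cysts"] = result
        else:
            raise InvalidInputError(f"unknown pipeline stage {stage!r}")
    (out / "run_report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=str) + "\n"
    )
    return report
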