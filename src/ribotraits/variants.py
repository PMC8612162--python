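"""Single-cell rDNA/rRNA sequence-variant analysis.

Operates downstream of amplicon denoising: each cell contributes a pool
of distinct variants with read counts (plus a residual per-base error
rate estimated from clone-library controls).  The module provides

* a global-alignment identity kernel (terminal gaps excluded),
* deterministic greedy centroid clustering at an identity threshold,
* a threshold scan (89%–100%) of OTU counts,
* the "leveling threshold" — the largest cutoff collapsing the pool to
  a single OTU — whose complement, minus the residual error rate, is
  the error-corrected maximum intraindividual sequence divergence,
* dominant-OTU proportion and seeded rarefied OTU richness, and
* the regression of per-cell OTU richness on log10 copy number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import edlib
import numpy as np

from ribotraits.allometry import PowerLawFit
from ribotraits.errors import InsufficientDataError, InvalidInputError

__all__ = [
    "Variant",
    "VariantPool",
    "Cluster",
    "ClusteringResult",
    "DEFAULT_THRESHOLDS",
    "pairwise_identity",
    "greedy_cluster",
    "threshold_scan",
    "leveling_threshold",
    "corrected_divergence",
    "dominant_proportion",
    "rarefied_richness",
    "expected_rarefied_richness",
    "richness_vs_cn_regression",
]

_VALID_SEQ = re.compile(r"^[ACGT]+$")
_CIGAR_OP = re.compile(r"(\d+)([=XID])")

#: identity-threshold grid matching the published scan: 89%–100% in 1% steps
DEFAULT_THRESHOLDS: Tuple[float, ...] = tuple(
    round(0.89 + 0.01 * i, 2) for i in range(12)
)


@dataclass(frozen=True)
class Variant:
    """One denoised amplicon sequence variant with its read count."""

    sequence: str
    count: int
    variant_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or not _VALID_SEQ.match(self.sequence):
            raise InvalidInputError(
                f"variant {self.variant_id or '?'}: sequence must be non-empty ACGT"
            )
        if self.count < 1:
            raise InvalidInputError(
                f"variant {self.variant_id or '?'}: count must be >= 1"
            )


@dataclass(frozen=True)
class VariantPool:
    """All denoised variants from one cell's rDNA or rRNA pool."""

    cell_id: str
    pool_type: str  # "rDNA" | "rRNA"
    variants: Tuple[Variant, ...]
    residual_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pool_type not in ("rDNA", "rRNA"):
            raise InvalidInputError(f"pool_type must be rDNA or rRNA, got {self.pool_type!r}")
        if not 0.0 <= self.residual_error_rate <= 0.05:
            raise InvalidInputError(
                f"residual error rate {self.residual_error_rate} outside [0, 0.05]"
            )
        object.__setattr__(self, "variants", tuple(self.variants))

    @property
    def total_reads(self) -> int:
        return sum(v.count for v in self.variants)


@dataclass(frozen=True)
class Cluster:
    """One OTU: its centroid plus member variants and summed reads."""

    centroid: Variant
    members: Tuple[Variant, ...]
    total_count: int


@dataclass(frozen=True)
class ClusteringResult:
    threshold: float
    clusters: Tuple[Cluster, ...]

    @property
    def otu_count(self) -> int:
        return len(self.clusters)


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity of two sequences under global alignment.

    Needleman–Wunsch with unit mismatch and gap costs (via edlib);
    identity = matched columns / alignment columns, where terminal gap
    runs are excluded from the columns and each internal gap position
    counts as one (mismatching) column.
    """
    if not a or not b:
        raise InvalidInputError("sequences must be non-empty")
    if a == b:
        return 1.0
    cigar = edlib.align(a, b, mode="NW", task="path")["cigar"]
    ops = [(int(n), op) for n, op in _CIGAR_OP.findall(cigar)]
    # strip terminal gap runs (insertions/deletions at either end)
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    columns = sum(n for n, _ in ops)
    if columns == 0:
        return 0.0
    matches = sum(n for n, op in ops if op == "=")
    return matches / columns


def _sorted_variants(pool: VariantPool) -> List[Variant]:
    # descending count, lexicographic sequence tie-break: a total order,
    # so clustering is invariant to input order
    return sorted(pool.variants, key=lambda v: (-v.count, v.sequence))


def greedy_cluster(pool: VariantPool, threshold: float) -> ClusteringResult:
    """Deterministic greedy centroid clustering at an identity threshold.

    Variants are visited in descending read count (ties broken
    lexicographically by sequence); each joins the first existing
    centroid it matches at identity ≥ threshold, else founds a new
    cluster.  At threshold 1.0 clusters are exact-sequence groups.
    """
    if not 0.80 <= threshold <= 1.00:
        raise InvalidInputError(f"threshold {threshold} outside [0.80, 1.00]")
    centroids: List[Variant] = []
    members: List[List[Variant]] = []
    for v in _sorted_variants(pool):
        for i, c in enumerate(centroids):
            if pairwise_identity(v.sequence, c.sequence) >= threshold:
                members[i].append(v)
                break
        else:
            centroids.append(v)
            members.append([v])
    clusters = tuple(
        Cluster(centroid=c, members=tuple(m), total_count=sum(v.count for v in m))
        for c, m in zip(centroids, members)
    )
    return ClusteringResult(threshold=threshold, clusters=clusters)


def threshold_scan(
    pool: VariantPool, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> List[Tuple[float, int]]:
    """OTU count at each identity threshold, sorted descending by threshold."""
    out = [
        (t, greedy_cluster(pool, t).otu_count)
        for t in sorted(thresholds, reverse=True)
    ]
    return out


def leveling_threshold(scan: Sequence[Tuple[float, int]]) -> Tuple[float, bool]:
    """Largest threshold at which the pool collapses to a single OTU.

    Returns ``(threshold, leveled)``.  When the count never reaches 1
    on the grid, the lowest scanned threshold is returned with
    ``leveled = False``.
    """
    if not scan:
        raise InvalidInputError("empty threshold scan")
    ordered = sorted(scan, key=lambda p: -p[0])
    for t, count in ordered:
        if count == 1:
            return t, True
    return ordered[-1][0], False


def corrected_divergence(leveling: float, residual_error_rate: float) -> float:
    """Error-corrected maximum intraindividual divergence.

    ``(1 − leveling threshold) − residual error rate``, floored at 0:
    the portion of the apparent divergence not attributable to residual
    sequencing error.
    """
    if not 0.0 <= leveling <= 1.0 or not 0.0 <= residual_error_rate <= 1.0:
        raise InvalidInputError("inputs must lie in [0, 1]")
    return max((1.0 - leveling) - residual_error_rate, 0.0)


def dominant_proportion(pool: VariantPool, threshold: float = 0.99) -> float:
    """Read fraction of the most abundant OTU at the given threshold."""
    if not pool.variants:
        raise InvalidInputError("empty variant pool")
    result = greedy_cluster(pool, threshold)
    # max count; ties resolved toward the earlier-founded (higher-count
    # centroid) cluster, which the stable max over insertion order gives
    top = max(result.clusters, key=lambda c: c.total_count)
    return top.total_count / pool.total_reads


def _counts_per_cluster(pool: VariantPool, threshold: float) -> np.ndarray:
    return np.array(
        [c.total_count for c in greedy_cluster(pool, threshold).clusters], dtype=int
    )


def rarefied_richness(
    pool: VariantPool,
    depth: int = 1600,
    threshold: float = 0.99,
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Mean OTU count after repeatedly subsampling ``depth`` reads.

    Subsampling is without replacement at the read level, repeated
    ``reps`` times with a seeded generator.  Clustering is computed once
    on the full pool; a rarefaction replicate counts the OTUs that
    retain at least one read.
    """
    total = pool.total_reads
    if total < depth:
        raise InsufficientDataError(
            f"pool has {total} reads, fewer than rarefaction depth {depth}"
        )
    counts = _counts_per_cluster(pool, threshold)
    if total == depth:
        return float(len(counts))
    rng = np.random.default_rng(seed)
    # multivariate hypergeometric draw of reads per OTU
    richness = [
        int(np.count_nonzero(rng.multivariate_hypergeometric(counts, depth)))
        for _ in range(reps)
    ]
    return float(np.mean(richness))


def expected_rarefied_richness(
    pool: VariantPool, depth: int = 1600, threshold: float = 0.99
) -> float:
    """Analytic expectation of rarefied OTU richness (hypergeometric).

    E[S] = Σ_otu (1 − P(otu absent from a without-replacement sample of
    ``depth`` reads)); the independent check for :func:`rarefied_richness`.
    """
    from scipy.stats import hypergeom

    total = pool.total_reads
    if total < depth:
        raise InsufficientDataError(
            f"pool has {total} reads, fewer than rarefaction depth {depth}"
        )
    counts = _counts_per_cluster(pool, threshold)
    p_absent = np.array([hypergeom.pmf(0, total, c, depth) for c in counts])
    return float(np.sum(1.0 - p_absent))


def richness_vs_cn_regression(
    otu_counts: Sequence[float], copy_numbers: Sequence[float]
) -> PowerLawFit:
    """OLS of per-cell OTU count on log10 per-cell copy number.

    The response stays untransformed (OTU counts are small integers);
    only the copy number is logged.  A negative slope indicates that
    copy-rich cells harbour proportionally fewer distinct variants.
    """
    y = np.asarray(otu_counts, dtype=float)
    x = np.asarray(copy_numbers, dtype=float)
    if y.shape != x.shape:
        raise InvalidInputError("otu_counts and copy_numbers must have equal length")
    bad = np.nonzero((x <= 0) | (y <= 0))[0]
    if bad.size:
        raise InvalidInputError(f"non-positive values at rows {bad.tolist()}")
    if y.size < 3:
        raise InvalidInputError(f"regression needs n >= 3, got {y.size}")
    from scipy import stats

    res = stats.linregress(np.log10(x), y)
    r2 = float(res.rvalue) ** 2
    pval = float(res.pvalue)
    if np.isnan(r2):  # constant richness: no association to quantify
        r2, pval = 0.0, 1.0
    return PowerLawFit(
        response="otu_count",
        predictor="rDNA_CNPC",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=pval,
        n=int(y.size),
    )
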