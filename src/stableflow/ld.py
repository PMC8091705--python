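"""Pairwise linkage disequilibrium as squared correlation of feature columns.

LD between two variants is estimated as the squared Pearson correlation R^2
of their presence columns. On binary presence indicators this coincides with
the classical genotype r^2 = D^2 / (p_A p_a p_B p_b); on the continuous
simulated features it is plain squared correlation. R^2 is only ever
evaluated for candidate pairs within one chromosome — genome-wide all-pairs
LD is deliberately never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, VariantKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDEdgeCandidate:
    variant_a: VariantKey
    variant_b: VariantKey
    r_squared: float

    def __post_init__(self) -> None:
        if self.variant_a.chromosome != self.variant_b.chromosome:
            raise ValueError("LD is only defined within one chromosome")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of range: {self.r_squared}")


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two feature columns.

    Returns NaN (undefined) when either column has zero variance; callers
    treat such pairs as not linked.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("columns must be 1-D, equal length >= 2")
    if x.std() == 0.0 or y.std() == 0.0:
        logger.info("r_squared undefined: zero-variance column")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def ld_pairs_within_chromosome(
    m: GenotypeMatrix,
    candidate_ids_a: list[str],
    candidate_ids_b: list[str],
    threshold: float = 0.8,
) -> list[LDEdgeCandidate]:
    """All same-chromosome pairs (a from list A, b from list B) with R^2 > threshold.

    The inequality is strict. A variant id present in both lists is emitted
    with R^2 = 1 without computing a correlation (a variant is trivially in
    LD with itself). Pairs touching a zero-variance column are dropped, and
    pairs where either binary column has fewer than 2 carriers are logged as
    unstable LD estimates but still evaluated.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    index = {vid: i for i, vid in enumerate(m.variant_ids)}
    for vid in set(candidate_ids_a) | set(candidate_ids_b):
        if vid not in index:
            raise KeyError(f"candidate variant {vid} not in matrix")

    by_chrom_a: dict[str, list[str]] = {}
    by_chrom_b: dict[str, list[str]] = {}
    for vid in candidate_ids_a:
        by_chrom_a.setdefault(m.variants[index[vid]].chromosome, []).append(vid)
    for vid in candidate_ids_b:
        by_chrom_b.setdefault(m.variants[index[vid]].chromosome, []).append(vid)

    out: list[LDEdgeCandidate] = []
    for chrom, a_ids in by_chrom_a.items():
        b_ids = by_chrom_b.get(chrom)
        if not b_ids:
            continue
        out.extend(_chrom_block(m, index, a_ids, b_ids, threshold))
    return out


def _chrom_block(
    m: GenotypeMatrix,
    index: dict[str, int],
    a_ids: list[str],
    b_ids: list[str],
    threshold: float,
) -> list[LDEdgeCandidate]:
    A = m.values[:, [index[v] for v in a_ids]].astype(float)
    B = m.values[:, [index[v] for v in b_ids]].astype(float)
    sa = A.std(axis=0)
    sb = B.std(axis=0)
    if m.encoding_mode == "binary":
        for ids, block in ((a_ids, A), (b_ids, B)):
            rare = np.asarray(block).sum(axis=0) < 2
            for vid in np.array(ids)[rare]:
                logger.info("variant %s has < 2 carriers; LD estimate unstable", vid)

    n = m.n_samples
    Az = (A - A.mean(axis=0)) / np.where(sa > 0, sa, 1.0)
    Bz = (B - B.mean(axis=0)) / np.where(sb > 0, sb, 1.0)
    R = (Az.T @ Bz) / n
    R2 = np.clip(R * R, 0.0, 1.0)

    out: list[LDEdgeCandidate] = []
    for i, va in enumerate(a_ids):
        for j, vb in enumerate(b_ids):
            if va == vb:
                r2 = 1.0  # identical variant: trivially in LD, no computation
            else:
                if sa[i] == 0.0 or sb[j] == 0.0:
                    logger.info("zero-variance column in pair (%s, %s); no edge", va, vb)
                    continue
                r2 = float(R2[i, j])
                if not r2 > threshold:
                    continue
            if r2 > threshold or va == vb:
                out.append(
                    LDEdgeCandidate(
                        variant_a=m.variants[index[va]],
                        variant_b=m.variants[index[vb]],
                        r_squared=r2,
                    )
                )
    return out
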