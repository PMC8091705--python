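"""Genotype matrices, variant identity, and plain-text serialization.

The central in-memory container is :class:`GenotypeMatrix`, a samples x
features matrix of variant presence indicators (binary mode) or simulated
continuous features (continuous mode), with one :class:`VariantKey` per
column and a case/control label per row.

All on-disk formats are tab-separated text so artifacts diff and round-trip
cleanly: the matrix TSV carries variant ids as the header row, sample ids in
the first column and the class label in the last; fold selections, variant
groups and stability reports each get a small columnar TSV of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
LABELS = (CASE, CONTROL)


class ParseError(ValueError):
    """Raised for a malformed input file; the message names the line."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one biallelic variant: chromosome, position, ref, alt.

    ``position`` is 1-based (VCF convention). The ``id`` property is the
    stable string key ``chrom:pos:ref:alt`` used as the matrix column name.
    """

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def id(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}:{self.alt}"

    @classmethod
    def from_id(cls, vid: str) -> "VariantKey":
        parts = vid.split(":")
        if len(parts) != 4:
            raise ParseError(f"malformed variant id {vid!r}; expected chrom:pos:ref:alt")
        chrom, pos, ref, alt = parts
        return cls(chromosome=chrom, position=int(pos), ref=ref, alt=alt)


@dataclass
class GenotypeMatrix:
    """Samples x features matrix with variant metadata and class labels.

    ``encoding_mode`` is ``"binary"`` for presence/absence genotype
    indicators and ``"continuous"`` for simulated feature matrices.
    """

    values: np.ndarray
    sample_ids: list[str]
    variants: list[VariantKey]
    labels: np.ndarray  # array of CASE / CONTROL strings
    encoding_mode: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels, dtype=object)
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("row count, sample_ids and labels must agree")
        if len(self.variants) != m:
            raise ValueError("column count must equal number of variants")
        ids = self.variant_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in matrix")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.encoding_mode == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary mode requires all entries in {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def y(self) -> np.ndarray:
        """Labels as 0/1 integers with case = 1."""
        return (self.labels == CASE).astype(int)

    def column(self, variant_id: str) -> np.ndarray:
        return self.values[:, self.variant_ids.index(variant_id)]

    def subset_samples(self, row_idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(row_idx)
        return GenotypeMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            labels=self.labels[idx],
            encoding_mode=self.encoding_mode,
        )

    def subset_features(self, col_idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(col_idx, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, idx] if len(idx) else np.empty((self.n_samples, 0)),
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            labels=self.labels.copy(),
            encoding_mode=self.encoding_mode,
        )


def read_vcf_to_matrix(vcf_path: str | Path, labels_path: str | Path) -> GenotypeMatrix:
    """Encode a VCF as a binary presence matrix.

    A cell is 1 when the sample carries at least one copy of the column's
    alternate allele (heterozygous or homozygous alternate) and 0 when it
    matches the reference. Missing genotypes are encoded 0 (reference-like).
    Multi-allelic records are split into one column per alternate allele.

    ``labels_path`` is a two-column TSV ``sample_id<TAB>label`` with label in
    {case, control}; every VCF sample must appear in it.
    """
    from cyvcf2 import VCF

    label_map = _read_labels(labels_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in label_map]
    if missing:
        raise ValueError(f"samples in VCF absent from labels file: {missing}")

    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        gts = np.array([g[:2] for g in rec.genotypes])  # (n_samples, 2) allele idx
        for ai, alt in enumerate(rec.ALT, start=1):
            key = VariantKey(str(rec.CHROM), int(rec.POS), str(rec.REF), str(alt))
            if key.id in seen:
                logger.warning("duplicate VCF record for %s; keeping first", key.id)
                continue
            seen.add(key.id)
            variants.append(key)
            columns.append((gts == ai).any(axis=1).astype(np.int8))
    values = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    labels = np.array([label_map[s] for s in samples], dtype=object)
    return GenotypeMatrix(values, samples, variants, labels, encoding_mode="binary")


def _read_labels(path: str | Path) -> dict[str, str]:
    label_map: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in LABELS:
                raise ParseError(f"{path}:{lineno}: expected 'sample<TAB>case|control'")
            label_map[parts[0]] = parts[1]
    return label_map


def filter_variants_by_regions(m: GenotypeMatrix, bed_path: str | Path) -> GenotypeMatrix:
    """Keep only columns whose position falls in a BED region on the same chromosome.

    BED is 0-based half-open; a 1-based variant position p is retained iff
    start < p <= end for some region, i.e. the 0-based point p-1 lies inside
    [start, end). Column order is preserved.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{bed_path}:{lineno}: expected at least 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)

    keep = [
        i
        for i, v in enumerate(m.variants)
        if v.chromosome in trees and trees[v.chromosome].overlaps_point(v.position - 1)
    ]
    if not keep:
        logger.warning("region filter removed every variant column")
    return m.subset_features(keep)


# ---------------------------------------------------------------------------
# TSV serializers (round-trip safe)

def write_matrix(m: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.variant_ids)
    df.insert(0, "sample_id", m.sample_ids)
    df["label"] = m.labels
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, encoding_mode: str | None = None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "sample_id" or df.columns[-1] != "label":
        raise ParseError(f"{path}:1: header must start with 'sample_id' and end with 'label'")
    vids = list(df.columns[1:-1])
    values = df[vids].to_numpy() if vids else np.empty((len(df), 0))
    if encoding_mode is None:
        binary = values.size == 0 or (np.isin(values, (0, 1)).all())
        encoding_mode = "binary" if binary else "continuous"
    if encoding_mode == "binary":
        values = values.astype(np.int8)
    return GenotypeMatrix(
        values=values,
        sample_ids=list(df["sample_id"]),
        variants=[VariantKey.from_id(v) for v in vids],
        labels=df["label"].to_numpy(dtype=object),
        encoding_mode=encoding_mode,
    )


def write_fold_selections(folds: Iterable, path: str | Path) -> None:
    """Serialize FoldSelections as TSV rows (fold, variant_id, coefficient)."""
    rows = [
        {"fold": fs.fold, "variant_id": vid, "coefficient": coef}
        for fs in folds
        for vid, coef in sorted(fs.coefficients.items())
    ]
    pd.DataFrame(rows, columns=["fold", "variant_id", "coefficient"]).to_csv(
        path, sep="\t", index=False
    )


def read_fold_selections(path: str | Path) -> list:
    from .selection_stability import FoldSelection

    df = pd.read_csv(path, sep="\t")
    expected = ["fold", "variant_id", "coefficient"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}:1: expected header {expected}")
    out = []
    for fold, sub in df.groupby("fold", sort=True):
        out.append(
            FoldSelection(
                fold=int(fold),
                coefficients=dict(zip(sub["variant_id"], sub["coefficient"])),
            )
        )
    return out


def write_variant_groups(groups: Iterable, path: str | Path) -> None:
    rows = [
        {"group_id": g.group_id, "variant_ids": ",".join(v.id for v in g.variants)}
        for g in groups
    ]
    pd.DataFrame(rows, columns=["group_id", "variant_ids"]).to_csv(path, sep="\t", index=False)


def read_variant_groups(path: str | Path) -> list:
    from .flownet import VariantGroup

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["group_id", "variant_ids"]:
        raise ParseError(f"{path}:1: expected header ['group_id', 'variant_ids']")
    return [
        VariantGroup(
            group_id=str(row.group_id),
            variants=[VariantKey.from_id(v) for v in str(row.variant_ids).split(",")],
        )
        for row in df.itertuples()
    ]


def write_report(report, path: str | Path) -> None:
    """Serialize a StabilityReport to TSV, one row per fold pair."""
    rows = [
        {
            "stage": report.stage,
            "fold_i": i,
            "fold_j": j,
            "pearson": pm.pearson,
            "kendall_tau": pm.kendall_tau,
            "jaccard": pm.jaccard,
        }
        for (i, j), pm in sorted(report.pairs.items())
    ]
    pd.DataFrame(
        rows, columns=["stage", "fold_i", "fold_j", "pearson", "kendall_tau", "jaccard"]
    ).to_csv(path, sep="\t", index=False)


def read_report(path: str | Path):
    from .selection_stability import PairMetrics, StabilityReport

    df = pd.read_csv(path, sep="\t")
    expected = ["stage", "fold_i", "fold_j", "pearson", "kendall_tau", "jaccard"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}:1: expected header {expected}")
    stage = str(df["stage"].iloc[0]) if len(df) else "pre_flow"
    pairs = {
        (int(r.fold_i), int(r.fold_j)): PairMetrics(
            pearson=float(r.pearson), kendall_tau=float(r.kendall_tau), jaccard=float(r.jaccard)
        )
        for r in df.itertuples()
    }
    return StabilityReport(stage=stage, pairs=pairs)
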