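"""Per-fold regularized feature selection and pairwise stability metrics.

A sparse linear classifier (L1 or elastic-net logistic regression, or
L1-penalized linear SVC) is fit once per cross-validation fold on the
complementary folds; the variants with non-zero coefficients form that
fold's selection. Stability across folds is quantified by three pairwise
metrics:

* Pearson correlation of the coefficient vectors, aligned on the union of
  the two selections (a variant unselected in one fold contributes 0 there);
* Kendall-Tau (P - Q) / (P + Q) over the rank orderings of the aligned
  coefficients, with ties broken deterministically by variant id;
* Jaccard index |A and B| / |A or B| of the selected variant-id sets.

The regularization strength is expressed as lambda, the penalty weight;
fitting backends that use the inverse parameterization C receive C = 1/lambda.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

#: returned where a metric is mathematically undefined (e.g. zero variance)
UNDEFINED = float("nan")

MAX_ITER = 10_000
TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Family, penalty and strength of the per-fold selector.

    lambda_ > 0 is the regularization weight; ``elastic_net_mixing`` is the
    L1 share of the elastic-net penalty (ignored for pure L1).
    """

    model_family: str = "logistic_regression"  # or "linear_svc"
    penalty: str = "l1"  # or "elastic_net"
    lambda_: float = 10.0
    # L1 share of the elastic-net penalty; 0.1 keeps the effective L1
    # strength at lambda=100 equal to the pure-L1 setting at lambda=10
    elastic_net_mixing: float = 0.1
    class_weighting: str = "none"  # or "inverse_class_size"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in ("logistic_regression", "linear_svc"):
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.penalty not in ("l1", "elastic_net"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.model_family == "linear_svc" and self.penalty != "l1":
            raise ValueError("linear_svc supports the l1 penalty only")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if not 0.0 < self.elastic_net_mixing < 1.0:
            raise ValueError("elastic_net_mixing must be in (0, 1)")

    def build_estimator(self, penalty_override: str | None = None):
        """Instantiate the scikit-learn estimator this spec describes."""
        C = 1.0 / self.lambda_
        cw = "balanced" if self.class_weighting == "inverse_class_size" else None
        penalty = penalty_override or self.penalty
        if self.model_family == "linear_svc":
            sk_penalty = {"l1": "l1", "l2": "l2"}[penalty if penalty != "elastic_net" else "l1"]
            return LinearSVC(
                penalty=sk_penalty,
                loss="squared_hinge",
                dual=False,
                C=C,
                class_weight=cw,
                tol=TOL,
                max_iter=MAX_ITER,
                random_state=self.seed,
            )
        if penalty == "l1":
            return LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", class_weight=cw,
                tol=TOL, max_iter=MAX_ITER, random_state=self.seed,
            )
        if penalty == "l2":
            return LogisticRegression(
                l1_ratio=0.0, C=C, solver="lbfgs", class_weight=cw,
                tol=TOL, max_iter=MAX_ITER,
            )
        return LogisticRegression(
            l1_ratio=self.elastic_net_mixing, C=C,
            solver="saga", class_weight=cw, tol=TOL, max_iter=MAX_ITER,
            random_state=self.seed,
        )


@dataclass
class FoldSelection:
    """Variants selected in one CV fold, with their non-zero coefficients."""

    fold: int
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = {v: float(c) for v, c in self.coefficients.items() if c != 0.0}

    @property
    def variant_ids(self) -> set[str]:
        return set(self.coefficients)


@dataclass(frozen=True)
class PairMetrics:
    pearson: float
    kendall_tau: float
    jaccard: float


@dataclass
class StabilityReport:
    """All pairwise fold-to-fold stability metrics for one stage."""

    stage: str  # "pre_flow" | "post_flow"
    pairs: dict[tuple[int, int], PairMetrics]
    rank_scatter: dict[tuple[int, int], list[tuple[str, int, int]]] = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for metric in ("pearson", "kendall_tau", "jaccard"):
            vals = [
                getattr(pm, metric)
                for pm in self.pairs.values()
                if not math.isnan(getattr(pm, metric))
            ]
            out[metric] = {
                "min": min(vals) if vals else UNDEFINED,
                "max": max(vals) if vals else UNDEFINED,
                "mean": float(np.mean(vals)) if vals else UNDEFINED,
            }
        return out


def split_train_test(
    m: GenotypeMatrix, train_fraction: float = 0.8, seed: int = 0
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Label-stratified train/test split of the samples."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = {lab: int((m.labels == lab).sum()) for lab in set(m.labels)}
    if min(counts.values(), default=0) < 2:
        raise ValueError(f"each class needs at least 2 samples for stratification: {counts}")
    idx_train, idx_test = train_test_split(
        np.arange(m.n_samples),
        train_size=train_fraction,
        stratify=m.labels,
        random_state=seed,
    )
    return m.subset_samples(np.sort(idx_train)), m.subset_samples(np.sort(idx_test))


def select_per_fold(
    train: GenotypeMatrix,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    keep_zero: bool = False,
    penalty_override: str | None = None,
) -> list[FoldSelection]:
    """Fit the selector once per stratified CV fold; record non-zero coefficients.

    For fold f the model is trained on the k-1 complementary folds (the fold
    itself is the held-out validation split). With ``keep_zero`` every
    feature's coefficient is recorded, which pins the selected feature set —
    used for the post-flow refit on grouped features.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    vids = train.variant_ids
    out: list[FoldSelection] = []
    for f, (train_idx, _val_idx) in enumerate(skf.split(train.values, train.y), start=1):
        est = spec.build_estimator(penalty_override=penalty_override)
        X, y = train.values[train_idx], train.y[train_idx]
        try:
            est.fit(X, y)
        except Exception:
            logger.warning("fold %d fit failed; retrying with larger iteration cap", f)
            est.set_params(max_iter=10 * MAX_ITER)
            est.fit(X, y)
        coefs = np.ravel(est.coef_)
        if keep_zero:
            fs = FoldSelection(fold=f)
            fs.coefficients = {v: float(c) for v, c in zip(vids, coefs)}
            out.append(fs)
        else:
            nz = np.nonzero(coefs)[0]
            out.append(FoldSelection(fold=f, coefficients={vids[i]: coefs[i] for i in nz}))
    return out


def _aligned(a: FoldSelection, b: FoldSelection) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Union-aligned coefficient vectors; absent variants contribute 0."""
    union = sorted(a.variant_ids | b.variant_ids)
    wa = np.array([a.coefficients.get(v, 0.0) for v in union])
    wb = np.array([b.coefficients.get(v, 0.0) for v in union])
    return union, wa, wb


def pearson_stability(a: FoldSelection, b: FoldSelection) -> float:
    """Pearson correlation of union-aligned coefficient vectors."""
    _, wa, wb = _aligned(a, b)
    if len(wa) < 2:
        logger.info("pearson undefined: fewer than 2 aligned variants")
        return UNDEFINED
    sa, sb = wa.std(), wb.std()
    if sa == 0.0 or sb == 0.0:
        logger.info("pearson undefined: zero variance in aligned coefficients")
        return UNDEFINED
    return float(np.corrcoef(wa, wb)[0, 1])


def kendall_tau_stability(a: FoldSelection, b: FoldSelection) -> float:
    """(P - Q) / (P + Q) over union-aligned rankings, ties broken by variant id.

    Variants are ranked by signed coefficient within each fold; because ties
    (including the zeros of unselected variants) are broken by the lexical
    order of the variant ids, every pair is either concordant or discordant.
    """
    union, wa, wb = _aligned(a, b)
    n = len(union)
    if n < 2:
        logger.info("kendall-tau undefined: fewer than 2 aligned variants")
        return UNDEFINED
    # sort key (coefficient, variant id) -> strict total order, no ties
    ra = _rank(union, wa)
    rb = _rank(union, wb)
    da = ra[:, None] - ra[None, :]
    db = rb[:, None] - rb[None, :]
    iu = np.triu_indices(n, k=1)
    concordant = (da[iu] * db[iu]) > 0
    P = int(concordant.sum())
    Q = concordant.size - P
    return (P - Q) / (P + Q)


def _rank(union: list[str], w: np.ndarray) -> np.ndarray:
    order = sorted(range(len(union)), key=lambda i: (w[i], union[i]))
    ranks = np.empty(len(union), dtype=int)
    for r, i in enumerate(order):
        ranks[i] = r
    return ranks


def jaccard_index(a: FoldSelection, b: FoldSelection) -> float:
    """|A and B| / |A or B| on the selected variant-id sets."""
    sa, sb = a.variant_ids, b.variant_ids
    if not sa and not sb:
        logger.info("jaccard of two empty selections: 1.0 by convention")
        return 1.0
    return len(sa & sb) / len(sa | sb)


def pairwise_stability_report(
    folds: list[FoldSelection], stage: str = "pre_flow"
) -> StabilityReport:
    """All k(k-1)/2 pairwise metrics, plus rank-scatter data for plotting.

    The rank scatter lists, for each fold pair, every variant selected in
    both folds with its |coefficient| rank (0 = largest) in each fold.
    """
    pairs: dict[tuple[int, int], PairMetrics] = {}
    scatter: dict[tuple[int, int], list[tuple[str, int, int]]] = {}
    for a, b in combinations(sorted(folds, key=lambda f: f.fold), 2):
        key = (a.fold, b.fold)
        pairs[key] = PairMetrics(
            pearson=pearson_stability(a, b),
            kendall_tau=kendall_tau_stability(a, b),
            jaccard=jaccard_index(a, b),
        )
        scatter[key] = _rank_scatter(a, b)
    return StabilityReport(stage=stage, pairs=pairs, rank_scatter=scatter)


def _rank_scatter(a: FoldSelection, b: FoldSelection) -> list[tuple[str, int, int]]:
    def mag_ranks(fs: FoldSelection) -> dict[str, int]:
        order = sorted(fs.coefficients, key=lambda v: (-abs(fs.coefficients[v]), v))
        return {v: r for r, v in enumerate(order)}

    ra, rb = mag_ranks(a), mag_ranks(b)
    return [(v, ra[v], rb[v]) for v in sorted(a.variant_ids & b.variant_ids)]
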