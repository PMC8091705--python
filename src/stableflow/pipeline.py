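"""End-to-end orchestration: selection, flow, grouping, re-training, experiments.

The core pipeline mirrors the full procedure: stratified 80/20 split,
k-fold sparse selection on the training set, pre-flow stability report,
LD flow network and node-disjoint path extraction, OR-grouping of each
path's variants into a single binary feature, refit on the grouped matrix,
post-flow stability report and held-out evaluation. Because the grouped
feature set is identical in every fold, the post-flow Jaccard index is
structurally 1.0; the interesting post-flow signal is in the Pearson and
Kendall-Tau agreement of the refit coefficients.

The simulation grid reruns the pipeline over synthetic matrices across
feature correlation levels, dimensionalities and model families, with
per-cell means and standard deviations over repeated random matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from .flownet import (
    StablePath,
    VariantGroup,
    build_ld_graph,
    decompose_paths,
    distinct_variants,
    extract_variant_groups,
    max_flow,
    to_flow_network,
)
from .io_formats import GenotypeMatrix, VariantKey
from .selection_stability import (
    FoldSelection,
    ModelSpec,
    StabilityReport,
    pairwise_stability_report,
    select_per_fold,
    split_train_test,
)
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class GroupedMatrix:
    """Samples x groups matrix with one column per stable variant group.

    For binary genotype matrices the column is the OR over the group's
    variants: 1 iff the sample carries at least one of them. For continuous
    simulated matrices the column is the mean of the member features — the
    region-level signal of a set of noisy feature copies.
    """

    values: np.ndarray
    sample_ids: list[str]
    groups: list[VariantGroup]
    labels: np.ndarray
    source_n_features: int
    encoding_mode: str = "binary"

    def as_genotype_matrix(self) -> GenotypeMatrix:
        """View the grouped matrix as a GenotypeMatrix (one pseudo-variant per group)."""
        variants = [
            VariantKey(chromosome="group", position=i + 1, ref="0", alt=g.group_id)
            for i, g in enumerate(self.groups)
        ]
        return GenotypeMatrix(
            values=self.values,
            sample_ids=list(self.sample_ids),
            variants=variants,
            labels=self.labels.copy(),
            encoding_mode=self.encoding_mode,
        )


@dataclass(frozen=True)
class EvaluationResult:
    precision: float
    recall: float
    auc_roc: float
    tp: int
    fp: int
    tn: int
    fn: int
    stage: str = "post_flow"


@dataclass
class PipelineResult:
    pre_report: StabilityReport
    folds: list[FoldSelection]
    paths: list[StablePath]
    groups: list[VariantGroup]
    post_report: StabilityReport | None
    grouped_train: GroupedMatrix | None
    grouped_test: GroupedMatrix | None
    flow_value: int
    train: GenotypeMatrix
    test: GenotypeMatrix

    @property
    def n_distinct_variants(self) -> int:
        return len(distinct_variants(self.groups))


def build_grouped_matrix(m: GenotypeMatrix, groups: list[VariantGroup]) -> GroupedMatrix:
    """Reduce each variant group to one column of the grouped matrix.

    Binary genotype matrices use the presence OR: 1 iff the sample carries
    at least one variant of the group. Continuous simulated matrices use the
    mean of the member columns, which denoises a group of noisy copies into
    one region-level feature.
    """
    index = {vid: i for i, vid in enumerate(m.variant_ids)}
    for g in groups:
        for vid in g.variant_ids:
            if vid not in index:
                raise KeyError(f"group {g.group_id} references unknown variant {vid}")
    if m.encoding_mode == "binary":
        cols = [
            m.values.astype(bool)[:, [index[vid] for vid in g.variant_ids]]
            .any(axis=1)
            .astype(np.int8)
            for g in groups
        ]
        empty_dtype = np.int8
    else:
        cols = [
            m.values[:, [index[vid] for vid in g.variant_ids]].mean(axis=1) for g in groups
        ]
        empty_dtype = float
    values = np.column_stack(cols) if cols else np.empty((m.n_samples, 0), dtype=empty_dtype)
    return GroupedMatrix(
        values=values,
        sample_ids=list(m.sample_ids),
        groups=list(groups),
        labels=m.labels.copy(),
        source_n_features=m.n_features,
        encoding_mode=m.encoding_mode,
    )


def run_core_pipeline(
    m: GenotypeMatrix,
    spec: ModelSpec,
    k: int = 5,
    threshold: float = 0.8,
    train_fraction: float = 0.8,
    split_seed: int = 0,
    cv_seed: int = 0,
    traversal_seed: int = 0,
) -> PipelineResult:
    """Full stability-selection pipeline on one matrix.

    The post-flow refit keeps the model family and lambda of ``spec`` but
    uses an L2 penalty, so every grouped feature retains a coefficient and
    the grouped feature set stays fixed across folds (hence Jaccard = 1).
    """
    train, test = split_train_test(m, train_fraction, seed=split_seed)
    folds = select_per_fold(train, spec, k=k, seed=cv_seed)
    pre_report = pairwise_stability_report(folds, stage="pre_flow")

    graph = build_ld_graph(folds, train, threshold)
    value, network = max_flow(to_flow_network(graph), traversal_seed=traversal_seed)
    paths = decompose_paths(network)
    groups = extract_variant_groups(paths)
    logger.info(
        "flow value %d; %d groups over %d distinct variants",
        value, len(groups), len(distinct_variants(groups)),
    )

    if not groups:
        logger.warning("maximum flow is 0: no stable groups; post-flow stage skipped")
        return PipelineResult(
            pre_report=pre_report, folds=folds, paths=paths, groups=groups,
            post_report=None, grouped_train=None, grouped_test=None,
            flow_value=value, train=train, test=test,
        )

    grouped_train = build_grouped_matrix(train, groups)
    grouped_test = build_grouped_matrix(test, groups)
    post_folds = _refit_grouped(grouped_train, spec, k=k, seed=cv_seed)
    post_report = pairwise_stability_report(post_folds, stage="post_flow")
    return PipelineResult(
        pre_report=pre_report, folds=folds, paths=paths, groups=groups,
        post_report=post_report, grouped_train=grouped_train, grouped_test=grouped_test,
        flow_value=value, train=train, test=test,
    )


def _refit_grouped(
    grouped: GroupedMatrix, spec: ModelSpec, k: int, seed: int
) -> list[FoldSelection]:
    gm = grouped.as_genotype_matrix()
    return select_per_fold(gm, spec, k=k, seed=seed, keep_zero=True, penalty_override="l2")


def evaluate_heldout(
    grouped_train: GroupedMatrix, grouped_test: GroupedMatrix, spec: ModelSpec
) -> EvaluationResult:
    """Train on the grouped training matrix, score on the grouped test matrix.

    Precision and recall treat case as the positive class; AUC-ROC uses the
    continuous decision score. A single-class test set yields NaN AUC.
    """
    est = spec.build_estimator(penalty_override="l2")
    y_train = (grouped_train.labels == "case").astype(int)
    y_test = (grouped_test.labels == "case").astype(int)
    est.fit(grouped_train.values, y_train)
    y_pred = est.predict(grouped_test.values)
    score = (
        est.decision_function(grouped_test.values)
        if hasattr(est, "decision_function")
        else est.predict_proba(grouped_test.values)[:, 1]
    )
    if len(set(y_test)) < 2:
        logger.warning("single-class test set: AUC-ROC undefined")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_test, score))
    tp = int(((y_pred == 1) & (y_test == 1)).sum())
    fp = int(((y_pred == 1) & (y_test == 0)).sum())
    tn = int(((y_pred == 0) & (y_test == 0)).sum())
    fn = int(((y_pred == 0) & (y_test == 1)).sum())
    return EvaluationResult(
        precision=float(precision_score(y_test, y_pred, zero_division=0)),
        recall=float(recall_score(y_test, y_pred, zero_division=0)),
        auc_roc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def _auc_full(train: GenotypeMatrix, test: GenotypeMatrix, spec: ModelSpec) -> float:
    """Pre-flow baseline AUC: the sparse model on the full feature set."""
    est = spec.build_estimator()
    est.fit(train.values, train.y)
    score = (
        est.decision_function(test.values)
        if hasattr(est, "decision_function")
        else est.predict_proba(test.values)[:, 1]
    )
    if len(set(test.y)) < 2:
        return float("nan")
    return float(roc_auc_score(test.y, score))


@dataclass(frozen=True)
class GridCell:
    name: str
    sim: SimulationConfig
    model: ModelSpec


@dataclass
class ExperimentGrid:
    cells: list[GridCell]
    repeats: int = 20

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def default_grid(repeats: int = 20, n_samples: int = 500) -> ExperimentGrid:
    """The validation grid: correlation sweep at 1000 features and a
    dimensionality sweep at 50% correlation, for three model families.

    Regularization strengths: lambda = 10 for L1 models; elastic-net logistic
    uses lambda = 100 in the correlation sweep and lambda = 1000 in the
    dimensionality sweep.
    """
    models_corr = [
        ("l1_logistic", ModelSpec("logistic_regression", "l1", 10.0)),
        ("en_logistic", ModelSpec("logistic_regression", "elastic_net", 100.0)),
        ("l1_svc", ModelSpec("linear_svc", "l1", 10.0)),
    ]
    models_dim = [
        ("l1_logistic", ModelSpec("logistic_regression", "l1", 10.0)),
        ("en_logistic", ModelSpec("logistic_regression", "elastic_net", 1000.0)),
        ("l1_svc", ModelSpec("linear_svc", "l1", 10.0)),
    ]
    cells = []
    for corr in (0.2, 0.5, 0.8):
        for mname, mspec in models_corr:
            cells.append(
                GridCell(
                    name=f"corr{int(corr * 100)}_{mname}",
                    sim=SimulationConfig(
                        n_samples=n_samples, n_features=1000, correlation_level=corr
                    ),
                    model=mspec,
                )
            )
    for n_feat in (1000, 2000, 5000):
        for mname, mspec in models_dim:
            cells.append(
                GridCell(
                    name=f"dim{n_feat}_{mname}",
                    sim=SimulationConfig(
                        n_samples=n_samples, n_features=n_feat, correlation_level=0.5
                    ),
                    model=mspec,
                )
            )
    return ExperimentGrid(cells=cells, repeats=20 if repeats is None else repeats)


def run_cell_once(
    sim: SimulationConfig, model: ModelSpec, seed: int, k: int = 5, threshold: float = 0.8
) -> dict[str, float]:
    """One repeat of one grid cell; returns pre/post metrics for that matrix."""
    cfg = SimulationConfig(
        n_samples=sim.n_samples,
        n_features=sim.n_features,
        n_informative=sim.n_informative,
        correlation_level=sim.correlation_level,
        noise_sd=sim.noise_sd,
        n_chromosome_groups=sim.n_chromosome_groups,
        class_balance=sim.class_balance,
        seed=seed,
    )
    m = simulate(cfg)
    res = run_core_pipeline(
        m, model, k=k, threshold=threshold,
        split_seed=seed, cv_seed=seed, traversal_seed=seed,
    )
    pre = res.pre_report.summary()
    out = {
        "flow_value": float(res.flow_value),
        "n_distinct_variants": float(res.n_distinct_variants),
        "pre_pearson": pre["pearson"]["mean"],
        "pre_kendall_tau": pre["kendall_tau"]["mean"],
        "pre_jaccard": pre["jaccard"]["mean"],
        "pre_auc": _auc_full(res.train, res.test, model),
    }
    if res.post_report is not None:
        post = res.post_report.summary()
        ev = evaluate_heldout(res.grouped_train, res.grouped_test, model)
        out.update(
            post_pearson=post["pearson"]["mean"],
            post_kendall_tau=post["kendall_tau"]["mean"],
            post_jaccard=post["jaccard"]["mean"],
            post_auc=ev.auc_roc,
            post_precision=ev.precision,
            post_recall=ev.recall,
        )
    else:
        out.update(
            post_pearson=float("nan"), post_kendall_tau=float("nan"),
            post_jaccard=float("nan"), post_auc=float("nan"),
            post_precision=float("nan"), post_recall=float("nan"),
        )
    return out


def run_simulation_grid(grid: ExperimentGrid, seed: int = 0, k: int = 5) -> "pd.DataFrame":
    """Run every cell of the grid; per-cell mean and sd over the repeats.

    A failing repeat is recorded (NaN row) and the grid continues.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for cell in grid.cells:
        per_repeat = []
        for rep in range(grid.repeats):
            rep_seed = int(rng.integers(2**31))
            try:
                per_repeat.append(run_cell_once(cell.sim, cell.model, seed=rep_seed, k=k))
            except Exception:
                logger.exception("cell %s repeat %d failed; continuing", cell.name, rep)
        if not per_repeat:
            rows.append({"cell": cell.name, "n_ok": 0})
            continue
        df = pd.DataFrame(per_repeat)
        row: dict[str, float | str | int] = {"cell": cell.name, "n_ok": len(per_repeat)}
        for col in df.columns:
            row[f"{col}_mean"] = float(np.nanmean(df[col]))
            row[f"{col}_sd"] = float(np.nanstd(df[col]))
        rows.append(row)
    return pd.DataFrame(rows)


def ordering_sensitivity(
    folds: list[FoldSelection],
    m: GenotypeMatrix,
    threshold: float = 0.8,
    orderings: list[list[int]] | None = None,
    seed: int = 0,
) -> dict:
    """Fold-ordering sensitivity of the extracted variant set.

    For each ordering of the folds the graph is re-layered, flow re-run, and
    the distinct-variant set extracted; reported are the flow values and the
    mean pairwise shared-variant count between orderings.
    """
    fold_ids = sorted(fs.fold for fs in folds)
    if orderings is None:
        orderings = [list(p) for p in permutations(fold_ids)]
    for o in orderings:
        if sorted(o) != fold_ids:
            raise ValueError(f"ordering {o} is not a permutation of {fold_ids}")
    rng = np.random.default_rng(seed)
    variant_sets: list[set[str]] = []
    flow_values: list[int] = []
    for order in orderings:
        g = build_ld_graph(folds, m, threshold, fold_order=order)
        value, network = max_flow(to_flow_network(g), traversal_seed=int(rng.integers(2**31)))
        groups = extract_variant_groups(decompose_paths(network))
        variant_sets.append({v.id for v in distinct_variants(groups)})
        flow_values.append(value)
    overlaps = [len(a & b) for a, b in combinations(variant_sets, 2)]
    return {
        "orderings": [list(o) for o in orderings],
        "flow_values": flow_values,
        "variant_sets": variant_sets,
        "mean_pairwise_shared_variants": float(np.mean(overlaps)) if overlaps else float("nan"),
    }
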