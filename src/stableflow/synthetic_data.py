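"""Synthetic 2-class feature matrices with chromosome-grouped correlated features.

The generator reproduces the statistical structure used to validate the
flow-based stability method, not population-genetic realism:

1. a base hypercube-cluster classification dataset (class-dependent cluster
   centres at hypercube vertices with unit-variance Gaussian scatter, small
   per-feature effect sizes, approximately balanced classes);
2. a random partition of the features into chromosome groups (default 23);
3. linkage-disequilibrium-like correlation injected *within* groups: each
   feature, independently with probability ``p``, is replaced by a copy of
   another feature from the same group plus Gaussian noise.

With features standardized to unit variance and ``noise_sd`` = 0.1, a copied
feature has squared correlation about 1/(1 + noise_sd^2) ~ 0.99 with its
source, comfortably above the 0.8 LD threshold used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.datasets import make_classification

from .io_formats import CASE, CONTROL, GenotypeMatrix, VariantKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``correlation_level`` is the probability p that a feature is replaced by
    a noisy copy of a same-group feature; ``n_informative`` defaults to 5%
    of the features when left as None.
    """

    n_samples: int = 500
    n_features: int = 1000
    n_informative: int | None = None
    correlation_level: float = 0.5
    noise_sd: float = 0.1
    n_chromosome_groups: int = 23
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be positive")
        if not 0.0 <= self.correlation_level <= 1.0:
            raise ValueError("correlation_level must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.n_chromosome_groups > self.n_features:
            raise ValueError("n_chromosome_groups cannot exceed n_features")
        if self.informative_count < 1:
            raise ValueError("need at least one informative feature")
        if self.informative_count > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")

    @property
    def informative_count(self) -> int:
        if self.n_informative is not None:
            return self.n_informative
        return max(1, round(0.05 * self.n_features))


def assign_chromosome_groups(n_features: int, n_groups: int, seed: int) -> np.ndarray:
    """Randomly partition features into ``n_groups`` non-empty groups.

    Returns an integer group label in [0, n_groups) per feature. Group sizes
    are arbitrary (multinomial around equal shares) but never zero.
    """
    if n_groups > n_features:
        raise ValueError("n_groups cannot exceed n_features")
    if n_groups < 1:
        raise ValueError("n_groups must be positive")
    rng = np.random.default_rng(seed)
    # guarantee non-emptiness: seed one feature per group, distribute the rest
    labels = np.concatenate(
        [np.arange(n_groups), rng.integers(0, n_groups, size=n_features - n_groups)]
    )
    rng.shuffle(labels)
    return labels.astype(int)


def generate_base_dataset(cfg: SimulationConfig) -> GenotypeMatrix:
    """Hypercube-cluster classification matrix with planted informative features.

    Exactly ``cfg.informative_count`` columns carry class signal; the rest
    are label-independent Gaussian noise. All columns are standardized to
    zero mean and unit variance. The returned matrix is in continuous mode;
    each column gets a VariantKey whose chromosome is its group label.
    """
    n_inf = cfg.informative_count
    X, y = make_classification(
        n_samples=cfg.n_samples,
        n_features=cfg.n_features,
        n_informative=n_inf,
        n_redundant=0,
        n_repeated=0,
        n_clusters_per_class=1,
        weights=[1 - cfg.class_balance],
        class_sep=1.0,
        hypercube=True,
        flip_y=0.0,
        shuffle=False,  # keep informative columns first; rows reshuffled below
        random_state=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(cfg.n_samples)
    X, y = X[order], y[order]
    # unit variance so copy-noise translates directly into a known R^2
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    groups = assign_chromosome_groups(cfg.n_features, cfg.n_chromosome_groups, cfg.seed)
    variants = _variants_for_groups(groups)
    labels = np.where(y == 1, CASE, CONTROL).astype(object)
    sample_ids = [f"S{i:05d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(X, sample_ids, variants, labels, encoding_mode="continuous")


def _variants_for_groups(groups: np.ndarray) -> list[VariantKey]:
    # position = 1-based feature index so ids stay unique within a chromosome
    return [
        VariantKey(chromosome=str(int(g) + 1), position=i + 1, ref="A", alt="T")
        for i, g in enumerate(groups)
    ]


def inject_group_correlation(
    m: GenotypeMatrix,
    groups: np.ndarray,
    p: float,
    noise_sd: float,
    seed: int,
) -> GenotypeMatrix:
    """Replace each feature, with probability p, by a noisy same-group copy.

    Copy sources are drawn uniformly among the *other* members of the
    feature's group and always read from the pre-injection matrix, so chains
    of copies do not compound noise. A feature selected for copying inside a
    singleton group is left untouched and logged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    groups = np.asarray(groups)
    if len(groups) != m.n_features:
        raise ValueError("group labels must match feature count")
    rng = np.random.default_rng(seed)
    base = m.values
    out = base.copy()
    to_copy = rng.random(m.n_features) < p
    for j in np.nonzero(to_copy)[0]:
        members = np.nonzero(groups == groups[j])[0]
        others = members[members != j]
        if len(others) == 0:
            logger.info("feature %d is alone in its group; skipping copy", j)
            continue
        src = rng.choice(others)
        out[:, j] = base[:, src] + rng.normal(0.0, noise_sd, size=m.n_samples)
    return GenotypeMatrix(
        out, list(m.sample_ids), list(m.variants), m.labels.copy(), encoding_mode="continuous"
    )


def simulate(cfg: SimulationConfig) -> GenotypeMatrix:
    """Full generator: base hypercube dataset + within-group correlation."""
    base = generate_base_dataset(cfg)
    groups = np.array([int(v.chromosome) - 1 for v in base.variants])
    return inject_group_correlation(
        base, groups, cfg.correlation_level, cfg.noise_sd, seed=cfg.seed + 1
    )
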