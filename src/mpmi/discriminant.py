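"""Functional discriminant analysis of EC abundance profiles.

The pipeline that separates treatment groups by microbiome *function*:

1. train a random-forest classifier on the normalized EC abundances
   (defaults: ``mtry`` = 2 candidate features per split, 10,000 trees);
2. rank every EC by *mean decrease in accuracy* — for each tree, permute
   the feature's values over the tree's out-of-bag samples and record the
   drop in OOB accuracy, averaged over trees (the classic permutation
   importance of Breiman's random forest);
3. truncate to the 30 most important ECs and retrain on that reduced panel
   to limit overfitting;
4. assess robustness with an ensemble of models trained on independent
   random 60% subsets and scored on the held-out complement;
5. embed samples in 2-D by local Fisher discriminant analysis (LFDA) on
   the truncated panel;
6. aggregate EC importances up to KEGG pathways, signed by the direction
   of enrichment relative to the control class.

LFDA (Sugiyama, 2007) maximizes between-class scatter against within-class
scatter, both weighted by a local-scaling affinity so multimodal classes
are not collapsed.  It is implemented here directly on the weighted
scatter matrices with a generalized symmetric eigensolver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier

def _oob_indices(tree_seed: int, n_samples: int) -> np.ndarray:
    """Out-of-bag row indices of a tree, reproducing sklearn's bootstrap
    draw (uniform sampling with replacement, n draws, tree-seeded)."""
    rng = np.random.RandomState(tree_seed)
    sampled = rng.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


class DiscriminantError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest / truncation parameters.

    ``mtry`` is deliberately small (2) — it is kept at the published value
    even for 30-feature panels; override if you want sqrt(p) behavior.
    """

    mtry: int = 2
    n_trees: int = 10_000
    truncation_size: int = 30
    subsample_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtry < 1 or self.n_trees < 1 or self.truncation_size < 1:
            raise DiscriminantError("mtry, n_trees, truncation_size must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise DiscriminantError("subsample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FeatureRanking:
    ec_id: str
    importance: float  # mean decrease in OOB accuracy
    rank: int  # 1 = most important


@dataclass(frozen=True)
class EmbeddingResult:
    sample_id: str
    coords: tuple[float, float]
    class_label: str


@dataclass
class TruncatedModel:
    model: RandomForestClassifier
    retained_features: list[str]
    oob_accuracy: float


@dataclass
class EnsembleReport:
    holdout_accuracies: list[float]
    selection_frequency: pd.Series  # per EC, fraction of models retaining it
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.holdout_accuracies))


def _as_xy(matrix, labels) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    df = matrix.abundance if hasattr(matrix, "abundance") else matrix
    y = pd.Series(labels, index=df.index) if not isinstance(labels, pd.Series) else labels
    y = y.loc[df.index]
    X = np.ascontiguousarray(df.to_numpy(dtype=np.float32))
    return X, y.to_numpy(), list(df.columns), [str(s) for s in df.index]


def _validate_classes(y: np.ndarray, min_per_class: int = 3) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DiscriminantError("need at least 2 classes")
    if (counts < min_per_class).any():
        raise DiscriminantError(
            f"every class needs >= {min_per_class} samples; got {dict(zip(classes, counts))}"
        )


def _fit_forest(X: np.ndarray, y: np.ndarray, config: ClassifierConfig) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.mtry, X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def mean_decrease_in_accuracy(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Per-feature mean decrease in OOB accuracy over the forest's trees.

    For each tree: score its out-of-bag samples, then rescore them with one
    feature's OOB values permuted (one fresh permutation per tree and
    feature), and average the accuracy drops over all trees.
    """
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    classes = forest.classes_
    y_codes = np.searchsorted(classes, y)
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    used = 0
    for tree in forest.estimators_:
        oob = _oob_indices(tree.random_state, n)
        if len(oob) == 0:
            continue
        used += 1
        Xo = X32[oob]
        yo = y_codes[oob]
        m = len(oob)
        base_codes = np.argmax(tree.tree_.predict(Xo).reshape(m, -1), axis=1)
        base_acc = float(np.mean(base_codes == yo))
        # one stacked prediction per tree: block j has feature j permuted
        stacked = np.tile(Xo, (p, 1))
        for j in range(p):
            perm = rng.permutation(m)
            stacked[j * m : (j + 1) * m, j] = Xo[perm, j]
        pred = np.argmax(
            tree.tree_.predict(stacked).reshape(p * m, -1), axis=1
        ).reshape(p, m)
        drops += base_acc - np.mean(pred == yo[None, :], axis=1)
    if used == 0:
        raise DiscriminantError("no tree had out-of-bag samples")
    return drops / used


def rank_features(matrix, labels, config: ClassifierConfig) -> list[FeatureRanking]:
    """Rank every EC by mean decrease in accuracy, descending.

    Ties are broken lexicographically by EC id, so the ranking is a
    deterministic function of (matrix, labels, config).
    """
    X, y, feature_ids, _ = _as_xy(matrix, labels)
    _validate_classes(y)
    if np.allclose(X, X[0:1, :]):
        raise DiscriminantError("constant feature matrix")
    forest = _fit_forest(X, y, config)
    importance = mean_decrease_in_accuracy(forest, X, y, seed=config.seed)
    order = sorted(range(len(feature_ids)), key=lambda j: (-importance[j], feature_ids[j]))
    return [
        FeatureRanking(ec_id=feature_ids[j], importance=float(importance[j]), rank=r + 1)
        for r, j in enumerate(order)
    ]


def truncate_and_retrain(
    matrix, labels, ranking: list[FeatureRanking], config: ClassifierConfig
) -> TruncatedModel:
    """Keep the ``truncation_size`` top-ranked features and retrain."""
    df = matrix.abundance if hasattr(matrix, "abundance") else matrix
    ranked_ids = [r.ec_id for r in sorted(ranking, key=lambda r: r.rank)]
    missing = set(df.columns) - set(ranked_ids)
    if missing:
        raise DiscriminantError(f"ranking does not cover features: {sorted(missing)[:5]}")
    if config.truncation_size > len(ranked_ids):
        raise DiscriminantError(
            f"truncation_size {config.truncation_size} > {len(ranked_ids)} features"
        )
    retained = ranked_ids[: config.truncation_size]
    X, y, _, _ = _as_xy(df[retained], labels)
    forest = _fit_forest(X, y, config)
    return TruncatedModel(
        model=forest, retained_features=retained, oob_accuracy=float(forest.oob_score_)
    )


def ensemble_validate(
    matrix,
    labels,
    config: ClassifierConfig,
    n_models: int = 10,
    seeds: list[int] | None = None,
) -> EnsembleReport:
    """Robustness check: independent models on random subsets.

    Each model draws a stratified ``subsample_fraction`` training subset,
    runs the rank → truncate → retrain pipeline on it, and is scored on
    the held-out complement.  Also reports, per EC, the fraction of models
    that kept it in their truncated panel.
    """
    if n_models < 2:
        raise DiscriminantError("n_models must be >= 2")
    df = matrix.abundance if hasattr(matrix, "abundance") else matrix
    y_all = pd.Series(labels, index=df.index) if not isinstance(labels, pd.Series) else labels
    if seeds is None:
        seeds = [config.seed + 1000 * (i + 1) for i in range(n_models)]
    if len(seeds) != n_models:
        raise DiscriminantError("len(seeds) must equal n_models")

    accs: list[float] = []
    selections = pd.Series(0.0, index=df.columns)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        train_idx: list[int] = []
        positions = np.arange(len(df))
        for cls in np.unique(y_all):
            pos = positions[(y_all == cls).to_numpy()]
            k = max(1, int(round(config.subsample_fraction * len(pos))))
            train_idx.extend(rng.choice(pos, size=k, replace=False))
        train_mask = np.zeros(len(df), dtype=bool)
        train_mask[train_idx] = True
        if not (~train_mask).any():
            raise DiscriminantError("subsample leaves an empty test set")
        sub_cfg = ClassifierConfig(
            mtry=config.mtry,
            n_trees=config.n_trees,
            truncation_size=min(config.truncation_size, df.shape[1]),
            subsample_fraction=config.subsample_fraction,
            seed=seed,
        )
        train_df, test_df = df.iloc[train_mask], df.iloc[~train_mask]
        ranking = rank_features(train_df, y_all.iloc[train_mask], sub_cfg)
        model = truncate_and_retrain(train_df, y_all.iloc[train_mask], ranking, sub_cfg)
        selections[model.retained_features] += 1.0
        X_test = np.ascontiguousarray(
            test_df[model.retained_features].to_numpy(dtype=np.float32)
        )
        pred = model.model.predict(X_test)
        accs.append(float(np.mean(pred == y_all.iloc[~train_mask].to_numpy())))
    return EnsembleReport(
        holdout_accuracies=accs, selection_frequency=selections / n_models
    )


# ------------------------------------------------------------------- LFDA

def _local_scaling_affinity(X: np.ndarray, knn: int = 7) -> np.ndarray:
    """Affinity with per-point local scaling: sigma_i = distance to the
    knn-th neighbor (or the farthest point when fewer exist)."""
    d2 = np.square(X[:, None, :] - X[None, :, :]).sum(axis=2)
    d = np.sqrt(d2)
    n = len(X)
    sigma = np.empty(n)
    for i in range(n):
        others = np.sort(d[i][np.arange(n) != i])
        if len(others) == 0:
            sigma[i] = 1.0
        else:
            sigma[i] = others[min(knn, len(others)) - 1]
    sigma[sigma == 0] = 1e-12
    return np.exp(-d2 / np.outer(sigma, sigma))


def lfda_scatter_matrices(
    X: np.ndarray, y: np.ndarray, knn: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Local within-class and between-class weighted scatter matrices."""
    n, d = X.shape
    W_w = np.zeros((n, n))
    W_b = np.full((n, n), 1.0 / n)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        nc = len(idx)
        A = _local_scaling_affinity(X[idx], knn=knn)
        W_w[np.ix_(idx, idx)] = A / nc
        W_b[np.ix_(idx, idx)] = A * (1.0 / n - 1.0 / nc)

    def scatter(W: np.ndarray) -> np.ndarray:
        D = np.diag(W.sum(axis=1))
        L = D - W
        return X.T @ L @ X

    return scatter(W_w), scatter(W_b)


def lfda_embed(
    matrix,
    labels,
    retained_features: list[str] | None = None,
    embedding_rank: int = 2,
    knn: int = 7,
    regularization: float = 1e-9,
) -> list[EmbeddingResult]:
    """Project samples onto the top LFDA discriminant coordinates.

    The transform is fit on the (centered) truncated feature submatrix;
    eigenvectors of the generalized problem S_b v = lambda S_w v are
    weighted by sqrt(max(lambda, 0)) so that more discriminative axes
    stretch further (the convention of the reference R implementation).
    Component signs are fixed by making each axis's largest-magnitude
    loading positive.
    """
    df = matrix.abundance if hasattr(matrix, "abundance") else matrix
    if retained_features is not None:
        df = df[retained_features]
    y = (pd.Series(labels, index=df.index) if not isinstance(labels, pd.Series) else labels).loc[df.index]
    if len(np.unique(y)) < 2:
        raise DiscriminantError("need at least 2 classes")
    if len(df) < embedding_rank + 1:
        raise DiscriminantError("fewer samples than embedding rank + 1")
    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    S_w, S_b = lfda_scatter_matrices(X, y.to_numpy(), knn=knn)
    S_w = S_w + regularization * np.trace(S_w) / max(X.shape[1], 1) * np.eye(X.shape[1])
    S_w = S_w + regularization * np.eye(X.shape[1])
    eigvals, eigvecs = linalg.eigh(S_b, S_w)
    order = np.argsort(eigvals)[::-1][:embedding_rank]
    V = eigvecs[:, order] * np.sqrt(np.maximum(eigvals[order], 0.0))[None, :]
    for k in range(V.shape[1]):  # deterministic sign
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    Z = X @ V
    if not np.isfinite(Z).all():
        raise DiscriminantError("non-finite embedding coordinates")
    return [
        EmbeddingResult(
            sample_id=str(s), coords=(float(Z[i, 0]), float(Z[i, 1])), class_label=str(y.iloc[i])
        )
        for i, s in enumerate(df.index)
    ]


def pathway_importance(
    ranking: list[FeatureRanking],
    pathway_annotation: dict[str, list[str]],
    matrix=None,
    labels=None,
    control_label: str | None = None,
) -> pd.Series:
    """Aggregate EC importances up to KEGG pathways.

    Each EC contributes its importance to each of its (<= 5) annotated
    pathways in full — mirroring the sum-regrouping policy of the profiling
    stage.  When ``matrix``/``labels``/``control_label`` are given, each
    EC's contribution is signed by its direction of enrichment relative to
    the control class (control baseline at 0): positive when the non-control
    class mean abundance is higher.
    """
    if not ranking:
        raise DiscriminantError("empty ranking")
    signs: dict[str, float] = {}
    if matrix is not None and labels is not None and control_label is not None:
        df = matrix.abundance if hasattr(matrix, "abundance") else matrix
        y = pd.Series(labels, index=df.index) if not isinstance(labels, pd.Series) else labels
        ctrl = df[(y == control_label).to_numpy()].mean(axis=0)
        trt = df[(y != control_label).to_numpy()].mean(axis=0)
        diff = trt - ctrl
        signs = {ec: (1.0 if diff.get(ec, 0) >= 0 else -1.0) for ec in df.columns}
    totals: dict[str, float] = {}
    for r in ranking:
        for pw in pathway_annotation.get(r.ec_id, [])[:5]:
            totals[pw] = totals.get(pw, 0.0) + r.importance * signs.get(r.ec_id, 1.0)
    if not totals:
        return pd.Series(dtype=float)
    out = pd.Series(totals).sort_values(ascending=False)
    out.index.name = "pathway"
    return out
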