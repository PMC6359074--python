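"""Random-forest discrimination with OOB tuning and permutation importance.

Implements the classical bagged-CART forest workflow for small-n, large-p
metabolite tables: bootstrap resampling per tree, Gini-impurity CART trees
grown to purity with ``mtry`` candidate features per split, out-of-bag (OOB)
error as the internal test error, OOB permutation importance (mean decrease
in accuracy, raw and SD-scaled), OOB tuning of ``mtry`` over a grid, and
Ward clustering of the top-ranked metabolites for heat-map display.

Individual trees are sklearn CART estimators; the bagging loop, OOB
bookkeeping, importance and tuning policies are implemented here so that
every step of the OOB computation is explicit and reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.tree import DecisionTreeClassifier

from .io import AbundanceTable


@dataclass
class RfConfig:
    """Forest hyperparameters: tree count, candidate-feature grid, seed."""

    ntree: int = 1000
    mtry_grid: tuple[int, ...] = (5, 18, 100, 250, 350)
    mtry_selected: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if any(m < 1 for m in self.mtry_grid):
            raise ValueError("every mtry must be >= 1")


@dataclass
class RfFit:
    """A fitted forest with its OOB diagnostics.

    ``importance`` has columns raw (mean decrease in OOB accuracy over
    trees) and scaled (raw divided by its standard error over trees);
    rankings use the scaled column.
    """

    classes: list[str]
    oob_error: float
    per_class_error: dict[str, float]
    confusion: pd.DataFrame
    oob_votes: pd.DataFrame
    importance: pd.DataFrame | None = None
    config: RfConfig = field(default_factory=RfConfig)
    trees: list[DecisionTreeClassifier] = field(default_factory=list, repr=False)
    oob_masks: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)
    feature_names: list[str] = field(default_factory=list, repr=False)


def _validate(table: AbundanceTable, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(labels)
    if list(labels.index) != list(table.sample_ids):
        labels = labels.reindex(table.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.astype(str).values
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise ValueError(f"classes with a single sample (OOB undefined): {small}")
    return table.values.values.astype(float), y


def fit_forest(table: AbundanceTable, labels: pd.Series, config: RfConfig) -> RfFit:
    """Grow a bagged ensemble and compute OOB error and per-class error.

    Each tree is trained on a bootstrap resample; a sample's OOB prediction
    is the majority vote over the trees whose bootstrap excluded it, so no
    validation set is needed. Deterministic for a fixed ``config.seed``.
    """
    X, y = _validate(table, labels)
    n, p = X.shape
    mtry = config.mtry_selected if config.mtry_selected is not None else max(
        1, int(math.isqrt(p))
    )
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds number of metabolites p={p}")
    classes = sorted(set(y))
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[c] for c in y])

    rng = np.random.default_rng(config.seed)
    trees: list[DecisionTreeClassifier] = []
    oob_masks = np.zeros((config.ntree, n), dtype=bool)
    votes = np.zeros((n, len(classes)))
    for t in range(config.ntree):
        boot = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        oob_masks[t] = oob
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y_idx[boot])
        trees.append(tree)
        if oob.any():
            pred = tree.predict(X[oob]).astype(int)
            votes[np.where(oob)[0], pred] += 1

    has_vote = votes.sum(axis=1) > 0
    oob_pred = votes.argmax(axis=1)
    err = float(np.mean(oob_pred[has_vote] != y_idx[has_vote]))
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for i in np.where(has_vote)[0]:
        confusion.loc[classes[y_idx[i]], classes[oob_pred[i]]] += 1
    per_class = {
        c: float(
            1.0 - confusion.loc[c, c] / confusion.loc[c].sum()
            if confusion.loc[c].sum() > 0
            else np.nan
        )
        for c in classes
    }
    frac = votes / np.clip(votes.sum(axis=1, keepdims=True), 1, None)
    oob_votes = pd.DataFrame(frac, index=table.sample_ids, columns=classes)
    return RfFit(
        classes=classes,
        oob_error=err,
        per_class_error=per_class,
        confusion=confusion,
        oob_votes=oob_votes,
        config=config,
        trees=trees,
        oob_masks=oob_masks,
        _X=X,
        _y=y_idx,
        feature_names=table.metabolite_ids,
    )


def permutation_importance(fit: RfFit, seed: int | None = None) -> pd.DataFrame:
    """OOB permutation importance (mean decrease in accuracy) per metabolite.

    For each tree and each feature the tree uses, the tree's OOB accuracy is
    recomputed after shuffling that feature's values among the tree's OOB
    samples; the per-tree decrease is averaged over trees (raw) and divided
    by its standard error (scaled). Features a tree never splits on
    contribute an exact zero for that tree.
    """
    X, y = fit._X, fit._y
    if X is None or fit.oob_masks is None:
        raise ValueError("fit does not retain trees/OOB membership")
    n, p = X.shape
    ntree = len(fit.trees)
    rng = np.random.default_rng(fit.config.seed + 17 if seed is None else seed)
    decrease = np.zeros((ntree, p))
    for t, tree in enumerate(fit.trees):
        oob = fit.oob_masks[t]
        m = int(oob.sum())
        if m == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base_acc = float(np.mean(tree.predict(X_oob).astype(int) == y_oob))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if len(used) == 0:
            continue
        # One batched predict over all used features' permuted copies.
        block = np.repeat(X_oob[None, :, :], len(used), axis=0)
        for k, j in enumerate(used):
            block[k, :, j] = X_oob[rng.permutation(m), j]
        preds = tree.predict(block.reshape(-1, p)).astype(int).reshape(len(used), m)
        acc = (preds == y_oob[None, :]).mean(axis=1)
        decrease[t, used] = base_acc - acc
    raw = decrease.mean(axis=0)
    sd = decrease.std(axis=0, ddof=0)
    se = sd / math.sqrt(ntree)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(se > 0, raw / se, 0.0)
    out = pd.DataFrame(
        {"raw": raw, "scaled": scaled}, index=fit.feature_names
    ).sort_values("scaled", ascending=False)
    return out


def tune_mtry(table: AbundanceTable, labels: pd.Series, config: RfConfig) -> RfConfig:
    """Pick the grid value with the lowest OOB error.

    One forest per grid value, each seeded from the base seed plus the grid
    position. Ties go to the value nearest floor(sqrt(p)), the classical
    default for the candidate-feature count.
    """
    p = table.n_metabolites
    for m in config.mtry_grid:
        if m > p:
            raise ValueError(f"grid value mtry={m} exceeds p={p}")
    anchor = int(math.isqrt(p))
    results = []
    for offset, m in enumerate(config.mtry_grid):
        sub = RfConfig(
            ntree=config.ntree,
            mtry_grid=config.mtry_grid,
            mtry_selected=m,
            seed=config.seed + offset,
        )
        fit = fit_forest(table, labels, sub)
        results.append((m, fit.oob_error))
    best_err = min(e for _, e in results)
    tied = [m for m, e in results if e == best_err]
    chosen = min(tied, key=lambda m: (abs(m - anchor), m))
    return RfConfig(
        ntree=config.ntree,
        mtry_grid=config.mtry_grid,
        mtry_selected=chosen,
        seed=config.seed,
    )


def extreme_class_subset(
    table: AbundanceTable, meta: list, classes: tuple[str, str] = ("N_gt_HF", "N_lt_HF")
) -> tuple[AbundanceTable, pd.Series]:
    """Restrict to the two extreme reaction-norm classes for the phenotype contrast."""
    keep = [m.sample_id for m in meta if m.reaction_norm in classes]
    labels = pd.Series(
        {m.sample_id: m.reaction_norm for m in meta if m.reaction_norm in classes}
    )
    sub = table.subset_samples(keep)
    return sub, labels.loc[sub.sample_ids]


@dataclass
class WardClustering:
    """Two-axis Ward clustering of a z-scored metabolite block."""

    zscores: pd.DataFrame
    metabolite_linkage: np.ndarray
    sample_linkage: np.ndarray
    metabolite_order: list[str]
    sample_order: list[str]
    metabolite_clusters: dict[str, int]
    sample_clusters: dict[str, int]


def top_k_and_ward(
    table: AbundanceTable,
    importance: pd.DataFrame,
    k: int = 10,
    n_clusters: int = 3,
) -> WardClustering:
    """Ward-cluster the top-k metabolites by scaled importance, on both axes.

    The selected metabolites' log abundances are z-scored across samples;
    Ward agglomeration on Euclidean distance orders metabolites and samples
    for heat-map layout and cuts each axis into ``n_clusters`` groups.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > table.n_metabolites:
        raise ValueError("k exceeds number of metabolites")
    top = list(importance.sort_values("scaled", ascending=False).index[:k])
    block = table.values[top]
    sd = block.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn("zero-variance metabolites z-scored to 0", stacklevel=2)
    z = (block - block.mean(axis=0)) / sd.replace(0, 1.0)

    def cluster(mat: np.ndarray, names: list[str]):
        d = pdist(mat, metric="euclidean")
        if np.allclose(d, 0):
            warnings.warn("degenerate zero-distance clustering input", stacklevel=3)
        link = hierarchy.ward(d)
        order = [names[i] for i in hierarchy.leaves_list(link)]
        cut = hierarchy.fcluster(link, t=min(n_clusters, len(names)), criterion="maxclust")
        return link, order, {nm: int(c) for nm, c in zip(names, cut)}

    m_link, m_order, m_clust = cluster(z.values.T, top)
    s_link, s_order, s_clust = cluster(z.values, list(z.index))
    return WardClustering(
        zscores=z,
        metabolite_linkage=m_link,
        sample_linkage=s_link,
        metabolite_order=m_order,
        sample_order=s_order,
        metabolite_clusters=m_clust,
        sample_clusters=s_clust,
    )
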