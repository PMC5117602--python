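"""Joint-modeling classifiers: discriminant analysis of principal
components (DAPC) with a-score axis selection, cross-validated accuracy
against a twin-aware permutation null, and random forests with optional
per-tree balanced down-sampling.

DAPC reduces the feature matrix by PCA and runs linear discriminant
analysis on the retained scores, predicting by nearest group centroid in
discriminant space (uniform priors). The number of retained PCs is chosen
by the a-score: observed reassignment success minus its mean over
label-permuted refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.tree import DecisionTreeClassifier

from .permutation import PermutationPlan, empirical_p, permute_phenotypes

MAX_DISCRIMINANT_AXES = 100


@dataclass
class DapcModel:
    mean: np.ndarray
    components: np.ndarray      # (p, n_pcs)
    lda: LinearDiscriminantAnalysis
    n_pcs: int
    classes: np.ndarray
    training_accuracy: float

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, float) - self.mean) @ self.components

    def predict(self, data: np.ndarray) -> np.ndarray:
        return self.lda.predict(self.transform(data))


def dapc_fit(data: np.ndarray, groups: np.ndarray, n_pcs: int) -> DapcModel:
    """PCA to ``n_pcs`` scores, then LDA with uniform priors.

    Discriminant axes are capped at min(100, #groups - 1).
    """
    x = np.asarray(data, dtype=float)
    y = np.asarray(groups)
    n = x.shape[0]
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs > n - 1:
        raise ValueError("n_pcs must be <= n - 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"groups with < 2 members: {list(small)}")
    mean = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    n_pcs = min(n_pcs, rank)
    comps = vt[:n_pcs].T
    scores = u[:, :n_pcs] * s[:n_pcs]
    n_axes = min(MAX_DISCRIMINANT_AXES, len(classes) - 1, n_pcs)
    priors = np.full(len(classes), 1.0 / len(classes))
    lda = LinearDiscriminantAnalysis(n_components=n_axes, priors=priors)
    lda.fit(scores, y)
    acc = float((lda.predict(scores) == y).mean())
    return DapcModel(mean, comps, lda, n_pcs, classes, acc)


def optim_a_score(data: np.ndarray, groups: np.ndarray,
                  candidate_n_pcs, n_reps: int = 10,
                  seed: int = 0) -> int:
    """Select the PC count maximizing the a-score.

    a-score(c) = training reassignment success at c PCs minus its mean over
    ``n_reps`` fits with permuted group labels. Ties pick the smaller c.
    """
    grid = sorted(set(int(c) for c in candidate_n_pcs))
    n = np.asarray(data).shape[0]
    grid = [c for c in grid if 1 <= c <= n - 1]
    if not grid:
        raise ValueError("no valid candidate PC counts")
    rng = np.random.default_rng(seed)
    y = np.asarray(groups)
    perms = [rng.permutation(y) for _ in range(n_reps)]
    best_c, best_score = None, -np.inf
    for c in grid:
        obs = dapc_fit(data, y, c).training_accuracy
        null = np.mean([dapc_fit(data, p, c).training_accuracy
                        for p in perms])
        score = obs - null
        if score > best_score + 1e-12:
            best_c, best_score = c, score
    return best_c


@dataclass
class CvResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    null_accuracies: np.ndarray = field(default=None)
    p: float = np.nan

    def __post_init__(self) -> None:
        for a in self.fold_accuracies:
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracy outside [0, 1]")


def _family_stratified_folds(y: np.ndarray, families: np.ndarray,
                             k_folds: int, rng: np.random.Generator
                             ) -> np.ndarray:
    """Fold assignment keeping co-members of a family in the same fold and
    balancing class counts across folds (family class = first member's)."""
    fold = np.empty(len(y), dtype=int)
    fams = pd.Series(families)
    fam_class = pd.Series(y).groupby(fams.values, sort=False).first()
    fam_names = fam_class.index.to_numpy()
    order = rng.permutation(len(fam_names))
    counter: dict = {}
    for fi in order:
        cls = fam_class.iloc[fi]
        nxt = counter.get(cls, 0)
        fold[fams.values == fam_names[fi]] = nxt % k_folds
        counter[cls] = nxt + 1
    return fold


def _cv_accuracy(x: np.ndarray, y: np.ndarray, families: np.ndarray,
                 k_folds: int, pcs_grid, a_score_reps: int,
                 rng: np.random.Generator) -> list[float]:
    fold = _family_stratified_folds(y, families, k_folds, rng)
    accs = []
    for f in range(k_folds):
        tr, te = fold != f, fold == f
        if len(np.unique(y[tr])) < 2 or te.sum() == 0:
            continue
        grid = [c for c in pcs_grid if c <= tr.sum() - 1]
        c = optim_a_score(x[tr], y[tr], grid, n_reps=a_score_reps,
                          seed=int(rng.integers(2 ** 31)))
        model = dapc_fit(x[tr], y[tr], c)
        accs.append(float((model.predict(x[te]) == y[te]).mean()))
    return accs


def dapc_cv(data: np.ndarray, groups: pd.Series, k_folds: int = 5,
            plan: PermutationPlan | None = None, n_perm: int = 100,
            seed: int = 0, families: np.ndarray | None = None,
            pcs_grid=None, a_score_reps: int = 4) -> CvResult:
    """Family-stratified k-fold CV accuracy of DAPC with an a-score PC
    selection inside each training fold, and an empirical p-value from
    twin-aware label permutations.

    ``groups`` must be indexed by sample ID when a ``plan`` is given.
    Co-twins share a fold (no leakage through shared genetics); the null
    repeats the full CV on each permuted labeling.
    """
    x = np.asarray(data, dtype=float)
    y = np.asarray(groups)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest group ({counts.min()}) smaller than k_folds")
    if families is None:
        families = np.arange(len(y)).astype(str)
    if pcs_grid is None:
        top = min(60, x.shape[0] - 1, x.shape[1])
        pcs_grid = sorted({max(1, top // 8), max(2, top // 4),
                           max(3, top // 2), top})
    rng = np.random.default_rng([seed, 101])
    accs = _cv_accuracy(x, y, families, k_folds, pcs_grid, a_score_reps, rng)
    observed = float(np.mean(accs))
    null = None
    p = np.nan
    if plan is not None:
        null = np.empty(n_perm)
        g = groups if isinstance(groups, pd.Series) else pd.Series(y)
        for b in range(n_perm):
            yp = permute_phenotypes(g, plan, b).reindex(g.index).values
            rng_b = np.random.default_rng([seed, 202, b])
            null[b] = float(np.mean(_cv_accuracy(
                x, yp, families, k_folds, pcs_grid, a_score_reps, rng_b)))
        p = empirical_p(observed, null, "ge")
    return CvResult(accs, observed, null, p)


# ---------------------------------------------------------------------------
# random forests

@dataclass
class ForestResult:
    oob_error: float
    oob_error_per_class: pd.Series
    predicted_counts: pd.Series
    n_trees: int


def random_forest_classify(data: np.ndarray, groups: np.ndarray,
                           n_trees: int = 500, downsample: bool = False,
                           seed: int = 0) -> ForestResult:
    """Bagged decision trees with sqrt(p) features per split and out-of-bag
    error.

    With ``downsample`` each tree's bootstrap draws an equal per-class
    sample of size equal to the smallest class, so no class dominates model
    building; otherwise each tree uses an ordinary bootstrap of all
    samples.
    """
    x = np.asarray(data, dtype=float)
    y = np.asarray(groups)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() == 0:
        raise ValueError("empty class")
    min_size = counts.min()
    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    rng = np.random.default_rng(seed)
    votes = pd.DataFrame(0, index=np.arange(n), columns=classes)
    for t in range(n_trees):
        if downsample:
            boot = np.concatenate([
                rng.choice(class_idx[c], size=min_size, replace=True)
                for c in classes])
        else:
            boot = rng.integers(n, size=n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
        tree.fit(x[boot], y[boot])
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        pred = tree.predict(x[oob])
        for c in classes:
            votes.loc[oob[pred == c], c] += 1
    voted = votes.sum(axis=1) > 0
    oob_pred = votes.loc[voted].idxmax(axis=1).values
    truth = y[voted.values]
    err = float((oob_pred != truth).mean())
    per_class = pd.Series(
        {c: float((oob_pred[truth == c] != c).mean())
         if (truth == c).any() else np.nan for c in classes})
    pred_counts = pd.Series(oob_pred).value_counts().reindex(
        classes, fill_value=0)
    return ForestResult(err, per_class, pred_counts, n_trees)
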