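"""Genotype clustering on TR features via unsupervised random forest + PAM.

The cluster count is chosen by the Dunn index over k-medoids partitions of
the standardized feature space.  Genotypes are then clustered on a random
forest dissimilarity: a two-class forest learns to separate the real
feature rows from a synthetic copy drawn from the product of the empirical
marginals (independent column permutation); the fraction of trees in which
two real rows share a terminal node is their proximity, and 1 - proximity
the dissimilarity that PAM partitions.  Feature importance (mean decrease
in Gini, permutation mean decrease in accuracy, overall and per cluster)
ranks the features, and a single least-squares change point on the sorted
Gini importances separates the informative subset.

The forest is a bagging loop over sklearn decision trees with explicitly
drawn bootstrap samples, so per-tree out-of-bag membership, proximities and
permutation importances are all available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.tree import DecisionTreeClassifier


# ---------------------------------------------------------------------------
# PAM (k-medoids) on a dissimilarity matrix
# ---------------------------------------------------------------------------

def pam_cluster(dissimilarity, k: int):
    """Partitioning around medoids: BUILD + SWAP on a dissimilarity matrix.

    Deterministic: BUILD greedily seeds medoids, SWAP applies the best
    improving (medoid, non-medoid) exchange until none improves.  Labels are
    nearest-medoid assignments (ties to the lower medoid index).

    Returns ``(labels, medoids)`` with labels in 0..k-1 ordered by medoid
    index.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < n; got k={k}, n={n}")

    # exact search when the medoid space is tiny (BUILD+SWAP is only
    # 1-swap-optimal and can miss the optimum on small instances)
    from math import comb

    if comb(n, k) <= 5000:
        import itertools

        best_cost, best_meds = np.inf, None
        for meds in itertools.combinations(range(n), k):
            c = D[:, meds].min(axis=1).sum()
            if c < best_cost - 1e-15:
                best_cost, best_meds = c, meds
        medoids = sorted(best_meds)
        labels = np.argmin(D[:, medoids], axis=1)
        return labels, np.asarray(medoids)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_med = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(dist_to_med - D[:, j], 0.0).sum()
            if j not in medoids else -np.inf
            for j in range(n)
        ])
        medoids.append(int(np.argmax(gains)))

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    # SWAP
    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                delta = cost(trial) - current
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            current += best[0]
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, np.asarray(medoids)


def dunn_index(dissimilarity, labels) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter."""
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("Dunn index needs at least two clusters")
    min_between = np.inf
    max_within = 0.0
    for a in ks:
        ia = np.flatnonzero(labels == a)
        if ia.size > 1:
            max_within = max(max_within, D[np.ix_(ia, ia)].max())
        for b in ks:
            if b <= a:
                continue
            ib = np.flatnonzero(labels == b)
            min_between = min(min_between, D[np.ix_(ia, ib)].min())
    if max_within == 0.0:
        return np.inf
    return float(min_between / max_within)


def standardize(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column (constant columns map to zero)."""
    sd = features.std(ddof=1).replace(0.0, 1.0)
    return (features - features.mean()) / sd


def dunn_select_k(features: pd.DataFrame, k_range=range(2, 11)) -> tuple:
    """Choose the cluster count maximising the Dunn index.

    Features are z-scored, partitioned by k-medoids on Euclidean distances
    for each k in ``k_range``, and the k with the largest Dunn index wins
    (ties go to the smallest k).  Returns ``(k, scores)`` with the per-k
    Dunn values.
    """
    X = standardize(features).to_numpy()
    n = X.shape[0]
    k_range = [k for k in k_range]
    if n < max(k_range) + 1:
        raise ValueError(f"need more genotypes than max k={max(k_range)}")
    D = squareform(pdist(X))
    scores = {}
    for k in k_range:
        labels, _ = pam_cluster(D, k)
        scores[k] = dunn_index(D, labels)
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


# ---------------------------------------------------------------------------
# Bagged forest with explicit bootstrap bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class BaggedForest:
    """Random forest as a bagging loop over sklearn decision trees."""

    trees: list = field(repr=False)
    inbag: list = field(repr=False)          # bootstrap row indices per tree
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    classes: np.ndarray = None
    mtry: int = None
    seed: int = None

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def oob_votes(self, X=None):
        """Per-row class vote counts from trees where the row is out of bag."""
        X = self.X if X is None else X
        n = X.shape[0]
        votes = np.zeros((n, self.classes.size))
        for tree, inbag in zip(self.trees, self.inbag):
            oob = np.ones(n, dtype=bool)
            oob[inbag] = False
            if not oob.any():
                continue
            pred = tree.predict(X[oob])
            for ci, c in enumerate(self.classes):
                votes[np.flatnonzero(oob)[pred == c], ci] += 1
        return votes

    def oob_error(self) -> float:
        """Out-of-bag misclassification rate, in percent."""
        votes = self.oob_votes()
        has_votes = votes.sum(axis=1) > 0
        pred = self.classes[np.argmax(votes, axis=1)]
        wrong = (pred[has_votes] != self.y[has_votes]).mean()
        return float(100.0 * wrong)

    def predict(self, X):
        votes = np.zeros((X.shape[0], self.classes.size))
        for tree in self.trees:
            pred = tree.predict(X)
            for ci, c in enumerate(self.classes):
                votes[pred == c, ci] += 1
        return self.classes[np.argmax(votes, axis=1)]

    def proximity(self, rows=None) -> np.ndarray:
        """Fraction of trees in which two rows share a terminal node."""
        X = self.X if rows is None else self.X[rows]
        n = X.shape[0]
        prox = np.zeros((n, n))
        for tree in self.trees:
            leaves = tree.apply(X)
            prox += leaves[:, None] == leaves[None, :]
        return prox / self.ntree

    def mean_decrease_gini(self) -> np.ndarray:
        """Unnormalised Gini importance averaged over trees.

        Per tree, the impurity decrease at every split on a feature, weighted
        by the fraction of samples reaching the node, summed per feature.
        """
        p = self.X.shape[1]
        total = np.zeros(p)
        for tree in self.trees:
            t = tree.tree_
            w = t.weighted_n_node_samples
            imp = t.impurity
            for node in range(t.node_count):
                left, right = t.children_left[node], t.children_right[node]
                if left == -1:
                    continue
                dec = (w[node] * imp[node] - w[left] * imp[left]
                       - w[right] * imp[right]) / w[0]
                total[t.feature[node]] += dec
        return total / self.ntree

    def mean_decrease_accuracy(self, seed: int = 0):
        """Permutation importance on out-of-bag samples, in percent.

        Per tree, OOB accuracy is compared before and after permuting one
        feature among the OOB rows; the mean drop x100 is the overall MDA,
        and the drop restricted to rows of each class the class-specific
        MDA.  Returns ``(overall, per_class)`` with shapes (p,) and (k, p).
        """
        rng = np.random.default_rng(seed)
        n, p = self.X.shape
        k = self.classes.size
        drops = np.zeros(p)
        class_drops = np.zeros((k, p))
        class_counts = np.zeros(k)
        tree_counts = 0
        for tree, inbag in zip(self.trees, self.inbag):
            oob = np.ones(n, dtype=bool)
            oob[inbag] = False
            if not oob.any():
                continue
            tree_counts += 1
            Xo, yo = self.X[oob], self.y[oob]
            base = tree.predict(Xo) == yo
            for ci, c in enumerate(self.classes):
                class_counts[ci] += (yo == c).any()
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                perm = tree.predict(Xp) == yo
                drops[j] += base.mean() - perm.mean()
                for ci, c in enumerate(self.classes):
                    m = yo == c
                    if m.any():
                        class_drops[ci, j] += base[m].mean() - perm[m].mean()
        if tree_counts == 0:
            raise ValueError("no tree has out-of-bag samples")
        overall = 100.0 * drops / tree_counts
        per_class = 100.0 * class_drops / np.maximum(class_counts[:, None], 1)
        return overall, per_class


def fit_forest(X, y, ntree: int = 500, mtry: int = None,
               seed: int = 0) -> BaggedForest:
    """Fit a bagged classification forest with explicit bootstrap draws."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds feature count {p}")
    rng = np.random.default_rng(seed)
    trees, inbag = [], []
    for _ in range(ntree):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag.append(idx)
    return BaggedForest(trees=trees, inbag=inbag, X=X, y=y,
                        classes=np.unique(y), mtry=mtry, seed=seed)


# ---------------------------------------------------------------------------
# Unsupervised random forest dissimilarity
# ---------------------------------------------------------------------------

def synthetic_contrast(X, rng) -> np.ndarray:
    """Synthetic rows from the product of empirical marginals.

    Each column of the real data is independently permuted, destroying the
    joint dependence structure while keeping every marginal distribution.
    """
    X = np.asarray(X, dtype=float)
    return np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])


@dataclass
class URFResult:
    """Unsupervised-forest dissimilarity with model bookkeeping."""

    dissimilarity: np.ndarray
    oob_error: float              # percent, real-vs-synthetic task
    mdg: pd.Series                # mean decrease in Gini per feature
    forest: BaggedForest = field(repr=False, default=None)


def urf_dissimilarity(features: pd.DataFrame, mtry: int, ntree: int = 500,
                      seed: int = 0, method: str = "one_minus") -> URFResult:
    """Random-forest dissimilarity between the rows of a feature table.

    A two-class forest separates the real rows (class 0) from a
    column-permuted synthetic copy (class 1); proximity between real rows is
    the fraction of trees in which they share a terminal node and the
    dissimilarity is ``1 - proximity`` (or ``sqrt(1 - proximity)`` with
    ``method="sqrt"``).
    """
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    rng = np.random.default_rng(seed)
    X_syn = synthetic_contrast(X, rng)
    X_aug = np.vstack([X, X_syn])
    y = np.repeat([0, 1], X.shape[0])
    forest = fit_forest(X_aug, y, ntree=ntree, mtry=mtry,
                        seed=int(rng.integers(2 ** 31 - 1)))
    prox = forest.proximity(rows=np.arange(X.shape[0]))
    if method == "one_minus":
        D = 1.0 - prox
    elif method == "sqrt":
        D = np.sqrt(np.clip(1.0 - prox, 0.0, None))
    else:
        raise ValueError("method must be 'one_minus' or 'sqrt'")
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    mdg = pd.Series(forest.mean_decrease_gini(), index=features.columns,
                    name="MDG")
    return URFResult(dissimilarity=D, oob_error=forest.oob_error(),
                     mdg=mdg, forest=forest)


def tune_mtry(features: pd.DataFrame, mtry_range=range(1, 11),
              folds: int = 10, ntree: int = 100, seed: int = 0):
    """Ten-fold cross-validation of the real-vs-synthetic task over mtry.

    Returns ``(best_mtry, errors)`` where errors maps mtry to the mean CV
    misclassification rate (percent); ties go to the smallest mtry.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    mtry_range = [m for m in mtry_range]
    if max(mtry_range) > p:
        raise ValueError("mtry range exceeds feature count")
    rng = np.random.default_rng(seed)
    # folds are over the real rows; the synthetic contrast is regenerated
    # inside each fold from the training rows only, otherwise the held-out
    # rows' exact values leak into the training synthetic copy and trees
    # memorise them
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    fold_rngs = [np.random.default_rng(int(rng.integers(2 ** 31 - 1)))
                 for _ in range(folds)]
    fold_seeds = rng.integers(2 ** 31 - 1, size=(len(mtry_range), folds))
    errors = {}
    for mi, m in enumerate(mtry_range):
        errs = []
        for f in range(folds):
            test = fold_of == f
            Xtr, Xte = X[~test], X[test]
            if len(Xte) == 0:
                continue
            r = np.random.default_rng(fold_rngs[f].integers(2 ** 31 - 1))
            Xa_tr = np.vstack([Xtr, synthetic_contrast(Xtr, r)])
            ya_tr = np.repeat([0, 1], len(Xtr))
            Xa_te = np.vstack([Xte, synthetic_contrast(Xte, r)])
            ya_te = np.repeat([0, 1], len(Xte))
            forest = fit_forest(Xa_tr, ya_tr, ntree=ntree, mtry=m,
                                seed=int(fold_seeds[mi, f]))
            pred = forest.predict(Xa_te)
            errs.append((pred != ya_te).mean())
        errors[m] = float(100.0 * np.mean(errs))
    best = min(errors, key=lambda m: (errors[m], m))
    return best, errors


def class_specific_importance(features: pd.DataFrame, labels,
                              ntree: int = 500, mtry: int = None,
                              seed: int = 0) -> pd.DataFrame:
    """MDG and permutation MDA (overall and per cluster) for given labels.

    A supervised forest is fitted on the cluster labels (class-specific
    out-of-bag accuracy is undefined for the two-class unsupervised task),
    and permutation importance computed on its out-of-bag samples.
    """
    labels = np.asarray(labels)
    forest = fit_forest(features.to_numpy(dtype=float), labels,
                        ntree=ntree, mtry=mtry, seed=seed)
    overall, per_class = forest.mean_decrease_accuracy(seed=seed)
    out = pd.DataFrame({"MDG": forest.mean_decrease_gini(),
                        "MDA_overall": overall}, index=features.columns)
    for ci, c in enumerate(forest.classes):
        out[f"MDA_C{c}"] = per_class[ci]
    return out


# ---------------------------------------------------------------------------
# Change-point feature selection on sorted MDG
# ---------------------------------------------------------------------------

def select_features(mdg: pd.Series):
    """Single least-squares change point on the ascending-sorted MDG vector.

    The split position minimising the total within-segment squared deviation
    from the segment means is found exhaustively; features in the upper
    segment are selected.  A constant MDG vector has no change point: all
    features are returned with a warning.
    """
    if len(mdg) < 3:
        raise ValueError("need at least 3 features for change-point selection")
    s = mdg.sort_values(kind="mergesort")
    v = s.to_numpy(dtype=float)
    if np.ptp(v) == 0:
        warnings.warn("constant importance vector: no change point; "
                      "returning all features")
        return list(mdg.index), None
    best_sse, best_split = np.inf, None
    for split in range(1, v.size):
        lo, hi = v[:split], v[split:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse - 1e-15:
            best_sse, best_split = sse, split
    selected = list(s.index[best_split:])
    return selected, best_split
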