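"""From-scratch random-forest classification of group status.

The classifier is an ensemble of unpruned CARTs grown on bootstrap
samples (n draws with replacement, hence ~2/3 unique observations per
tree).  At every node a random subset of M features is assessed; the
node splits on the feature/threshold pair maximizing the Gini gain

    Gain(X_i, v) = Gini(v) - w_l * Gini(v_l) - w_r * Gini(v_r),
    Gini(v)      = sum_c p_c(v) * (1 - p_c(v)),

with thresholds at midpoints between consecutive distinct sorted
values.  Feature importance is the summed Gini gain over all nodes
split by a feature, divided by the number of trees; scores are the
fraction of trees voting for the positive class.  Classifier
performance is the AUC of held-out scores, judged against a permutation
null built by reshuffling the held-out labels.

Everything is deterministic given a seed.  Ties break toward the lower
feature index, then the lower threshold; leaf-label and 0.5-score ties
resolve to class 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import VertexScalarMap

__all__ = [
    "FeatureMatrix",
    "SplitNode",
    "RandomForestModel",
    "RandomForestResults",
    "ClassifierEvaluation",
    "gini",
    "best_split",
    "grow_tree",
    "predict_scores",
    "importance",
    "roc_auc",
    "permutation_pvalue",
    "evaluate_protocol",
    "evaluate_feature_subsets",
    "importance_to_surfaces",
]


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects-by-features matrix with per-column (structure, kind, vertex) tags."""

    X: np.ndarray  # (n, P)
    y: np.ndarray  # (n,) integer class labels
    tags: list  # [(structure_id, kind, vertex_index_or_None)]
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, int).ravel()
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, P) aligned with y")
        if len(self.tags) != self.X.shape[1]:
            raise ValueError("one tag per feature column required")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("feature tags must be unique")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix has missing cells")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def names(self):
        return [
            f"{s}.{k}" + (f".{i}" if i is not None else "") for s, k, i in self.tags
        ]

    @classmethod
    def from_feature_table(cls, table, covariates: pd.DataFrame,
                           label: str = "HIVStatus") -> "FeatureMatrix":
        """Combine volumes, RD and JD into one tagged predictor matrix."""
        cov = covariates.set_index("subject_id").loc[table.subjects]
        cols, tags = [], []
        for s in table.shape_structures:
            nv = table.rd[s].shape[1]
            cols.append(table.rd[s])
            tags += [(s, "RD", i) for i in range(nv)]
            cols.append(table.logjd[s])
            tags += [(s, "JD", i) for i in range(nv)]
        cols.append(table.volumes[table.structures].to_numpy())
        tags += [(s, "volume", None) for s in table.structures]
        X = np.column_stack(cols)
        return cls(X, cov[label].to_numpy(), tags, list(table.subjects))

    def subset(self, kind: str) -> "FeatureMatrix":
        """Restrict to one feature kind: 'RD', 'JD', 'volume' or 'all'."""
        if kind == "all":
            return self
        keep = [i for i, t in enumerate(self.tags) if t[1] == kind]
        if not keep:
            raise ValueError(f"no features of kind {kind!r}")
        return FeatureMatrix(self.X[:, keep], self.y,
                             [self.tags[i] for i in keep], self.subjects)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names,
                          index=pd.Index(self.subjects or range(len(self.y)),
                                         name="subject_id"))
        df.insert(0, "label", self.y)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        y = df["label"].to_numpy()
        feat = df.drop(columns=["label"])
        tags = []
        for c in feat.columns:
            parts = c.split(".")
            tags.append((parts[0], parts[1],
                         int(parts[2]) if len(parts) > 2 else None))
        return cls(feat.to_numpy(), y, tags, list(df.index))


# ---------------------------------------------------------------------------
# Gini machinery
# ---------------------------------------------------------------------------

def gini(class_counts) -> float:
    """Gini impurity sum_c p_c (1 - p_c) of a node's class counts."""
    c = np.asarray(class_counts, float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty node")
    p = c / n
    return float(np.sum(p * (1.0 - p)))


def _counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def best_split(X: np.ndarray, y: np.ndarray, candidates, n_classes: int = 2):
    """Best (feature, threshold, gain) among candidate features, or None.

    Thresholds are midpoints between consecutive distinct sorted values;
    ties break toward the lower feature index, then the lower threshold.
    Returns None if every candidate is constant on the node ("no-split").
    """
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("need >= 2 observations to split")
    parent_counts = _counts(y, n_classes)
    g_parent = gini(parent_counts)
    if g_parent == 0.0:
        raise ValueError("node is pure; precondition violated")
    cand = np.sort(np.asarray(candidates, int))
    Xc = X[:, cand]
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    valid = xs[1:] > xs[:-1]  # a cut exists between distinct neighbours
    if not valid.any():
        return None
    ys = y[order]  # (n, M)
    nl = np.arange(1, n)[:, None].astype(float)
    nr = n - nl
    # prefix class counts
    gl = np.zeros((n - 1, len(cand)))
    gr = np.zeros_like(gl)
    sum_pl2 = np.zeros_like(gl)
    sum_pr2 = np.zeros_like(gl)
    for c in range(n_classes):
        pc = np.cumsum(ys == c, axis=0)[:-1]
        pl = pc / nl
        pr = (parent_counts[c] - pc) / nr
        sum_pl2 += pl * pl
        sum_pr2 += pr * pr
    gl = 1.0 - sum_pl2
    gr = 1.0 - sum_pr2
    gains = g_parent - (nl / n) * gl - (nr / n) * gr
    gains[~valid] = -np.inf
    best_gain = gains.max()
    rows, cols = np.nonzero(gains == best_gain)
    col = cols.min()
    row = rows[cols == col].min()  # lowest threshold within the winning feature
    feat = int(cand[col])
    thr = 0.5 * (xs[row, col] + xs[row + 1, col])
    return feat, float(thr), float(best_gain)


@dataclass
class SplitNode:
    """One CART node; terminal nodes carry a leaf class."""

    counts: np.ndarray
    feature: int | None = None
    threshold: float = np.nan
    gain: float = 0.0
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None
    leaf_class: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class is not None

    def gini(self) -> float:
        return gini(self.counts)


def grow_tree(X: np.ndarray, y: np.ndarray, mtry: int,
              rng: np.random.Generator, n_classes: int = 2) -> SplitNode:
    """Grow one unpruned CART to purity (or until no split is possible).

    At every node ``mtry`` features are drawn without replacement from
    all P; leaf labels are the majority class (ties to the lower label).
    """
    if len(y) == 0:
        raise ValueError("empty sample")
    P = X.shape[1]

    def build(rows: np.ndarray) -> SplitNode:
        ysub = y[rows]
        counts = _counts(ysub, n_classes)
        node = SplitNode(counts)
        if np.count_nonzero(counts) <= 1 or len(rows) < 2:
            node.leaf_class = int(np.argmax(counts))
            return node
        cand = rng.choice(P, size=min(mtry, P), replace=False)
        found = best_split(X[rows], ysub, cand, n_classes)
        if found is None:
            node.leaf_class = int(np.argmax(counts))
            return node
        feat, thr, g = found
        node.feature, node.threshold, node.gain = feat, thr, g
        go_left = X[rows, feat] <= thr
        node.left = build(rows[go_left])
        node.right = build(rows[~go_left])
        return node

    return build(np.arange(len(y)))


def _tree_vote(node: SplitNode, x: np.ndarray) -> int:
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.leaf_class


# ---------------------------------------------------------------------------
# Forest model / results
# ---------------------------------------------------------------------------

class RandomForestModel:
    """Random forest over a tagged feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Training subjects, predictors and class labels.
    n_trees : int
        Ensemble size (5000 by default; use fewer for quick runs).
    mtry : int, optional
        Features assessed per node; defaults to floor(sqrt(P)).
    seed : int
        Root seed; per-tree streams are derived deterministically.
    """

    def __init__(self, features: FeatureMatrix, n_trees: int = 5000,
                 mtry: int | None = None, seed: int = 0):
        self.features = features
        self.n_trees = int(n_trees)
        P = features.X.shape[1]
        self.mtry = int(mtry) if mtry else max(1, int(np.floor(np.sqrt(P))))
        self.seed = int(seed)
        self.n_classes = int(features.y.max()) + 1

    def fit(self) -> "RandomForestResults":
        X, y = self.features.X, self.features.y
        if min(np.bincount(y)) < 2:
            raise ValueError("need >= 2 subjects per class to train")
        n = len(y)
        trees, boots = [], []
        ss = np.random.SeedSequence([self.seed, 0x5F])
        for child in ss.spawn(self.n_trees):
            rng = np.random.default_rng(child)
            idx = rng.integers(0, n, size=n)
            trees.append(grow_tree(X[idx], y[idx], self.mtry, rng, self.n_classes))
            boots.append(idx)
        return RandomForestResults(self, trees, boots)


@dataclass
class RandomForestResults:
    """A fitted ensemble: trees, bootstrap indices, importance, scoring."""

    model: RandomForestModel
    trees: list = field(repr=False)
    bootstrap_indices: list = field(repr=False)

    def predict_scores(self, X, tags=None) -> np.ndarray:
        """Fraction of trees voting class 1 for each row of X."""
        if isinstance(X, FeatureMatrix):
            if X.tags != self.model.features.tags:
                raise ValueError("feature tags do not match the training matrix")
            X = X.X
        X = np.asarray(X, float)
        if X.shape[1] != self.model.features.X.shape[1]:
            raise ValueError("feature count does not match the training matrix")
        if tags is not None and tags != self.model.features.tags:
            raise ValueError("feature tags do not match the training matrix")
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += [_tree_vote(tree, x) == 1 for x in X]
        return votes / len(self.trees)

    def predict(self, X) -> np.ndarray:
        """Hard labels; a 0.5 score ties to class 0."""
        return (self.predict_scores(X) > 0.5).astype(int)

    def importance(self) -> pd.DataFrame:
        """Per-feature summed Gini gain divided by the tree count."""
        P = self.model.features.X.shape[1]
        imp = np.zeros(P)
        n_nodes = np.zeros(P, int)

        def walk(node):
            if node.is_leaf:
                return
            imp[node.feature] += node.gain
            n_nodes[node.feature] += 1
            walk(node.left)
            walk(node.right)

        for t in self.trees:
            walk(t)
        imp /= len(self.trees)
        tags = self.model.features.tags
        return pd.DataFrame(
            {
                "feature": self.model.features.names,
                "structure": [t[0] for t in tags],
                "kind": [t[1] for t in tags],
                "vertex": [t[2] for t in tags],
                "importance": imp,
                "n_split_nodes": n_nodes,
            }
        )

    def summary(self) -> str:
        f = self.model.features
        top = self.importance().nlargest(5, "importance")
        return (
            f"Random forest: {len(self.trees)} trees, mtry={self.model.mtry}, "
            f"P={f.X.shape[1]}, n={len(f.y)}\n"
            "Top features by Gini importance:\n"
            + top.to_string(index=False, float_format=lambda x: f"{x:.4g}")
        )


# module-level conveniences mirroring the procedural surface
def predict_scores(forest: RandomForestResults, X) -> np.ndarray:
    return forest.predict_scores(X)


def importance(forest: RandomForestResults) -> pd.DataFrame:
    return forest.importance()


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores, labels):
    """ROC curve and AUC (Mann-Whitney: P(score+ > score-) + 0.5 P(tie))."""
    from scipy.stats import rankdata

    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    thresholds = np.unique(s)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pred = s >= t
        pts.append((float((pred & (y == 0)).sum() / n0), float((pred & (y == 1)).sum() / n1)))
    pts.append((1.0, 1.0))
    return np.array(pts), float(auc)


def _auc_from_ranks(r: np.ndarray, case_mask: np.ndarray, n1: int, n0: int) -> float:
    return (r[case_mask].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def permutation_pvalue(scores, labels, B: int = 1000, seed: int = 0,
                       smoothed: bool = False):
    """Permutation-null p-value for the observed AUC.

    Shuffles the held-out labels B times over the fixed score vector;
    p = #(null AUC > observed)/B (strict inequality); ``smoothed`` uses
    (#+1)/(B+1) instead.  Returns (observed_auc, null_aucs, p).
    """
    from scipy.stats import rankdata

    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    _, obs = roc_auc(s, y)
    r = rankdata(s)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(y) == 1
        null[b] = _auc_from_ranks(r, perm, n1, n0)
    exceed = int((null > obs).sum())
    p = (exceed + 1) / (B + 1) if smoothed else exceed / B
    return obs, null, p


@dataclass
class ClassifierEvaluation:
    """Held-out scores, ROC/AUC and permutation-null significance."""

    feature_subset: str
    scheme: str
    scores: np.ndarray
    labels: np.ndarray
    roc_points: np.ndarray
    auc: float
    null_aucs: np.ndarray
    p_value: float
    fold_sizes: dict
    seed: int
    q_value: float | None = None
    importance_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_record(self) -> dict:
        return {
            "feature_subset": self.feature_subset,
            "scheme": self.scheme,
            "auc": self.auc,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "fold_sizes": self.fold_sizes,
            "seed": self.seed,
        }


def _stratified_halves(y: np.ndarray, rng: np.random.Generator):
    """Class-stratified 50/50 split; odd class counts give training the
    extra subject."""
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        n_test = len(idx) // 2  # extra subject (odd counts) stays in training
        test += list(idx[:n_test])
        train += list(idx[n_test:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def evaluate_protocol(features: FeatureMatrix, scheme: str = "stratified2fold",
                      feature_subset: str = "all", seed: int = 0,
                      n_trees: int = 5000, mtry: int | None = None,
                      B: int = 1000) -> ClassifierEvaluation:
    """Train/evaluate one classifier under the stated validation scheme.

    ``stratified2fold`` trains on a class-stratified half and scores the
    held-out half once; ``loocv`` scores every subject with a forest
    trained on the others and computes a single AUC from the aggregated
    held-out scores.  Significance comes from the permutation null.
    """
    fm = features.subset(feature_subset)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEA]))
    if scheme == "stratified2fold":
        tr, te = _stratified_halves(fm.y, rng)
        if len(np.unique(fm.y[tr])) < 2 or len(np.unique(fm.y[te])) < 2:
            raise ValueError("a class is absent from one fold")
        sub = FeatureMatrix(fm.X[tr], fm.y[tr], fm.tags)
        fitted = RandomForestModel(sub, n_trees, mtry, seed=int(seed)).fit()
        scores = fitted.predict_scores(fm.X[te])
        labels = fm.y[te]
        fold_sizes = {
            "train": {int(c): int((fm.y[tr] == c).sum()) for c in np.unique(fm.y)},
            "test": {int(c): int((fm.y[te] == c).sum()) for c in np.unique(fm.y)},
        }
    elif scheme == "loocv":
        n = len(fm.y)
        scores = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            sub = FeatureMatrix(fm.X[keep], fm.y[keep], fm.tags)
            fitted = RandomForestModel(sub, n_trees, mtry,
                                       seed=int(seed) * 1009 + i).fit()
            scores[i] = fitted.predict_scores(fm.X[i:i + 1])[0]
        labels = fm.y
        fold_sizes = {"train": n - 1, "test": 1, "n": n}
    else:
        raise ValueError("scheme must be 'stratified2fold' or 'loocv'")
    pts, auc = roc_auc(scores, labels)
    _, null, p = permutation_pvalue(scores, labels, B=B, seed=int(seed) + 7)
    imp = fitted.importance() if scheme == "stratified2fold" else None
    return ClassifierEvaluation(feature_subset, scheme, scores, labels, pts,
                                auc, null, p, fold_sizes, int(seed),
                                importance_table=imp)


def evaluate_feature_subsets(features: FeatureMatrix,
                             subsets=("all", "RD", "JD", "volume"),
                             scheme: str = "stratified2fold", seed: int = 0,
                             n_trees: int = 5000, mtry: int | None = None,
                             B: int = 1000, q_threshold: float = 0.05):
    """Evaluate several feature-subset classifiers; FDR over their p-values."""
    from .glm import fdr_bh

    evals = [
        evaluate_protocol(features, scheme, sub, seed, n_trees, mtry, B)
        for sub in subsets
    ]
    q, rej = fdr_bh(np.array([e.p_value for e in evals]), q_threshold)
    for e, qv in zip(evals, q):
        e.q_value = float(qv)
    return evals


def importance_to_surfaces(imp: pd.DataFrame, templates: dict):
    """Map per-vertex importances onto surfaces and average per region.

    Returns (overlays, summary): ``overlays[(structure, kind)]`` is a
    VertexScalarMap on that structure's template; ``summary`` lists the
    mean importance per (structure, kind), with volume features as their
    own rows.
    """
    if imp["structure"].isna().any() or (imp["structure"] == "").any():
        raise ValueError("untagged feature in importance table")
    overlays = {}
    for (s, kind), grp in imp.groupby(["structure", "kind"]):
        if kind == "volume":
            continue
        if s not in templates:
            raise KeyError(f"no template for structure {s!r}")
        vals = np.zeros(templates[s].n_vertices)
        vals[grp["vertex"].to_numpy(int)] = grp["importance"].to_numpy()
        overlays[(s, kind)] = VertexScalarMap(s, vals, f"importance_{kind}")
    summary = (
        imp.groupby(["structure", "kind"], as_index=False)["importance"]
        .mean()
        .sort_values(["kind", "importance"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return overlays, summary
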