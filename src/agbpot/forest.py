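"""Bagged model-tree ensemble: binary regression trees with OLS leaves.

Each tree partitions feature space by greedy binary splits that maximize the
reduction in the target sum of squares; every terminal node then carries a
multiple linear regression on the continuous features (falling back to the
leaf mean when the local design matrix is rank deficient or under-determined).
The ensemble prediction is the arithmetic mean over trees, clipped at zero
because biomass cannot be negative.

Randomness is fully reproducible: each tree draws its bootstrap resample and
its per-node candidate-feature subsets from a substream derived from
``SeedSequence([master_seed, tree_index])``, so fits are independent of
thread scheduling and of training-row order (rows are canonicalized by row
id before fitting).

Continuous features are indexed 0..p−1; the single categorical open-water
flag, when enabled, has feature id p and splits as ``flag is True`` → left.
The flag is excluded from leaf regressions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, SchemaError

SCHEMA_VERSION = 1

#: relative singular-value cutoff for leaf regressions. Directions of the
#: leaf design matrix carrying less than this fraction of the dominant
#: singular value are dropped from the solve: monthly climate layers are
#: strongly correlated, and coefficients estimated along near-null
#: directions amplify target noise enormously once a leaf extrapolates.
LEAF_SV_CUTOFF = 1e-3


@dataclass
class TrainingTable:
    """Pixel rows with continuous features, a water flag and an AGB target."""

    X: np.ndarray            # (n, p) continuous features
    water: np.ndarray        # (n,) bool categorical flag
    y: np.ndarray            # (n,) target, Mg C ha-1
    row_id: np.ndarray       # (n,) canonical pixel index
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.water = np.asarray(self.water, dtype=bool)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.row_id = np.asarray(self.row_id, dtype=np.int64)
        n = self.y.size
        if self.X.shape != (n, len(self.feature_names)):
            raise ConfigurationError("X shape inconsistent with feature names")
        if self.water.shape != (n,) or self.row_id.shape != (n,):
            raise ConfigurationError("column length mismatch")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ConfigurationError("training table contains missing values")

    @property
    def n_rows(self) -> int:
        return self.y.size

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def canonical_sort(self) -> "TrainingTable":
        """Rows sorted by pixel id — makes fits invariant to input order."""
        order = np.argsort(self.row_id, kind="stable")
        return TrainingTable(self.X[order], self.water[order], self.y[order],
                             self.row_id[order], list(self.feature_names))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "row_id", self.row_id)
        df["water"] = self.water.astype(int)
        df["target"] = self.y
        df.to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingTable":
        df = pd.read_csv(Path(path))
        feat = [c for c in df.columns if c not in ("row_id", "water", "target")]
        return cls(df[feat].to_numpy(float), df["water"].to_numpy(bool),
                   df["target"].to_numpy(float), df["row_id"].to_numpy(int),
                   feat)


@dataclass
class LeafModel:
    intercept: float
    coef: np.ndarray
    fallback: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


@dataclass
class SplitNode:
    feature: int
    threshold: float | None   # None for the categorical water split
    categorical: bool
    left: "SplitNode | LeafNode"
    right: "SplitNode | LeafNode"


@dataclass
class LeafNode:
    model: LeafModel
    n_rows: int


@dataclass
class ForestParams:
    n_trees: int = 1000
    max_depth: int = 12
    min_leaf_rows: int | None = None   # default 2·(p+1)
    mtry: int | None = None            # default ⌈√n_features⌉
    bootstrap: bool = True

    def resolve(self, n_continuous: int, n_total_features: int) -> "ForestParams":
        min_leaf = (self.min_leaf_rows if self.min_leaf_rows is not None
                    else 2 * (n_continuous + 1))
        mtry = (self.mtry if self.mtry is not None
                else int(np.ceil(np.sqrt(n_total_features))))
        return ForestParams(self.n_trees, self.max_depth, min_leaf,
                            min(mtry, n_total_features), self.bootstrap)


@dataclass
class ModelTreeForest:
    trees: list
    bootstrap_indices: list[np.ndarray]
    params: ForestParams
    seed: int
    feature_names: list[str]
    use_water: bool = True


def fit_leaf(X: np.ndarray, y: np.ndarray) -> LeafModel:
    """OLS of target on the continuous features; mean fallback when the
    system is under-determined (n < p + 2) or rank deficient."""
    n, p = X.shape
    if n < 1:
        raise DomainError("fit_leaf requires at least one row")
    if n < p + 2:
        return LeafModel(float(y.mean()), np.zeros(p), fallback=True)
    # centered solve: the intercept is recovered from the means, so a
    # constant target yields exactly zero coefficients
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # exact rank deficiency (machine-precision tolerance) -> mean fallback
    tol_rank = s[0] * max(n, p) * np.finfo(float).eps if s[0] > 0 else 0.0
    if s[0] == 0.0 or np.sum(s > tol_rank) < p:
        return LeafModel(ym, np.zeros(p), fallback=True)
    keep = s > s[0] * LEAF_SV_CUTOFF
    proj = U[:, keep].T @ (y - ym)
    coef = Vt[keep].T @ (proj / s[keep])
    return LeafModel(ym - float(xm @ coef), coef)


def _split_continuous(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best threshold for one continuous feature.

    Returns (score, threshold) where score = Σ_l S_l²/n_l + S_r²/n_r (the
    sum-of-squares terms that vary across splits), or None if no admissible
    split exists. Thresholds are midpoints between adjacent distinct values;
    the lowest-threshold maximizer wins ties.
    """
    n = y.size
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cs = np.cumsum(ys)
    total = cs[-1]
    i = np.arange(min_leaf, n - min_leaf + 1)
    if i.size == 0:
        return None
    valid = xs[i - 1] < xs[i]
    if not valid.any():
        return None
    i = i[valid]
    score = cs[i - 1] ** 2 / i + (total - cs[i - 1]) ** 2 / (n - i)
    k = int(np.argmax(score))   # argmax returns first maximizer → lowest threshold
    return float(score[k]), float(0.5 * (xs[i[k] - 1] + xs[i[k]]))


def _split_categorical(water: np.ndarray, y: np.ndarray, min_leaf: int):
    n_l = int(water.sum())
    n_r = y.size - n_l
    if n_l < min_leaf or n_r < min_leaf:
        return None
    s_l = float(y[water].sum())
    s_r = float(y.sum()) - s_l
    return s_l ** 2 / n_l + s_r ** 2 / n_r


def best_split(X: np.ndarray, water: np.ndarray, y: np.ndarray,
               candidate_features, min_leaf: int, use_water: bool):
    """Best (feature, threshold) over the candidate features.

    The criterion is reduction in target sum of squares; since the total
    Σy² term is constant, maximizing Σ S_child²/n_child is equivalent. Ties
    break to the lowest feature id, then the lowest threshold. Returns
    ``None`` when no split achieves a positive reduction.
    """
    n = y.size
    p = X.shape[1]
    base = float(y.sum()) ** 2 / n
    best = None  # (score, feature, threshold, categorical)
    for f in sorted(int(f) for f in candidate_features):
        if use_water and f == p:
            res = _split_categorical(water, y, min_leaf)
            if res is not None and (best is None or res > best[0]):
                best = (res, f, None, True)
        else:
            res = _split_continuous(X[:, f], y, min_leaf)
            if res is not None and (best is None or res[0] > best[0]):
                best = (res[0], f, res[1], False)
    if best is None:
        return None
    reduction = best[0] - base
    if reduction <= 1e-10 * max(1.0, float(np.sum(y * y))):
        return None
    return best[1], best[2], best[3]


def grow_tree(X: np.ndarray, water: np.ndarray, y: np.ndarray,
              params: ForestParams, rng: np.random.Generator,
              use_water: bool = True, depth: int = 0):
    """Greedy recursive binary splitting; OLS leaves at terminal nodes."""
    n, p = X.shape
    n_features = p + (1 if use_water else 0)
    if (depth >= params.max_depth or n < 2 * params.min_leaf_rows
            or np.ptp(y) == 0.0):
        return LeafNode(fit_leaf(X, y), n)
    mtry = min(params.mtry, n_features)
    feats = rng.choice(n_features, size=mtry, replace=False)
    found = best_split(X, water, y, feats, params.min_leaf_rows, use_water)
    if found is None:
        return LeafNode(fit_leaf(X, y), n)
    f, threshold, categorical = found
    if categorical:
        go_left = water
    else:
        go_left = X[:, f] <= threshold
    left = grow_tree(X[go_left], water[go_left], y[go_left], params, rng,
                     use_water, depth + 1)
    right = grow_tree(X[~go_left], water[~go_left], y[~go_left], params, rng,
                      use_water, depth + 1)
    return SplitNode(f, threshold, categorical, left, right)


def predict_tree(node, X: np.ndarray, water: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    _route(node, X, water, np.arange(X.shape[0]), out)
    return out


def _route(node, X, water, idx, out) -> None:
    if isinstance(node, LeafNode):
        out[idx] = node.model.predict(X[idx])
        return
    if node.categorical:
        go_left = water[idx]
    else:
        go_left = X[idx, node.feature] <= node.threshold
    _route(node.left, X, water, idx[go_left], out)
    _route(node.right, X, water, idx[~go_left], out)


def fit_forest(table: TrainingTable, params: ForestParams | None = None,
               seed: int = 0, use_water: bool = True) -> ModelTreeForest:
    """Fit a bagged ensemble: each tree sees a with-replacement bootstrap of
    the (canonically sorted) table, same size as the table."""
    if params is None:
        params = ForestParams()
    if params.n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    table = table.canonical_sort()
    p = table.n_features
    n_total = p + (1 if use_water else 0)
    resolved = params.resolve(p, n_total)
    n = table.n_rows
    trees, boots = [], []
    for t in range(resolved.n_trees):
        rng = np.random.default_rng(np.random.SeedSequence([seed, t]))
        if resolved.bootstrap:
            idx = np.sort(rng.integers(0, n, size=n))
        else:
            idx = np.arange(n)
        trees.append(grow_tree(table.X[idx], table.water[idx], table.y[idx],
                               resolved, rng, use_water))
        boots.append(idx)
    return ModelTreeForest(trees, boots, resolved, seed,
                           list(table.feature_names), use_water)


def predict(forest: ModelTreeForest, X: np.ndarray,
            water: np.ndarray | None = None) -> np.ndarray:
    """Mean prediction over trees, clipped at zero (AGB is non-negative)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(forest.feature_names):
        raise SchemaError(
            f"expected {len(forest.feature_names)} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}")
    if water is None:
        water = np.zeros(X.shape[0], dtype=bool)
    water = np.asarray(water, dtype=bool)
    acc = np.zeros(X.shape[0])
    for tree in forest.trees:
        acc += predict_tree(tree, X, water)
    return np.clip(acc / len(forest.trees), 0.0, None)


# ---------------------------------------------------------------------------
# JSON serialization (bit-exact round trip: Python json preserves doubles)

def _node_to_dict(node) -> dict:
    if isinstance(node, LeafNode):
        return {"type": "leaf", "intercept": node.model.intercept,
                "coef": node.model.coef.tolist(),
                "fallback": node.model.fallback, "n_rows": node.n_rows}
    return {"type": "split", "feature": node.feature,
            "threshold": node.threshold, "categorical": node.categorical,
            "left": _node_to_dict(node.left),
            "right": _node_to_dict(node.right)}


def _node_from_dict(d: dict):
    if d["type"] == "leaf":
        return LeafNode(LeafModel(d["intercept"], np.asarray(d["coef"]),
                                  d["fallback"]), d["n_rows"])
    return SplitNode(d["feature"], d["threshold"], d["categorical"],
                     _node_from_dict(d["left"]), _node_from_dict(d["right"]))


def save_forest(forest: ModelTreeForest, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "params": {"n_trees": forest.params.n_trees,
                   "max_depth": forest.params.max_depth,
                   "min_leaf_rows": forest.params.min_leaf_rows,
                   "mtry": forest.params.mtry,
                   "bootstrap": forest.params.bootstrap},
        "seed": forest.seed,
        "feature_names": forest.feature_names,
        "use_water": forest.use_water,
        "bootstrap_indices": [b.tolist() for b in forest.bootstrap_indices],
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    Path(path).write_text(json.dumps(doc))


def load_forest(path) -> ModelTreeForest:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError("unknown forest schema version")
    p = doc["params"]
    params = ForestParams(p["n_trees"], p["max_depth"], p["min_leaf_rows"],
                          p["mtry"], p["bootstrap"])
    return ModelTreeForest(
        [_node_from_dict(t) for t in doc["trees"]],
        [np.asarray(b, dtype=np.int64) for b in doc["bootstrap_indices"]],
        params, doc["seed"], doc["feature_names"], doc["use_water"])
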