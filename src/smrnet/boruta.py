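"""All-relevant feature selection with shadow features (Boruta).

Each run permutes every feature into a "shadow" copy, fits a random forest
on originals plus shadows, and computes a Z-score per column as the mean
per-tree out-of-bag accuracy loss divided by its standard deviation.  A
feature scores a hit when its Z-score exceeds the maximum shadow Z-score
(MZSA).  Accumulated hits over M runs follow Binomial(M, 0.5) under the
null; a two-sided binomial test at a Bonferroni-corrected level confirms
features whose hits significantly exceed 0.5*M and rejects those
significantly below.  Only confirmed features count as selected; features
still tentative when the run budget is exhausted are not selected.

Note on symbols: ``max_runs`` here is the number of Boruta iterations, a
different quantity from the number of trees in the regression forest
(``models.RFConfig.n_trees``).

The forest is a hand-rolled bagging loop over sklearn regression trees so
that each tree's bootstrap (and hence out-of-bag set) is explicit; the
accuracy loss is the increase in OOB mean squared error after permuting one
column, with a single permutation per feature per tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass
class BorutaDecision:
    """Outcome of a Boruta run: per-feature status, hits, and Z history."""

    feature_names: list[str]
    status: dict[str, str]
    hits: dict[str, int]
    n_runs: dict[str, int]
    z_history: dict[str, list[float]] = field(default_factory=dict)
    mzsa_history: list[float] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def confirmed(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == TENTATIVE]

    def selected_mask(self) -> np.ndarray:
        """Boolean mask over features; tentative features are NOT selected."""
        return np.array([self.status[f] == CONFIRMED for f in self.feature_names])

    def to_records(self) -> list[dict]:
        return [
            {
                "feature": f,
                "status": self.status[f],
                "hits": self.hits[f],
                "runs": self.n_runs[f],
            }
            for f in self.feature_names
        ]


def make_shadows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Append an independent row-permutation of every column of X.

    Output has 2S columns; column S+j is a permuted copy of column j, so it
    preserves each feature's marginal distribution while destroying its link
    to the target.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    n, p = X.shape
    # one independent permutation per column
    order = np.argsort(rng.random((p, n)), axis=1)
    shadows = X.T[np.arange(p)[:, None], order].T
    return np.hstack([X, shadows])


def _fit_oob_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    max_features: int,
    rng: np.random.Generator,
) -> list[tuple[DecisionTreeRegressor, np.ndarray]]:
    """Bagged regression trees with explicit out-of-bag index sets."""
    n = len(y)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y64 = np.ascontiguousarray(y, dtype=np.float64)
    forest = []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        # inputs are pre-validated float32/float64, skip sklearn's checks
        tree.fit(np.ascontiguousarray(X32[boot]), y64[boot], check_input=False)
        forest.append((tree, oob))
    return forest


def _tree_predict(tree: DecisionTreeRegressor, X32: np.ndarray) -> np.ndarray:
    """Validation-free tree prediction on a float32 C-contiguous matrix."""
    leaves = tree.tree_.apply(X32)
    return tree.tree_.value[leaves, 0, 0]


def importance_zscores(
    X_aug: np.ndarray,
    y: np.ndarray,
    rf_params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-column mean-decrease-accuracy Z-scores.

    For each tree, the accuracy loss of column j is the increase in OOB mean
    squared error after permuting column j (one permutation per feature per
    tree).  Z_j = mean over trees of the loss divided by its standard
    deviation; a zero standard deviation yields Z = 0 by convention.
    """
    rf_params = dict(rf_params or {})
    rng = rng if rng is not None else np.random.default_rng()
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X_aug.shape
    n_trees = int(rf_params.get("n_trees", 200))
    if n_trees < 2:
        raise ValueError("need at least 2 trees for a Z-score (sd undefined)")
    max_features = int(rf_params.get("max_features") or max(1, math.ceil(p / 3)))

    losses = np.zeros((n_trees, p))
    forest = _fit_oob_forest(X_aug, y, n_trees, max_features, rng)
    X32 = np.ascontiguousarray(X_aug, dtype=np.float32)
    for t, (tree, oob) in enumerate(forest):
        if len(oob) < 2:
            continue
        X_oob = X32[oob]
        y_oob = y[oob]
        base_mse = float(np.mean((_tree_predict(tree, X_oob) - y_oob) ** 2))
        m = len(oob)
        # one batched predict over all per-feature permuted copies
        perm = np.argsort(rng.random((p, m)), axis=1)
        big = np.ascontiguousarray(np.tile(X_oob, (p, 1)))
        rows = np.arange(m)
        for j in range(p):
            big[j * m + rows, j] = X_oob[perm[j], j]
        preds = _tree_predict(tree, big).reshape(p, m)
        losses[t] = np.mean((preds - y_oob[None, :]) ** 2, axis=1) - base_mse

    mean = losses.mean(axis=0)
    sd = losses.std(axis=0, ddof=1)
    z = np.zeros(p)
    nz = sd > 0
    z[nz] = mean[nz] / sd[nz]
    return z


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    *,
    feature_names: list[str] | None = None,
    max_runs: int = 100,
    alpha: float = 0.05,
    rf_params: dict | None = None,
    rng: np.random.Generator | int | None = None,
) -> BorutaDecision:
    """Run the iterative shadow-comparison selection.

    Each run regenerates shadows and refits the forest; a hit is recorded
    for features whose Z-score exceeds the maximum shadow Z-score.  After
    every run a two-sided binomial test (p = q = 0.5) on the accumulated
    hits, Bonferroni-corrected across the original feature count, confirms
    or rejects features.  Rejected features are dropped from subsequent
    runs; confirmed features stay in the forest.  The loop stops early once
    no feature is tentative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    if max_runs < 10:
        raise ValueError("max_runs must be at least 10")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    p = X.shape[1]
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length mismatch")

    alpha_corr = alpha / p  # Bonferroni across the original features
    status = {f: TENTATIVE for f in names}
    hits = np.zeros(p, dtype=int)
    runs = np.zeros(p, dtype=int)
    z_history: dict[str, list[float]] = {f: [] for f in names}
    mzsa_history: list[float] = []
    active = np.arange(p)

    for _ in range(max_runs):
        X_act = X[:, active]
        X_aug = make_shadows(X_act, rng)
        z = importance_zscores(X_aug, y, rf_params, rng)
        k = len(active)
        z_real, z_shadow = z[:k], z[k:]
        mzsa = float(z_shadow.max())
        mzsa_history.append(mzsa)
        hit = z_real > mzsa
        hits[active] += hit
        runs[active] += 1
        for pos, j in enumerate(active):
            z_history[names[j]].append(float(z_real[pos]))

        keep = np.ones(k, dtype=bool)
        for pos, j in enumerate(active):
            f = names[j]
            if status[f] != TENTATIVE:
                continue
            res = stats.binomtest(int(hits[j]), int(runs[j]), 0.5)
            if res.pvalue < alpha_corr:
                if hits[j] > runs[j] / 2:
                    status[f] = CONFIRMED
                else:
                    status[f] = REJECTED
                    keep[pos] = False
        active = active[keep]
        if all(status[f] != TENTATIVE for f in names):
            break

    return BorutaDecision(
        feature_names=names,
        status=status,
        hits={f: int(hits[j]) for j, f in enumerate(names)},
        n_runs={f: int(runs[j]) for j, f in enumerate(names)},
        z_history=z_history,
        mzsa_history=mzsa_history,
        alpha=alpha,
    )
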