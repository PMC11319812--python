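"""Shapley-value attribution for regression models.

Both routines use the interventional convention: the value of a coalition F
for sample x is the mean model output over a background (reference) matrix
whose columns in F are overwritten with x's values,

    f_x(F) = mean_z f(x_F, z_{S \\ F}),

and the Shapley value of feature j is the factorial-weighted sum of its
marginal contributions over all subsets F of S \\ {j}:

    phi_j(x) = sum_F |F|! (|S|-|F|-1)! / |S|! * [f_x(F u {j}) - f_x(F)].

``shap_exact`` evaluates that sum literally (feasible up to 15 features) and
serves as the oracle for ``shap_fast``, a polynomial-time algorithm for tree
ensembles.  For a single tree and a single background row z, the coalition
game is a sum of leaf indicator games: a leaf is reached under coalition F
iff every path feature taken from x routes toward it when in F and every
path feature taken from z routes toward it when not in F.  Writing U for
the path features only x satisfies and V for those only z satisfies (a leaf
with a feature satisfied by neither can never be reached), the Shapley
value of the indicator game has the closed form

    phi_j = (|U|-1)! |V|! / (|U|+|V|)!        for j in U,
    phi_j = -|U|! (|V|-1)! / (|U|+|V|)!       for j in V,

which summed over leaves, background rows and trees yields exact
interventional Shapley values satisfying the efficiency axiom.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.special import gammaln

MAX_EXACT_FEATURES = 15


def shap_exact(
    model_predict,
    x: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Shapley values by brute-force subset enumeration.

    ``model_predict`` maps an (m, p) matrix to m predictions.  Feasible for
    p <= 15; above that, use ``shap_fast`` for tree ensembles.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = len(x)
    if p > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{p} features exceed the enumeration limit ({MAX_EXACT_FEATURES}); "
            "use shap_fast for tree ensembles"
        )
    if background.shape[1] != p:
        raise ValueError("background column count must match x")
    n_bg = len(background)

    # coalition values v[mask], evaluated in memory-bounded chunks
    n_sub = 1 << p
    v = np.empty(n_sub)
    chunk = max(1, 2**22 // max(1, n_bg * p))
    for start in range(0, n_sub, chunk):
        masks = np.arange(start, min(start + chunk, n_sub))
        stacked = np.repeat(background[None, :, :], len(masks), axis=0)
        for j in range(p):
            member = (masks >> j) & 1 == 1
            stacked[member, :, j] = x[j]
        v[masks] = (
            model_predict(stacked.reshape(len(masks) * n_bg, p))
            .reshape(len(masks), n_bg)
            .mean(axis=1)
        )

    weights = np.array(
        [factorial(f) * factorial(p - f - 1) / factorial(p) for f in range(p)]
    )
    all_masks = np.arange(n_sub)
    sizes = np.array([int(m).bit_count() for m in range(n_sub)])
    phi = np.zeros(p)
    for j in range(p):
        without = all_masks[(all_masks >> j) & 1 == 0]
        phi[j] = np.sum(weights[sizes[without]] * (v[without | (1 << j)] - v[without]))
    return phi


def _tree_leaf_table(tree) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-leaf path constraints of an sklearn regression tree.

    Returns padded arrays (features, lows, highs) of shape (L, D) and leaf
    values (L,).  A sample x follows the path to leaf l iff
    ``lows[l, t] < x[features[l, t]] <= highs[l, t]`` for every slot t;
    padding slots use (-inf, +inf] bounds and are satisfied by everything.
    """
    t = tree.tree_
    leaves: list[tuple[dict, float]] = []

    def walk(node: int, bounds: dict[int, tuple[float, float]]) -> None:
        if t.children_left[node] == -1:
            leaves.append((dict(bounds), float(t.value[node, 0, 0])))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        bounds[f] = (lo, min(hi, thr))
        walk(t.children_left[node], bounds)
        bounds[f] = (max(lo, thr), hi)
        walk(t.children_right[node], bounds)
        if lo == -np.inf and hi == np.inf:
            del bounds[f]
        else:
            bounds[f] = (lo, hi)

    walk(0, {})
    L = len(leaves)
    D = max(1, max(len(b) for b, _ in leaves))
    features = np.zeros((L, D), dtype=np.intp)
    lows = np.full((L, D), -np.inf)
    highs = np.full((L, D), np.inf)
    values = np.empty(L)
    for l, (bounds, val) in enumerate(leaves):
        values[l] = val
        for s, (f, (lo, hi)) in enumerate(bounds.items()):
            features[l, s] = f
            lows[l, s] = lo
            highs[l, s] = hi
    return features, lows, highs, values


def _shapley_coef_tables(dmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form leaf-game coefficients indexed by (|U|, |V|)."""
    u = np.arange(dmax + 1, dtype=float)[:, None]
    v = np.arange(dmax + 1, dtype=float)[None, :]
    with np.errstate(invalid="ignore"):
        pu = np.exp(gammaln(u) + gammaln(v + 1) - gammaln(u + v + 1))
        pv = -np.exp(gammaln(u + 1) + gammaln(v) - gammaln(u + v + 1))
    pu[0, :] = 0.0  # coefficient for j in U requires |U| >= 1
    pv[:, 0] = 0.0
    return pu, pv


def _tree_shap(tree, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    features, lows, highs, values = _tree_leaf_table(tree)
    L, D = features.shape
    n_x, p = X.shape
    n_b = len(background)

    ok_x = (X[:, features] > lows) & (X[:, features] <= highs)        # (n_x, L, D)
    ok_z = (background[:, features] > lows) & (background[:, features] <= highs)

    xo = ok_x[:, None, :, :]
    zo = ok_z[None, :, :, :]
    U = xo & ~zo
    V = zo & ~xo
    valid = ~(~xo & ~zo).any(axis=3)                                  # (n_x, n_b, L)
    u = U.sum(axis=3)
    v = V.sum(axis=3)
    pu, pv = _shapley_coef_tables(D)
    coef_u = pu[u, v] * values[None, None, :]
    coef_v = pv[u, v] * values[None, None, :]

    phi_t = np.zeros((p, n_x))
    for s in range(D):
        contrib = np.where(U[:, :, :, s] & valid, coef_u, 0.0)
        contrib += np.where(V[:, :, :, s] & valid, coef_v, 0.0)
        per_leaf = contrib.sum(axis=1)                                # (n_x, L)
        np.add.at(phi_t, features[:, s], per_leaf.T)
    return phi_t.T / n_b


def shap_fast(model, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Interventional Shapley values for a tree ensemble, shape (n_x, p).

    ``model`` is a fitted sklearn forest (its trees are averaged), a single
    fitted tree, or a sequence of fitted trees.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if X.shape[1] != background.shape[1]:
        raise ValueError("X and background must have the same feature count")
    if hasattr(model, "estimators_"):
        trees = list(model.estimators_)
    elif hasattr(model, "tree_"):
        trees = [model]
    else:
        trees = list(model)
        if not trees:
            raise ValueError("empty tree ensemble")
        for t in trees:
            if not hasattr(t, "tree_"):
                raise ValueError("model must be a fitted tree ensemble")
    phi = np.zeros(X.shape)
    for tree in trees:
        phi += _tree_shap(tree, X, background)
    return phi / len(trees)


def expected_value(model_predict, background: np.ndarray) -> float:
    """Base value: mean model output over the background matrix."""
    return float(np.mean(model_predict(np.atleast_2d(background))))


@dataclass
class ShapReport:
    """Per-province Shapley values averaged over CV repeats, with ranking."""

    values: np.ndarray              # (n_samples, n_features)
    feature_names: list[str]
    sample_ids: np.ndarray | None = None

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(-self.mean_abs)
        return [self.feature_names[j] for j in order]


def aggregate_shap(
    per_repeat: list[np.ndarray],
    feature_names: list[str],
    sample_ids: np.ndarray | None = None,
) -> ShapReport:
    """Mean the per-repeat (n_samples, n_features) Shapley matrices.

    Every repeat must cover every sample (out-of-fold coverage guarantees
    exactly one value per sample per repeat).
    """
    if not per_repeat:
        raise ValueError("no SHAP matrices to aggregate")
    stack = np.stack(per_repeat)
    if np.isnan(stack).any():
        raise ValueError("incomplete sample coverage in at least one repeat")
    return ShapReport(stack.mean(axis=0), list(feature_names), sample_ids)
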