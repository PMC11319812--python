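"""SMR regression: linear and random-forest models under repeated k-fold CV.

The forest follows the study configuration of 600 trees with ceil(S/3)
candidate features per split, mean-decrease-impurity importances, and trees
grown to full depth.  Cross-validation is 5-fold, repeated (100 times at
full scale) with a fresh random partition per repeat; the per-repeat error
is the mean over folds of the mean absolute error of out-of-fold
predictions, and the predicted-vs-actual association is the Pearson
correlation of the pooled out-of-fold predictions.

When feature selection is enabled, Boruta runs on each training fold only
and the model is fit on the confirmed features; features never confirmed
score zero importance in that fit.  Optionally the out-of-fold samples of
every fold are also explained with interventional tree-Shapley values
against a training-fold background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from . import boruta as boruta_mod
from . import explain


@dataclass
class LinearModelFit:
    """Ordinary-least-squares fit y = b0 + b1 x1 + ... + bn xn + eta."""

    intercept: float
    coefficients: np.ndarray
    residual_sd: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


@dataclass
class RFConfig:
    """Forest configuration: tree count and features per split.

    ``max_features=None`` means ceil(S/3) resolved at fit time from the
    number of input features S.
    """

    n_trees: int = 600
    max_features: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_max_features(self, n_features: int) -> int:
        f = self.max_features if self.max_features is not None else math.ceil(n_features / 3)
        if not 1 <= f <= n_features:
            raise ValueError(f"features per split {f} outside [1, {n_features}]")
        return f


def fit_linear(X: np.ndarray, y: np.ndarray) -> LinearModelFit:
    """OLS with an intercept; rank-deficient design matrices are an error."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than features for OLS")
    A = np.hstack([np.ones((n, 1)), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        raise ValueError("rank-deficient design matrix (duplicate or constant columns)")
    resid = y - A @ beta
    dof = max(1, n - p - 1)
    return LinearModelFit(float(beta[0]), beta[1:], float(np.sqrt(resid @ resid / dof)))


def fit_rf(
    X: np.ndarray, y: np.ndarray, cfg: RFConfig | None = None, random_state: int | None = None
) -> RandomForestRegressor:
    """Fit the bootstrap forest; exposes MDI importances summing to 1."""
    cfg = cfg or RFConfig()
    X = np.asarray(X, dtype=float)
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolve_max_features(X.shape[1]),
        random_state=random_state if random_state is not None else cfg.seed,
        n_jobs=1,
    )
    rf.fit(X, np.asarray(y, dtype=float))
    return rf


def mae(A: np.ndarray, P: np.ndarray) -> float:
    """Mean absolute error (1/n) sum |A_i - P_i|."""
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    if A.shape != P.shape:
        raise ValueError("actual and predicted vectors must have equal length")
    if A.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(np.abs(A - P)))


@dataclass
class CVEvaluation:
    """Out-of-fold predictions and summary metrics over repeated CV."""

    feature_names: list[str]
    mae_per_repeat: np.ndarray            # (repeats,)
    oof_predictions: np.ndarray           # (repeats, n)
    actuals: np.ndarray                   # (n,)
    pearson_r: float
    pearson_p: float
    importance_mean: np.ndarray | None    # (p,) mean MDI, unselected scored 0
    selection_frequency: np.ndarray       # (p,) fraction of fits confirming each feature
    shap_values: np.ndarray | None = None  # (n, p) mean over repeats
    boruta_fallbacks: int = 0             # fits where no feature was confirmed

    @property
    def mae_mean(self) -> float:
        return float(self.mae_per_repeat.mean())

    @property
    def mae_sd(self) -> float:
        return float(self.mae_per_repeat.std(ddof=1)) if len(self.mae_per_repeat) > 1 else 0.0

    def selected_mask(self, threshold: float = 0.5) -> np.ndarray:
        """Features confirmed in more than ``threshold`` of the fits."""
        return self.selection_frequency > threshold


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "rf",
    *,
    feature_names: list[str] | None = None,
    k: int = 5,
    repeats: int = 100,
    use_boruta: bool = False,
    seed: int = 0,
    rf_config: RFConfig | None = None,
    boruta_params: dict | None = None,
    collect_shap: bool = False,
    shap_background: int = 100,
) -> CVEvaluation:
    """Repeated k-fold cross-validation of an SMR regressor.

    Every observation is predicted exactly once per repeat (out-of-fold).
    All randomness — fold assignment, forest bootstraps, Boruta shuffles,
    background subsampling — derives from the single ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if model not in ("lm", "rf"):
        raise ValueError("model must be 'lm' or 'rf'")
    if n < k:
        raise ValueError("need at least k rows")
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    rf_config = rf_config or RFConfig()
    boruta_params = dict(boruta_params or {})
    master = np.random.SeedSequence(entropy=(int(seed), 17))
    rng = np.random.default_rng(master)

    mae_repeat = np.empty(repeats)
    oof = np.full((repeats, n), np.nan)
    sel_counts = np.zeros(p)
    imp_sum = np.zeros(p)
    n_fits = 0
    fallbacks = 0
    shap_mats: list[np.ndarray] = []

    for r in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
        fold_maes = []
        shap_r = np.full((n, p), np.nan) if collect_shap else None
        for train, test in kf.split(X):
            X_tr, y_tr = X[train], y[train]
            cols = np.arange(p)
            if use_boruta:
                decision = boruta_mod.boruta_run(
                    X_tr, y_tr,
                    feature_names=names,
                    rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))),
                    **boruta_params,
                )
                mask = decision.selected_mask()
                if mask.any():
                    cols = np.flatnonzero(mask)
                else:
                    fallbacks += 1  # nothing confirmed: fall back to all features
            sel_counts[cols] += 1
            n_fits += 1
            if model == "lm":
                fit = fit_linear(X_tr[:, cols], y_tr)
                pred = fit.predict(X[test][:, cols])
            else:
                rf_seed = int(rng.integers(0, 2**31 - 1))
                fit = fit_rf(X_tr[:, cols], y_tr, rf_config, random_state=rf_seed)
                pred = fit.predict(X[test][:, cols])
                imp_sum[cols] += fit.feature_importances_
                if collect_shap:
                    bg = X_tr[:, cols]
                    if len(bg) > shap_background:
                        bg = bg[rng.choice(len(bg), shap_background, replace=False)]
                    shap_r[np.ix_(test, cols)] = explain.shap_fast(fit, X[test][:, cols], bg)
            oof[r, test] = pred
            fold_maes.append(mae(y[test], pred))
        mae_repeat[r] = float(np.mean(fold_maes))
        if collect_shap:
            shap_mats.append(np.nan_to_num(shap_r, nan=0.0))

    pooled_pred = oof.ravel()
    pooled_act = np.tile(y, repeats)
    r_val, p_val = stats.pearsonr(pooled_pred, pooled_act)

    return CVEvaluation(
        feature_names=names,
        mae_per_repeat=mae_repeat,
        oof_predictions=oof,
        actuals=y,
        pearson_r=float(r_val),
        pearson_p=float(p_val),
        importance_mean=imp_sum / n_fits if model == "rf" else None,
        selection_frequency=sel_counts / n_fits,
        shap_values=np.stack(shap_mats).mean(axis=0) if shap_mats else None,
        boruta_fallbacks=fallbacks,
    )
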