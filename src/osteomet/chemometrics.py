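"""PCA and PLS-DA in scikit-learn estimator style.

PLS-DA is PLS1 regression (NIPALS) on a 0/1 dummy coding of two classes,
with prediction at a 0.5 cutoff.  Variable importance in projection follows
the standard Wold definition

    VIP_k = sqrt( p * sum_a SSY_a (w_ak / ||w_a||)^2 / sum_a SSY_a )

where SSY_a = q_a^2 t_a't_a is the y-variance captured by component a; the
mean squared VIP over variables is 1 by construction.  Loadings can be
back-transformed to the original intensity scale by multiplying each
variable's loading by its standard deviation.
"""

from __future__ import annotations

import inspect
import warnings

import numpy as np


class _BaseEstimator:
    """Minimal get_params/set_params so estimators compose with sklearn
    pipelines and model selection without importing sklearn at runtime."""

    @classmethod
    def _param_names(cls):
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self

    def __repr__(self):
        args = ", ".join(f"{k}={getattr(self, k)!r}" for k in self._param_names())
        return f"{type(self).__name__}({args})"


def _validate_X(X, min_samples=1):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x variables array")
    if X.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


class Scaler(_BaseEstimator):
    """Column centering ('center') or unit-variance autoscaling ('uv').

    Zero-variance columns are dropped with a warning in 'uv' mode (kept,
    centered, in 'center' mode).  ``inverse_transform`` restores original
    values for retained columns.
    """

    def __init__(self, mode: str = "uv"):
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("center", "uv"):
            raise ValueError("mode must be 'center' or 'uv'")
        X = _validate_X(X, min_samples=1)
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        if self.mode == "uv":
            keep = self.std_ > 0
            if not np.all(keep):
                warnings.warn(f"dropping {int((~keep).sum())} zero-variance "
                              "column(s) before UV scaling", stacklevel=2)
            self.keep_ = keep
        else:
            self.keep_ = np.ones(X.shape[1], dtype=bool)
        return self

    def transform(self, X):
        X = _validate_X(X)
        Xc = X[:, self.keep_] - self.mean_[self.keep_]
        if self.mode == "uv":
            Xc = Xc / self.std_[self.keep_]
        return Xc

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def inverse_transform(self, Xs):
        Xs = np.asarray(Xs, dtype=float)
        if self.mode == "uv":
            Xs = Xs * self.std_[self.keep_]
        return Xs + self.mean_[self.keep_]

    @property
    def retained_std_(self):
        return (self.std_[self.keep_] if self.mode == "uv"
                else np.ones(int(self.keep_.sum())))


def _fix_sign(vec: np.ndarray) -> float:
    """Deterministic sign convention: the largest-|entry| element positive."""
    j = int(np.argmax(np.abs(vec)))
    return -1.0 if vec[j] < 0 else 1.0


class PCA(_BaseEstimator):
    """Principal component analysis via SVD of the scaled matrix.

    Components are ordered by explained variance with the deterministic
    sign convention (largest-|loading| element positive).
    """

    def __init__(self, n_components: int = 2, scale: str = "center"):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = _validate_X(X, min_samples=2)
        self.scaler_ = Scaler(mode=self.scale).fit(X)
        Xs = self.scaler_.transform(X)
        rank = min(Xs.shape)
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank {rank}")
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        A = self.n_components
        flips = np.array([_fix_sign(Vt[a]) for a in range(A)])
        self.components_ = Vt[:A] * flips[:, None]
        self.scores_ = (U[:, :A] * S[:A]) * flips[None, :]
        n = Xs.shape[0]
        ev = S ** 2 / (n - 1)
        self.explained_variance_ = ev[:A]
        self.explained_variance_ratio_ = ev[:A] / ev.sum()
        return self

    def transform(self, X):
        return self.scaler_.transform(X) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_

    def inverse_transform(self, scores):
        return self.scaler_.inverse_transform(
            np.asarray(scores) @ self.components_)


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 NIPALS on already centered/scaled data.

    Returns (W weights, T scores, P x-loadings, q y-loadings) with columns
    per component.  Deflates both X and y; stops early when no covariance
    remains.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    n, p = X.shape
    W, T, P, q = [], [], [], []
    for _ in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.abs(X).max(initial=0.0)):
            break
        w = w / nw
        sgn = _fix_sign(w)
        w = w * sgn
        t = X @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_load = X.T @ t / tt
        q_a = float(y @ t / tt)
        X = X - np.outer(t, p_load)
        y = y - q_a * t
        W.append(w)
        T.append(t)
        P.append(p_load)
        q.append(q_a)
    if not W:
        raise ValueError("no usable covariance between X and y")
    return (np.column_stack(W), np.column_stack(T),
            np.column_stack(P), np.asarray(q))


def vip_scores(W: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Wold VIP from weights, scores and y-loadings (see module docstring)."""
    p = W.shape[0]
    ssy = q ** 2 * (T ** 2).sum(axis=0)            # per-component y-variance
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    denom = ssy.sum()
    if denom <= 0:
        return np.zeros(p)
    return np.sqrt(p * (wn2 * ssy).sum(axis=1) / denom)


class PLSDA(_BaseEstimator):
    """Two-class PLS-DA with internal train-only scaling.

    Labels are dummy-coded 0/1 in sorted label order; prediction thresholds
    the continuous regression output at 0.5 (exact ties go to class 0).
    """

    def __init__(self, n_components: int = 2, scale: str = "uv"):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = _validate_X(X, min_samples=2)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("PLS-DA requires exactly two classes in y")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        y01 = (y == self.classes_[1]).astype(float)
        self.y_mean_ = float(y01.mean())
        self.scaler_ = Scaler(mode=self.scale).fit(X)
        Xs = self.scaler_.transform(X)
        yc = y01 - self.y_mean_
        W, T, P, q = nipals_pls1(Xs, yc, self.n_components)
        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, q
        self.n_components_ = W.shape[1]
        # regression vector in scaled space: b = W (P'W)^-1 q
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        self.vip_ = vip_scores(W, T, q)
        self.back_loadings_ = P * self.scaler_.retained_std_[:, None]
        ssy = q ** 2 * (T ** 2).sum(axis=0)
        tssy = float((yc ** 2).sum())
        self.explained_y_variance_ratio_ = (ssy / tssy if tssy > 0
                                            else np.zeros_like(ssy))
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous prediction on the 0/1 dummy scale."""
        Xs = self.scaler_.transform(_validate_X(X))
        return self.y_mean_ + Xs @ self.coef_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0.5,
                        self.classes_[1], self.classes_[0])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def to_dict(self) -> dict:
        """JSON-compatible export of the fitted model."""
        return {
            "classes": self.classes_.tolist(),
            "scale": self.scale,
            "n_components": self.n_components_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
            "vip": self.vip_.tolist(),
            "back_loadings": self.back_loadings_.tolist(),
            "y_mean": self.y_mean_,
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_std": self.scaler_.std_.tolist(),
            "scaler_keep": self.scaler_.keep_.tolist(),
        }


def fit_pca(X, n_components: int = 2, scale: str = "center") -> PCA:
    return PCA(n_components=n_components, scale=scale).fit(X)


def fit_plsda(X, y, n_components: int = 2, scale: str = "uv") -> PLSDA:
    return PLSDA(n_components=n_components, scale=scale).fit(X, y)


def vip(model: PLSDA) -> np.ndarray:
    """Per-variable VIP of a fitted PLS-DA model."""
    if not hasattr(model, "vip_"):
        raise ValueError("model is not fitted")
    return model.vip_
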