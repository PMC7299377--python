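"""Sparse network-regularized linear models.

Four regression models for a continuous trait y on a concatenated
multi-omic feature matrix X (standardized by default):

``ModularityLasso``
    minimises ``(1/2)||y - Xw||^2 + (lam/2) w'(lambda_B I - B) w + threshold ||w||_1``
    where B is the modularity matrix of a prior feature network and
    ``lambda_B`` its largest absolute eigenvalue.  Because ``lambda_B I - B``
    is positive semidefinite the problem is convex; rewarding ``w'Bw``
    steers the nonzero support toward densely interconnected modules of the
    prior network rather than isolated features.

``GraphNetLasso``
    replaces the modularity term with the Laplacian smoothness penalty
    ``(lam/2) w'Lw``, which enforces local pairwise similarity of
    coefficients of connected features.

``Lasso`` / ``ElasticNet``
    the plain L1 model and its L2-stabilised variant (``ridge`` acting as
    the elastic-net quadratic weight).

Two solver modes are available.  ``closed_form`` follows the one-pass
scheme of solving the smooth quadratic exactly and then soft-thresholding
once; it is exact whenever the effective design is orthonormal or the L1
term is absent, and is deterministic and fast.  ``proximal`` runs ISTA
(proximal gradient with a 1/L step) on the full composite objective to the
requested tolerance and is exact for every convex instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .network import TransOmicNetwork

__all__ = [
    "soft_threshold",
    "modularity_penalty",
    "mlasso_smooth_solution",
    "ModularityLasso",
    "GraphNetLasso",
    "Lasso",
    "ElasticNet",
    "FitConfig",
    "ModelFit",
    "fit_mlasso",
    "fit_glasso",
    "fit_lasso",
    "fit_enet",
    "fit_model",
    "predict",
    "MODEL_REGISTRY",
]


def soft_threshold(v: np.ndarray | float, theta: float) -> np.ndarray:
    """Elementwise soft-thresholding ``sign(v) * max(|v| - theta, 0)``.

    The proximal operator of ``theta * || . ||_1``.
    """
    if theta < 0:
        raise ValueError(f"soft-threshold level must be >= 0, got {theta}")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - theta, 0.0)


def modularity_penalty(w: np.ndarray, B: np.ndarray) -> float:
    """Quadratic form ``sum_ij w_i B_ij w_j`` (Frobenius product <w w', B>).

    Positive values indicate a weight support concentrated on feature sets
    that are more densely interconnected than a degree-matched random graph
    would predict; for any valid modularity matrix the all-ones vector gives
    exactly zero (rows of B sum to zero).
    """
    w = np.asarray(w, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    if B.shape != (w.size, w.size):
        raise ValueError(f"dimension mismatch: w has {w.size} entries, B is {B.shape}")
    return float(w @ B @ w)


def mlasso_smooth_solution(
    X: np.ndarray,
    y: np.ndarray,
    B_shifted: np.ndarray,
    lam: float,
    ridge: float = 0.0,
) -> np.ndarray:
    """Exact minimiser of the smooth part of the modularity-constrained model.

    Solves ``(X'X - lam * B_shifted + ridge * I) w = X'y`` where
    ``B_shifted = B - lambda_B I`` must be negative semidefinite (so the
    quadratic is convex).  Raises if the shift leaves a positive eigenvalue
    beyond tolerance or if the system is singular with ``ridge = 0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    B_shifted = np.asarray(B_shifted, dtype=float)
    p = X.shape[1]
    if B_shifted.shape != (p, p):
        raise ValueError(f"B_shifted must be {p}x{p}, got {B_shifted.shape}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if B_shifted.size:
        top = float(np.max(np.linalg.eigvalsh((B_shifted + B_shifted.T) / 2.0)))
        if top > 1e-6:
            raise ValueError(
                f"B_shifted is not negative semidefinite (max eigenvalue {top:.3g} > 1e-6); "
                "shift B by its largest absolute eigenvalue first"
            )
    A = X.T @ X - lam * B_shifted + ridge * np.eye(p)
    b = X.T @ y
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular smooth system; set ridge > 0 to regularize"
        ) from exc
    resid = np.linalg.norm(A @ w - b)
    if resid > 1e-8 * max(1.0, np.linalg.norm(b)):
        raise ValueError(
            "ill-conditioned smooth system (relative residual "
            f"{resid / max(1.0, np.linalg.norm(b)):.3g}); set ridge > 0 to regularize"
        )
    return w


def _ista(A: np.ndarray, b: np.ndarray, theta: float, w0: np.ndarray,
          max_iter: int, tol: float) -> tuple[np.ndarray, int, list[float]]:
    """ISTA on ``(1/2) w'Aw - b'w + theta ||w||_1`` with step 1/L.

    A must be symmetric PSD.  Returns (w, n_iter, objective trace); the
    objective is non-increasing at every iteration by the majorization
    property of the 1/L proximal step.
    """
    L = float(np.max(np.linalg.eigvalsh(A))) if A.size else 1.0
    L = max(L, 1e-12)
    w = w0.copy()

    def obj(wv):
        return 0.5 * wv @ A @ wv - b @ wv + theta * np.abs(wv).sum()

    trace = [obj(w)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = A @ w - b
        w_new = soft_threshold(w - grad / L, theta / L)
        trace.append(obj(w_new))
        delta = np.max(np.abs(w_new - w)) if w.size else 0.0
        w = w_new
        if delta <= tol * max(1.0, np.max(np.abs(w)) if w.size else 1.0):
            break
    return w, n_iter, trace


class _BaseSparseNet(RegressorMixin, BaseEstimator):
    """Shared machinery for the four penalized regressions."""

    _requires_network = False

    def __init__(self, lam=1.0, threshold=0.1, ridge=1e-8, standardize=True,
                 solver="closed_form", max_iter=20000, tol=1e-8, network=None):
        self.lam = lam
        self.threshold = threshold
        self.ridge = ridge
        self.standardize = standardize
        self.solver = solver
        self.max_iter = max_iter
        self.tol = tol
        self.network = network

    # subclasses return the p x p quadratic-penalty matrix (in the order of
    # the fitted feature columns) or None for pure L1/L2 models
    def _penalty_matrix(self, feature_ids) -> np.ndarray | None:
        return None

    def _validate_params_(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.solver not in ("closed_form", "proximal"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self._requires_network and self.network is None:
            raise ValueError(f"{type(self).__name__} requires a prior network")

    def _coerce_X(self, X, fitting: bool):
        names = None
        if isinstance(X, pd.DataFrame):
            names = list(map(str, X.columns))
            if len(set(names)) != len(names):
                raise ValueError("duplicate feature names in X")
            if not fitting:
                missing = [f for f in self.feature_names_in_ if f not in names]
                if missing:
                    raise ValueError(f"X_new is missing training features: {missing[:5]}")
                X = X.loc[:, list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isfinite(X).all():
            raise ValueError("X contains NaN or infinite values")
        return X, names

    def fit(self, X, y):
        self._validate_params_()
        X, names = self._coerce_X(X, fitting=True)
        if isinstance(y, (pd.Series, pd.DataFrame)):
            y = y.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
        if not np.isfinite(y).all():
            raise ValueError("y contains NaN or infinite values")
        if n < 2:
            raise ValueError("need at least 2 samples")
        self.n_features_in_ = p
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        elif hasattr(self, "feature_names_in_"):
            del self.feature_names_in_

        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.x_scale_ = np.where(sd > 0, sd, 1.0)
            self.y_mean_ = float(y.mean())
        else:
            self.x_mean_ = np.zeros(p)
            self.x_scale_ = np.ones(p)
            self.y_mean_ = 0.0
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = y - self.y_mean_

        feature_ids = list(self.feature_names_in_) if names is not None else None
        M = self._penalty_matrix(feature_ids)
        if M is not None and M.shape != (p, p):
            raise ValueError(
                f"network penalty matrix is {M.shape} but X has {p} feature columns; "
                "feature IDs must align with network nodes"
            )

        A = Xs.T @ Xs + self.ridge * np.eye(p)
        if M is not None and self.lam > 0:
            A = A + self.lam * M
        b = Xs.T @ ys

        if self.solver == "closed_form":
            try:
                w_smooth = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular smooth system; set ridge > 0") from exc
            w = soft_threshold(w_smooth, self.threshold)
            self.smooth_coef_ = w_smooth
            self.n_iter_ = 1
        else:
            w, self.n_iter_, trace = _ista(
                A, b, self.threshold, np.zeros(p), self.max_iter, self.tol
            )
            self.objective_trace_ = trace
        self.coef_ = w
        self.intercept_ = self.y_mean_ - float((self.x_mean_ / self.x_scale_) @ w)
        self.selected_ = w != 0
        self.objective_value_ = float(
            0.5 * np.sum((ys - Xs @ w) ** 2)
            + (0.5 * self.lam * (w @ M @ w) if M is not None else 0.0)
            + 0.5 * self.ridge * np.sum(w**2)
            + self.threshold * np.abs(w).sum()
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X, _ = self._coerce_X(X, fitting=False)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X @ (self.coef_ / self.x_scale_) + self.intercept_

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self, "coef_")
        if hasattr(self, "feature_names_in_"):
            return [f for f, s in zip(self.feature_names_in_, self.selected_) if s]
        return [str(i) for i in np.flatnonzero(self.selected_)]


class ModularityLasso(_BaseSparseNet):
    """Lasso with a modularity reward from a prior feature network.

    ``lam`` scales the (convexified) modularity penalty
    ``w'(lambda_B I - B)w``; ``threshold`` is the soft-threshold level of
    the L1 part.  The ``network`` must be a :class:`TransOmicNetwork` whose
    nodes match the feature columns (by name when X is a DataFrame,
    otherwise by position).
    """

    _requires_network = True

    def _penalty_matrix(self, feature_ids):
        net: TransOmicNetwork = self.network
        M = net.lambda_B * np.eye(net.p) - net.B
        if feature_ids is not None:
            return net.embed(M, feature_ids)
        return M


class GraphNetLasso(_BaseSparseNet):
    """Lasso with a Laplacian (GraphNet) smoothness penalty ``lam * w'Lw``."""

    _requires_network = True

    def _penalty_matrix(self, feature_ids):
        net: TransOmicNetwork = self.network
        if feature_ids is not None:
            return net.embed(net.L, feature_ids)
        return net.L


class Lasso(_BaseSparseNet):
    """Plain L1-penalized least squares (one-pass or proximal solver)."""

    def __init__(self, threshold=0.1, ridge=1e-8, standardize=True,
                 solver="closed_form", max_iter=20000, tol=1e-8):
        super().__init__(lam=0.0, threshold=threshold, ridge=ridge,
                         standardize=standardize, solver=solver,
                         max_iter=max_iter, tol=tol, network=None)


class ElasticNet(Lasso):
    """L1 + L2 penalized least squares; ``ridge`` is the quadratic weight."""

    def __init__(self, threshold=0.1, ridge=1.0, standardize=True,
                 solver="closed_form", max_iter=20000, tol=1e-8):
        super().__init__(threshold=threshold, ridge=ridge,
                         standardize=standardize, solver=solver,
                         max_iter=max_iter, tol=tol)


MODEL_REGISTRY: dict[str, type] = {
    "mlasso": ModularityLasso,
    "glasso": GraphNetLasso,
    "lasso": Lasso,
    "enet": ElasticNet,
}

_NETWORK_MODELS = ("mlasso", "glasso")


# ---------------------------------------------------------------------------
# functional surface


@dataclass
class FitConfig:
    """Hyperparameters and solver controls for one model fit."""

    lam: float = 1.0
    threshold: float = 0.1
    ridge: float = 1e-8
    standardize: bool = True
    solver: str = "closed_form"
    max_iter: int = 20000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0 or self.threshold < 0 or self.ridge < 0:
            raise ValueError("lam, threshold and ridge must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ModelFit:
    """Result of one model fit on a dataset."""

    model: str
    w: pd.Series
    selected: tuple[str, ...]
    config: FitConfig
    objective_value: float
    n_iter: int
    estimator: _BaseSparseNet = field(repr=False)

    @property
    def support_size(self) -> int:
        return len(self.selected)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "config": asdict(self.config),
            "objective_value": self.objective_value,
            "n_iter": self.n_iter,
            "support_size": self.support_size,
            "selected": list(self.selected),
        }


def _make_estimator(model: str, net: TransOmicNetwork | None, config: FitConfig):
    if model not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODEL_REGISTRY)}")
    kwargs = dict(
        threshold=config.threshold, ridge=config.ridge,
        standardize=config.standardize, solver=config.solver,
        max_iter=config.max_iter, tol=config.tol,
    )
    if model in _NETWORK_MODELS:
        if net is None:
            raise ValueError(f"model {model!r} requires a prior network")
        kwargs.update(lam=config.lam, network=net)
    return MODEL_REGISTRY[model](**kwargs)


def fit_model(model: str, data, net: TransOmicNetwork | None = None,
              config: FitConfig | None = None) -> ModelFit:
    """Fit one of the registered models on a :class:`MultiOmicDataset`."""
    config = config or FitConfig()
    est = _make_estimator(model, net, config)
    est.fit(data.X, data.y)
    w = pd.Series(est.coef_, index=list(data.X.columns), name="weight")
    return ModelFit(
        model=model,
        w=w,
        selected=tuple(w.index[est.selected_]),
        config=config,
        objective_value=est.objective_value_,
        n_iter=est.n_iter_,
        estimator=est,
    )


def fit_mlasso(data, net, config: FitConfig | None = None) -> ModelFit:
    return fit_model("mlasso", data, net, config)


def fit_glasso(data, net, config: FitConfig | None = None) -> ModelFit:
    return fit_model("glasso", data, net, config)


def fit_lasso(data, config: FitConfig | None = None) -> ModelFit:
    return fit_model("lasso", data, None, config)


def fit_enet(data, config: FitConfig | None = None) -> ModelFit:
    return fit_model("enet", data, None, config)


def predict(fit: ModelFit, X_new) -> np.ndarray:
    """Predict the outcome for new subjects with a fitted model."""
    return fit.estimator.predict(X_new)
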