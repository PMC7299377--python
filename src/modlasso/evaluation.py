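"""Model evaluation: stratified folds, nested CV, error metrics, and the
degree--weight analysis of selected features.

The protocol mirrors standard practice for penalized regression on cohort
data: outer k-fold cross-validation stratified by diagnosis estimates test
error (RMSE, MAE), while an inner k-fold grid search on each outer training
set chooses the hyperparameters.  The same fold plan is reused across all
models being compared so error differences are not fold artefacts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import FitConfig, ModelFit, fit_model, predict, MODEL_REGISTRY, _NETWORK_MODELS
from .network import TransOmicNetwork, induced_components

__all__ = [
    "FoldPlan",
    "FoldResult",
    "CVResult",
    "stratified_folds",
    "rmse",
    "mae",
    "grid_search_fit",
    "nested_cv",
    "compare_models",
    "degree_weight_correlation",
    "selection_summary",
    "DEFAULT_GRIDS",
]

# logarithmic default grids; lam in 10^-3..10^2, threshold in 10^-3..10^1
DEFAULT_GRIDS: dict[str, dict[str, list[float]]] = {
    "mlasso": {"lam": list(np.logspace(-3, 2, 6)),
               "threshold": list(np.logspace(-3, 1, 5))},
    "glasso": {"lam": list(np.logspace(-3, 2, 6)),
               "threshold": list(np.logspace(-3, 1, 5))},
    "lasso": {"threshold": list(np.logspace(-3, 1, 5))},
    "enet": {"threshold": list(np.logspace(-3, 1, 5)),
             "ridge": [0.1, 1.0, 10.0]},
}


@dataclass
class FoldPlan:
    """Deterministic stratified assignment of subjects to k folds."""

    k: int
    assignments: dict[str, int]
    strata: dict[str, str]
    seed: int
    warnings: tuple[str, ...] = ()

    def test_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f != fold]


def stratified_folds(labels: Mapping[str, str] | pd.Series, k: int,
                     seed: int = 0) -> FoldPlan:
    """Partition subjects into k folds preserving stratum proportions.

    Within every stratum the fold sizes differ by at most one subject.  If a
    stratum has fewer members than ``k`` a warning is recorded on the plan
    (some folds then lack that stratum) but the assignment remains valid.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if k < 2:
        raise ValueError("k must be >= 2")
    if not labels:
        raise ValueError("no subjects to assign")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    warns: list[str] = []
    offset = 0
    for stratum in sorted(set(labels.values())):
        members = [s for s in labels if labels[s] == stratum]
        if len(members) < k:
            warns.append(
                f"stratum {stratum!r} has {len(members)} subjects < k={k}; "
                "some folds will lack it"
            )
        order = rng.permutation(len(members))
        # deal round-robin, rotating the starting fold across strata so the
        # remainder subjects do not pile onto the low-index folds
        for pos, idx in enumerate(order):
            assignments[members[idx]] = (pos + offset) % k
        offset += len(members)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    # keep subject order of the input mapping
    assignments = {s: assignments[s] for s in labels}
    return FoldPlan(k=k, assignments=assignments, strata=dict(labels),
                    seed=seed, warnings=tuple(warns))


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error (always <= RMSE)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(np.mean(np.abs(y_true - y_pred)))


@dataclass
class FoldResult:
    fold: int
    params: dict
    rmse: float
    mae: float
    selected: tuple[str, ...]


@dataclass
class CVResult:
    model: str
    folds: list[FoldResult]
    fold_plan: FoldPlan = field(repr=False)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([f.rmse for f in self.folds]))

    @property
    def mean_mae(self) -> float:
        return float(np.mean([f.mae for f in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": f.fold, "rmse": f.rmse, "mae": f.mae,
                 "support_size": len(f.selected), **f.params} for f in self.folds]
        return pd.DataFrame(rows).set_index("fold")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mean_rmse": self.mean_rmse,
            "mean_mae": self.mean_mae,
            "folds": [
                {"fold": f.fold, "params": f.params, "rmse": f.rmse,
                 "mae": f.mae, "selected": list(f.selected)}
                for f in self.folds
            ],
        }


def _expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    keys = sorted(grid)
    combos = []
    seen = set()
    for values in itertools.product(*(grid[k] for k in keys)):
        entry = dict(zip(keys, values))
        key = tuple(entry.items())
        if key not in seen:
            seen.add(key)
            combos.append(entry)
    return combos


def _validate_grid(model: str, combos: list[dict]):
    if model not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {model!r}")
    allowed = {"lam", "threshold", "ridge"} if model in _NETWORK_MODELS \
        else {"threshold", "ridge"}
    for entry in combos:
        bad = set(entry) - allowed
        if bad:
            raise ValueError(
                f"grid entry {entry} invalid for model {model!r}: "
                f"unknown/unsupported parameter(s) {sorted(bad)}"
            )
        FitConfig(**entry)  # range checks


def _tie_break_key(entry: dict) -> tuple:
    # smaller lam first, then larger threshold (sparser model)
    return (entry.get("lam", 0.0), -entry.get("threshold", 0.0),
            entry.get("ridge", 0.0))


def _subset(data, subjects):
    from .simulate import MultiOmicDataset  # local to avoid cycle at import

    X = data.X.loc[subjects]
    sd = X.std(axis=0, ddof=0)
    X_std = (X - X.mean(axis=0)) / sd.where(sd > 0, 1.0)
    return MultiOmicDataset(
        X=X, y=data.y.loc[subjects], layers=data.layers, X_std=X_std,
        diagnosis=None if data.diagnosis is None else data.diagnosis.loc[subjects],
        w_star=data.w_star, support=data.support, modules=data.modules,
        config=data.config,
    )


def grid_search_fit(data, net: TransOmicNetwork | None, model: str,
                    grid: Mapping[str, Sequence] | None = None, k: int = 5,
                    seed: int = 0, base_config: FitConfig | None = None
                    ) -> tuple[ModelFit, dict]:
    """k-fold CV over a grid, then refit on all of ``data`` with the winner.

    Hyperparameters minimise the mean validation RMSE; ties resolve toward
    the sparser model (smallest lam, then largest threshold).
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[model]
    combos = _expand_grid(grid)
    _validate_grid(model, combos)
    base = base_config or FitConfig()
    labels = data.diagnosis if data.diagnosis is not None else pd.Series(
        "all", index=data.X.index)
    plan = stratified_folds(labels, k=k, seed=seed)
    mean_rmse = {}
    for i, entry in enumerate(combos):
        errs = []
        for fold in range(k):
            tr = _subset(data, plan.train_subjects(fold))
            te = _subset(data, plan.test_subjects(fold))
            cfg = FitConfig(**{**_cfg_dict(base), **entry})
            fit = fit_model(model, tr, net, cfg)
            errs.append(rmse(te.y, predict(fit, te.X)))
        mean_rmse[i] = float(np.mean(errs))
    best_i = min(range(len(combos)),
                 key=lambda i: (mean_rmse[i], _tie_break_key(combos[i])))
    best = combos[best_i]
    cfg = FitConfig(**{**_cfg_dict(base), **best})
    return fit_model(model, data, net, cfg), best


def _cfg_dict(cfg: FitConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def nested_cv(data, net: TransOmicNetwork | None, model: str,
              grid: Mapping[str, Sequence] | None = None, k_outer: int = 5,
              k_inner: int = 5, seed: int = 0,
              fold_plan: FoldPlan | None = None,
              base_config: FitConfig | None = None) -> CVResult:
    """Nested stratified cross-validation of one model.

    For every outer fold, an inner ``k_inner``-fold grid search on the outer
    training set picks the hyperparameters (mean inner RMSE, ties toward
    sparsity); the model is refit on the full outer training set and scored
    on the held-out fold.  Pass the same ``fold_plan`` to compare several
    models on identical partitions.
    """
    if k_outer < 2 or k_inner < 2:
        raise ValueError("fold counts must be >= 2")
    grid = grid if grid is not None else DEFAULT_GRIDS[model]
    combos = _expand_grid(grid)
    _validate_grid(model, combos)
    if fold_plan is None:
        labels = data.diagnosis if data.diagnosis is not None else pd.Series(
            "all", index=data.X.index)
        fold_plan = stratified_folds(labels, k=k_outer, seed=seed)
    elif fold_plan.k != k_outer:
        raise ValueError("fold_plan.k does not match k_outer")
    folds = []
    for fold in range(k_outer):
        train = _subset(data, fold_plan.train_subjects(fold))
        test = _subset(data, fold_plan.test_subjects(fold))
        fit, best = grid_search_fit(
            train, net, model, grid={k: sorted(set(v)) for k, v in grid.items()},
            k=k_inner, seed=seed + 1 + fold, base_config=base_config,
        )
        pred = predict(fit, test.X)
        folds.append(FoldResult(
            fold=fold, params=best, rmse=rmse(test.y, pred),
            mae=mae(test.y, pred), selected=fit.selected,
        ))
    return CVResult(model=model, folds=folds, fold_plan=fold_plan)


def compare_models(data, net: TransOmicNetwork | None, models: Sequence[str],
                   grids: Mapping[str, Mapping] | None = None, k_outer: int = 5,
                   k_inner: int = 5, seed: int = 0) -> dict[str, CVResult]:
    """Run nested CV for several models on one shared fold plan."""
    labels = data.diagnosis if data.diagnosis is not None else pd.Series(
        "all", index=data.X.index)
    plan = stratified_folds(labels, k=k_outer, seed=seed)
    out = {}
    for model in models:
        grid = None if grids is None else grids.get(model)
        out[model] = nested_cv(data, net, model, grid=grid, k_outer=k_outer,
                               k_inner=k_inner, seed=seed, fold_plan=plan)
    return out


def degree_weight_correlation(fit: ModelFit, net: TransOmicNetwork,
                              min_degree: int = 0,
                              scope: str = "selected") -> tuple[float, int]:
    """Pearson correlation between node degree and |weight| of selected features.

    ``scope='selected'`` (default) takes degrees in the subgraph induced on
    the selected features; ``scope='full'`` uses full prior-network degrees.
    Returns ``(r, n_used)``; raises when fewer than 3 usable points remain
    or either variable has zero variance.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    if scope not in ("selected", "full"):
        raise ValueError("scope must be 'selected' or 'full'")
    selected = [f for f in fit.selected if f in net]
    if scope == "selected":
        sub = net.graph.subgraph(selected)
        deg = {f: sub.degree[f] for f in selected}
    else:
        deg = {f: net.graph.degree[f] for f in selected}
    pts = [(deg[f], abs(fit.w[f])) for f in selected if deg[f] >= min_degree]
    n_used = len(pts)
    if n_used < 3:
        raise ValueError(
            f"undefined correlation: only {n_used} selected features with "
            f"degree >= {min_degree}"
        )
    d = np.array([p[0] for p in pts], dtype=float)
    w = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(d) == 0 or np.ptp(w) == 0:
        raise ValueError("undefined correlation: zero variance in degrees or weights")
    r, _ = stats.pearsonr(d, w)
    return float(r), n_used


def selection_summary(fit: ModelFit, net: TransOmicNetwork,
                      min_size: int = 1) -> dict:
    """Per-layer counts and connected-component census of a fit's support."""
    selected = list(fit.selected)
    layer_counts = {layer: 0 for layer in ("SNP", "gene", "protein")}
    for f in selected:
        layer = net.layers.get(f)
        if layer in layer_counts:
            layer_counts[layer] += 1
    in_net = [f for f in selected if f in net]
    comps = induced_components(net, in_net, min_size=min_size) if in_net else []
    census: dict[int, int] = {}
    for c in comps:
        census[c.size] = census.get(c.size, 0) + 1
    largest = comps[0] if comps else None
    return {
        "support_size": len(selected),
        "layer_counts": layer_counts,
        "n_components": len(comps),
        "component_census": census,
        "largest_component_size": largest.size if largest else 0,
        "largest_component_edges": largest.n_edges if largest else 0,
    }
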