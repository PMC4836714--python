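"""Per-flux regression ensemble: SVR, k-NN and decision trees with CV tuning.

Each of the 29 fluxes gets its own single-output regressor trained on the
encoded condition features and min-max-scaled flux target.  Hyperparameters
are tuned per flux by exhaustive grid search under seeded k-fold
cross-validation scored with mean squared error on the scaled targets (so
the scores are comparable across fluxes).  Fluxes whose training range is
degenerate are predicted at their constant and skip fitting entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .encoding import CultureCondition, ScalerState, encode, unscale_targets
from .stoichiometry import FLUX_IDS, N_FLUXES, FluxVector

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "RegressorEnsemble",
    "CVResult",
    "make_folds",
    "make_estimator",
    "grid_search",
    "train",
    "predict_raw",
    "compare_algorithms",
    "save_ensemble",
    "load_ensemble",
]

ALGORITHMS = ("svr-rbf", "svr-linear", "knn", "tree")

#: default hyperparameter search grids, overridable from configuration
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svr-rbf": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "epsilon": [0.001, 0.01, 0.1],
        # multiples of scikit-learn's "scale" heuristic 1/(n_features * X.var())
        "gamma_scale_multiplier": [0.1, 1.0, 10.0],
    },
    "svr-linear": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "epsilon": [0.001, 0.01, 0.1],
    },
    "knn": {
        "n_neighbors": [1, 3, 5, 7, 9],
        "weights": ["uniform", "distance"],
    },
    "tree": {
        "max_depth": [2, 4, 8, 16, None],
    },
}


def make_folds(n_samples: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then split into k near-equal disjoint parts."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    return [np.sort(part) for part in np.array_split(perm, k)]


def make_estimator(algorithm: str, params: dict, n_features: int | None = None):
    """Instantiate a scikit-learn regressor for one grid point."""
    p = dict(params)
    if algorithm == "svr-rbf":
        mult = p.pop("gamma_scale_multiplier", 1.0)
        est = SVR(kernel="rbf", **p)
        est._gamma_multiplier = mult  # resolved at fit time against X
        return est
    if algorithm == "svr-linear":
        return SVR(kernel="linear", **p)
    if algorithm == "knn":
        return KNeighborsRegressor(**p)
    if algorithm == "tree":
        return DecisionTreeRegressor(random_state=0, **p)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _fit(est, X, y):
    """Fit, resolving the RBF gamma multiplier against this X if present."""
    mult = getattr(est, "_gamma_multiplier", None)
    if mult is not None and mult != 1.0:
        var = X.var()
        gamma = mult / (X.shape[1] * var) if var > 0 else "scale"
        est.set_params(gamma=gamma)
    est.fit(X, y)
    return est


def _grid_points(grid: dict[str, list]) -> list[dict]:
    """Cartesian product in declared key/value order (ties break to earlier)."""
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass(frozen=True)
class CVResult:
    """Cross-validation record for one flux: per-grid-point mean MSE."""

    flux_id: str
    algorithm: str
    grid_points: tuple[dict, ...]
    mean_mse: np.ndarray  # per grid point, on scaled targets
    best_index: int
    folds: tuple[np.ndarray, ...]

    @property
    def best_params(self) -> dict:
        return self.grid_points[self.best_index]

    @property
    def best_mse(self) -> float:
        return float(self.mean_mse[self.best_index])


def _cv_mse(algorithm, params, X, y, folds) -> float:
    errs = []
    n = len(y)
    for test_idx in folds:
        mask = np.ones(n, bool)
        mask[test_idx] = False
        est = make_estimator(algorithm, params)
        _fit(est, X[mask], y[mask])
        pred = est.predict(X[test_idx])
        errs.append(np.mean((pred - y[test_idx]) ** 2))
    return float(np.mean(errs))


def grid_search(
    X: np.ndarray,
    Y: np.ndarray,
    algorithm: str,
    grid: dict[str, list] | None = None,
    k: int = 10,
    seed: int = 0,
    constant_fluxes: np.ndarray | None = None,
) -> list[CVResult]:
    """Per-flux exhaustive grid search under seeded k-fold CV.

    Returns one :class:`CVResult` per flux; the best grid point minimizes the
    mean CV MSE with ties broken by grid declaration order.  Constant fluxes
    get a zero-MSE placeholder with the first grid point.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[algorithm]
    points = _grid_points(grid)
    if not points:
        raise ValueError("hyperparameter grid is empty")
    folds = make_folds(len(X), k, seed)
    if constant_fluxes is None:
        constant_fluxes = np.array([np.ptp(Y[:, j]) == 0 for j in range(Y.shape[1])])
    results = []
    for j, fid in enumerate(FLUX_IDS[: Y.shape[1]]):
        if constant_fluxes[j]:
            mse = np.zeros(len(points))
        else:
            mse = np.array([_cv_mse(algorithm, p, X, Y[:, j], folds) for p in points])
        best = int(np.argmin(mse))  # argmin takes the first minimum: grid order
        results.append(
            CVResult(
                flux_id=fid,
                algorithm=algorithm,
                grid_points=tuple(points),
                mean_mse=mse,
                best_index=best,
                folds=tuple(folds),
            )
        )
    return results


@dataclass
class RegressorEnsemble:
    """29 fitted single-flux regressors plus the scaler state they assume."""

    members: list  # fitted estimators; None for constant fluxes
    algorithms: list[str]
    params: list[dict]
    scalers: ScalerState
    constants: np.ndarray  # scaled-space constant for degenerate fluxes

    def __post_init__(self):
        if not (
            len(self.members) == len(self.algorithms) == len(self.params) == N_FLUXES
        ):
            raise ValueError(f"ensemble must have exactly {N_FLUXES} members")

    def predict_scaled(self, features: np.ndarray) -> np.ndarray:
        x = features.reshape(1, -1)
        out = np.empty(N_FLUXES)
        for j, est in enumerate(self.members):
            out[j] = self.constants[j] if est is None else est.predict(x)[0]
        return out


def train(
    X: np.ndarray,
    Y: np.ndarray,
    per_flux: list[tuple[str, dict]],
    scalers: ScalerState,
) -> RegressorEnsemble:
    """Fit all 29 regressors on the full dataset with their tuned parameters.

    ``per_flux`` carries one (algorithm, params) pair per flux.  Degenerate
    fluxes (flagged in the scaler state) are stored as constants.
    """
    if len(per_flux) != N_FLUXES:
        raise ValueError(f"need hyperparameters for all {N_FLUXES} fluxes")
    members, algs, params = [], [], []
    constants = np.zeros(N_FLUXES)
    for j, (algorithm, p) in enumerate(per_flux):
        algs.append(algorithm)
        params.append(dict(p))
        if scalers.constant_fluxes[j]:
            members.append(None)
            constants[j] = float(Y[0, j]) if len(Y) else 0.0
        else:
            members.append(_fit(make_estimator(algorithm, p), X, Y[:, j]))
    return RegressorEnsemble(
        members=members, algorithms=algs, params=params, scalers=scalers, constants=constants
    )


def predict_raw(ens: RegressorEnsemble, cond: CultureCondition, *, strict: bool = False) -> FluxVector:
    """ML-only flux prediction v-hat; makes no stoichiometric guarantee."""
    sample = encode(cond, ens.scalers, strict=strict)
    return unscale_targets(ens.predict_scaled(sample.features), ens.scalers)


def compare_algorithms(
    X: np.ndarray,
    Y: np.ndarray,
    grids: dict[str, dict[str, list]] | None = None,
    k: int = 10,
    seed: int = 0,
    constant_fluxes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Best CV MSE per flux for each algorithm (long-format table)."""
    if grids is None:
        grids = {a: DEFAULT_GRIDS[a] for a in ALGORITHMS}
    rows = []
    for algorithm, grid in grids.items():
        for res in grid_search(X, Y, algorithm, grid, k=k, seed=seed, constant_fluxes=constant_fluxes):
            rows.append(
                {
                    "flux_id": res.flux_id,
                    "algorithm": algorithm,
                    "best_params": repr(res.best_params),
                    "cv_mse": res.best_mse,
                }
            )
    return pd.DataFrame(rows)


def save_ensemble(ens: RegressorEnsemble, path) -> None:
    joblib.dump(
        {
            "members": ens.members,
            "algorithms": ens.algorithms,
            "params": ens.params,
            "scalers_json": ens.scalers.to_json(),
            "constants": ens.constants,
        },
        path,
    )


def load_ensemble(path) -> RegressorEnsemble:
    d = joblib.load(path)
    return RegressorEnsemble(
        members=d["members"],
        algorithms=d["algorithms"],
        params=d["params"],
        scalers=ScalerState.from_json(d["scalers_json"]),
        constants=np.asarray(d["constants"]),
    )
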