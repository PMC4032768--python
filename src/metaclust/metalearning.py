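"""Metaexample repository, regression metamodels and algorithm ranking.

A metaexample relates 24 meta-attributes (13 dataset descriptors, 5 algorithm
descriptors, 6 internal measures) to a measured AMI label.  Five regressor
families predict AMI from the meta-attributes: linear regression (LR), least
median squares regression (LMSR), an RBF network realized as RBF-kernel ridge
regression (RBFN), a single-hidden-layer neural network (NN) and an
epsilon-SVR with RBF kernel (SVM).  Models are compared on a seeded 70/30
holdout (hyperparameters chosen by 10-fold CV on the training side) by RMSE,
with MAE breaking ties; the winner ranks candidate algorithms for new
datasets by predicted AMI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .components import DISTANCE_TOKENS, EVALUATE_TOKENS, INIT_TOKENS, UPDATE_TOKENS
from .dataset import NORMALIZATION_METHODS, ExpressionDataset, impute_missing
from .engine import AlgorithmSpec, run_algorithm
from .metafeatures import (
    ALGORITHM_DESCRIPTOR_NAMES,
    INTERNAL_MEASURE_COLUMNS,
    INTERNAL_MEASURE_TOKENS,
    META_ATTRIBUTE_COLUMNS,
    NOMINAL_META_ATTRIBUTES,
    describe_algorithm,
    extract_metafeatures,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetaTable",
    "Recipe",
    "MetaModel",
    "REGRESSOR_KINDS",
    "preprocess_meta_table",
    "train_and_select",
    "evaluate_metamodel",
    "save_model",
    "load_model",
    "rank_algorithms",
    "SchemaMismatchError",
    "ModelFormatError",
]

MODEL_FORMAT_VERSION = 1

LABEL_COLUMN = "AMI"
KEY_COLUMNS = ("dataset_id", "algorithm_name")

#: Full vocabularies for the nominal algorithm descriptors, so dummy coding
#: always yields one indicator per RC level regardless of which levels the
#: training table happens to contain.
_FIXED_LEVELS = {
    "init": INIT_TOKENS,
    "distance": DISTANCE_TOKENS,
    "update": UPDATE_TOKENS,
    "evaluate": EVALUATE_TOKENS,
    "normalization": tuple(sorted(NORMALIZATION_METHODS)),
}


class SchemaMismatchError(ValueError):
    """A model was applied to rows with a different meta-attribute schema."""


class ModelFormatError(ValueError):
    """A model file is unreadable or has an incompatible format version."""


@dataclass
class MetaTable:
    """A metaexample repository: one row per (dataset, algorithm) run."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in META_ATTRIBUTE_COLUMNS + (LABEL_COLUMN,) + KEY_COLUMNS
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"meta table is missing columns: {missing}")
        keys = self.frame[list(KEY_COLUMNS) + (["seed"] if "seed" in self.frame else [])]
        if keys.duplicated().any():
            raise ValueError("duplicate (dataset_id, algorithm_name, seed) keys")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_rows(cls, rows, provenance=None) -> "MetaTable":
        return cls(pd.DataFrame(list(rows)), provenance=provenance or {})

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MetaTable":
        return cls(pd.read_csv(path))


def schema_fingerprint(columns=META_ATTRIBUTE_COLUMNS) -> str:
    return "|".join(columns)


@dataclass
class Recipe:
    """Preprocessing learned at training time and replayed at predict time.

    Nominal meta-attributes are expanded to full one-hot indicator columns;
    missing numeric values are imputed with the training column mean.  Unseen
    nominal levels map to an all-zero indicator block (and are logged).
    """

    categories: dict[str, tuple]
    means: dict[str, float]
    feature_names: tuple
    fingerprint: str = field(default_factory=schema_fingerprint)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in META_ATTRIBUTE_COLUMNS:
            if name in self.categories:
                levels = self.categories[name]
                values = frame[name].astype(str)
                unseen = ~values.isin(levels)
                if unseen.any():
                    logger.warning(
                        "column %r: %d unseen nominal value(s) mapped to zeros",
                        name, int(unseen.sum()),
                    )
                for level in levels:
                    cols.append((values == level).to_numpy(dtype=float))
            else:
                v = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
                v = np.where(np.isfinite(v), v, self.means[name])
                cols.append(v)
        return np.column_stack(cols)


def preprocess_meta_table(table: MetaTable):
    """Dummy-code nominals, mean-impute numerics; returns (X, y, recipe)."""
    frame = table.frame
    if len(frame) == 0:
        raise ValueError("empty meta table")
    categories: dict[str, tuple] = {}
    means: dict[str, float] = {}
    names: list[str] = []
    for name in META_ATTRIBUTE_COLUMNS:
        if name in NOMINAL_META_ATTRIBUTES:
            if name in _FIXED_LEVELS:
                levels = _FIXED_LEVELS[name]
            else:
                levels = tuple(sorted(frame[name].astype(str).unique()))
            categories[name] = levels
            names.extend(f"{name}={level}" for level in levels)
        else:
            v = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
            finite = v[np.isfinite(v)]
            means[name] = float(finite.mean()) if finite.size else 0.0
            names.append(name)
    recipe = Recipe(categories=categories, means=means, feature_names=tuple(names))
    x = recipe.transform(frame)
    y = frame[LABEL_COLUMN].to_numpy(dtype=float)
    return x, y, recipe


class LeastMedianSquaresRegressor(BaseEstimator, RegressorMixin):
    """Least median of squares linear regression by random p-subset search.

    Classic PROGRESS-style estimator: fit exact planes through random
    elemental subsets and keep the coefficients minimizing the median squared
    residual.  Robust to up to ~50% label contamination; no closed form
    exists, so the optimum is approximated by seeded subsampling.
    """

    def __init__(self, n_subsets: int = 200, random_state: int = 0):
        self.n_subsets = n_subsets
        self.random_state = random_state

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = x.shape
        design = np.column_stack([np.ones(n), x])
        rng = np.random.default_rng(self.random_state)
        m = min(p + 2, n)  # elemental subsets, slightly over-determined
        best_med, best_coef = np.inf, None
        # the all-data LS fit is always a candidate (helps tiny/noiseless data)
        candidates = [np.linalg.lstsq(design, y, rcond=None)[0]]
        for _ in range(self.n_subsets):
            idx = rng.choice(n, size=m, replace=False)
            coef, *_ = np.linalg.lstsq(design[idx], y[idx], rcond=None)
            candidates.append(coef)
        for coef in candidates:
            med = np.median((y - design @ coef) ** 2)
            if med < best_med:
                best_med, best_coef = med, coef
        self.intercept_ = float(best_coef[0])
        self.coef_ = best_coef[1:]
        return self

    def predict(self, x):
        return np.asarray(x, dtype=float) @ self.coef_ + self.intercept_


def _regressor_factories(seed: int):
    """The five meta-algorithm families with their (small) CV grids."""
    return {
        "LR": (Pipeline([("scale", StandardScaler()), ("model", LinearRegression())]), {}),
        "LMSR": (
            Pipeline([
                ("scale", StandardScaler()),
                ("model", LeastMedianSquaresRegressor(random_state=seed)),
            ]),
            {},
        ),
        "RBFN": (
            Pipeline([("scale", StandardScaler()), ("model", KernelRidge(kernel="rbf"))]),
            {"model__alpha": [0.01, 0.1, 1.0]},
        ),
        "NN": (
            Pipeline([
                ("scale", StandardScaler()),
                ("model", MLPRegressor(hidden_layer_sizes=(32,), max_iter=4000,
                                       random_state=seed)),
            ]),
            {"model__alpha": [1e-4, 1e-2]},
        ),
        "SVM": (
            Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf"))]),
            {"model__C": [1.0, 10.0], "model__epsilon": [0.01, 0.1]},
        ),
    }


REGRESSOR_KINDS = ("RBFN", "LR", "LMSR", "NN", "SVM")

#: Deterministic preference order when holdout RMSE and MAE tie exactly.
TIE_ORDER = ("LR", "RBFN", "LMSR", "NN", "SVM")


@dataclass
class MetaModel:
    """A fitted AMI regressor with its preprocessing recipe and report."""

    regressor_kind: str
    estimator: object
    recipe: Recipe
    report: dict
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        if self.recipe.fingerprint != schema_fingerprint():
            raise SchemaMismatchError(
                "model was trained under a different meta-attribute schema"
            )
        missing = [c for c in META_ATTRIBUTE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaMismatchError(f"prediction rows lack columns: {missing}")
        return np.asarray(self.estimator.predict(self.recipe.transform(frame)), dtype=float)


def _error_report(y_true, y_pred) -> dict:
    err = np.abs(np.asarray(y_pred) - np.asarray(y_true))
    return {
        "MAE": float(err.mean()),
        "RMSE": float(np.sqrt((err**2).mean())),
        "sd_abs_err": float(err.std(ddof=1)) if err.size > 1 else 0.0,
    }


def _split_keys(frame: pd.DataFrame, holdout_fraction: float, seed: int, group_by_dataset: bool):
    """70/30 split by seeded shuffle of sorted row keys (not positions)."""
    rng = np.random.default_rng(seed)
    if group_by_dataset:
        groups = sorted(frame["dataset_id"].astype(str).unique())
        rng.shuffle(groups)
        n_test = max(1, int(round(holdout_fraction * len(groups))))
        test_groups = set(groups[:n_test])
        test_mask = frame["dataset_id"].astype(str).isin(test_groups).to_numpy()
        return ~test_mask, test_mask
    key_cols = [c for c in ("dataset_id", "algorithm_name", "seed") if c in frame.columns]
    keys = frame[key_cols].astype(str).agg("||".join, axis=1).to_numpy()
    order = np.argsort(keys, kind="stable")
    shuffled = order.copy()
    rng.shuffle(shuffled)
    n_test = max(1, int(round(holdout_fraction * len(frame))))
    test_idx = shuffled[:n_test]
    test_mask = np.zeros(len(frame), dtype=bool)
    test_mask[test_idx] = True
    return ~test_mask, test_mask


def train_and_select(
    table: MetaTable,
    regressors=REGRESSOR_KINDS,
    holdout_fraction: float = 0.30,
    cv_folds: int = 10,
    seed: int = 0,
    group_by_dataset: bool = False,
    save_dir=None,
):
    """Train the requested regressors and select the best on a 70/30 holdout.

    Hyperparameters are chosen by ``cv_folds``-fold cross validation on the
    training side; the holdout report carries MAE, RMSE and the sd of
    absolute errors.  Selection minimizes RMSE, breaking ties by MAE and then
    by the documented kind order.  Returns ``(best_model, reports)``.
    """
    if len(table) < 50:
        raise ValueError("need at least 50 metaexamples to train")
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    frame = table.frame.reset_index(drop=True)
    train_mask, test_mask = _split_keys(frame, holdout_fraction, seed, group_by_dataset)
    train_table = MetaTable(frame[train_mask].reset_index(drop=True))
    x_train, y_train, recipe = preprocess_meta_table(train_table)
    x_test = recipe.transform(frame[test_mask])
    y_test = frame.loc[test_mask, LABEL_COLUMN].to_numpy(dtype=float)

    factories = _regressor_factories(seed)
    models: dict[str, MetaModel] = {}
    reports: dict[str, dict] = {}
    for kind in regressors:
        if kind not in factories:
            raise ValueError(f"unknown regressor kind: {kind!r}")
        estimator, grid = factories[kind]
        try:
            if grid:
                search = GridSearchCV(
                    estimator, grid, cv=cv_folds,
                    scoring="neg_root_mean_squared_error", n_jobs=1,
                )
                search.fit(x_train, y_train)
                fitted = search.best_estimator_
            else:
                fitted = estimator.fit(x_train, y_train)
        except Exception as exc:  # a diverging fit must not sink the selection
            logger.warning("regressor %s failed and is excluded: %s", kind, exc)
            continue
        report = _error_report(y_test, fitted.predict(x_test))
        model = MetaModel(regressor_kind=kind, estimator=fitted, recipe=recipe, report=report)
        models[kind] = model
        reports[kind] = report
        if save_dir is not None:
            from pathlib import Path

            save_model(model, Path(save_dir) / f"metamodel_{kind}.joblib")
    if not models:
        raise RuntimeError("every regressor failed to train")
    best_kind = min(
        models,
        key=lambda kd: (reports[kd]["RMSE"], reports[kd]["MAE"], TIE_ORDER.index(kd)),
    )
    return models[best_kind], reports


def evaluate_metamodel(model: MetaModel, table: MetaTable):
    """Holdout-style evaluation of a fitted model on labelled rows."""
    pred = model.predict(table.frame)
    rep = _error_report(table.frame[LABEL_COLUMN].to_numpy(dtype=float), pred)
    return rep["MAE"], rep["RMSE"], rep["sd_abs_err"]


def save_model(model: MetaModel, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> MetaModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a metaclust model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {payload['format_version']} != "
            f"supported {MODEL_FORMAT_VERSION}"
        )
    return payload["model"]


def rank_algorithms(
    model: MetaModel,
    ds: ExpressionDataset,
    candidates: list[AlgorithmSpec],
    mode: str = "a_priori",
    k: int | None = None,
    seed: int = 0,
    n_restarts: int = 1,
) -> pd.DataFrame:
    """Rank candidate algorithms for a new dataset by predicted AMI.

    ``a_priori`` predicts before any clustering: the six internal measures
    are left missing and imputed with their training means.  ``post_hoc``
    actually runs every candidate on the dataset and fills in the observed
    internal measures, reproducing the full 24-attribute schema.  The result
    is sorted non-increasing by predicted AMI (ties broken by name).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if mode not in ("a_priori", "post_hoc"):
        raise ValueError(f"unknown ranking mode: {mode!r}")
    mf = extract_metafeatures(ds)
    imputed = impute_missing(ds) if mode == "post_hoc" else None
    rows = []
    for spec in candidates:
        row = dict(mf)
        row.update(describe_algorithm(spec))
        if mode == "post_hoc":
            k_run = k if k is not None else max(ds.n_classes or 2, 2)
            result = run_algorithm(imputed, spec, k_run, seed=seed, n_restarts=n_restarts)
            row.update({
                col: result.internal_scores[tok]
                for col, tok in zip(INTERNAL_MEASURE_COLUMNS, INTERNAL_MEASURE_TOKENS)
            })
        else:
            row.update({col: np.nan for col in INTERNAL_MEASURE_COLUMNS})
        row["algorithm_name"] = spec.full_name
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["predicted_ami"] = model.predict(frame)
    ranking = frame[["algorithm_name", "predicted_ami"]].copy()
    ranking = ranking.sort_values(
        ["predicted_ami", "algorithm_name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    ranking.attrs["dataset_id"] = ds.name
    ranking.attrs["mode"] = mode
    return ranking
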