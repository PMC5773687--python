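"""Native learners and the learner contract.

Two learners are built in: the surface range envelope (SRE, the
BIOCLIM-style quantile box model used both as a habitat-suitability model
and to delimit the pseudo-absence background) and a logistic GLM.  Any
further algorithm joins the ensemble through :func:`register_adapter`,
which enforces a uniform contract — scores in [0, 1], determinism under a
fixed seed, and feature-schema tolerance — before the adapter becomes
available to the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, ContractViolation

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

Schema = list[tuple[str, str]]


# ---------------------------------------------------------------------------
# Surface range envelope


@dataclass
class SREEnvelope:
    """Per-variable quantile bounds; a row scores 1 iff every continuous
    variable lies inside its [low, high] interval (inclusive)."""

    bounds: dict[str, tuple[float, float]]
    q: float


def sre_fit(presence_features: pd.DataFrame, q: float = 0.025) -> SREEnvelope:
    """Empirical q / 1-q quantile bounds (linear-interpolation definition)
    of the presence values, per continuous variable."""
    if not 0 <= q < 0.5:
        raise ConfigError("q must lie in [0, 0.5)")
    if len(presence_features) < 2:
        raise ConfigError("need at least 2 presence rows to fit an envelope")
    bounds: dict[str, tuple[float, float]] = {}
    for var in presence_features.columns:
        x = presence_features[var].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        lo, hi = np.quantile(x, [q, 1.0 - q], method="linear")
        if lo == hi and q > 0:
            warnings.warn(
                f"variable {var!r} is constant across presences; "
                "envelope collapses to a point",
                stacklevel=2,
            )
        bounds[var] = (float(lo), float(hi))
    return SREEnvelope(bounds=bounds, q=q)


def sre_predict(env: SREEnvelope, features: pd.DataFrame) -> np.ndarray:
    """0/1 envelope membership; rows with a missing feature score NaN."""
    missing_cols = set(env.bounds) - set(features.columns)
    if missing_cols:
        raise ConfigError(f"features lack envelope variable(s) {sorted(missing_cols)}")
    inside = np.ones(len(features), dtype=float)
    flagged = np.zeros(len(features), dtype=bool)
    for var, (lo, hi) in env.bounds.items():
        x = features[var].to_numpy(dtype=float)
        bad = ~np.isfinite(x)
        flagged |= bad
        with np.errstate(invalid="ignore"):
            inside *= ((x >= lo) & (x <= hi)).astype(float)
    inside[flagged] = np.nan
    return inside


# ---------------------------------------------------------------------------
# Learner contract and registry


@dataclass
class FittedLearner:
    algorithm_id: str
    state: object
    schema: Schema

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict(self, features)


FitFn = Callable[[pd.DataFrame, np.ndarray, Schema, int], object]
PredictFn = Callable[[object, pd.DataFrame], np.ndarray]

_REGISTRY: dict[str, tuple[FitFn, PredictFn]] = {}


def available_algorithms() -> list[str]:
    return sorted(_REGISTRY)


def fit(
    algorithm_id: str,
    features: pd.DataFrame,
    labels: np.ndarray,
    schema: Schema,
    seed: int = 0,
) -> FittedLearner:
    if algorithm_id not in _REGISTRY:
        raise ConfigError(
            f"unknown algorithm {algorithm_id!r}; registered: {available_algorithms()}"
        )
    fit_fn, _ = _REGISTRY[algorithm_id]
    state = fit_fn(features, np.asarray(labels), schema, seed)
    return FittedLearner(algorithm_id=algorithm_id, state=state, schema=schema)


def predict(model: FittedLearner, features: pd.DataFrame) -> np.ndarray:
    _, predict_fn = _REGISTRY[model.algorithm_id]
    cols = [name for name, _ in model.schema]
    missing = set(cols) - set(features.columns)
    if missing:
        raise ConfigError(f"features lack schema variable(s) {sorted(missing)}")
    return np.asarray(predict_fn(model.state, features[cols]), dtype=float)


def _contract_dataset() -> tuple[pd.DataFrame, np.ndarray, Schema]:
    rng = np.random.default_rng(1234)
    n = 80
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    # enough label noise that even quadratic logistic fits stay away from
    # separation, so well-behaved adapters never hit their fallbacks here
    y = (x1 + 1.5 * rng.normal(size=n) > 0).astype(int)
    X = pd.DataFrame({"cv_a": x1, "cv_b": x2})
    return X, y, [("cv_a", CONTINUOUS), ("cv_b", CONTINUOUS)]


def check_contract(algorithm_id: str, fit_fn: FitFn, predict_fn: PredictFn) -> None:
    """Run the learner contract suite; raise ContractViolation on failure.

    Checks: scores within [0, 1] (NaN allowed only for rows with missing
    features), bit-identical predictions across two fits with the same
    seed, and invariance to feature column order.
    """
    X, y, schema = _contract_dataset()
    try:
        s1 = predict_fn(fit_fn(X, y, schema, 7), X)
        s2 = predict_fn(fit_fn(X, y, schema, 7), X)
    except Exception as exc:  # noqa: BLE001 - report as contract failure
        raise ContractViolation(f"{algorithm_id}: fit/predict raised {exc!r}") from exc
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != (len(X),):
        raise ContractViolation(
            f"{algorithm_id}: prediction shape {s1.shape} != ({len(X)},)"
        )
    finite = s1[np.isfinite(s1)]
    if finite.size == 0:
        raise ContractViolation(f"{algorithm_id}: no finite scores on clean input")
    if finite.min() < 0.0 or finite.max() > 1.0:
        raise ContractViolation(
            f"{algorithm_id}: scores outside [0, 1] "
            f"(min {finite.min():.4g}, max {finite.max():.4g})"
        )
    if not np.array_equal(s1, s2, equal_nan=True):
        raise ContractViolation(
            f"{algorithm_id}: predictions differ across fits with the same seed"
        )


def register_adapter(
    algorithm_id: str, fit_fn: FitFn, predict_fn: PredictFn, overwrite: bool = False
) -> None:
    """Register an algorithm for pipeline use; the contract suite runs at
    registration time and a violation refuses the registration."""
    if algorithm_id in _REGISTRY and not overwrite:
        raise ConfigError(f"algorithm {algorithm_id!r} already registered")
    check_contract(algorithm_id, fit_fn, predict_fn)
    _REGISTRY[algorithm_id] = (fit_fn, predict_fn)


def unregister(algorithm_id: str) -> None:
    _REGISTRY.pop(algorithm_id, None)


# ---------------------------------------------------------------------------
# Native learner: logistic GLM (IRLS via statsmodels)


@dataclass
class _GLMState:
    params: np.ndarray
    design_info: dict
    used_ridge: bool


def _glm_design(
    features: pd.DataFrame, schema: Schema, degree: int, levels: dict | None = None
) -> tuple[np.ndarray, dict]:
    """Intercept + linear (and optionally squared) continuous terms +
    one-hot categorical terms with the first observed level as reference."""
    cols = [np.ones(len(features))]
    if levels is None:
        levels = {}
        learning = True
    else:
        learning = False
    for name, kind in schema:
        x = features[name].to_numpy(dtype=float)
        if kind == CONTINUOUS:
            cols.append(x)
            if degree == 2:
                cols.append(x**2)
        else:
            if learning:
                levels[name] = sorted(np.unique(x[np.isfinite(x)]).tolist())
            for lev in levels[name][1:]:  # first level is the reference
                cols.append((x == lev).astype(float))
    X = np.column_stack(cols)
    return X, {"schema": schema, "degree": degree, "levels": levels}


def glm_fit_fn(degree: int = 2) -> FitFn:
    """Build a GLM fit function with the given polynomial degree (1 or 2)."""
    if degree not in (1, 2):
        raise ConfigError("degree must be 1 or 2")

    def _fit(features: pd.DataFrame, labels: np.ndarray, schema: Schema, seed: int):
        if len(np.unique(labels)) < 2:
            raise ConfigError("GLM needs both labels present")
        X, info = _glm_design(features, schema, degree)
        model = sm.GLM(labels, X, family=sm.families.Binomial())
        used_ridge = False
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = model.fit(maxiter=100, tol=1e-8)
                params = np.asarray(res.params)
                if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e8:
                    raise ValueError("non-finite or diverging coefficients")
            except Exception:
                # perfect separation or failed IRLS: small ridge penalty
                res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, maxiter=200)
                params = np.asarray(res.params)
                used_ridge = True
        if used_ridge:
            warnings.warn(
                "GLM: IRLS failed (likely perfect separation); "
                "fell back to ridge penalty 1e-6",
                stacklevel=2,
            )
        return _GLMState(params=params, design_info=info, used_ridge=used_ridge)

    return _fit


def glm_predict_fn(state: _GLMState, features: pd.DataFrame) -> np.ndarray:
    info = state.design_info
    X, _ = _glm_design(features, info["schema"], info["degree"], levels=info["levels"])
    bad = ~np.isfinite(X).all(axis=1)
    X = np.where(np.isfinite(X), X, 0.0)
    eta = X @ state.params
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    p[bad] = np.nan
    return p


def _sre_fit_learner(q: float = 0.025) -> FitFn:
    def _fit(features: pd.DataFrame, labels: np.ndarray, schema: Schema, seed: int):
        cont = [name for name, kind in schema if kind == CONTINUOUS]
        pres = features.loc[np.asarray(labels) == 1, cont]
        return sre_fit(pres, q=q)

    return _fit


def _sre_predict_learner(state: SREEnvelope, features: pd.DataFrame) -> np.ndarray:
    return sre_predict(state, features)


def register_native_learners(glm_degree: int = 2, sre_q: float = 0.025) -> None:
    """(Re-)register the two built-in algorithms under ids 'GLM' and 'SRE'."""
    register_adapter("GLM", glm_fit_fn(degree=glm_degree), glm_predict_fn,
                     overwrite=True)
    register_adapter("SRE", _sre_fit_learner(q=sre_q), _sre_predict_learner,
                     overwrite=True)


def make_constant_learner(value: float = 0.5) -> tuple[FitFn, PredictFn]:
    """A degenerate learner predicting a constant score; useful as a dummy
    adapter when exercising the full run-design bookkeeping."""

    def _fit(features, labels, schema, seed):
        return float(value)

    def _predict(state, features):
        return np.full(len(features), float(state))

    return _fit, _predict


register_native_learners()
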