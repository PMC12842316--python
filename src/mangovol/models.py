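"""The volume-regression model suite, scikit-learn estimator style.

Each model maps a subset of the nine geometric features to volume (cm^3):

====  ============== =====================================  ==================
id    category       formulation                            features
====  ============== =====================================  ==================
B     Single-View    V ~ k * A_s^1.5                        A_s15
G     Single-View    V ~ k * A_b^1.5                        A_b15
I     Multi-View     V ~ k1*A_s^1.5 + k2*A_b^1.5            A_s15, A_b15
L     Multi-View     degree-2 polynomial + intercept        A_s15, A_b15
M     Ellipsoid      V ~ k * V_e                            V_e
N     Hybrid         V ~ k1*A_s^1.5 + k2*A_b^1.5 + k3*V_e   A_s15, A_b15, V_e
O     Advanced ML    gradient boosting (300 trees, d=3)     A_s15, A_b15, V_e
P     Advanced ML    SVR, RBF kernel (C=10, eps=0.1)        A_s15, A_b15, V_e
====  ============== =====================================  ==================

The pure ``k . x`` formulations (B, G, I, M, N) are fitted by ordinary
least squares WITHOUT an intercept, matching their written form; an
explicit ``fit_intercept`` switch exists because the choice is a
convention.  Model L uses the standard degree-2 expansion
{x1, x2, x1^2, x1*x2, x2^2} plus an intercept.  O and P ship with fixed,
documented hyperparameters and are reported for completeness only — they
over-fit small geometric tables and are excluded from headline analysis.

Negative predictions are returned as-is (never clipped silently); the
count of negative training predictions is kept in ``fit_diagnostics_``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR

from .data import Dataset
from .evaluation import EvalConfig, evaluate
from .exceptions import ParameterError
from .geometry import FeatureVector

MODEL_FEATURES: dict[str, tuple[str, ...]] = {
    "B": ("A_s15",),
    "G": ("A_b15",),
    "I": ("A_s15", "A_b15"),
    "L": ("A_s15", "A_b15"),
    "M": ("V_e",),
    "N": ("A_s15", "A_b15", "V_e"),
    "O": ("A_s15", "A_b15", "V_e"),
    "P": ("A_s15", "A_b15", "V_e"),
}

MODEL_CATEGORY = {
    "B": "Single-View",
    "G": "Single-View",
    "I": "Multi-View",
    "L": "Multi-View",
    "M": "Ellipsoid",
    "N": "Hybrid",
    "O": "Advanced ML",
    "P": "Advanced ML",
}

MODEL_LABEL = {
    "B": "B: Side-Only (A_s15)",
    "G": "G: Bottom-Only (A_b15)",
    "I": "I: Geo combined (A_s15+A_b15)",
    "L": "L: Poly-Geo (deg=2)",
    "M": "M: V_ellipsoid",
    "N": "N: Combined Linear (areas + V_ellipsoid)",
    "O": "O: Gradient Boosting",
    "P": "P: SVR (RBF)",
}

PARAMETRIC_IDS = ("B", "G", "I", "L", "M", "N")
DEFAULT_MODEL_IDS = PARAMETRIC_IDS

__all__ = [
    "GeometricVolumeRegressor",
    "MODEL_FEATURES",
    "MODEL_CATEGORY",
    "MODEL_LABEL",
    "PARAMETRIC_IDS",
    "DEFAULT_MODEL_IDS",
    "fit_model",
    "predict_volume",
    "fit_and_compare",
    "save_model",
    "load_model",
]


def _feature_matrix(X, feature_names) -> np.ndarray:
    """Pull the named feature columns out of whatever the caller handed us."""
    if isinstance(X, Dataset):
        X = X.records
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise ParameterError(f"missing feature columns: {missing}")
        arr = X[list(feature_names)].to_numpy(float)
    else:
        arr = np.asarray(X, float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1) if len(feature_names) > 1 else arr.reshape(-1, 1)
        if arr.shape[1] != len(feature_names):
            raise ParameterError(
                f"expected {len(feature_names)} feature columns, got {arr.shape[1]}"
            )
    if not np.all(np.isfinite(arr)):
        raise ParameterError("features must be finite")
    return arr


class GeometricVolumeRegressor(RegressorMixin, BaseEstimator):
    """One formulation of the suite, selected by ``model_id``.

    Parameters
    ----------
    model_id : str
        One of B, G, I, L, M, N, O, P (see module docstring).
    fit_intercept : bool or None
        None (default) resolves to the per-model convention: False for the
        pure-proportionality forms B/G/I/M/N, True for the polynomial L.
    random_state : int
        Seed for the stochastic O model (ignored elsewhere).

    Attributes (after ``fit``)
    --------------------------
    coef_ : dict mapping term name -> coefficient (parametric models)
    intercept_ : float
    features_ : tuple of input feature names
    training_n_ : number of training rows
    fit_diagnostics_ : dict with training R^2 and negative-prediction count
    """

    def __init__(self, model_id: str = "N", fit_intercept: bool | None = None,
                 random_state: int = 0):
        self.model_id = model_id
        self.fit_intercept = fit_intercept
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolved_intercept(self) -> bool:
        if self.fit_intercept is not None:
            return bool(self.fit_intercept)
        return self.model_id == "L"

    def _powers(self, n_features: int) -> np.ndarray:
        """Exponent matrix of the parametric design (rows = terms)."""
        if self.model_id == "L":
            poly = PolynomialFeatures(degree=2, include_bias=False)
            poly.fit(np.zeros((1, n_features)))
            return poly.powers_
        return np.eye(n_features, dtype=int)

    @staticmethod
    def _expand(Xf: np.ndarray, powers: np.ndarray) -> np.ndarray:
        return np.prod(Xf[:, None, :] ** powers[None, :, :], axis=2)

    @staticmethod
    def _term_names(feature_names, powers) -> list[str]:
        names = []
        for row in powers:
            parts = [
                f if p == 1 else f"{f}^{p}"
                for f, p in zip(feature_names, row)
                if p > 0
            ]
            names.append("*".join(parts) if parts else "1")
        return names

    # ------------------------------------------------------------------
    def fit(self, X, y):
        if self.model_id not in MODEL_FEATURES:
            raise ParameterError(f"unknown model_id {self.model_id!r}")
        self.features_ = MODEL_FEATURES[self.model_id]
        Xf = _feature_matrix(X, self.features_)
        yv = np.asarray(y, float).ravel()
        if len(yv) != len(Xf):
            raise ParameterError("X and y have different lengths")
        if len(yv) == 0:
            raise ParameterError("training set is empty")
        if not np.all(np.isfinite(yv)):
            raise ParameterError("target must be finite")

        if self.model_id in ("O", "P"):
            if self.model_id == "O":
                self.estimator_ = GradientBoostingRegressor(
                    n_estimators=300, max_depth=3, learning_rate=0.05,
                    random_state=self.random_state,
                )
            else:
                self.estimator_ = SVR(kernel="rbf", C=10.0, epsilon=0.1, gamma="scale")
            self.estimator_.fit(Xf, yv)
            self.powers_ = None
            self.coef_ = None
            self.intercept_ = 0.0
        else:
            self.powers_ = self._powers(Xf.shape[1])
            design = self._expand(Xf, self.powers_)
            intercept = self._resolved_intercept()
            n_params = design.shape[1] + int(intercept)
            if len(yv) < n_params:
                raise ParameterError(
                    f"{len(yv)} rows cannot identify {n_params} parameters"
                )
            full = np.column_stack([design, np.ones(len(yv))]) if intercept else design
            if np.linalg.matrix_rank(full) < full.shape[1]:
                warnings.warn(
                    f"model {self.model_id}: rank-deficient design; "
                    "least-norm solution", stacklevel=2,
                )
            lr = LinearRegression(fit_intercept=intercept).fit(design, yv)
            names = self._term_names(self.features_, self.powers_)
            self.coef_ = dict(zip(names, map(float, lr.coef_)))
            self.intercept_ = float(lr.intercept_)
            self.estimator_ = None

        self.training_n_ = len(yv)
        pred = self.predict(Xf)
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        self.fit_diagnostics_ = {
            "train_r2": (1.0 - float(np.sum((yv - pred) ** 2)) / ss_tot)
            if ss_tot > 0 else float("nan"),
            "n_negative_train_pred": int(np.sum(pred < 0)),
        }
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "features_"):
            raise ParameterError("model is not fitted")
        Xf = _feature_matrix(X, self.features_)
        if self.estimator_ is not None:
            return self.estimator_.predict(Xf)
        design = self._expand(Xf, self.powers_)
        coefs = np.array(list(self.coef_.values()))
        return design @ coefs + self.intercept_

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        if not hasattr(self, "features_"):
            raise ParameterError("model is not fitted")
        return {
            "model_id": self.model_id,
            "feature_names": list(self.features_),
            "coefficients": self.coef_,
            "intercept": self.intercept_,
            "powers": None if self.powers_ is None else self.powers_.tolist(),
            "training_n": self.training_n_,
            "fit_diagnostics": self.fit_diagnostics_,
            "note": None if self.coef_ is not None
            else "non-parametric model; coefficients not serializable",
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GeometricVolumeRegressor":
        if payload.get("coefficients") is None:
            raise ParameterError("cannot restore a non-parametric model from JSON")
        model = cls(model_id=payload["model_id"])
        model.features_ = tuple(payload["feature_names"])
        model.coef_ = dict(payload["coefficients"])
        model.intercept_ = float(payload["intercept"])
        model.powers_ = np.asarray(payload["powers"], int)
        model.estimator_ = None
        model.training_n_ = int(payload["training_n"])
        model.fit_diagnostics_ = dict(payload.get("fit_diagnostics", {}))
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_model(model_id: str, train: Dataset, fit_intercept: bool | None = None,
              random_state: int = 0) -> GeometricVolumeRegressor:
    model = GeometricVolumeRegressor(model_id, fit_intercept, random_state)
    return model.fit(train.records, train.records["v_true"].to_numpy(float))


def predict_volume(model: GeometricVolumeRegressor, features) -> float | np.ndarray:
    """Predict volume for a FeatureVector, dict, DataFrame or Dataset."""
    if isinstance(features, FeatureVector):
        features = pd.DataFrame([features.as_row()])
        return float(model.predict(features)[0])
    if isinstance(features, dict):
        return float(model.predict(pd.DataFrame([features]))[0])
    return model.predict(features)


def fit_and_compare(
    model_ids,
    train: Dataset,
    test: Dataset,
    config: EvalConfig | None = None,
    fit_intercept: bool | None = None,
) -> pd.DataFrame:
    """Comparison table: one row per model with test-set R^2/MAPE/RMSE/Bias.

    A model that fails to fit gets a row with status='failed' and NaN
    metrics; the other rows are unaffected.
    """
    config = config or EvalConfig()
    y_test = test.records["v_true"].to_numpy(float)
    rows = []
    for mid in model_ids:
        row = {
            "Category": MODEL_CATEGORY.get(mid, "?"),
            "Model": MODEL_LABEL.get(mid, mid),
            "R2": np.nan, "MAPE": np.nan, "RMSE": np.nan, "Bias": np.nan,
            "status": "ok",
        }
        try:
            model = fit_model(mid, train, fit_intercept=fit_intercept)
            report = evaluate(y_test, model.predict(test.records), config)
            row.update(
                R2=report.r2, MAPE=report.mape, RMSE=report.rmse, Bias=report.bias
            )
        except Exception as exc:  # one model's failure must not abort the table
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def save_model(model: GeometricVolumeRegressor, path) -> None:
    # coefficient order must stay aligned with the powers matrix: no key sorting
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path) -> GeometricVolumeRegressor:
    return GeometricVolumeRegressor.from_dict(json.loads(Path(path).read_text()))
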