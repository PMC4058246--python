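"""Activity-prediction models for pEC50 (log10(1/EC50)) regression.

Three fitted model families — ordinary multiple linear regression (MLR),
ε-insensitive support-vector regression (SVR, via libsvm through
scikit-learn) and Bayesian linear regression — plus the frozen published
linear equation relating the six topological descriptors to PPAR-γ agonist
potency:

    pEC50 = −5.987 + 1.987·ES_Sum_sssCH − 0.812·ES_Count_aaN + 8.608·BIC
            − 2.047·IAC_Mean + 0.812·CHI_3_P + 2.159·JY

The Bayesian model is a Gaussian-prior linear regression (flat prior on the
intercept); it stands in for the original study's unspecified "Bayes network
toolbox" regression and reduces to MLR in the flat-prior limit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainingTable",
    "QsarModel",
    "EQ1_INTERCEPT",
    "EQ1_COEFFICIENTS",
    "eq1_model",
    "eq1_predict",
    "fit_mlr",
    "fit_svr",
    "fit_bayes",
    "save_model",
    "load_model",
]

#: Frozen published-model coefficients, in descriptor order.
EQ1_INTERCEPT = -5.987
EQ1_COEFFICIENTS = {
    "ES_Sum_sssCH": 1.987,
    "ES_Count_aaN": -0.812,
    "BIC": 8.608,
    "IAC_Mean": -2.047,
    "CHI_3_P": 0.812,
    "JY": 2.159,
}


@dataclass
class TrainingTable:
    """Compound ids, an n×k descriptor matrix X and a pEC50 vector y."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, k = self.X.shape
        if len(self.y) != n or len(self.ids) != n:
            raise ValueError("ids, X rows and y must agree in length")
        if len(self.names) != k:
            raise ValueError("one name per descriptor column required")
        if len(set(self.names)) != k:
            raise ValueError("descriptor names must be unique")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("training table contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def subset(self, columns) -> "TrainingTable":
        cols = list(columns)
        return TrainingTable(
            ids=self.ids,
            X=self.X[:, cols],
            y=self.y,
            names=[self.names[c] for c in cols],
        )

    @classmethod
    def from_dataframe(cls, df, id_column="name", target_column="pEC50"):
        names = [c for c in df.columns if c not in (id_column, target_column)]
        return cls(
            ids=[str(v) for v in df[id_column]],
            X=df[names].to_numpy(dtype=float),
            y=df[target_column].to_numpy(dtype=float),
            names=names,
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "name", self.ids)
        df["pEC50"] = self.y
        return df


@dataclass
class QsarModel:
    """A fitted or frozen activity predictor.

    ``kind`` is one of ``mlr``, ``svr``, ``bayes``, ``frozen-eq1``,
    ``frozen-table``. ``payload`` carries the kind-specific parameters and
    ``diagnostics`` the training-set R² / LOO-q² figures where applicable.
    """

    kind: str
    names: list[str]
    payload: dict
    diagnostics: dict = field(default_factory=dict)

    def _matrix(self, v) -> np.ndarray:
        if isinstance(v, dict):
            missing = [n for n in self.names if n not in v]
            if missing:
                raise KeyError(f"missing descriptor(s) {missing} for {self.kind} model")
            return np.array([[float(v[n]) for n in self.names]])
        x = np.asarray(v, dtype=float)
        return x[None, :] if x.ndim == 1 else x

    def predict(self, v):
        """Predict pEC50 for a descriptor mapping, vector, or n×k matrix."""
        if self.kind == "frozen-table":
            raise TypeError(
                "frozen-table models predict by compound id; use predict_by_id"
            )
        x = self._matrix(v)
        if self.kind in ("mlr", "bayes", "frozen-eq1"):
            beta0 = self.payload["intercept"]
            beta = np.array([self.payload["coefficients"][n] for n in self.names])
            out = beta0 + x @ beta
        elif self.kind == "svr":
            out = _svr_decision(self.payload, x)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        scalar_in = isinstance(v, dict) or np.asarray(v).ndim == 1
        return float(out[0]) if scalar_in else out

    def predict_by_id(self, compound_id: str) -> float:
        if self.kind != "frozen-table":
            raise TypeError("predict_by_id only applies to frozen-table models")
        table = self.payload["values"]
        if compound_id not in table:
            raise KeyError(f"no frozen prediction for compound {compound_id!r}")
        return float(table[compound_id])


def eq1_model() -> QsarModel:
    """The frozen published six-descriptor linear model."""
    return QsarModel(
        kind="frozen-eq1",
        names=list(EQ1_COEFFICIENTS),
        payload={"intercept": EQ1_INTERCEPT, "coefficients": dict(EQ1_COEFFICIENTS)},
    )


def eq1_predict(v) -> float:
    """Evaluate the frozen published equation on one descriptor mapping/vector."""
    return eq1_model().predict(v)


def frozen_table_model(values: dict[str, float], source: str = "") -> QsarModel:
    """A predictor that looks predictions up by compound id.

    Used to inject externally published predicted activities (e.g. vendor
    SVM/BNT columns of a results table) into the screening funnel.
    """
    return QsarModel(
        kind="frozen-table",
        names=[],
        payload={"values": dict(values), "source": source},
    )


def _ss_tot(y) -> float:
    ss = float(((y - y.mean()) ** 2).sum())
    # constant response up to rounding counts as zero variance
    return 0.0 if ss <= 1e-12 * max(1.0, float((y**2).sum())) else ss


def _r2_scores(y, yhat) -> dict:
    ss_tot = _ss_tot(y)
    ss_res = float(((y - yhat) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant response: R² defined as 0")
        r2 = 0.0
        pearson = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        sd = np.std(yhat)
        pearson = float(np.corrcoef(y, yhat)[0, 1] ** 2) if sd > 0 else 0.0
    return {"r2": r2, "pearson_r2": pearson}


def _design(X) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(t: TrainingTable) -> QsarModel:
    """Ordinary least squares with intercept.

    Diagnostics: coefficient-of-determination R², squared Pearson correlation
    of observed vs predicted, and leave-one-out q² computed from the hat
    matrix (PRESS), so no refits are needed.
    """
    A = _design(t.X)
    n, p = A.shape
    if n < p:
        raise ValueError(f"need n ≥ k+1 rows to fit MLR (n={n}, k={p - 1})")
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        # identify collinear columns via the QR diagonal
        _, r = np.linalg.qr(A)
        bad = [t.names[i - 1] for i in range(1, p)
               if abs(r[i, i]) < 1e-10 * max(abs(r[0, 0]), 1.0)]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    if np.allclose(t.y, t.y[0]):
        warnings.warn("constant response: all slopes 0, R² defined as 0")
        beta = np.zeros(p)
        beta[0] = t.y[0]
    else:
        beta, *_ = np.linalg.lstsq(A, t.y, rcond=None)
    yhat = A @ beta
    diag = _r2_scores(t.y, yhat)
    # LOO residual e_i/(1 − h_ii)
    h = np.einsum("ij,jk,ik->i", A, np.linalg.inv(A.T @ A), A)
    denom = np.clip(1.0 - h, 1e-12, None)
    press = float((((t.y - yhat) / denom) ** 2).sum())
    ss_tot = _ss_tot(t.y)
    diag["loo_q2"] = 1.0 - press / ss_tot if ss_tot > 0 else 0.0
    return QsarModel(
        kind="mlr",
        names=list(t.names),
        payload={
            "intercept": float(beta[0]),
            "coefficients": {n_: float(b) for n_, b in zip(t.names, beta[1:])},
        },
        diagnostics=diag,
    )


def _svr_decision(payload: dict, x: np.ndarray) -> np.ndarray:
    sv = np.asarray(payload["support_vectors"])
    dual = np.asarray(payload["dual_coef"])
    b = payload["intercept"]
    mean = np.asarray(payload["x_mean"])
    scale = np.asarray(payload["x_scale"])
    xs = (x - mean) / scale
    if sv.size == 0:  # all residuals inside the ε-tube: bias-only solution
        return np.full(len(xs), float(b))
    if payload["kernel"] == "linear":
        k = xs @ sv.T
    else:  # rbf
        gamma = payload["gamma"]
        d2 = ((xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        k = np.exp(-gamma * d2)
    return k @ dual + b


def fit_svr(
    t: TrainingTable,
    C: float = 10.0,
    epsilon: float = 0.1,
    kernel: str = "linear",
    gamma: float | str = "scale",
    tol: float = 1e-3,
    max_iter: int = 200_000,
) -> QsarModel:
    """ε-insensitive support-vector regression (libsvm solver).

    Descriptors are standardized internally (the kernel is scale-sensitive);
    the stored model carries the support vectors and dual weights so that
    prediction is self-contained and JSON-serializable.
    """
    from sklearn.svm import SVR

    if C <= 0 or epsilon < 0:
        raise ValueError("C must be > 0 and epsilon ≥ 0")
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    mean = t.X.mean(axis=0)
    scale = t.X.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (t.X - mean) / scale
    est = SVR(kernel=kernel, C=C, epsilon=epsilon, gamma=gamma, tol=tol, max_iter=max_iter)
    est.fit(xs, t.y)
    if est.fit_status_ != 0:
        raise RuntimeError(f"SVR solver did not converge within {max_iter} iterations")
    gamma_val = est._gamma if kernel == "rbf" else 0.0
    payload = {
        "kernel": kernel,
        "C": C,
        "epsilon": epsilon,
        "gamma": float(gamma_val),
        "support_vectors": est.support_vectors_.tolist(),
        "dual_coef": est.dual_coef_.ravel().tolist(),
        "intercept": float(est.intercept_[0]),
        "x_mean": mean.tolist(),
        "x_scale": scale.tolist(),
    }
    model = QsarModel(kind="svr", names=list(t.names), payload=payload)
    model.diagnostics = _r2_scores(t.y, model.predict(t.X))
    return model


def fit_bayes(
    t: TrainingTable,
    prior_precision: float = 1e-6,
    noise_precision: float = 1.0,
) -> QsarModel:
    """Bayesian linear regression with a Gaussian prior on the slopes.

    Prior N(0, α⁻¹I) on slopes, flat (unpenalized) on the intercept; noise
    precision λ.  The posterior-mean coefficients give the point prediction.
    α → 0 recovers ordinary least squares; α → ∞ shrinks to the training
    mean.
    """
    alpha, lam = prior_precision, noise_precision
    if alpha < 0 or lam <= 0:
        raise ValueError("prior precision must be ≥ 0 and noise precision > 0")
    A = _design(t.X)
    p = A.shape[1]
    prior = np.eye(p) * alpha
    prior[0, 0] = 0.0  # flat prior on the intercept
    precision = lam * A.T @ A + prior
    cov = np.linalg.inv(precision)
    mean = cov @ (lam * A.T @ t.y)
    model = QsarModel(
        kind="bayes",
        names=list(t.names),
        payload={
            "intercept": float(mean[0]),
            "coefficients": {n_: float(b) for n_, b in zip(t.names, mean[1:])},
            "posterior_covariance": cov.tolist(),
            "prior_precision": alpha,
            "noise_precision": lam,
        },
    )
    model.diagnostics = _r2_scores(t.y, model.predict(t.X))
    return model


def prediction_interval(model: QsarModel, t: TrainingTable, x, level: float = 0.95):
    """Classical MLR prediction interval for a new descriptor vector."""
    from scipy import stats

    if model.kind != "mlr":
        raise TypeError("prediction intervals implemented for MLR models only")
    A = _design(t.X)
    n, p = A.shape
    beta = np.array([model.payload["intercept"]] +
                    [model.payload["coefficients"][nm] for nm in model.names])
    resid = t.y - A @ beta
    dof = n - p
    s2 = float(resid @ resid) / dof
    x0 = np.concatenate([[1.0], np.asarray(
        [x[nm] for nm in model.names] if isinstance(x, dict) else x, dtype=float)])
    se = np.sqrt(s2 * (1.0 + x0 @ np.linalg.inv(A.T @ A) @ x0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    center = float(x0 @ beta)
    return center - tcrit * se, center + tcrit * se


def save_model(model: QsarModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"kind": model.kind, "names": model.names,
             "payload": model.payload, "diagnostics": model.diagnostics},
            fh, indent=2)


def load_model(path) -> QsarModel:
    with open(path) as fh:
        d = json.load(fh)
    return QsarModel(kind=d["kind"], names=d["names"],
                     payload=d["payload"], diagnostics=d.get("diagnostics", {}))
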