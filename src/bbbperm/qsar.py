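"""QSAR estimation of blood-brain-barrier permeation (logBB).

The central object is a multiple linear regression of logBB on three
molecular descriptors:

    logBB = b0 + b1 * dlogp + b2 * lipophilicity + b3 * E

where ``dlogp`` = logPow - logPcw is a hydrogen-bonding-capacity descriptor,
``lipophilicity`` is logPow or a chromatographic surrogate (a logkw value
extrapolated to pure water from an IAM, CHOL or BMC system), and ``E`` is the
Abraham excess molar refraction.  :func:`published_model` returns the
literature model with coefficients (-0.114, -0.098, 0.278, 0.218) fitted on
40 chemically diverse compounds.

Model building follows the usual QSAR workflow: ordinary least squares with
backward elimination of insignificant descriptors, leave-ten-out
cross-validation (PRESS, RMSECV, R²_CV), external validation on a held-out
test split (R²_pred), and a leverage-based applicability domain with the
Williams cut-off h* = 3(p+1)/n.  R² quantities are stored as percents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    ConfigurationError,
    DataQualityWarning,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "PREDICTORS",
    "ModelDiagnostics",
    "ADState",
    "QSARModel",
    "TrainingTable",
    "LogBBRegression",
    "QSARResults",
    "published_model",
    "delta_logp",
    "predict_logbb",
    "predict_logbb_biomimetic",
    "fit_mlr",
    "backward_eliminate",
    "cross_validate_lto",
    "applicability_domain",
    "best_subset_by_alpha",
]

PREDICTORS = ("dlogp", "lipophilicity", "e")
_COEF_ATTR = {"dlogp": "coef_dlogp", "lipophilicity": "coef_lipophilicity", "e": "coef_e"}


@dataclass
class ModelDiagnostics:
    """Training and validation statistics of a fitted logBB model.

    R² quantities are percents (78.25 means 78.25%); PRESS is in squared
    logBB units; RMSE, RMSECV and the residual standard error ``s`` are in
    logBB units.  Fields not yet computed are ``None``.
    """

    r_squared: float | None = None
    r_squared_cv: float | None = None
    r_squared_pred: float | None = None
    press: float | None = None
    rmse: float | None = None
    rmsecv: float | None = None
    s: float | None = None

    def __post_init__(self) -> None:
        for name in ("press", "rmse", "rmsecv"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class ADState:
    """Leverage applicability domain of a fitted model.

    Stores the sufficient statistics to compute the leverage
    h = x (XᵀX)⁻¹ xᵀ of a query point (x includes the intercept column),
    the training leverages, and the Williams threshold h* = 3(p+1)/n.
    """

    columns: tuple[str, ...]            # retained predictors, intercept excluded
    xtx_inv: np.ndarray                 # (p+1, p+1), intercept first
    n_train: int
    training_leverages: np.ndarray

    @property
    def p(self) -> int:
        return len(self.columns)

    @property
    def leverage_threshold(self) -> float:
        return 3.0 * (self.p + 1) / self.n_train

    def leverage(self, x: Sequence[float] | Mapping[str, float]) -> float:
        if isinstance(x, Mapping):
            x = [x[c] for c in self.columns]
        row = np.concatenate([[1.0], np.asarray(x, dtype=float)])
        return float(row @ self.xtx_inv @ row)

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "xtx_inv": self.xtx_inv.tolist(),
            "n_train": self.n_train,
            "training_leverages": self.training_leverages.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ADState":
        return cls(
            columns=tuple(doc["columns"]),
            xtx_inv=np.asarray(doc["xtx_inv"], dtype=float),
            n_train=int(doc["n_train"]),
            training_leverages=np.asarray(doc["training_leverages"], dtype=float),
        )


@dataclass
class QSARModel:
    """An affine logBB model over (dlogp, lipophilicity, E).

    A descriptor eliminated during model building keeps a coefficient of 0.0,
    so prediction is always the same affine map.
    """

    intercept: float
    coef_dlogp: float
    coef_lipophilicity: float
    coef_e: float
    n_train: int | None = None
    diagnostics: ModelDiagnostics | None = None
    ad_state: ADState | None = None

    def predict(self, dlogp: float, lipophilicity: float, e: float) -> float:
        return (
            self.intercept
            + self.coef_dlogp * dlogp
            + self.coef_lipophilicity * lipophilicity
            + self.coef_e * e
        )


def published_model() -> QSARModel:
    """The literature logBB model: logBB = -0.114 - 0.098 dlogp + 0.278 logPow + 0.218 E.

    Fitted on 40 chemically diverse compounds (30 train / 10 test), with
    reported R²_CV = 78.25%, R²_pred = 74.02% and residual standard error
    s = 0.436 logBB units.
    """
    return QSARModel(
        intercept=-0.114,
        coef_dlogp=-0.098,
        coef_lipophilicity=0.278,
        coef_e=0.218,
        n_train=40,
        diagnostics=ModelDiagnostics(r_squared_cv=78.25, r_squared_pred=74.02, s=0.436),
    )


def delta_logp(logpow: float, logpcw: float) -> float:
    """Hydrogen-bonding descriptor: logPow - logPcw."""
    return float(logpow) - float(logpcw)


def predict_logbb(model: QSARModel, dlogp: float, lipophilicity: float, e: float) -> float:
    """Evaluate the affine logBB model at one descriptor triple."""
    return model.predict(dlogp, lipophilicity, e)


@dataclass(frozen=True)
class LabeledLogBB:
    """A logBB prediction labeled by the lipophilicity source used."""

    label: str
    value: float


def predict_logbb_biomimetic(model: QSARModel, dlogp: float, logkw, e: float) -> LabeledLogBB:
    """Predict logBB with a chromatographic logkw substituted for logPow.

    ``logkw`` is a fitted pure-water retention result carrying ``.logkw`` and
    ``.system`` attributes; the output is labeled logBB-IAM / logBB-CHOL /
    logBB-BMC accordingly.
    """
    value = model.predict(dlogp, logkw.logkw, e)
    return LabeledLogBB(label=f"logBB-{logkw.system}", value=value)


# -- training data ---------------------------------------------------------


@dataclass
class TrainingTable:
    """A QSAR training table: descriptors, observed logBB and a train/test split.

    ``data`` must have columns compound_id, dlogp, lipophilicity, e, logbb and
    split (values ``train``/``test``); missing cells in used columns are
    rejected.
    """

    data: pd.DataFrame

    REQUIRED = ("compound_id", "dlogp", "lipophilicity", "e", "logbb", "split")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"training table missing column(s) {missing}")
        used = self.data[list(self.REQUIRED)]
        if used.isna().any().any():
            raise ValidationError("training table contains missing cells")
        bad = set(self.data["split"]) - {"train", "test"}
        if bad:
            raise ValidationError(f"unknown split label(s) {sorted(bad)}")

    @classmethod
    def from_csv(cls, path) -> "TrainingTable":
        df = pd.read_csv(path)
        if "split" not in df.columns:
            df = df.assign(split="train")
        return cls(df)

    @property
    def train(self) -> pd.DataFrame:
        return self.data[self.data["split"] == "train"]

    @property
    def test(self) -> pd.DataFrame:
        return self.data[self.data["split"] == "test"]

    @property
    def n_train(self) -> int:
        return len(self.train)


def _design(df: pd.DataFrame, predictors: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    y = df["logbb"].to_numpy(float)
    return X, y


# -- model classes ---------------------------------------------------------


class LogBBRegression:
    """MLR model of logBB on (dlogp, lipophilicity, E), built from a training table.

    ``fit()`` performs OLS on the train split; ``fit(method="backward")``
    additionally removes, one at a time, the predictor with the largest
    p-value while that p-value exceeds ``alpha`` (default 0.10).
    """

    def __init__(self, table: TrainingTable):
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LogBBRegression":
        if "split" not in df.columns:
            df = df.assign(split="train")
        return cls(TrainingTable(df))

    def _ols(self, predictors: Sequence[str]):
        train = self.table.train
        n = len(train)
        if n <= len(predictors) + 1:
            raise InsufficientDataError(
                f"n_train = {n} rows cannot identify {len(predictors)} predictors "
                "plus an intercept"
            )
        X, y = _design(train, predictors)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError("design matrix is rank deficient")
        return sm.OLS(y, X).fit()

    def fit(self, method: str = "ols", alpha: float = 0.10) -> "QSARResults":
        if method == "ols":
            predictors = list(PREDICTORS)
            res = self._ols(predictors)
            log: list[dict] = []
        elif method == "backward":
            predictors, res, log = self._backward(alpha)
        else:
            raise ConfigurationError(f"unknown fit method {method!r}")
        return QSARResults(self, predictors, res, elimination_log=log)

    def _backward(self, alpha: float):
        predictors = list(PREDICTORS)
        log: list[dict] = []
        res = self._ols(predictors)
        while predictors:
            pvals = {p: res.pvalues[i + 1] for i, p in enumerate(predictors)}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= alpha:
                break
            log.append({"removed": worst, "p_value": float(pvals[worst])})
            predictors.remove(worst)
            if not predictors:
                warnings.warn(
                    "all predictors eliminated; returning intercept-only model",
                    DataQualityWarning,
                    stacklevel=3,
                )
                train = self.table.train
                res = sm.OLS(train["logbb"].to_numpy(float), np.ones((len(train), 1))).fit()
                break
            res = self._ols(predictors)
        return predictors, res, log


class QSARResults:
    """Results of a :class:`LogBBRegression` fit.

    Exposes ``params``, ``bse`` and ``pvalues`` as pandas Series indexed by
    term name, the portable :class:`QSARModel` via ``.model``, prediction,
    leverage queries and a text ``summary()``.
    """

    def __init__(self, regression: LogBBRegression, predictors: list[str], sm_results,
                 elimination_log: list[dict]):
        self.regression = regression
        self.predictors = tuple(predictors)
        self._sm = sm_results
        self.elimination_log = elimination_log
        self.model = self._build_model()

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._sm.params, index=["const", *self.predictors])

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._sm.bse, index=["const", *self.predictors])

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self._sm.pvalues, index=["const", *self.predictors])

    def _build_model(self) -> QSARModel:
        table = self.regression.table
        train, test = table.train, table.test
        params = self.params
        coefs = {p: float(params.get(p, 0.0)) for p in PREDICTORS}
        n = len(train)
        p = len(self.predictors)
        resid = self._sm.resid
        ss_res = float(resid @ resid)
        rmse = float(np.sqrt(ss_res / n))
        s = float(np.sqrt(ss_res / (n - p - 1))) if n > p + 1 else float("nan")
        y = train["logbb"].to_numpy(float)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 100.0 * (1.0 - ss_res / ss_tot) if ss_tot > 0 else 100.0
        r2_pred = None
        if len(test) > 0:
            model_tmp = QSARModel(float(params["const"]), coefs["dlogp"],
                                  coefs["lipophilicity"], coefs["e"])
            yhat = np.array([
                model_tmp.predict(r.dlogp, r.lipophilicity, r.e)
                for r in test.itertuples()
            ])
            yt = test["logbb"].to_numpy(float)
            # external-validation convention: SS_tot of the test residuals about
            # the training mean
            denom = float(((yt - y.mean()) ** 2).sum())
            if denom > 0:
                r2_pred = 100.0 * (1.0 - float(((yhat - yt) ** 2).sum()) / denom)
        diagnostics = ModelDiagnostics(r_squared=r2, r_squared_pred=r2_pred, rmse=rmse, s=s)
        X, _ = _design(train, self.predictors)
        xtx_inv = np.linalg.inv(X.T @ X)
        hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        ad = ADState(columns=self.predictors, xtx_inv=xtx_inv, n_train=n,
                     training_leverages=hat)
        return QSARModel(
            intercept=float(params["const"]),
            coef_dlogp=coefs["dlogp"],
            coef_lipophilicity=coefs["lipophilicity"],
            coef_e=coefs["e"],
            n_train=n,
            diagnostics=diagnostics,
            ad_state=ad,
        )

    def predict(self, dlogp, lipophilicity, e):
        return self.model.predict(dlogp, lipophilicity, e)

    def leverage(self, query) -> tuple[float, bool]:
        return applicability_domain(self.model, query)

    def summary(self) -> str:
        d = self.model.diagnostics
        lines = [
            "logBB multiple linear regression",
            f"  n_train = {self.model.n_train}, predictors = {list(self.predictors)}",
            f"  intercept = {self.model.intercept:+.4f}",
        ]
        for p in self.predictors:
            lines.append(
                f"  {p:<14} coef = {self.params[p]:+.4f}  se = {self.bse[p]:.4f}"
                f"  p = {self.pvalues[p]:.3g}"
            )
        lines.append(f"  R² = {d.r_squared:.2f}%   RMSE = {d.rmse:.4f}   s = {d.s:.4f}")
        if d.r_squared_pred is not None:
            lines.append(f"  R²_pred = {d.r_squared_pred:.2f}% (held-out test split)")
        if d.r_squared_cv is not None:
            lines.append(
                f"  R²_CV = {d.r_squared_cv:.2f}%   RMSECV = {d.rmsecv:.4f}"
                f"   PRESS = {d.press:.4f}"
            )
        for entry in self.elimination_log:
            lines.append(
                f"  eliminated {entry['removed']} (p = {entry['p_value']:.3f})"
            )
        return "\n".join(lines)


# -- spec-level convenience operations -------------------------------------


def fit_mlr(table: TrainingTable) -> QSARModel:
    """OLS fit of the full three-descriptor model; returns the portable model."""
    return LogBBRegression(table).fit().model


def backward_eliminate(table: TrainingTable, alpha: float = 0.10) -> QSARModel:
    """Backward elimination at significance level ``alpha``; returns the final model."""
    return LogBBRegression(table).fit(method="backward", alpha=alpha).model


def cross_validate_lto(
    table: TrainingTable,
    seed: int,
    n_repeats: int = 1,
    fold_size: int = 10,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[float, float, float]:
    """Leave-ten-out cross-validation of the full model on the train split.

    Rows are partitioned at random (seeded) into folds of ``fold_size``;
    each fold is predicted from an OLS fit on the remaining rows.  Returns
    ``(rmsecv, r_squared_cv, press)`` averaged over ``n_repeats`` partitions,
    with R²_CV in percent.  A remainder fold smaller than ``fold_size`` is
    allowed.
    """
    train = table.train
    n = len(train)
    if n <= fold_size:
        raise InsufficientDataError(
            f"n_train = {n} rows cannot be cross-validated with folds of {fold_size}"
        )
    X, y = _design(train, predictors)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rng = np.random.default_rng(seed)
    press_list, rmsecv_list, r2cv_list = [], [], []
    for _ in range(n_repeats):
        order = rng.permutation(n)
        press = 0.0
        for start in range(0, n, fold_size):
            out = order[start : start + fold_size]
            idx = np.ones(n, dtype=bool)
            idx[out] = False
            beta, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            resid = y[out] - X[out] @ beta
            press += float(resid @ resid)
        press_list.append(press)
        rmsecv_list.append(np.sqrt(press / n))
        r2cv_list.append(100.0 * (1.0 - press / ss_tot) if ss_tot > 0 else 100.0)
    return (
        float(np.mean(rmsecv_list)),
        float(np.mean(r2cv_list)),
        float(np.mean(press_list)),
    )


def attach_cv(model: QSARModel, table: TrainingTable, seed: int, n_repeats: int = 1) -> QSARModel:
    """Return a copy of ``model`` whose diagnostics carry LTO CV statistics."""
    rmsecv, r2cv, press = cross_validate_lto(table, seed=seed, n_repeats=n_repeats)
    diag = model.diagnostics or ModelDiagnostics()
    diag = replace(diag, rmsecv=rmsecv, r_squared_cv=r2cv, press=press)
    return replace(model, diagnostics=diag)


def applicability_domain(model: QSARModel, query) -> tuple[float, bool]:
    """Leverage of a query point and whether it lies inside the domain.

    ``query`` is a mapping of descriptor name to value, or a sequence ordered
    as the model's retained predictors.  Inside means h <= h* = 3(p+1)/n.
    """
    if model.ad_state is None:
        raise ConfigurationError(
            "model has no applicability-domain state; refit it from a training "
            "table to enable leverage queries"
        )
    h = model.ad_state.leverage(query)
    return h, h <= model.ad_state.leverage_threshold


def best_subset_by_alpha(table: TrainingTable, alpha: float = 0.10) -> tuple[str, ...]:
    """Exhaustive-subset oracle for backward elimination tests.

    Among all predictor subsets whose fitted coefficients are all significant
    at ``alpha``, returns the largest (ties broken by smaller residual sum of
    squares).  Returns an empty tuple when no subset qualifies.
    """
    train = table.train
    best: tuple[str, ...] | None = None
    best_key = None
    for mask in range(1, 2 ** len(PREDICTORS)):
        subset = tuple(p for i, p in enumerate(PREDICTORS) if mask >> i & 1)
        X, y = _design(train, subset)
        if np.linalg.matrix_rank(X) < X.shape[1] or len(train) <= len(subset) + 1:
            continue
        res = sm.OLS(y, X).fit()
        if (res.pvalues[1:] <= alpha).all():
            key = (len(subset), -float(res.ssr))
            if best is None or key > best_key:
                best, best_key = subset, key
    return best if best is not None else tuple()
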