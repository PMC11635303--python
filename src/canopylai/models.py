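"""Regression models and evaluation for plot-level LAI estimation.

Three regressors are supported, mirroring common practice in canopy
trait retrieval: partial least squares regression (PLSR, component
count picked by internal 5-fold CV), random forest regression (RFR,
ntree=500, mtry = floor(p/3)), and Gaussian process regression (GPR,
squared-exponential kernel plus a fitted noise term, hyperparameters by
marginal-likelihood maximization). The calibration/validation split is
replicate-based: replicates 2-3 of every growth stage train (96
samples on the full design), replicate 1 validates (48 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .containers import FeatureTable

METHODS = ("PLSR", "RFR", "GPR")
FEATURE_SETS = ("OSR", "FDSR", "VI", "TEX", "ALL")


@dataclass
class ModelSpec:
    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class SplitPlan:
    """Replicate-based calibration/validation partition."""
    train_keys: list
    validation_keys: list


@dataclass
class EvalReport:
    split: str
    r2: float
    rmse: float
    nrmse_percent: float
    n: int
    measured: np.ndarray = None
    predicted: np.ndarray = None


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: Pipeline
    columns: list

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy(dtype=float)
        pred = self.estimator.predict(np.asarray(X, dtype=float))
        return np.asarray(pred).ravel()


def make_split(truth) -> SplitPlan:
    """Replicates 2-3 calibrate, replicate 1 validates; deterministic."""
    train, val = [], []
    for rec in truth:
        rep = getattr(rec, "replicate", None)
        if rep not in (1, 2, 3):
            raise ValueError("ground-truth records need replicate labels 1-3")
        key = (rec.plot_id, rec.stage)
        (val if rep == 1 else train).append(key)
    if not train:
        raise ValueError("empty calibration set: only replicate 1 present")
    if not val:
        raise ValueError("empty validation set: no replicate-1 samples")
    return SplitPlan(train, val)


def r2_score_(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("zero-variance measured vector: R^2 undefined")
    return float(1.0 - ((y - yhat) ** 2).sum() / ss_tot)


def rmse_(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def nrmse_percent_(y, yhat) -> float:
    return float(100.0 * rmse_(y, yhat) / np.mean(np.asarray(y, float)))


def _pick_pls_components(X, y, seed, max_components=10, folds=5):
    n, p = X.shape
    cmax = max(1, min(max_components, p, n - 1 - n // folds))
    if cmax == 1:
        return 1
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best_c, best_err = 1, np.inf
    for c in range(1, cmax + 1):
        errs = []
        for tr, te in kf.split(X):
            m = Pipeline([("scale", StandardScaler()),
                          ("pls", PLSRegression(n_components=c))])
            m.fit(X[tr], y[tr])
            errs.append(((y[te] - m.predict(X[te]).ravel()) ** 2).sum())
        err = np.sqrt(np.sum(errs) / n)
        if err < best_err:
            best_err, best_c = err, c
    return best_c


def fit(spec: ModelSpec, X, y, columns=None) -> FittedModel:
    """Train one regressor; features are standardized inside the
    pipeline so prediction-time inputs go through the same scaling."""
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or X.shape[0] < 5:
        raise ValueError("need matching X/y with at least 5 samples")
    hp = dict(spec.hyperparameters)
    if spec.method == "PLSR":
        ncomp = hp.get("n_components")
        if ncomp is None:
            ncomp = _pick_pls_components(X, y, spec.seed)
        est = PLSRegression(n_components=int(ncomp))
    elif spec.method == "RFR":
        ntree = int(hp.get("ntree", 500))
        mtry = hp.get("mtry", max(1, X.shape[1] // 3))
        est = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                                    random_state=spec.seed, n_jobs=1)
    else:  # GPR
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(length_scale=np.sqrt(X.shape[1]),
                        length_scale_bounds=(1e-2, 1e3))
                  + WhiteKernel(noise_level=hp.get("noise_level", 0.1),
                                noise_level_bounds=(1e-6, 1e1)))
        est = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                       n_restarts_optimizer=2,
                                       random_state=spec.seed)
    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    pipe.fit(X, y)
    if columns is None:
        columns = list(range(X.shape[1]))
    return FittedModel(spec, pipe, columns)


def evaluate(model: FittedModel, X, y_measured, split: str = "validation"
             ) -> EvalReport:
    """Standard accuracy metrics of a fitted model on one split.

    r2 = 1 - SS_res/SS_tot; rmse = sqrt(mean squared error);
    nrmse = 100 * rmse / mean(measured).
    """
    y = np.asarray(y_measured, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation set")
    yhat = model.predict(X)
    return EvalReport(split=split, r2=r2_score_(y, yhat),
                      rmse=rmse_(y, yhat),
                      nrmse_percent=nrmse_percent_(y, yhat),
                      n=y.size, measured=y, predicted=yhat)


def run_experiment(combined: FeatureTable, truth, *,
                   selections: dict | None = None,
                   kmax: int | None = None, folds: int = 5,
                   seed: int = 0, methods=METHODS) -> dict:
    """The full evaluation grid: 5 feature sets x 3 methods x 2 splits.

    ``combined`` holds all 308 default columns; per family an
    SPA-selected subset (computed on the calibration split unless
    passed in via ``selections``) feeds each regressor. Returns a dict
    with the report grid, per-stage validation breakdowns, the fitted
    models and the selections used.
    """
    from .selection import spa_select

    split = make_split(truth)
    lai_by_key = {(t.plot_id, t.stage): t.lai for t in truth}
    data = combined.data
    train_idx = [k for k in data.index if tuple(k) in set(
        map(tuple, split.train_keys))]
    val_idx = [k for k in data.index if tuple(k) in set(
        map(tuple, split.validation_keys))]
    y_train = np.array([lai_by_key[tuple(k)] for k in train_idx])
    y_val = np.array([lai_by_key[tuple(k)] for k in val_idx])

    family_cols = {fam: combined.columns_of(fam)
                   for fam in ("OSR", "FDSR", "VI", "TEX")}
    family_cols["ALL"] = list(data.columns)

    if selections is None:
        selections = {}
        for fs in FEATURE_SETS:
            sub = combined.subset(family_cols[fs])
            sub_train = FeatureTable(sub.data.loc[train_idx], sub.families)
            selections[fs] = spa_select(sub_train, y_train, kmax=kmax,
                                        folds=folds, seed=seed)

    reports, per_stage, models = {}, {}, {}
    for fs in FEATURE_SETS:
        cols = (selections[fs].chosen_columns
                if hasattr(selections[fs], "chosen_columns")
                else list(selections[fs]))
        X_train = data.loc[train_idx, cols]
        X_val = data.loc[val_idx, cols]
        for method in methods:
            m = fit(ModelSpec(method, seed=seed), X_train, y_train)
            reports[(fs, method, "calibration")] = evaluate(
                m, X_train, y_train, split="calibration")
            rep_val = evaluate(m, X_val, y_val, split="validation")
            reports[(fs, method, "validation")] = rep_val
            models[(fs, method)] = m
            stages = sorted({k[1] for k in val_idx})
            for stage in stages:
                sel = [i for i, k in enumerate(val_idx) if k[1] == stage]
                ys = y_val[sel]
                per_stage[(fs, method, stage)] = EvalReport(
                    split="validation", r2=r2_score_(ys, rep_val.predicted[sel]),
                    rmse=rmse_(ys, rep_val.predicted[sel]),
                    nrmse_percent=nrmse_percent_(ys, rep_val.predicted[sel]),
                    n=len(sel), measured=ys, predicted=rep_val.predicted[sel])
    return {"reports": reports, "per_stage": per_stage,
            "selections": selections, "models": models,
            "split": split}


def reports_to_frame(reports: dict) -> pd.DataFrame:
    rows = []
    for (fs, method, split), rep in reports.items():
        rows.append({"feature_set": fs, "method": method, "split": split,
                     "r2": rep.r2, "rmse": rep.rmse,
                     "nrmse_percent": rep.nrmse_percent, "n": rep.n})
    return pd.DataFrame(rows)
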