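"""Multivariable LCC regression under k-fold cross-validation.

Four regression families are supported:

* **PLSR** -- partial least squares, latent-variable count chosen by inner
  5-fold CV over 1..min(10, n_features);
* **ARS** -- adaptive regression splines (additive piecewise-linear
  forward/backward basis, max 21 terms);
* **SVR** -- RBF support vector regression, (C, gamma, epsilon) by inner
  grid search on standardized features;
* **GPR** -- Gaussian process regression with an RBF + noise kernel,
  hyperparameters by marginal-likelihood maximization with restarts;
  returns a predictive standard deviation per sample.

Evaluation pools the out-of-fold predictions of a seeded 10-fold split and
reports the pooled coefficient of determination R2 = 1 - SS_res/SS_tot and
RMSE = sqrt(mean squared error), both in SPAD units. Standardization and
all hyperparameter selection happen inside each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._mars import AdaptiveRegressionSplines
from .errors import ConfigError, DataError, RegistryError
from .spectral_features import FeatureTable, VI_ORG_NAMES, VI_RE_NAMES

__all__ = [
    "MODEL_NAMES",
    "DEFAULT_CV_SEED",
    "FeatureGroup",
    "CVResult",
    "make_folds",
    "fit_predict",
    "evaluate",
    "standard_feature_groups",
    "results_matrix",
]

MODEL_NAMES = ("PLSR", "ARS", "SVR", "GPR")
DEFAULT_CV_SEED = 20240426

SVR_GRID = {
    "svr__C": [0.1, 1.0, 10.0, 100.0],
    "svr__gamma": ["scale", 0.1, 1.0, 10.0],
    "svr__epsilon": [0.01, 0.1, 1.0],
}


@dataclass
class FeatureGroup:
    """A named set of input features (one row of the model-comparison table)."""

    name: str
    members: list[str]

    @property
    def n_features(self) -> int:
        return len(self.members)


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one (model, feature group) pair."""

    model: str
    group: str
    k: int
    seed: int
    y_true: np.ndarray
    y_pred: np.ndarray
    y_sd: np.ndarray | None
    folds: np.ndarray
    r2: float
    rmse: float
    fold_rmse: list[float] = field(default_factory=list)


def make_folds(n: int, k: int = 10, seed: int = DEFAULT_CV_SEED) -> np.ndarray:
    """Seeded shuffle + round-robin fold assignment; sizes differ by <= 1."""
    if n < k:
        raise DataError(f"cannot split n={n} samples into k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[perm] = np.arange(n) % k
    return folds


def _pooled_scores(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(ss_res / y_true.size))
    return r2, rmse


def _fit_plsr(X_tr, y_tr, X_te, seed):
    n, p = X_tr.shape
    max_comp = max(1, min(10, p, n - 2))
    best_nc, best_mse = 1, np.inf
    inner = KFold(n_splits=min(5, n), shuffle=True, random_state=seed % (2**31))
    for nc in range(1, max_comp + 1):
        errs = []
        for tr, va in inner.split(X_tr):
            m = PLSRegression(n_components=min(nc, len(tr) - 1), scale=True)
            m.fit(X_tr[tr], y_tr[tr])
            errs.append(float(((y_tr[va] - m.predict(X_tr[va]).ravel()) ** 2).mean()))
        mse = float(np.mean(errs))
        if mse < best_mse - 1e-12:
            best_mse, best_nc = mse, nc
    model = PLSRegression(n_components=best_nc, scale=True)
    model.fit(X_tr, y_tr)
    return model.predict(X_te).ravel(), None


def _fit_ars(X_tr, y_tr, X_te, seed):
    model = AdaptiveRegressionSplines(max_terms=21)
    model.fit(X_tr, y_tr)
    return model.predict(X_te), None


def _fit_svr(X_tr, y_tr, X_te, seed):
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    n = X_tr.shape[0]
    search = GridSearchCV(pipe, SVR_GRID, cv=min(3, n),
                          scoring="neg_mean_squared_error", n_jobs=1)
    search.fit(X_tr, y_tr)
    return search.predict(X_te), None


def _fit_gpr(X_tr, y_tr, X_te, seed, n_restarts: int = 5):
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=np.sqrt(X_tr.shape[1]), length_scale_bounds=(1e-2, 1e3))
        + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e2))
    )
    pipe_scaler = StandardScaler().fit(X_tr)
    gpr = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=n_restarts,
        random_state=seed % (2**31),
    )
    gpr.fit(pipe_scaler.transform(X_tr), y_tr)
    mean, sd = gpr.predict(pipe_scaler.transform(X_te), return_std=True)
    return mean, sd


_FITTERS = {"PLSR": _fit_plsr, "ARS": _fit_ars, "SVR": _fit_svr, "GPR": _fit_gpr}


def fit_predict(model_spec: str, X_train, y_train, X_test,
                seed: int = DEFAULT_CV_SEED, **kwargs):
    """Train one model family and predict; GPR also returns predictive sd.

    Returns ``(predictions, sd_or_None)``. All feature scaling is fit on
    the training data only.
    """
    if model_spec not in _FITTERS:
        raise RegistryError(f"unknown model '{model_spec}'; use {MODEL_NAMES}")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if not (np.isfinite(X_train).all() and np.isfinite(y_train).all()
            and np.isfinite(X_test).all()):
        raise DataError("model inputs must be finite")
    try:
        return _FITTERS[model_spec](X_train, y_train, X_test, seed, **kwargs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DataError(f"{model_spec} fit failed: {exc}") from exc


def evaluate(
    model_spec: str,
    group: FeatureGroup,
    table: FeatureTable,
    k: int = 10,
    seed: int = DEFAULT_CV_SEED,
    **kwargs,
) -> CVResult:
    """Pooled out-of-fold evaluation of one model on one feature group."""
    if not group.members:
        raise DataError(f"feature group '{group.name}' is empty")
    X = table.select(group.members).to_numpy(dtype=float)
    y = table.spad.to_numpy(dtype=float)
    folds = make_folds(y.size, k=k, seed=seed)
    y_pred = np.full_like(y, np.nan)
    y_sd = np.full_like(y, np.nan)
    has_sd = False
    fold_rmse = []
    for f in range(k):
        te = folds == f
        tr = ~te
        pred, sd = fit_predict(model_spec, X[tr], y[tr], X[te],
                               seed=seed + f, **kwargs)
        y_pred[te] = pred
        if sd is not None:
            y_sd[te] = sd
            has_sd = True
        fold_rmse.append(float(np.sqrt(((y[te] - pred) ** 2).mean())))
    r2, rmse = _pooled_scores(y, y_pred)
    return CVResult(
        model=model_spec, group=group.name, k=k, seed=seed,
        y_true=y, y_pred=y_pred, y_sd=y_sd if has_sd else None,
        folds=folds, r2=r2, rmse=rmse, fold_rmse=fold_rmse,
    )


def standard_feature_groups(
    table: FeatureTable,
    selected_r: dict[str, list[str]] | None = None,
    selected_mic: dict[str, list[str]] | None = None,
) -> list[FeatureGroup]:
    """The variable groups of the model-comparison design.

    Original groups: all 20 VIs; the 9 VI_re; all VIs plus the 8 textures
    of each PC image (28 features each). When screening selections are
    given (as provenance -> names maps), the corresponding
    "Selected VIs+TFs-PCk" groups are appended for each PC image with a
    non-empty texture selection.
    """
    names = set(table.feature_names)
    groups = []
    vis_all = [n for n in VI_ORG_NAMES + VI_RE_NAMES if n in names]
    vire = [n for n in VI_RE_NAMES if n in names]
    if vis_all:
        groups.append(FeatureGroup("All VIs", vis_all))
    if vire:
        groups.append(FeatureGroup("All VI_re", vire))
    for pc in ("PC1", "PC2", "PC3"):
        tfs = [n for n in table.feature_names if n.startswith(f"{pc}_")]
        if tfs:
            groups.append(FeatureGroup(f"All VIs+TFs-{pc}", vis_all + tfs))
    for label, sel in (("r", selected_r), ("MIC", selected_mic)):
        if not sel:
            continue
        sel_vis = sel.get("VI", [])
        for pc in ("PC1", "PC2", "PC3"):
            sel_tfs = sel.get(f"TF-{pc}", [])
            if sel_vis or sel_tfs:
                groups.append(FeatureGroup(
                    f"Selected({label}) VIs+TFs-{pc}", sel_vis + sel_tfs))
    for g in groups:
        missing = [m for m in g.members if m not in names]
        if missing:
            raise ConfigError(f"group '{g.name}' references missing features {missing}")
    return groups


def results_matrix(results: list[CVResult]) -> pd.DataFrame:
    """Model-comparison matrix: rows = groups, columns = model x {r2, rmse}."""
    rows: dict[str, dict] = {}
    for res in results:
        rows.setdefault(res.group, {})[f"{res.model}_r2"] = res.r2
        rows.setdefault(res.group, {})[f"{res.model}_rmse"] = res.rmse
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "variable_group"
    return frame
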