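"""Logistic NTCP models: univariate index sweeps, LASSO selection, MLE fits.

The logistic NTCP model is

    log(NTCP / (1 - NTCP)) = alpha_0 + sum_k alpha_k x_k + gamma * D,

where D is a dosimetric index (D_X% or V_DGy) and x_k are patient
covariates (binary coded 0/1, continuous entered untransformed).  Three
layers are provided:

* :func:`fit_logistic` — unpenalized MLE with per-coefficient
  profile-likelihood 95% CIs (Wald optional) and Wald p-values;
* :func:`sweep_univariate` — a family of univariate fits over a grid of
  dosimetric indices, ranked by ROC AUC, used to pick the dosimetric
  correlate for multivariate modeling;
* :func:`lasso_select` — L1-penalized selection of patient covariates with
  the dose term unpenalized, penalty chosen by stratified cross-validated
  deviance; inference is then obtained by an unpenalized refit on exactly
  the selected set (two-stage reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .dvh import (
    ConfigurationError,
    DoseIndexSpec,
    FractionationScheme,
    dose_index,
    eqd2_convert,
)
from .lkb import DegenerateDataError
from .roc import auc, auc_ci

__all__ = [
    "SeparationError",
    "RankDeficiencyError",
    "LogisticNTCPModel",
    "SweepCell",
    "SweepResult",
    "LassoSelection",
    "fit_logistic",
    "predict_ntcp",
    "compute_index_values",
    "sweep_univariate",
    "lasso_select",
]


class SeparationError(RuntimeError):
    """The MLE does not exist (perfect or quasi-perfect separation)."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; message names collinear columns."""


@dataclass
class LogisticNTCPModel:
    """Fitted logistic NTCP model.

    ``coefs`` maps term names (``"intercept"``, the index name, covariate
    names) to estimates; ``ci95`` and ``pvalues`` are keyed identically.
    """

    coefs: dict
    ci95: dict
    pvalues: dict
    index_spec: DoseIndexSpec | None
    covariate_names: tuple
    loglik: float
    n_obs: int
    converged: bool = True

    @property
    def intercept(self) -> float:
        return self.coefs["intercept"]

    @property
    def dose_coef(self) -> float | None:
        return None if self.index_spec is None else self.coefs[self.index_spec.name]

    def linear_predictor(self, patient, dose_index_value=None) -> float:
        lp = self.intercept
        if self.index_spec is not None:
            if dose_index_value is None:
                raise ConfigurationError("dose_index_value: required by this model")
            lp += self.coefs[self.index_spec.name] * float(dose_index_value)
        for name in self.covariate_names:
            try:
                lp += self.coefs[name] * float(patient[name])
            except (KeyError, IndexError):
                raise ConfigurationError(f"covariate {name!r}: missing for patient") from None
        return lp

    def predict(self, patient=None, dose_index_value=None) -> float:
        if patient is None:
            patient = {}
        return float(expit(self.linear_predictor(patient, dose_index_value)))


def predict_ntcp(model: LogisticNTCPModel, patient, dose_index_value=None) -> float:
    """NTCP = logistic(linear predictor) for one patient."""
    return model.predict(patient, dose_index_value)


# ---------------------------------------------------------------------------
# Design matrix assembly and diagnostics
# ---------------------------------------------------------------------------

def _design(patients, outcomes, index_spec, dose_values, covariate_names):
    y = np.asarray(outcomes, int)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateDataError("cohort must contain at least one event and one non-event")
    cols = {"intercept": np.ones(y.size)}
    if index_spec is not None:
        if dose_values is None:
            raise ConfigurationError("dose_values: required when index_spec is given")
        cols[index_spec.name] = np.asarray(dose_values, float)
    for name in covariate_names:
        if name not in patients.columns:
            raise ConfigurationError(f"covariate {name!r}: not present in cohort")
        cols[name] = patients[name].to_numpy(float)
    X = pd.DataFrame(cols)
    _check_rank(X)
    return X, y


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank == X.shape[1]:
        return
    # name the offenders: columns that do not increase the rank when added
    bad = []
    kept = np.empty((arr.shape[0], 0))
    for j, name in enumerate(X.columns):
        trial = np.column_stack([kept, arr[:, j]])
        if np.linalg.matrix_rank(trial) > kept.shape[1]:
            kept = trial
        else:
            bad.append(name)
    raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {bad}")


def _fit_sm(X: pd.DataFrame, y: np.ndarray):
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=500, method="newton")
    except Exception as exc:  # PerfectSeparationError and numerical failures
        raise SeparationError(f"logistic MLE failed: {exc}") from None
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged or np.any(np.abs(res.params.to_numpy()) > 1e3):
        raise SeparationError("logistic MLE did not converge (possible separation)")
    fitted = res.predict(X)
    if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)):
        raise SeparationError("perfect separation: all fitted probabilities saturated")
    return res


def _bernoulli_ll(lp, y):
    # sum(y*lp - log(1 + exp(lp))), stable for large |lp|
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


def _profile_ci(X, y, res, name, z2=3.841458820694124):
    """Profile-likelihood 95% CI for one coefficient.

    The remaining coefficients are re-optimized by BFGS with analytic
    gradient at each fixed value of the profiled coefficient.
    """
    from scipy.optimize import minimize

    cols = list(X.columns)
    j = cols.index(name)
    xj = X.iloc[:, j].to_numpy(float)
    rest = X.drop(columns=[name]).to_numpy(float)
    rest_hat = res.params.drop(name).to_numpy(float)
    beta_hat = float(res.params.iloc[j])
    se = float(res.bse.iloc[j])
    llmax = float(res.llf)

    def ll_profile(b):
        offset = b * xj
        if rest.shape[1] == 0:
            return _bernoulli_ll(offset, y)

        def nll(beta):
            lp = offset + rest @ beta
            return -_bernoulli_ll(lp, y)

        def grad(beta):
            lp = offset + rest @ beta
            return -(rest.T @ (y - expit(lp)))

        opt = minimize(nll, rest_hat, jac=grad, method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 500})
        return -float(opt.fun)

    def g(b):
        return 2.0 * (llmax - ll_profile(b)) - z2

    def bound(direction):
        step = max(se, 1e-3)
        lo = beta_hat
        for _ in range(60):
            hi = lo + direction * step
            if g(hi) >= 0:
                a, b = sorted((lo, hi))
                return brentq(g, a, b, xtol=1e-6 * max(1.0, abs(beta_hat)))
            lo = hi
            step *= 1.6
        return -np.inf if direction < 0 else np.inf

    return bound(-1.0), bound(+1.0)


def fit_logistic(
    patients: pd.DataFrame,
    outcomes,
    index_spec: DoseIndexSpec | None = None,
    dose_values=None,
    covariate_names=(),
    ci_method: str = "profile",
) -> LogisticNTCPModel:
    """Unpenalized logistic MLE with 95% CIs and Wald p-values.

    With no index and no covariates this is the intercept-only model
    (intercept = logit of the prevalence).  Perfect separation raises
    :class:`SeparationError`; a rank-deficient design raises
    :class:`RankDeficiencyError` naming the collinear columns.
    """
    X, y = _design(patients, outcomes, index_spec, dose_values, covariate_names)
    res = _fit_sm(X, y)
    coefs = {name: float(res.params[name]) for name in X.columns}
    pvalues = {name: float(res.pvalues[name]) for name in X.columns}
    if ci_method == "wald":
        ci_df = res.conf_int(alpha=0.05)
        ci95 = {name: (float(ci_df.loc[name, 0]), float(ci_df.loc[name, 1]))
                for name in X.columns}
    elif ci_method == "profile":
        ci95 = {name: _profile_ci(X, y, res, name) for name in X.columns}
    else:
        raise ConfigurationError(f"ci_method: unknown method {ci_method!r}")
    return LogisticNTCPModel(
        coefs=coefs,
        ci95=ci95,
        pvalues=pvalues,
        index_spec=index_spec,
        covariate_names=tuple(covariate_names),
        loglik=float(res.llf),
        n_obs=int(y.size),
    )


# ---------------------------------------------------------------------------
# Univariate sweep over dosimetric indices
# ---------------------------------------------------------------------------

def compute_index_values(
    doses_list,
    spec: DoseIndexSpec,
    scheme: FractionationScheme | None = None,
    eqd2: bool = True,
) -> np.ndarray:
    """Per-patient index values, EQD2-corrected by default."""
    scheme = scheme or FractionationScheme()
    return np.array(
        [dose_index(eqd2_convert(s, scheme) if eqd2 else s, spec) for s in doses_list]
    )


@dataclass
class SweepCell:
    spec: DoseIndexSpec
    model: LogisticNTCPModel | None
    auc: float | None
    auc_ci95: tuple | None
    error: str | None = None


@dataclass
class SweepResult:
    cells: list
    best_index: DoseIndexSpec | None

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "index": c.spec.name,
                    "kind": c.spec.kind,
                    "threshold": c.spec.threshold,
                    "gamma": None if c.model is None else c.model.dose_coef,
                    "auc": c.auc,
                    "auc_lo": None if c.auc_ci95 is None else c.auc_ci95[0],
                    "auc_hi": None if c.auc_ci95 is None else c.auc_ci95[1],
                    "error": c.error,
                }
            )
        return pd.DataFrame(rows)


def sweep_univariate(
    doses_list,
    outcomes,
    patients: pd.DataFrame | None = None,
    x_grid=tuple(range(10, 100, 5)),
    d_grid=tuple(range(10, 75, 5)),
    scheme: FractionationScheme | None = None,
    eqd2: bool = True,
    n_boot: int = 0,
    seed: int | None = None,
    covariate_names=(),
) -> SweepResult:
    """Fit one logistic model per dosimetric index and rank them by AUC.

    Grids default to D_X% for X = 10..95% and V_DGy for D = 10..70 Gy in
    5-unit steps.  The best index attains the maximum AUC; ties break by
    grid order (D_X% ascending X first, then V_D ascending D).  Fit
    failures become flagged cells, never a run abort.  With
    ``covariate_names`` the same sweep is run with patient covariates
    added to every fit (the multivariate AUC family).
    """
    if len(x_grid) + len(d_grid) == 0:
        raise ConfigurationError("x_grid/d_grid: at least one grid must be nonempty")
    if patients is None:
        patients = pd.DataFrame(index=range(len(doses_list)))
    y = np.asarray(outcomes, int)
    specs = [DoseIndexSpec("D_at_volume", float(x)) for x in x_grid]
    specs += [DoseIndexSpec("V_at_dose", float(d)) for d in d_grid]
    if eqd2:
        sch = scheme or FractionationScheme()
        doses_list = [eqd2_convert(s, sch) for s in doses_list]
    cells = []
    for spec in specs:
        values = compute_index_values(doses_list, spec, eqd2=False)
        try:
            model = fit_logistic(patients, y, spec, values, covariate_names,
                                 ci_method="wald")
            scores = np.array(
                [model.predict(patients.iloc[i], values[i]) for i in range(y.size)]
            )
            a = auc(scores, y)
            ci = auc_ci(scores, y, n_boot=n_boot, seed=seed) if n_boot else None
            cells.append(SweepCell(spec, model, a, ci))
        except SeparationError as exc:
            # the MLE does not exist, but the index still ranks patients:
            # report the raw-index AUC (sign-corrected) with the fit flagged
            direction = 1.0 if np.corrcoef(values, y)[0, 1] >= 0 else -1.0
            a = auc(direction * values, y)
            cells.append(SweepCell(spec, None, a, None, error=str(exc)))
        except (RankDeficiencyError, DegenerateDataError) as exc:
            cells.append(SweepCell(spec, None, None, None, error=str(exc)))
    best = None
    best_auc = -np.inf
    for c in cells:
        if c.auc is not None and c.auc > best_auc:
            best_auc, best = c.auc, c.spec
    return SweepResult(cells=cells, best_index=best)


# ---------------------------------------------------------------------------
# LASSO covariate selection
# ---------------------------------------------------------------------------

@dataclass
class LassoSelection:
    selected: tuple
    alpha: float
    path: pd.DataFrame
    candidates: tuple = field(default_factory=tuple)


def _l1_fit(X, y, alpha_vec):
    import warnings

    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        # the QC check on near-zero coefficients is advisory; the selected
        # support is what matters here
        warnings.simplefilter("ignore")
        res = model.fit_regularized(
            method="l1", alpha=alpha_vec, disp=0, trim_mode="size",
            size_trim_tol=1e-6, maxiter=500, acc=1e-8,
        )
    return np.asarray(res.params, float)


def lasso_select(
    patients: pd.DataFrame,
    outcomes,
    index_spec: DoseIndexSpec,
    dose_values,
    candidate_covariates,
    cv_folds: int = 5,
    seed: int = 0,
    n_alpha: int = 25,
    alpha_min_ratio: float = 1e-3,
    penalize_dose: bool = False,
    rule: str = "1se",
) -> LassoSelection:
    """L1-penalized covariate selection with the dose term unpenalized.

    Candidate covariates are standardized to unit variance for the penalty
    only; the penalty weight is chosen by stratified cross-validated
    deviance over a geometric path from the smallest all-zero penalty
    downward.  ``rule="1se"`` (default) takes the sparsest penalty whose
    CV deviance is within one standard error of the minimum — the
    conventional choice when the goal is variable selection rather than
    prediction; ``rule="min"`` takes the deviance minimizer.  Returns the
    covariates with nonzero coefficients at the chosen penalty;
    deterministic given ``seed``.
    """
    candidates = tuple(candidate_covariates)
    if cv_folds < 3:
        raise ConfigurationError("cv_folds: must be >= 3")
    X, y = _design(patients, outcomes, index_spec, dose_values, candidates)
    if int(y.sum()) < cv_folds or int((1 - y).sum()) < cv_folds:
        raise DegenerateDataError(
            "too few events to form stratified folds with both classes"
        )
    # standardize candidates (penalization scale only)
    Xs = X.copy()
    scales = {}
    for name in candidates:
        sd = Xs[name].std(ddof=0)
        if sd == 0:
            raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: ['{name}']")
        scales[name] = sd
        Xs[name] = (Xs[name] - Xs[name].mean()) / sd
    arr = Xs.to_numpy(float)
    n_unpen = 2 if index_spec is not None else 1

    # smallest penalty that zeroes every candidate: KKT bound from the
    # unpenalized base model (intercept + dose only)
    base = _fit_sm(Xs.iloc[:, :n_unpen], y)
    resid = y - base.predict(Xs.iloc[:, :n_unpen])
    alpha_max = float(np.max(np.abs(arr[:, n_unpen:].T @ resid))) * 1.02
    alphas = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alpha)

    def alpha_vec(a):
        vec = np.full(arr.shape[1], a)
        vec[0] = 0.0
        if index_spec is not None and not penalize_dose:
            vec[1] = 0.0
        return vec

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(arr, y))
    fold_dev = np.zeros((cv_folds, n_alpha))  # mean per-observation deviance
    for f, (train, test) in enumerate(folds):
        for k, a in enumerate(alphas):
            params = _l1_fit(arr[train], y[train], alpha_vec(a))
            p = np.clip(expit(arr[test] @ params), 1e-12, 1 - 1e-12)
            dev = -2.0 * np.sum(y[test] * np.log(p) + (1 - y[test]) * np.log1p(-p))
            fold_dev[f, k] = dev / test.size
    cv_dev = fold_dev.mean(axis=0)
    k_min = int(np.argmin(cv_dev))
    if rule == "min":
        k_best = k_min
    elif rule == "1se":
        se = fold_dev[:, k_min].std(ddof=1) / np.sqrt(cv_folds)
        # alphas descend: the sparsest acceptable penalty is the first one
        within = np.nonzero(cv_dev <= cv_dev[k_min] + se)[0]
        k_best = int(within[0])
    else:
        raise ConfigurationError(f"rule: unknown penalty rule {rule!r}")
    alpha_best = float(alphas[k_best])
    full = _l1_fit(arr, y, alpha_vec(alpha_best))
    selected = tuple(
        name for j, name in enumerate(candidates) if abs(full[n_unpen + j]) > 1e-8
    )
    path = pd.DataFrame({"alpha": alphas, "cv_deviance": cv_dev})
    full_path = np.array([_l1_fit(arr, y, alpha_vec(a)) for a in alphas])
    for j, name in enumerate(candidates):
        path[name] = full_path[:, n_unpen + j] / scales[name]  # original scale
    return LassoSelection(selected=selected, alpha=alpha_best, path=path,
                          candidates=candidates)
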