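"""Lyman-Kutcher-Burman NTCP model: gEUD, maximum-likelihood fitting, CIs.

The LKB model maps a dose distribution to a complication probability via
the generalized equivalent uniform dose,

    gEUD = (sum_i v_i * D_i**(1/n)) ** n,

and a probit dose response,

    NTCP = Phi((gEUD - TD50) / (m * TD50)),

with TD50 (dose at 50% complication probability, Gy), m (relative slope)
and n (volume-effect exponent; n -> 0 approaches the maximum dose, n = 1
is the mean dose) as adjustable parameters.  Parameters are estimated by
maximizing the Bernoulli log-likelihood with Nelder-Mead in log-parameter
coordinates, restarted over a coarse initialization grid because the
likelihood is non-concave.  Confidence intervals are asymptotic Wald
intervals on the log scale (inverse observed information), with a
profile-likelihood fallback when the observed information is not positive
definite.

A covariate can be inserted through the standard dose-modifying-factor
convention TD50_i = TD50 * exp(delta * x_i), fitted jointly
(:func:`fit_lkb_partial`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .dvh import ConfigurationError, DoseSample, DVHCurve

__all__ = [
    "LKBParams",
    "LKBFitResult",
    "PartialLKBResult",
    "QUANTEC_LATE_RECTAL",
    "DegenerateDataError",
    "geud",
    "lkb_ntcp",
    "fit_lkb",
    "lkb_confint",
    "fit_lkb_partial",
    "apply_fixed_lkb",
    "lkb_loglik",
]


class DegenerateDataError(ValueError):
    """The cohort cannot identify the model (e.g. all-event or no-event)."""


@dataclass(frozen=True)
class LKBParams:
    """LKB parameters (TD50 in Gy; m, n dimensionless, all positive)."""

    td50: float
    m: float
    n: float

    def __post_init__(self) -> None:
        for name in ("td50", "m", "n"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name}: must be > 0")


#: Published late rectal toxicity parameters used for fixed-parameter
#: comparisons (QUANTEC pooled analysis).
QUANTEC_LATE_RECTAL = LKBParams(td50=76.9, m=0.13, n=0.09)


@dataclass
class LKBFitResult:
    params: LKBParams
    ci95: dict | None
    loglik: float
    converged: bool
    n_restarts_used: int


@dataclass
class PartialLKBResult:
    params: LKBParams
    delta: float
    delta_ci: tuple | None
    covariate: str
    ci95: dict | None
    loglik: float
    converged: bool
    degenerate_covariate: bool = False


# ---------------------------------------------------------------------------
# gEUD
# ---------------------------------------------------------------------------

def _values_weights(data) -> tuple:
    if isinstance(data, DoseSample):
        return data.voxel_doses, data.voxel_volumes
    if isinstance(data, DVHCurve):
        # differential volumes between grid points, doses at bin midpoints
        dv = data.cum_volume[:-1] - data.cum_volume[1:]
        mid = 0.5 * (data.dose_grid[:-1] + data.dose_grid[1:])
        tail = data.cum_volume[-1]
        if tail > 0:
            dv = np.append(dv, tail)
            mid = np.append(mid, data.dose_grid[-1])
        return mid, dv
    values, weights = data
    return np.asarray(values, float), np.asarray(weights, float)


def geud(data, n_exponent: float) -> float:
    """Generalized equivalent uniform dose (power mean with exponent 1/n).

    Accepts a :class:`DoseSample`, a :class:`DVHCurve`, or a
    ``(doses, volume_weights)`` pair.  Zero-dose voxels contribute zero;
    computed in log space so very small ``n`` stays finite.
    """
    if not n_exponent > 0:
        raise ConfigurationError("n_exponent: must be > 0")
    values, weights = _values_weights(data)
    weights = weights / weights.sum()
    pos = values > 0
    if not pos.any():
        return 0.0
    log_terms = np.log(weights[pos]) + np.log(values[pos]) / n_exponent
    return float(np.exp(n_exponent * logsumexp(log_terms)))


def lkb_ntcp(geud_gy, params: LKBParams):
    """Probit NTCP at the given gEUD; strictly increasing in gEUD."""
    t = (np.asarray(geud_gy, float) - params.td50) / (params.m * params.td50)
    return norm.cdf(t)


# ---------------------------------------------------------------------------
# Binned cohort representation for fast likelihood evaluation
# ---------------------------------------------------------------------------

def cohort_dose_matrix(doses_list, bin_width: float | None = 0.25) -> tuple:
    """Shared-grid differential-DVH matrix (bin centers, per-patient weights).

    Binning at 0.25 Gy changes gEUD by less than half a bin width and makes
    each likelihood evaluation a single matrix-vector product.  With
    ``bin_width=None`` raw (possibly ragged) voxel lists are padded into a
    zero-weighted matrix instead.
    """
    pairs = [_values_weights(d) for d in doses_list]
    if bin_width is None:
        width = max(v.size for v, _ in pairs)
        centers = np.zeros((len(pairs), width))
        weights = np.zeros((len(pairs), width))
        for i, (v, w) in enumerate(pairs):
            centers[i, : v.size] = v
            weights[i, : v.size] = w / w.sum()
        return centers, weights
    top = max(v.max() for v, _ in pairs)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights = np.zeros((len(pairs), centers.size))
    for i, (v, w) in enumerate(pairs):
        hist, _ = np.histogram(v, bins=edges, weights=w)
        weights[i] = hist / w.sum()
    return centers, weights


def _geud_vector(centers, weights, n_exponent: float) -> np.ndarray:
    # centers may be a shared 1-D grid or a per-patient 2-D array
    safe = np.where(centers > 0, centers, 1.0)
    log_safe = np.log(safe)
    if log_safe.max() / n_exponent > 690.0:
        # direct powers would overflow float64; go through log space
        log_terms = np.where(
            (weights > 0) & (centers > 0),
            np.log(np.where(weights > 0, weights, 1.0)) + log_safe / n_exponent,
            -np.inf,
        )
        if log_terms.ndim == 1:
            log_terms = np.broadcast_to(log_terms, weights.shape)
        return np.exp(n_exponent * logsumexp(log_terms, axis=-1))
    powed = np.where(centers > 0, safe ** (1.0 / n_exponent), 0.0)
    if powed.ndim == 1:
        s = weights @ powed
    else:
        s = np.sum(weights * powed, axis=1)
    return s ** n_exponent


def lkb_loglik(params: LKBParams, centers, weights, outcomes) -> float:
    """Bernoulli log-likelihood of the LKB model on a binned cohort."""
    g = _geud_vector(centers, weights, params.n)
    p = np.clip(lkb_ntcp(g, params), 1e-12, 1 - 1e-12)
    y = np.asarray(outcomes, float)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _check_outcomes(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, int)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateDataError("cohort must contain at least one event and one non-event")
    return y


_DEFAULT_INIT_GRID = tuple(
    itertools.product((40.0, 65.0, 90.0), (0.05, 0.15, 0.3), (0.05, 0.3, 1.0))
)


def _neg_loglik_factory(centers, weights, y, x=None):
    def nll(theta):
        td50, m, n = np.exp(theta[:3])
        if not (1e-2 < td50 < 1e4 and 1e-5 < m < 1e2 and 1e-4 < n < 50):
            return 1e10
        g = _geud_vector(centers, weights, n)
        td = td50 if x is None else td50 * np.exp(theta[3] * x)
        p = np.clip(norm.cdf((g - td) / (m * td)), 1e-12, 1 - 1e-12)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    return nll


def _is_flagged(params: LKBParams, loglik: float = -np.inf) -> bool:
    # near-separation or boundary drift: slope collapsing, absurd scales, or
    # an essentially zero deviance (every fitted probability saturated)
    return (
        params.m < 5e-3
        or params.td50 < 5.0
        or params.td50 > 500.0
        or params.n < 2e-3
        or params.n > 10.0
        or loglik > -1e-4
    )


def fit_lkb(
    doses_list,
    outcomes,
    init_grid=None,
    bin_width: float | None = 0.25,
    fatol: float = 1e-8,
    maxiter: int = 2000,
    compute_ci: bool = True,
) -> LKBFitResult:
    """Maximum-likelihood LKB fit with Nelder-Mead restarts.

    ``doses_list`` must already be EQD2-corrected if fractionation
    correction is wanted.  The returned log-likelihood is never below the
    likelihood at any initialization point; non-convergence or boundary
    drift is flagged via ``converged``, never silent.
    """
    y = _check_outcomes(outcomes)
    if len(doses_list) != y.size:
        raise ConfigurationError("outcomes: length mismatch with doses_list")
    centers, weights = cohort_dose_matrix(doses_list, bin_width)
    nll = _neg_loglik_factory(centers, weights, y)
    grid = init_grid if init_grid is not None else _DEFAULT_INIT_GRID
    best = None
    best_val = np.inf
    any_success = False
    for start in grid:
        theta0 = np.log(np.asarray(start, float))
        res = minimize(
            nll,
            theta0,
            method="Nelder-Mead",
            options={"fatol": fatol, "xatol": 1e-7, "maxiter": maxiter},
        )
        val = min(res.fun, nll(theta0))
        cand = res.x if res.fun <= nll(theta0) else theta0
        if val < best_val:
            best_val, best = val, cand
            any_success = res.success
        elif val == best_val and res.success:
            any_success = True
    td50, m, n = np.exp(best)
    params = LKBParams(td50, m, n)
    converged = any_success and not _is_flagged(params, -best_val)
    fit = LKBFitResult(
        params=params,
        ci95=None,
        loglik=-best_val,
        converged=converged,
        n_restarts_used=len(tuple(grid)),
    )
    if compute_ci and converged:
        try:
            fit.ci95 = lkb_confint(fit, (centers, weights), y)
        except DegenerateDataError:
            fit.ci95 = None
    return fit


def _numerical_hessian(f, theta, h=1e-4):
    k = theta.size
    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h**2)
    return H


def _profile_ci(nll, theta_hat, j, nll_min, z2=3.841458820694124):
    """Profile-likelihood interval for theta[j] (log scale), re-optimizing others.

    The inner optimization is warm-started from the solution at the nearest
    previously profiled point, so the optimizer tracks the likelihood ridge
    instead of restarting at the MLE far from it.
    """
    free = [i for i in range(theta_hat.size) if i != j]
    cache: dict = {}  # profiled value -> optimal free parameters

    def profile(vj):
        def inner(sub):
            full = theta_hat.copy()
            full[j] = vj
            full[free] = sub
            return nll(full)

        starts = [theta_hat[free]]
        if cache:
            nearest = min(cache, key=lambda v: abs(v - vj))
            starts.append(cache[nearest])
        best = None
        for s0 in starts:
            res = minimize(inner, s0, method="Nelder-Mead",
                           options={"fatol": 1e-9, "xatol": 1e-6, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        cache[vj] = best.x
        return best.fun

    def crossing(direction):
        step = 0.05
        lo = theta_hat[j]
        for _ in range(60):
            hi = lo + direction * step
            if 2 * (profile(hi) - nll_min) >= z2:
                a, b = sorted((lo, hi))
                return brentq(lambda v: 2 * (profile(v) - nll_min) - z2, a, b, xtol=1e-5)
            lo = hi
            step *= 1.6
        raise DegenerateDataError(f"profile likelihood for parameter {j} does not close")

    return crossing(-1.0), crossing(+1.0)


_PARAM_NAMES = ("td50", "m", "n")


def lkb_confint(
    fit: LKBFitResult,
    dose_data,
    outcomes,
    method: str = "profile",
    parameters=_PARAM_NAMES,
    h: float = 1e-4,
) -> dict:
    """Per-parameter 95% CIs for an LKB fit, on the original scale.

    ``method="profile"`` (default) inverts the likelihood-ratio statistic
    parameter by parameter; it tracks the strongly curved (TD50, n) ridge
    of the LKB likelihood, where the quadratic (Wald) approximation is
    known to be too narrow.  ``method="wald"`` uses the inverse observed
    information on the log scale (fast; falls back to profile when the
    Hessian is not positive definite).  ``parameters`` restricts which
    intervals are computed.
    """
    if isinstance(dose_data, tuple) and len(dose_data) == 2 and not isinstance(
        dose_data[0], (DoseSample, DVHCurve)
    ):
        centers, weights = dose_data
    else:
        centers, weights = cohort_dose_matrix(dose_data)
    y = np.asarray(outcomes, int)
    nll = _neg_loglik_factory(centers, weights, y)
    theta = np.log([fit.params.td50, fit.params.m, fit.params.n])
    if method == "wald":
        H = _numerical_hessian(nll, theta, h)
        eig = np.linalg.eigvalsh(H)
        if np.all(eig > 0):
            se = np.sqrt(np.diag(np.linalg.inv(H)))
            return {
                name: (float(np.exp(theta[i] - 1.96 * se[i])),
                       float(np.exp(theta[i] + 1.96 * se[i])))
                for i, name in enumerate(_PARAM_NAMES)
                if name in parameters
            }
        method = "profile"  # non-PD observed information: fall back
    if method != "profile":
        raise ConfigurationError(f"method: unknown CI method {method!r}")
    nll_min = nll(theta)
    ci = {}
    for i, name in enumerate(_PARAM_NAMES):
        if name not in parameters:
            continue
        try:
            lo, hi = _profile_ci(nll, theta, i, nll_min)
        except DegenerateDataError as exc:
            raise DegenerateDataError(
                f"cannot compute a confidence interval for {name}: {exc}"
            ) from None
        ci[name] = (float(np.exp(lo)), float(np.exp(hi)))
    return ci


def fit_lkb_partial(
    doses_list,
    outcomes,
    covariate,
    covariate_name: str = "x",
    init_grid=None,
    bin_width: float | None = 0.25,
    fatol: float = 1e-8,
    maxiter: int = 3000,
) -> PartialLKBResult:
    """LKB fit with one dose-modifying covariate: TD50_i = TD50 * exp(delta x_i).

    The modifier delta is fitted jointly with (TD50, m, n).  A constant
    covariate leaves delta unidentifiable: the result falls back to the
    base fit with ``degenerate_covariate`` set.
    """
    y = _check_outcomes(outcomes)
    x = np.asarray(covariate, float)
    if x.size != y.size:
        raise ConfigurationError("covariate: length mismatch with outcomes")
    if np.ptp(x) == 0:
        base = fit_lkb(doses_list, y, init_grid, bin_width, fatol, maxiter)
        return PartialLKBResult(
            params=base.params, delta=0.0, delta_ci=None,
            covariate=covariate_name, ci95=base.ci95, loglik=base.loglik,
            converged=False, degenerate_covariate=True,
        )
    centers, weights = cohort_dose_matrix(doses_list, bin_width)
    nll = _neg_loglik_factory(centers, weights, y, x=x)
    base = fit_lkb(doses_list, y, init_grid, bin_width, fatol, maxiter, compute_ci=False)
    p0 = np.log([base.params.td50, base.params.m, base.params.n])
    scale = max(abs(np.ptp(x)), 1.0)
    best, best_val, any_success = None, np.inf, False
    for d0 in (-0.1 / scale, 0.0, 0.1 / scale):
        theta0 = np.append(p0, d0)
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"fatol": fatol, "xatol": 1e-7, "maxiter": maxiter})
        if res.fun < best_val:
            best_val, best = res.fun, res.x
            any_success = res.success
    td50, m, n = np.exp(best[:3])
    params = LKBParams(td50, m, n)
    delta = float(best[3])
    converged = any_success and not _is_flagged(params, -best_val)
    delta_ci = None
    ci95 = None
    if converged:
        H = _numerical_hessian(nll, best)
        try:
            eig = np.linalg.eigvalsh(H)
            if np.any(eig <= 0):
                raise np.linalg.LinAlgError
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            delta_ci = (delta - 1.96 * se[3], delta + 1.96 * se[3])
            ci95 = {
                name: (float(np.exp(best[i] - 1.96 * se[i])),
                       float(np.exp(best[i] + 1.96 * se[i])))
                for i, name in enumerate(_PARAM_NAMES)
            }
        except np.linalg.LinAlgError:
            nll_min = best_val
            lo, hi = _profile_ci(nll, best, 3, nll_min)
            delta_ci = (lo, hi)
    return PartialLKBResult(
        params=params, delta=delta, delta_ci=delta_ci, covariate=covariate_name,
        ci95=ci95, loglik=-best_val, converged=converged,
    )


def apply_fixed_lkb(doses_list, params: LKBParams) -> tuple:
    """Evaluate a fixed published LKB parameter set on a cohort.

    Returns (per-patient NTCP array, mean predicted incidence).  Scores are
    deterministic and directly usable for ROC analysis.
    """
    g = np.array([geud(d, params.n) for d in doses_list])
    ntcp = lkb_ntcp(g, params)
    return ntcp, float(ntcp.mean())
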