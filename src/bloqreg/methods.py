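"""Methods for handling values below a lower limit of quantification.

Eight approaches behind one uniform interface (:func:`fit_method`):

==================  ===========================================  ============
tag                 completion / estimation rule                 BLOQ role
==================  ===========================================  ============
``discard``         drop censored rows, ordinary least squares   both
``sub_zero``        substitute 0                                 both
``sub_lloq``        substitute LLOQ                              both
``sub_half``        substitute LLOQ/2 (uniform-below assumption) both
``sub_sqrt2``       substitute LLOQ/sqrt(2) (triangular shape)   both
``tobit``           left-censored gaussian maximum likelihood    dependent
``knn``             mean of k nearest uncensored donors,         both
                    truncated at LLOQ
``kde``             iterative kernel-density conditional mean    both
                    E(X | X < LLOQ), one value for all slots
``two_compartment`` split into below-limit indicator + observed  independent
                    continuous part, both entered as regressors
==================  ===========================================  ============

All OLS-type fits report t-based 95% confidence intervals; the tobit fit
reports Wald (normal-quantile) intervals with standard errors from the
numerically evaluated observed information matrix.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.tools.numdiff import approx_hess

from .censoring import CensoredVector, apply_lloq

__all__ = [
    "MethodError",
    "KDEConvergenceError",
    "ModelFormula",
    "FitResult",
    "METHOD_TAGS",
    "APPLICABILITY",
    "applicable_methods",
    "substitute",
    "fit_discard",
    "tobit_loglik",
    "fit_tobit",
    "impute_knn",
    "impute_kde",
    "two_compartment_design",
    "complete",
    "fit_method",
]

_Z975 = float(stats.norm.ppf(0.975))

SUBSTITUTION_RULES = ("zero", "lloq", "half", "sqrt2")

METHOD_TAGS = (
    "discard",
    "sub_zero",
    "sub_lloq",
    "sub_half",
    "sub_sqrt2",
    "tobit",
    "knn",
    "kde",
    "two_compartment",
)

#: Which BLOQ-variable role each method supports. Tobit needs the censored
#: variable on the left-hand side (its likelihood censors the outcome); the
#: two-compartment split only makes sense for a regressor.
APPLICABILITY = {
    "discard": ("independent", "dependent"),
    "sub_zero": ("independent", "dependent"),
    "sub_lloq": ("independent", "dependent"),
    "sub_half": ("independent", "dependent"),
    "sub_sqrt2": ("independent", "dependent"),
    "tobit": ("dependent",),
    "knn": ("independent", "dependent"),
    "kde": ("independent", "dependent"),
    "two_compartment": ("independent",),
}


class MethodError(ValueError):
    """A BLOQ method could not be applied (role mismatch, degenerate data...)."""


class KDEConvergenceError(MethodError):
    """Iterative KDE imputation failed to converge; carries the iterate trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def applicable_methods(role: str) -> tuple[str, ...]:
    return tuple(m for m in METHOD_TAGS if role in APPLICABILITY[m])


@dataclasses.dataclass(frozen=True)
class ModelFormula:
    """Additive linear-model formula: a response and main-effect terms.

    Only ``y ~ a + b + c`` style formulas are supported — every term is a
    column name entering linearly, plus an implicit intercept. This restricted
    grammar is all the method comparison needs and keeps the per-fit cost low.
    """

    response: str
    terms: tuple[str, ...]

    @classmethod
    def parse(cls, s: str) -> "ModelFormula":
        if "~" not in s:
            raise MethodError(f"formula {s!r} must contain '~'")
        lhs, rhs = s.split("~", 1)
        response = lhs.strip()
        terms = tuple(t.strip() for t in rhs.split("+") if t.strip())
        if not response or not terms:
            raise MethodError(f"formula {s!r} needs a response and >=1 term")
        return cls(response=response, terms=terms)

    def __str__(self) -> str:
        return f"{self.response} ~ {' + '.join(self.terms)}"


@dataclasses.dataclass
class FitResult:
    """Uniform fit output: coefficients, uncertainty, and provenance."""

    coef: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    sigma_hat: float
    n_used: int
    converged: bool
    method: str
    message: str | None = None
    completion: dict | None = dataclasses.field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def _as_formula(formula) -> ModelFormula:
    return formula if isinstance(formula, ModelFormula) else ModelFormula.parse(formula)


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        if t not in data.columns:
            raise MethodError(f"term {t!r} not found in data")
        X[t] = data[t].to_numpy(dtype=float)
    return X

def _ols_fitresult(
    y: np.ndarray, X: pd.DataFrame, method: str, completion: dict | None = None
) -> FitResult:
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = res.conf_int(alpha=0.05)
    return FitResult(
        coef=res.params,
        se=res.bse,
        ci_lower=ci[0],
        ci_upper=ci[1],
        sigma_hat=float(np.sqrt(res.scale)),
        n_used=int(res.nobs),
        converged=True,
        method=method,
        completion=completion,
    )


# -- substitution -------------------------------------------------------------

def substitute(cv: CensoredVector, rule: str) -> np.ndarray:
    """Replace censored slots by a fixed constant.

    ``zero`` -> 0, ``lloq`` -> LLOQ, ``half`` -> LLOQ/2 (implicit uniform
    distribution below the limit), ``sqrt2`` -> LLOQ/sqrt(2) (the point
    splitting the mass of a triangular density on (0, LLOQ) in half).
    """
    if rule not in SUBSTITUTION_RULES:
        raise MethodError(f"unknown substitution rule {rule!r}")
    const = {
        "zero": 0.0,
        "lloq": cv.lloq,
        "half": cv.lloq / 2.0,
        "sqrt2": cv.lloq / np.sqrt(2.0),
    }[rule]
    out = cv.values.copy()
    out[cv.censored] = const
    return out


# -- discard ------------------------------------------------------------------

def fit_discard(
    data: pd.DataFrame, formula, censored: np.ndarray
) -> FitResult:
    """OLS on the uncensored subset only."""
    formula = _as_formula(formula)
    censored = np.asarray(censored, dtype=bool)
    keep = data.loc[~censored]
    p = len(formula.terms) + 1
    if len(keep) < p + 2:
        raise MethodError(
            f"insufficient data: {len(keep)} uncensored rows for {p} coefficients"
        )
    X = _design(keep, formula.terms)
    fr = _ols_fitresult(
        keep[formula.response].to_numpy(dtype=float), X, "discard",
        completion={"rule": "discard"},
    )
    return fr


# -- tobit --------------------------------------------------------------------

def tobit_loglik(
    beta: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    censored: np.ndarray,
    lloq: float,
) -> float:
    """Left-censored gaussian log-likelihood.

    Uncensored rows contribute the normal density of the residual; censored
    rows contribute ``log Phi((c - x'beta)/sigma)`` with ``c`` the LLOQ.
    """
    xb = X @ np.asarray(beta, dtype=float)
    r = (y[~censored] - xb[~censored]) / sigma
    ll = float(np.sum(stats.norm.logpdf(r) - np.log(sigma)))
    if censored.any():
        z = (lloq - xb[censored]) / sigma
        ll += float(np.sum(stats.norm.logcdf(z)))
    return ll


def _tobit_nll_grad(theta, y, Xm, cens, lloq):
    beta, logs = theta[:-1], theta[-1]
    s = np.exp(logs)
    xb = Xm @ beta
    r = (y - xb) / s
    ru = r[~cens]
    nll = 0.5 * float(ru @ ru) + (~cens).sum() * (logs + 0.5 * np.log(2 * np.pi))
    g_beta = -(Xm[~cens].T @ ru) / s
    g_logs = (~cens).sum() - float(ru @ ru)
    if cens.any():
        z = (lloq - xb[cens]) / s
        logphi = stats.norm.logpdf(z)
        logPhi = stats.norm.logcdf(z)
        nll -= float(np.sum(logPhi))
        lam = np.exp(logphi - logPhi)  # inverse Mills ratio, stable in the tail
        g_beta += (Xm[cens].T @ lam) / s
        g_logs += float(lam @ z)
    return nll, np.append(g_beta, g_logs)


def fit_tobit(y: CensoredVector, X: pd.DataFrame) -> FitResult:
    """Maximum-likelihood tobit fit of a left-censored outcome.

    Optimised over (beta, log sigma) so the scale stays positive; started at
    the OLS fit with censored outcomes held at the sentinel LLOQ. Standard
    errors come from the inverse of the numerically evaluated Hessian of the
    negative log-likelihood at the optimum; intervals are Wald.
    """
    if "Intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "Intercept", 1.0)
    cens = y.censored
    if cens.all():
        raise MethodError("likelihood unidentified: all observations censored")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise MethodError("design matrix is rank deficient")
    yv = y.values
    beta0, *_ = np.linalg.lstsq(Xm, yv, rcond=None)
    resid = yv - Xm @ beta0
    s0 = max(float(np.std(resid)), 1e-3)
    theta0 = np.append(beta0, np.log(s0))

    res = optimize.minimize(
        _tobit_nll_grad,
        theta0,
        args=(yv, Xm, cens, y.lloq),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 1000},
    )
    theta = res.x
    beta, sigma = theta[:-1], float(np.exp(theta[-1]))

    def nll_only(t):
        return _tobit_nll_grad(t, yv, Xm, cens, y.lloq)[0]

    # BFGS can stop on "precision loss" with the gradient already tiny;
    # accept any stationary point with a near-zero scaled gradient.
    gscale = 1.0 + abs(float(res.fun))
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-5 * gscale
    message = None if converged else f"optimizer: {res.message}"
    k = len(beta)
    se = np.full(k, np.nan)
    try:
        H = approx_hess(theta, nll_only)
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:k]
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(d)
    except np.linalg.LinAlgError as exc:  # keep the fit, flag the uncertainty
        converged = False
        message = (message or "") + f" information matrix not invertible ({exc})"

    coef = pd.Series(beta, index=names)
    se = pd.Series(se, index=names)
    return FitResult(
        coef=coef,
        se=se,
        ci_lower=coef - _Z975 * se,
        ci_upper=coef + _Z975 * se,
        sigma_hat=sigma,
        n_used=len(y),
        converged=converged,
        method="tobit",
        message=message,
    )


# -- k nearest neighbours -----------------------------------------------------

def impute_knn(
    covariates: pd.DataFrame,
    cv: CensoredVector,
    k: int = 5,
    *,
    truncate_at_lloq: bool = False,
) -> np.ndarray:
    """Impute censored slots with the mean of the k nearest uncensored donors.

    Distance is Euclidean on z-scored covariates (standardised over the full
    table); ties are broken by row order. The donor average is imputed
    directly by default. Because uncensored donors always lie above the
    detection limit, forcing the imputed value below it
    (``truncate_at_lloq=True``, i.e. ``min(average, lloq)``) collapses kNN to
    plain LLOQ substitution whenever the flags come from thresholding, so
    truncation is off by default.
    """
    if len(covariates) != len(cv):
        raise MethodError("covariates and censored vector length mismatch")
    donors = ~cv.censored
    n_donors = int(donors.sum())
    if n_donors == 0:
        raise MethodError("no donors: every row is censored")
    out = cv.values.copy()
    if not cv.censored.any():
        return out
    Z = covariates.to_numpy(dtype=float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    if not np.all(np.isfinite(Z)):
        raise MethodError("distance covariates must be finite")
    k_eff = min(k, n_donors)
    if k_eff < k:
        warnings.warn(
            f"only {n_donors} donors available, using all of them (k={k})",
            stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=k_eff).fit(Z[donors])
    _, idx = nn.kneighbors(Z[cv.censored])
    donor_vals = cv.values[donors]
    imputed = donor_vals[idx].mean(axis=1)
    if truncate_at_lloq:
        imputed = np.minimum(imputed, cv.lloq)
    out[cv.censored] = imputed
    return out


# -- kernel density imputation ------------------------------------------------

def impute_kde(
    cv: CensoredVector,
    eps_tol: float = 1e-5,
    max_iter: int = 500,
    *,
    bandwidth_exponent: float = -0.2,
    grid_size: int = 2048,
    augment: str = "refit",
    full_output: bool = False,
):
    """Iterative kernel-density estimate of E(X | X < LLOQ).

    A Gaussian-kernel density with Silverman bandwidth
    ``h = 1.06 * sd(observed) * m**bandwidth_exponent`` (m = number of values
    above the limit) is estimated from the observed values; the conditional
    mean below the limit, ``k_j``, is computed by trapezoid integration on a
    fixed grid of ``grid_size`` points spanning
    ``(max(0, min(observed) - 3h), lloq]``. The censored slots are then filled
    with ``k_j`` — ``augment='refit'`` re-estimates the density from the m
    observed values plus one copy of the current iterate per censored slot;
    ``augment='append'`` instead appends a single copy of each past iterate —
    and the process repeats until ``|k_j - k_{j-1}| < eps_tol``. The final
    iterate, a single value strictly below the limit, is imputed into every
    censored slot.
    """
    unc = cv.uncensored_values
    m = len(unc)
    n_cens = cv.n_censored
    if m < 2:
        raise MethodError("KDE needs at least 2 uncensored values for a bandwidth")
    if n_cens < 1:
        raise MethodError("no censored values to impute")
    if augment not in ("refit", "append"):
        raise MethodError(f"unknown augment scheme {augment!r}")
    sd = float(np.std(unc, ddof=1))
    if sd == 0:
        raise MethodError("degenerate uncensored sample (zero variance)")
    h = 1.06 * sd * m ** bandwidth_exponent
    lo = max(0.0, float(unc.min()) - 3.0 * h)
    if lo >= cv.lloq:
        raise MethodError("no mass below LLOQ: integration interval is empty")
    grid = np.linspace(lo, cv.lloq, grid_size)
    # kernel sums; normalisation constants cancel in the conditional mean
    base = np.exp(-0.5 * ((grid[:, None] - unc[None, :]) / h) ** 2).sum(axis=1)

    def cond_mean(dens: np.ndarray) -> float:
        mass = np.trapezoid(dens, grid)
        if not np.isfinite(mass) or mass <= 0:
            raise MethodError("no mass below LLOQ on the integration grid")
        return float(np.trapezoid(grid * dens, grid) / mass)

    k_prev = cond_mean(base)
    trace = [k_prev]
    past: list[float] = []
    for _ in range(max_iter):
        past.append(k_prev)
        if augment == "refit":
            extra = n_cens * np.exp(-0.5 * ((grid - k_prev) / h) ** 2)
        else:
            extra = np.exp(
                -0.5 * ((grid[:, None] - np.asarray(past)[None, :]) / h) ** 2
            ).sum(axis=1)
        k = cond_mean(base + extra)
        trace.append(k)
        if abs(k - k_prev) < eps_tol:
            return (k, trace) if full_output else k
        k_prev = k
    raise KDEConvergenceError(
        f"KDE imputation did not converge in {max_iter} iterations", trace
    )


# -- two compartment ----------------------------------------------------------

def two_compartment_design(
    cv: CensoredVector, fill: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split a left-censored covariate into indicator + continuous parts.

    ``x_bin`` is 1 for below-limit rows, 0 otherwise; ``x_cont`` carries the
    observed value for uncensored rows and ``fill`` (any constant in
    ``[0, lloq]``; the continuous-part coefficient is invariant to it when
    the indicator is in the model) for censored ones.
    """
    if not 0.0 <= fill <= cv.lloq:
        raise MethodError(f"invalid fill {fill}: must lie in [0, {cv.lloq}]")
    x_bin = cv.censored.astype(float)
    x_cont = np.where(cv.censored, fill, cv.values)
    return x_bin, x_cont


# -- uniform interface --------------------------------------------------------

def _get_cv(data: pd.DataFrame, bloq_var: str, lloq: float) -> CensoredVector:
    flag_col = f"{bloq_var}_censored"
    values = data[bloq_var].to_numpy(dtype=float)
    if flag_col in data.columns:
        return CensoredVector(values, data[flag_col].to_numpy(dtype=bool), lloq)
    return apply_lloq(values, lloq)


def complete(
    data: pd.DataFrame,
    bloq_var: str,
    lloq: float,
    method: str,
    role: str = "independent",
    formula=None,
    *,
    k: int = 5,
    knn_truncate: bool = False,
    fill: float = 0.0,
    kde_options: dict | None = None,
) -> pd.DataFrame:
    """Return a completed copy of ``data`` with an ``imputed_by`` column.

    ``discard`` drops censored rows; substitution/kNN/KDE overwrite the
    censored slots of ``bloq_var``; ``two_compartment`` adds the
    ``<var>_bin``/``<var>_cont`` columns. Tobit defines no completion.
    """
    _check_role(method, role)
    cv = _get_cv(data, bloq_var, lloq)
    out = data.copy()
    if method == "discard":
        out = out.loc[~cv.censored].copy()
        out["imputed_by"] = "discard"
        return out
    if method == "tobit":
        raise MethodError("tobit is a direct fit and defines no completed dataset")
    if method.startswith("sub_"):
        out[bloq_var] = substitute(cv, method.removeprefix("sub_"))
    elif method == "knn":
        cov_cols = _distance_columns(data, bloq_var, role, formula)
        out[bloq_var] = impute_knn(
            data[cov_cols], cv, k=k, truncate_at_lloq=knn_truncate
        )
    elif method == "kde":
        kval = impute_kde(cv, **(kde_options or {}))
        vals = cv.values.copy()
        vals[cv.censored] = kval
        out[bloq_var] = vals
    elif method == "two_compartment":
        x_bin, x_cont = two_compartment_design(cv, fill=fill)
        out[f"{bloq_var}_bin"] = x_bin
        out[f"{bloq_var}_cont"] = x_cont
    out["imputed_by"] = method
    return out


def _check_role(method: str, role: str) -> None:
    if method not in APPLICABILITY:
        raise MethodError(f"unknown method {method!r}")
    if role not in ("independent", "dependent"):
        raise MethodError(f"unknown role {role!r}")
    if role not in APPLICABILITY[method]:
        raise MethodError(
            f"method/role mismatch: {method!r} is only applicable when the "
            f"BLOQ variable is {' or '.join(APPLICABILITY[method])}"
        )


def _distance_columns(data, bloq_var, role, formula) -> list[str]:
    """Covariates used for kNN distances: all observed independent variables."""
    if formula is not None:
        formula = _as_formula(formula)
        cols = [t for t in formula.terms if t != bloq_var]
        if role == "dependent":
            cols = list(formula.terms)
        return cols
    drop = {bloq_var, f"{bloq_var}_censored", "imputed_by"}
    return [c for c in data.columns if c not in drop]


def fit_method(
    data: pd.DataFrame,
    bloq_var: str,
    lloq: float,
    role: str,
    method: str,
    formula,
    *,
    k: int = 5,
    knn_truncate: bool = False,
    fill: float = 0.0,
    kde_options: dict | None = None,
) -> FitResult:
    """Apply one BLOQ-handling method and fit the linear model.

    Imputation-style methods complete the data and fit OLS; ``discard`` fits
    OLS on the uncensored subset; ``tobit`` maximises the censored likelihood
    directly. The method/role applicability matrix is enforced up front.
    """
    _check_role(method, role)
    formula = _as_formula(formula)
    if role == "independent" and bloq_var not in formula.terms:
        raise MethodError(f"BLOQ variable {bloq_var!r} not among formula terms")
    if role == "dependent" and bloq_var != formula.response:
        raise MethodError(f"BLOQ variable {bloq_var!r} is not the response")
    cv = _get_cv(data, bloq_var, lloq)

    if method == "discard":
        return fit_discard(data, formula, cv.censored)

    if method == "tobit":
        X = _design(data, formula.terms)
        return fit_tobit(cv, X)

    if method == "two_compartment":
        x_bin, x_cont = two_compartment_design(cv, fill=fill)
        work = data.copy()
        work[f"{bloq_var}_bin"] = x_bin
        work[f"{bloq_var}_cont"] = x_cont
        terms = tuple(
            t if t != bloq_var else f"{bloq_var}_cont" for t in formula.terms
        )
        bin_dropped = not cv.censored.any()  # constant column would be collinear
        if not bin_dropped:
            terms = terms + (f"{bloq_var}_bin",)
        X = _design(work, terms)
        return _ols_fitresult(
            work[formula.response].to_numpy(dtype=float),
            X,
            "two_compartment",
            completion={
                "rule": "two_compartment",
                "fill": fill,
                "bin_dropped": bin_dropped,
            },
        )

    # substitution / knn / kde: complete then OLS
    if method.startswith("sub_"):
        vals = substitute(cv, method.removeprefix("sub_"))
        const = {
            "sub_zero": 0.0,
            "sub_lloq": cv.lloq,
            "sub_half": cv.lloq / 2.0,
            "sub_sqrt2": cv.lloq / np.sqrt(2.0),
        }[method]
        completion = {"rule": "constant", "value": const}
    elif method == "kde":
        kval = impute_kde(cv, **(kde_options or {}))
        vals = cv.values.copy()
        vals[cv.censored] = kval
        completion = {"rule": "constant", "value": kval}
    else:  # knn
        cov_cols = _distance_columns(data, bloq_var, role, formula)
        Zraw = data[cov_cols].to_numpy(dtype=float)
        mu = Zraw.mean(axis=0)
        sd = Zraw.std(axis=0)
        sd[sd == 0] = 1.0
        vals = impute_knn(data[cov_cols], cv, k=k, truncate_at_lloq=knn_truncate)
        donors = ~cv.censored
        completion = {
            "rule": "knn",
            "k": k,
            "truncate": knn_truncate,
            "columns": cov_cols,
            "means": mu,
            "stds": sd,
            "donor_Z": (Zraw[donors] - mu) / sd,
            "donor_values": cv.values[donors],
        }

    work = data.copy()
    work[bloq_var] = vals
    X = _design(work, formula.terms)
    return _ols_fitresult(
        work[formula.response].to_numpy(dtype=float),
        X,
        method,
        completion=completion,
    )
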