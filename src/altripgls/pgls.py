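"""Generalized least squares under a phylogenetic covariance structure.

The model is y = X beta + e with e ~ N(0, sigma^2 V), V = C(lambda) the
Brownian-motion covariance of the tree with its off-diagonal scaled by
Pagel's lambda.  ``fit_gls`` fits at a fixed covariance; ``profile_lambda``
maximizes the profile likelihood of lambda on [0, 1].

Two error-variance scales are carried: the ML scale e'V^-1 e / n enters the
log-likelihood, while standard errors, t statistics and residual
standardization use the unbiased e'V^-1 e / (n - p), matching conventional
PGLS software (t tests on n - p degrees of freedom).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

from .tree import VCVMatrix, lambda_transform

__all__ = [
    "DesignMatrix",
    "PGLSFit",
    "PGLSError",
    "design_matrix",
    "fit_gls",
    "profile_lambda",
    "standardized_residuals",
    "studentized_phylo_residuals",
    "diagnostic_qq_and_fit_data",
]

#: flag threshold for studentized phylogenetic residuals
OUTLIER_THRESHOLD = 3.0

#: profile-likelihood grid step for the lambda pre-scan
LAMBDA_GRID_STEP = 0.01


class PGLSError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Predictor matrix with named columns, rows aligned to species_order."""

    species_order: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.species_order), len(self.columns)):
            raise ValueError("design shape does not match labels")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise PGLSError("design matrix is rank deficient")


def design_matrix(species_order, **predictors) -> DesignMatrix:
    """Build an intercept-plus-slopes design from named predictor vectors."""
    cols = ["intercept"] + list(predictors)
    n = len(species_order)
    vals = np.column_stack(
        [np.ones(n)] + [np.asarray(v, dtype=float) for v in predictors.values()]
    )
    return DesignMatrix(list(species_order), cols, vals)


@dataclass
class PGLSFit:
    """Complete result of one GLS fit."""

    species_order: list[str]
    terms: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    df_resid: int
    sigma2_ml: float
    sigma2_resid: float
    lambda_hat: float
    log_lik: float
    r2: float
    r2_adj: float
    resid_raw: np.ndarray
    resid_std: np.ndarray = field(repr=False, default=None)
    resid_phylo_student: np.ndarray = field(repr=False, default=None)
    outlier_flags: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.species_order)

    # -- serialization -----------------------------------------------------
    def coef_table_tsv(self) -> str:
        rows = ["term\testimate\tse\tt\tdf\tp"]
        for i, term in enumerate(self.terms):
            rows.append(
                f"{term}\t{self.coefficients[i]!r}\t{self.std_errors[i]!r}"
                f"\t{self.t_values[i]!r}\t{self.df_resid}\t{self.p_values[i]!r}"
            )
        return "\n".join(rows) + "\n"

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coefficients": list(self.coefficients),
            "std_errors": list(self.std_errors),
            "t_values": list(self.t_values),
            "p_values": list(self.p_values),
            "df_resid": self.df_resid,
            "sigma2_ml": self.sigma2_ml,
            "sigma2_resid": self.sigma2_resid,
            "lambda_hat": self.lambda_hat,
            "log_lik": self.log_lik,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "species": self.species_order,
            "resid_raw": list(self.resid_raw),
            "resid_std": list(self.resid_std),
            "resid_phylo_student": list(self.resid_phylo_student),
            "fitted": list(self.fitted),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------

def _check_alignment(y, X: DesignMatrix, C: VCVMatrix):
    y = np.asarray(y, dtype=float)
    if X.species_order != C.species_order:
        raise PGLSError("design and covariance species orders differ")
    if len(y) != len(X.species_order):
        raise PGLSError("response length does not match species order")
    if len(y) <= X.values.shape[1]:
        raise PGLSError("need n > p observations")
    return y


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Cholesky-based GLS solve; returns (beta, resid, s2_ml, log_lik, XtViX)."""
    n = len(y)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise PGLSError(
            "covariance matrix is singular; jitter terminal branches or prune "
            "duplicate tips"
        ) from exc
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    e = y - X @ beta
    s2_ml = float(e @ cho_solve(cf, e)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if s2_ml > 0:
        log_lik = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
    else:
        log_lik = np.inf  # perfect fit; likelihood degenerates
    return beta, e, s2_ml, log_lik, XtViX, cf


def fit_gls(y, X: DesignMatrix, C: VCVMatrix, *, _lambda_hat: float = 1.0) -> PGLSFit:
    """GLS fit of y on X with error covariance proportional to ``C.values``.

    With ``C`` the identity this reduces exactly to ordinary least squares.
    ``_lambda_hat`` only annotates the returned fit; the covariance is used
    as given.
    """
    y = _check_alignment(y, X, C)
    n, p = X.values.shape
    V = C.values
    beta, e, s2_ml, log_lik, XtViX, cf = _gls_core(y, X.values, V)
    df = n - p
    s2_resid = s2_ml * n / df

    cov_beta = np.linalg.inv(XtViX) * s2_resid
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)

    # GLS R^2 against the phylogenetic-mean-only model under the same V
    ones = np.ones((n, 1))
    mu = float(_gls_core(y, ones, V)[0][0])
    dev = y - mu
    sse = float(e @ cho_solve(cf, e))
    sst = float(dev @ cho_solve(cf, dev))
    if sst <= 0:
        raise PGLSError("zero total GLS sum of squares; R^2 undefined")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df

    fit = PGLSFit(
        species_order=list(X.species_order),
        terms=list(X.columns),
        coefficients=beta,
        std_errors=se,
        t_values=t,
        p_values=pvals,
        df_resid=df,
        sigma2_ml=s2_ml,
        sigma2_resid=s2_resid,
        lambda_hat=float(_lambda_hat),
        log_lik=log_lik,
        r2=r2,
        r2_adj=r2_adj,
        resid_raw=e,
        fitted=X.values @ beta,
    )
    fit.resid_std = standardized_residuals(fit, C)
    stud, flags = studentized_phylo_residuals(fit, C, X)
    fit.resid_phylo_student = stud
    fit.outlier_flags = flags
    return fit


def profile_lambda(y, X: DesignMatrix, C: VCVMatrix) -> PGLSFit:
    """ML estimate of Pagel's lambda with the fit evaluated at the optimum.

    The profile log-likelihood is pre-scanned on the grid {0, 0.01, ..., 0.99}
    and refined by bounded Brent search in the bracketing +/-0.01 window
    (clipped to [0, 1], so a profile rising monotonically into lambda = 1 still
    reaches the boundary).  The boundary point 1.0 is deliberately excluded
    from the pre-scan: trees with effectively duplicated tips (near-zero
    terminal branches) develop a narrow degenerate likelihood spike at
    lambda = 1 where C is near-singular, and chasing it would return a fit no
    standard comparative-methods optimizer reports.
    """
    y = _check_alignment(y, X, C)
    grid = np.arange(0.0, 1.0, LAMBDA_GRID_STEP)

    def nll(lam: float) -> float:
        V = lambda_transform(C, lam)
        ll = _gls_core(y, X.values, V.values)[3]
        if np.isnan(ll) or ll == -np.inf:
            raise PGLSError(f"non-finite profile likelihood at lambda={lam:.6f}")
        return -ll

    lls = np.array([-nll(l) for l in grid])
    if np.isposinf(lls).any():
        # perfect fit: likelihood degenerates, any lambda reproduces y exactly
        lam_hat = float(grid[int(np.argmax(np.isposinf(lls)))])
        return fit_gls(y, X, lambda_transform(C, lam_hat), _lambda_hat=lam_hat)
    i = int(np.argmax(lls))
    lo = max(grid[i] - LAMBDA_GRID_STEP, 0.0)
    hi = min(grid[i] + LAMBDA_GRID_STEP, 1.0)
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    lam_hat = float(res.x) if -res.fun >= lls[i] else float(grid[i])
    return fit_gls(y, X, lambda_transform(C, lam_hat), _lambda_hat=lam_hat)


# ---------------------------------------------------------------------------
# Residual diagnostics

def standardized_residuals(fit: PGLSFit, C: VCVMatrix, mode: str = "tipvar") -> np.ndarray:
    """Standardize raw residuals for use as a derived trait.

    ``tipvar`` (default) divides by the model-implied tip standard deviation
    sqrt(sigma2_resid * C[i, i]); ``zscore`` divides by the sample SD of the
    raw residuals.  On an ultrametric tree (constant tip depth) the two are
    proportional, so downstream slopes rescale but t, p, R^2 and lambda-hat
    are unchanged.
    """
    e = fit.resid_raw
    if np.allclose(e, 0.0):
        return np.zeros_like(e)
    if mode == "tipvar":
        if fit.sigma2_resid <= 0:
            raise PGLSError("zero residual variance; standardization undefined")
        return e / np.sqrt(fit.sigma2_resid * np.diag(C.values))
    if mode == "zscore":
        sd = e.std(ddof=1)
        if sd <= 0:
            raise PGLSError("zero residual variance; standardization undefined")
        return e / sd
    raise ValueError(f"unknown standardization mode {mode!r}")


def studentized_phylo_residuals(
    fit: PGLSFit, C: VCVMatrix, X: DesignMatrix | None = None
):
    """Internally studentized residuals in the phylogenetically rotated frame.

    Residuals are rotated by the inverse lower Cholesky factor of the fitted
    covariance; leverages come from the equally rotated design.  With an
    identity covariance this is the classical internally studentized OLS
    residual.  Values with |r| >= 3 are flagged.
    """
    V = C.values
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise PGLSError("covariance matrix is not positive definite") from exc
    e_rot = solve_triangular(L, fit.resid_raw, lower=True)
    if X is None:
        raise PGLSError("design matrix required for leverage computation")
    Z = solve_triangular(L, X.values, lower=True)
    H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    s = np.sqrt(fit.sigma2_resid)
    scale = float(np.max(np.abs(fit.fitted))) if fit.fitted is not None else 1.0
    if s <= 1e-12 * max(scale, 1.0):  # numerically perfect fit
        stud = np.zeros_like(e_rot)
    else:
        stud = e_rot / (s * np.sqrt(1.0 - h))
    flags = np.abs(stud) >= OUTLIER_THRESHOLD
    return stud, flags


def diagnostic_qq_and_fit_data(fit: PGLSFit):
    """Numeric coordinates for the two standard residual diagnostic plots.

    Returns ``(qq, resid_vs_fitted)`` where ``qq`` pairs theoretical normal
    quantiles at (i - 0.5)/n with the ordered rotated (studentized)
    residuals, and ``resid_vs_fitted`` pairs fitted values with the rotated
    residuals.  Rendering is the caller's concern.
    """
    r = np.asarray(fit.resid_phylo_student, dtype=float)
    n = len(r)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    qq = np.column_stack([theo, np.sort(r)])
    rvf = np.column_stack([fit.fitted, r])
    return qq, rvf
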