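"""Random-intercept linear mixed models for family data.

Every regression in the pipeline is of the form

    y = X beta + u_family + e,     u_f ~ N(0, s2_u),  e ~ N(0, s2_e),

with one shared random intercept per family capturing relatedness-induced
correlation.  Estimation is restricted maximum likelihood (REML): the
criterion is profiled down to the single variance ratio lam = s2_u / s2_e,
for which the marginal covariance of a family of size n_f is
``s2_e (I + lam J)`` with closed-form inverse and determinant, so each
criterion evaluation costs O(F p^2) after one O(n p) pass.  The ratio is
located as the root of the criterion's analytic derivative (Brent, xtol
1e-12; variance floor 1e-10), which is deterministic and stable under
sample permutation.

Fixed effects get Wald z tests.  ``fitted_fixed`` deliberately excludes the
family BLUP so that downstream two-stage least squares does not leak
outcome-correlated family variance through the predicted exposure; the BLUP
is exposed separately as ``fitted_blup`` for models that must condition on
the full prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["LMMError", "LMMFit", "fit_lmm", "lmm_residualize",
           "profile_reml", "build_covariate_design"]

VAR_FLOOR = 1e-10
_P_FLOOR = 1e-300


class LMMError(ValueError):
    pass


def build_covariate_design(pheno: pd.DataFrame,
                           numeric: tuple[str, ...] = ("age",),
                           categorical: tuple[str, ...] = ("sex", "center", "smoking"),
                           ) -> pd.DataFrame:
    """Expand the standard covariate set (age, sex, center, smoking) into a
    numeric design with treatment-coded dummies (no intercept column)."""
    parts = [pheno[c].astype(float).rename(c) for c in numeric]
    for c in categorical:
        d = pd.get_dummies(pheno[c].astype("category"), prefix=c, drop_first=True)
        if d.shape[1]:
            parts.append(d.astype(float))
    out = pd.concat(parts, axis=1)
    out.index = pheno.index
    return out


@dataclass
class LMMFit:
    coef: dict[str, float]
    se: dict[str, float]
    pvalue: dict[str, float]
    var_family: float
    var_resid: float
    fitted_fixed: np.ndarray
    resid_marginal: np.ndarray
    fitted_blup: np.ndarray
    n: int
    loglik: float
    converged: bool
    terms: list[str]
    lambda_ratio: float

    def wald_f(self, term: str) -> float:
        """Squared Wald z for one term — the single-instrument F statistic."""
        return (self.coef[term] / self.se[term]) ** 2


def _as_design(fixed) -> pd.DataFrame:
    if isinstance(fixed, pd.DataFrame):
        X = fixed.astype(float).copy()
    elif isinstance(fixed, dict):
        X = pd.DataFrame({k: np.asarray(v, float) for k, v in fixed.items()})
    else:
        arr = np.atleast_2d(np.asarray(fixed, float))
        if arr.shape[0] == 1:
            arr = arr.T
        X = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    has_const = any(np.ptp(X[c].to_numpy()) == 0 and X[c].iloc[0] != 0 for c in X.columns)
    if not has_const:
        X.insert(0, "intercept", 1.0)
    return X


def _check_collinear(Xm: np.ndarray, names: list[str]) -> None:
    r, piv = linalg.qr(Xm, mode="r", pivoting=True)[0:2] if Xm.shape[1] > 1 else (None, None)
    if r is None:
        if np.ptp(Xm[:, 0]) == 0 and Xm[0, 0] == 0:
            raise LMMError("design column is identically zero")
        return
    d = np.abs(np.diag(r))
    tol = d.max() * max(Xm.shape) * np.finfo(float).eps
    rank = int((d > tol).sum())
    if rank < Xm.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise LMMError(f"singular fixed-effect design; collinear terms: {sorted(bad)}")


class _Prep:
    """Sufficient statistics for the profiled REML criterion."""

    def __init__(self, y: np.ndarray, Xm: np.ndarray, codes: np.ndarray, n_fam: int):
        self.y, self.Xm, self.codes, self.n_fam = y, Xm, codes, n_fam
        self.n, self.p = Xm.shape
        self.XtX = Xm.T @ Xm
        self.Xty = Xm.T @ y
        self.yty = float(y @ y)
        self.fam_n = np.bincount(codes, minlength=n_fam).astype(float)
        self.S = np.zeros((n_fam, self.p))
        np.add.at(self.S, codes, Xm)
        self.t = np.bincount(codes, weights=y, minlength=n_fam)

    def solve(self, lam: float):
        """Return (neg2reml, beta, cov_unscaled, sigma2_e, logdet_terms)."""
        c = lam / (1.0 + lam * self.fam_n)
        A = self.XtX - (self.S * c[:, None]).T @ self.S
        b = self.Xty - self.S.T @ (c * self.t)
        q = self.yty - float(c @ (self.t * self.t))
        try:
            cf = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as exc:
            raise LMMError(f"normal equations not positive definite: {exc}") from exc
        beta = linalg.cho_solve(cf, b)
        rss = max(q - float(beta @ b), 0.0)
        dof = self.n - self.p
        sigma2 = max(rss / dof, VAR_FLOOR)
        logdet_sigma = float(np.log1p(lam * self.fam_n).sum())
        logdet_A = 2.0 * float(np.log(np.diag(cf[0])).sum())
        crit = dof * np.log(sigma2) + logdet_sigma + logdet_A + rss / sigma2
        Ainv = linalg.cho_solve(cf, np.eye(self.p))
        return crit, beta, Ainv, sigma2

    def dcrit(self, lam: float) -> float:
        """Analytic d(criterion)/d(lam) — the optimum is its root."""
        c = lam / (1.0 + lam * self.fam_n)
        cp = 1.0 / (1.0 + lam * self.fam_n) ** 2        # dc/dlam
        A = self.XtX - (self.S * c[:, None]).T @ self.S
        b = self.Xty - self.S.T @ (c * self.t)
        q = self.yty - float(c @ (self.t * self.t))
        cf = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cf, b)
        rss = max(q - float(beta @ b), VAR_FLOOR)
        qp = -float(cp @ (self.t * self.t))
        bp = -self.S.T @ (cp * self.t)
        sb = self.S @ beta
        rss_p = qp - 2.0 * float(bp @ beta) - float(cp @ (sb * sb))
        T = linalg.cho_solve(cf, self.S.T).T             # F x p
        tr = -float(cp @ (T * self.S).sum(axis=1))       # tr(A^-1 dA/dlam)
        dlogdet_sigma = float((self.fam_n / (1.0 + lam * self.fam_n)).sum())
        return (self.n - self.p) * rss_p / rss + dlogdet_sigma + tr


_LAM_MAX = 1e8


def _optimize_lambda(prep: _Prep) -> tuple[float, bool]:
    """Locate the REML optimum as the root of the analytic criterion
    derivative (bisection bracket + Brent), which pins the variance ratio to
    near machine precision and makes the fit reproducible under sample
    permutation and covariate rescaling."""
    d0 = prep.dcrit(0.0)
    if d0 >= 0:                       # criterion increasing at the boundary
        return 0.0, True
    lo, hi = 0.0, 1.0
    dhi = prep.dcrit(hi)
    while dhi < 0 and hi < _LAM_MAX:
        lo, hi = hi, hi * 8.0
        dhi = prep.dcrit(hi)
    if dhi < 0:                       # variance ratio effectively unbounded
        return _LAM_MAX, False
    lam = optimize.brentq(prep.dcrit, lo, hi, xtol=1e-12, maxiter=200)
    return float(lam), True


def fit_lmm(y, fixed, family_ids, lambda_fixed: float | None = None) -> LMMFit:
    """REML fit of ``y ~ fixed`` with one random intercept per family.

    Parameters
    ----------
    y : response vector (no missing values).
    fixed : named design — DataFrame, dict of vectors, or array.  An
        intercept column is prepended unless a constant column is present.
    family_ids : per-sample family labels; at least two distinct families.
    lambda_fixed : optionally pin the variance ratio s2_u/s2_e instead of
        estimating it (``0`` constrains the model to independent errors,
        making the fit identical to generalized/ordinary least squares).
    """
    y = np.asarray(y, float).ravel()
    X = _as_design(fixed)
    if len(X) != len(y):
        raise LMMError(f"design has {len(X)} rows but response has {len(y)}")
    if np.isnan(y).any() or np.isnan(X.to_numpy()).any():
        raise LMMError("missing values in response or design; filter complete cases first")
    codes, fams = pd.factorize(np.asarray(family_ids))
    if len(fams) < 2:
        raise LMMError("at least 2 families are required to identify the family variance")
    names = list(X.columns)
    Xm = np.ascontiguousarray(X.to_numpy())
    n, p = Xm.shape
    if n < p + 2:
        raise LMMError(f"need at least {p + 2} samples for {p} fixed terms; got {n}")
    _check_collinear(Xm, names)

    prep = _Prep(y, Xm, codes, len(fams))

    if lambda_fixed is not None:
        if lambda_fixed < 0:
            raise LMMError("lambda_fixed must be >= 0")
        lam, converged = float(lambda_fixed), True
    else:
        lam, converged = _optimize_lambda(prep)

    crit, beta, Ainv, sigma2 = prep.solve(lam)
    var_resid = max(sigma2, VAR_FLOOR)
    var_family = lam * sigma2
    if var_family < VAR_FLOOR:
        var_family = 0.0

    se = np.sqrt(np.maximum(np.diag(Ainv) * var_resid, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pv = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)

    fitted_fixed = Xm @ beta
    resid = y - fitted_fixed
    c = lam / (1.0 + lam * prep.fam_n)
    u = c * np.bincount(codes, weights=resid, minlength=len(fams))
    fitted_blup = u[codes]
    loglik = -0.5 * (crit + (n - p) * np.log(2.0 * np.pi))

    return LMMFit(
        coef=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        pvalue=dict(zip(names, map(float, pv))),
        var_family=float(var_family),
        var_resid=float(var_resid),
        fitted_fixed=fitted_fixed,
        resid_marginal=resid,
        fitted_blup=fitted_blup,
        n=n,
        loglik=float(loglik),
        converged=converged,
        terms=names,
        lambda_ratio=float(lam),
    )


def lmm_residualize(y, covariate_design, family_ids) -> np.ndarray:
    """Marginal residuals of ``y`` after the covariate-only mixed model.

    The returned vector is observed minus the fixed-effect prediction
    (family BLUPs are not subtracted), and has mean ~0 because an intercept
    is always included.
    """
    return fit_lmm(y, covariate_design, family_ids).resid_marginal


def profile_reml(y, fixed, family_ids, lam: float) -> float:
    """-2 x profiled restricted log-likelihood (up to an additive constant)
    at a given variance ratio — a diagnostic for optimality checks."""
    y = np.asarray(y, float).ravel()
    X = _as_design(fixed)
    codes, fams = pd.factorize(np.asarray(family_ids))
    prep = _Prep(y, np.ascontiguousarray(X.to_numpy()), codes, len(fams))
    return float(prep.solve(lam)[0])
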