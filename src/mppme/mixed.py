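"""REML estimation of linear mixed models with structured covariance.

The models fitted throughout the package share one shape,

    y = X b + sum_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, diag(phi)),

so the marginal covariance of the observations is

    V(theta) = sum_k s2_k Z_k Z_k' + sum_s phi_s I_s,

a sum of random-term contributions (replicates, blocks, the compound-
symmetry genotype main effect linking the same genotype across
environments) and stratum-wise residual variances.  The residual strata
implement the cross-specific errors of the QTL models and the environment
cross-specific errors (ECSE) of the multi-environment models: each
(cross, environment) cell owns its variance, while the shared genotype
term supplies the covariance between environments (compound symmetry, CS).

Variance parameters are estimated by restricted maximum likelihood with an
analytic gradient on the log-variance scale (bounded L-BFGS-B, two starting
points); fixed effects follow by generalized least squares at the optimum.
Blocks of fixed effects are tested with Wald chi-square statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as scipy_linalg
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "VcovSpec",
    "MixedFit",
    "WaldResult",
    "build_vcov",
    "reml_fit",
    "wald_test",
    "neglog10p_chi2",
    "bonferroni_threshold",
]

_REL_FLOOR = 1e-8  # variance lower bound relative to var(y)


@dataclass
class VcovSpec:
    """Declarative covariance structure of the observation vector.

    ``strata`` assigns every observation to a residual stratum (its own
    error variance); ``random`` maps term names to (n x q) indicator/design
    matrices whose contribution is ``s2 Z Z'``.  Parameter order is random
    terms first (in insertion order), then strata.
    """

    kind: str
    strata: np.ndarray
    stratum_names: list[str]
    random: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata, dtype=int)
        n = self.strata.shape[0]
        for name, Z in self.random.items():
            if Z.shape[0] != n:
                raise ValueError(f"random term {name!r} has wrong row count")

    @property
    def n_obs(self) -> int:
        return self.strata.shape[0]

    @property
    def param_names(self) -> list[str]:
        return list(self.random) + [f"resid:{s}" for s in self.stratum_names]

    @property
    def n_params(self) -> int:
        return len(self.random) + len(self.stratum_names)

    # ---- constructors for the structures used in the QTL models ----

    @classmethod
    def iid(cls, n: int) -> "VcovSpec":
        return cls("iid", np.zeros(n, dtype=int), ["all"])

    @classmethod
    def cross_specific(cls, cross: pd.Series | np.ndarray) -> "VcovSpec":
        """One residual variance per cross (the single-environment QTL
        models)."""
        codes, names = pd.factorize(pd.Series(cross).astype(str))
        return cls("cross_specific", codes, list(names))

    @classmethod
    def cs_ecse(
        cls,
        genotype: pd.Series | np.ndarray,
        cross: pd.Series | np.ndarray,
        env: pd.Series | np.ndarray,
    ) -> "VcovSpec":
        """Compound symmetry + environment cross-specific errors.

        A shared genotype main-effect variance links observations on the
        same genotype across environments; each (cross, environment) cell
        has its own residual variance; observations from different crosses
        are independent.
        """
        gcodes, glabels = pd.factorize(pd.Series(genotype).astype(str))
        Zg = np.zeros((len(gcodes), len(glabels)))
        Zg[np.arange(len(gcodes)), gcodes] = 1.0
        cell = pd.Series(cross).astype(str) + ":" + pd.Series(env).astype(str)
        codes, names = pd.factorize(cell)
        return cls("cs_ecse", codes, list(names), {"genotype_cs": Zg})

    def with_random(self, name: str, Z: np.ndarray) -> "VcovSpec":
        new = dict(self.random)
        new[name] = Z
        return VcovSpec(self.kind, self.strata.copy(), list(self.stratum_names), new)


def build_vcov(spec: VcovSpec, params: np.ndarray | list[float]) -> np.ndarray:
    """Dense covariance matrix of the observations for given variance
    parameters (random-term variances first, then stratum variances)."""
    params = np.asarray(params, dtype=float)
    if params.shape[0] != spec.n_params:
        raise ValueError(
            f"expected {spec.n_params} variance parameters, got {params.shape[0]}"
        )
    if (params < 0).any():
        raise ValueError("variance parameters must be >= 0")
    n = spec.n_obs
    V = np.zeros((n, n))
    for k, Z in enumerate(spec.random.values()):
        V += params[k] * (Z @ Z.T)
    phi = params[len(spec.random):]
    V[np.diag_indices(n)] += phi[spec.strata]
    return V


@dataclass
class WaldResult:
    """Wald chi-square test of a block of fixed-effect coefficients."""

    W: float
    df: int
    p: float
    neglog10p: float


@dataclass
class MixedFit:
    """A fitted mixed model: GLS fixed effects at the REML optimum."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    varcomps: dict[str, float]
    reml_loglik: float
    n_obs: int
    converged: bool
    spec: VcovSpec
    dropped_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fixed_estimates": self.beta.round(10).to_dict(),
            "fixed_se": {
                k: float(np.sqrt(self.cov_beta.loc[k, k])) for k in self.beta.index
            },
            "variance_components": {k: float(v) for k, v in self.varcomps.items()},
            "reml_loglik": float(self.reml_loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }


def independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy left-to-right selection of a linearly independent column set.

    Earlier columns win ties, so designs should order structural effects
    (intercept, environment, cross) before QTL columns: a QTL column that is
    confounded with the structure is the one dropped.
    """
    n, m = X.shape
    Q = np.zeros((n, 0))
    keep: list[int] = []
    scale = max(np.abs(X).max(), 1.0)
    for j in range(m):
        v = X[:, j].astype(float)
        r = v - Q @ (Q.T @ v)
        # re-orthogonalize once for stability
        r = r - Q @ (Q.T @ r)
        if np.linalg.norm(r) > tol * scale * np.sqrt(n):
            keep.append(j)
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
    return keep


def _neg_reml(
    u: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    spec: VcovSpec,
    want_grad: bool,
):
    theta = np.exp(u)
    n, p = X.shape
    V = build_vcov(spec, theta)
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return (np.inf, np.zeros_like(u)) if want_grad else np.inf
    logdetV = 2.0 * np.log(np.diag(c[0])).sum()
    ViX = cho_solve(c, X)
    Viy = cho_solve(c, y)
    XtViX = X.T @ ViX
    try:
        cx = cho_factor(XtViX, lower=True)
    except np.linalg.LinAlgError:
        return (np.inf, np.zeros_like(u)) if want_grad else np.inf
    logdetX = 2.0 * np.log(np.diag(cx[0])).sum()
    beta = cho_solve(cx, X.T @ Viy)
    Py = Viy - ViX @ beta
    nll = 0.5 * (logdetV + logdetX + float(y @ Py))
    if not want_grad:
        return nll
    grad = np.empty_like(u)
    n_r = len(spec.random)
    # dV/ds2_k = Z_k Z_k'
    for k, Z in enumerate(spec.random.values()):
        ViZ = cho_solve(c, Z)
        PZ = ViZ - ViX @ cho_solve(cx, X.T @ ViZ)
        trPK = float(np.sum(PZ * Z))
        ZtPy = Z.T @ Py
        grad[k] = 0.5 * (trPK - float(ZtPy @ ZtPy)) * theta[k]
    if len(spec.stratum_names):
        Vi = cho_solve(c, np.eye(n))
        A = cho_solve(cx, ViX.T)
        diagP = np.diag(Vi) - np.sum(ViX * A.T, axis=1)
        Py2 = Py**2
        for s in range(len(spec.stratum_names)):
            mask = spec.strata == s
            grad[n_r + s] = (
                0.5 * (float(diagP[mask].sum()) - float(Py2[mask].sum()))
                * theta[n_r + s]
            )
    return nll, grad


def reml_fit(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    spec: VcovSpec,
    start: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    multistart: bool = True,
) -> MixedFit:
    """REML fit of ``y = X b + (random terms per spec) + e``.

    ``X`` must carry column names; collinear columns are dropped greedily
    left to right (structural effects should therefore come first).  The
    optimizer runs on log variances with an analytic gradient from two
    starting points (a warm ``start`` replaces the second; with
    ``multistart=False`` and a warm start only that start is used, the fast
    path for genome scans).  Variance components that converge to the lower
    bound are reported as 0.
    """
    yv = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if yv.shape[0] != Xm.shape[0] or yv.shape[0] != spec.n_obs:
        raise ValueError("y, X and spec disagree on the number of observations")
    keep = independent_columns(Xm)
    dropped = [names[j] for j in range(len(names)) if j not in set(keep)]
    if dropped:
        logger.warning("dropping collinear fixed-effect columns: %s", dropped)
    Xm = Xm[:, keep]
    names = [names[j] for j in keep]
    if Xm.shape[1] == 0:
        raise ValueError("fixed-effect design is empty after collinearity drops")
    n, p = Xm.shape
    if n < p:
        raise ValueError("not enough observations for the fixed-effect design")
    if n == p:
        # saturated design: exact solution, no residual information
        logger.warning("saturated fixed-effect design: variances not estimable")
        beta = np.linalg.solve(Xm, yv)
        return MixedFit(
            beta=pd.Series(beta, index=names),
            cov_beta=pd.DataFrame(np.zeros((p, p)), index=names, columns=names),
            varcomps={k: 0.0 for k in spec.param_names},
            reml_loglik=np.nan,
            n_obs=n,
            converged=True,
            spec=spec,
            dropped_columns=dropped,
        )
    # moment scale from OLS residual variance
    bols, *_ = np.linalg.lstsq(Xm, yv, rcond=None)
    resid = yv - Xm @ bols
    s2 = max(float(resid @ resid) / max(n - p, 1), 1e-12)
    m = spec.n_params
    floor = _REL_FLOOR * s2
    lo, hi = np.log(floor), np.log(s2 * 1e4 + floor)
    starts = [np.full(m, np.log(s2 / m + floor))]
    if start is not None:
        st = np.log(np.clip(np.asarray(start, dtype=float), floor, None))
        warm = np.clip(st, lo, hi)
        starts = [warm] if not multistart else starts + [warm]
    else:
        u2 = np.full(m, np.log(0.1 * s2 / max(m - 1, 1) + floor))
        u2[len(spec.random):] = np.log(0.9 * s2 + floor)
        starts.append(u2)
    best = None
    converged = False
    for u0 in starts:
        res = optimize.minimize(
            _neg_reml,
            u0,
            args=(yv, Xm, spec, True),
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * m,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        # a line search can fail right at the optimum (warm starts): accept
        # any point with an essentially zero gradient on the log scale
        grad_ok = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-3
        converged = converged or bool(res.success) or grad_ok
    theta = np.exp(best.x)
    # boundary components reported as zero
    theta_rep = np.where(theta <= floor * 1.01, 0.0, theta)
    V = build_vcov(spec, theta)
    c = cho_factor(V, lower=True)
    ViX = cho_solve(c, Xm)
    XtViX = Xm.T @ ViX
    cov = np.linalg.inv(XtViX)
    beta = cov @ (Xm.T @ cho_solve(c, yv))
    fit = MixedFit(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
        varcomps=dict(zip(spec.param_names, theta_rep)),
        reml_loglik=-float(best.fun),
        n_obs=n,
        converged=converged,
        spec=spec,
        dropped_columns=dropped,
    )
    return fit


def wald_test(fit: MixedFit, coefficients: list[str]) -> WaldResult:
    """Wald chi-square test that a block of fixed effects is zero.

    ``W = b' Cov(b)^-1 b`` over the named coefficients; the degrees of
    freedom equal the number tested (rank of the sub-covariance if it is
    singular, with a generalized inverse and a warning).
    """
    present = [cname for cname in coefficients if cname in fit.beta.index]
    if not present:
        return WaldResult(0.0, 1, 1.0, 0.0)
    b = fit.beta[present].to_numpy()
    C = fit.cov_beta.loc[present, present].to_numpy()
    df = len(present)
    try:
        ch = cho_factor(C, lower=True)
        W = float(b @ cho_solve(ch, b))
    except np.linalg.LinAlgError:
        Cinv = scipy_linalg.pinvh(C)
        rank = int(np.linalg.matrix_rank(C))
        logger.warning(
            "singular Wald sub-covariance: df reduced from %d to %d", df, rank
        )
        df = max(rank, 1)
        W = float(b @ Cinv @ b)
    W = max(W, 0.0)
    p = float(stats.chi2.sf(W, df))
    return WaldResult(W, df, p, neglog10p_chi2(W, df))


def neglog10p_chi2(W: float, df: int) -> float:
    """-log10 of the chi-square upper-tail probability at ``W``.

    Computed on the log scale, stable down to p ~ 1e-300.
    """
    if W < 0:
        raise ValueError("W must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    val = float(-stats.chi2.logsf(W, df) / np.log(10.0))
    if np.isfinite(val):
        return val
    # far tail where the survival function underflows: leading terms of the
    # asymptotic expansion of the upper incomplete gamma function
    x, a = W / 2.0, df / 2.0
    log_sf = (a - 1.0) * np.log(x) - x - gammaln(a) + np.log1p(
        max(a - 1.0, 0.0) / x
    )
    return float(-log_sf / np.log(10.0))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10 significance threshold after Bonferroni correction over
    ``n_tests`` positions."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))
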