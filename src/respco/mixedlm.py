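"""Maximum-likelihood mixed models for grouped trial data.

Two model families, both with per-participant random effects (intercept and
optionally a trial-number slope):

* a Gaussian linear mixed model fitted by profiling the fixed effects and
  the residual variance out of the ML deviance, leaving a low-dimensional
  optimisation over the relative random-effects Cholesky factor.  Because
  the profiled deviance depends on the data only through per-group
  cross-product matrices, a fit costs microseconds per deviance evaluation
  regardless of the number of trials — the lag scans and permutation tests
  refit the model thousands of times;

* a binomial (logistic) mixed model fitted by the Laplace approximation:
  penalised IRLS over the joint (fixed effects, spherical random effects)
  vector inside, Nelder-Mead over the covariance factor outside.

Both report the ML log-likelihood and AIC = 2k - 2*logLik with k counting
fixed effects, covariance parameters and (for the Gaussian model) the
residual variance, so AIC differences between nested fits on identical data
are directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["MixedFit", "fit_gaussian_lmm", "fit_binomial_glmm"]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixedFit:
    """Result of one mixed-model fit."""

    beta: np.ndarray
    se: np.ndarray
    names: list
    loglik: float
    aic: float
    k: int
    n_obs: int
    theta: np.ndarray
    sigma2: float | None
    converged: bool
    re_structure: str
    outcome: str = ""

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


def _group_stats(y, X, Z, codes, n_groups):
    """Per-group cross products; everything the Gaussian deviance needs."""
    p, q = X.shape[1], Z.shape[1]
    Azz = np.zeros((n_groups, q, q))
    Azx = np.zeros((n_groups, q, p))
    Azy = np.zeros((n_groups, q))
    for g in range(n_groups):
        m = codes == g
        Zg, Xg, yg = Z[m], X[m], y[m]
        Azz[g] = Zg.T @ Zg
        Azx[g] = Zg.T @ Xg
        Azy[g] = Zg.T @ yg
    return Azz, Azx, Azy, X.T @ X, X.T @ y, float(y @ y)


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    # diagonal entries act through L L^T, keep them non-negative
    d = np.abs(np.diag(L))
    L[np.diag_indices(q)] = d
    return L


def _gaussian_profiled(theta, q, n, Azz, Azx, Azy, Axx, Axy, Ayy):
    """Profiled -2 logLik plus the GLS pieces at this theta."""
    L = _chol_from_theta(np.asarray(theta, dtype=float), q)
    M = np.einsum("ij,gjk,kl->gil", L.T, Azz, L) + np.eye(q)[None]
    sign, logdet = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        return np.inf, None
    B = np.einsum("ij,gjk->gik", L.T, Azx)          # (G, q, p)
    c = np.einsum("ij,gj->gi", L.T, Azy)            # (G, q)
    MB = np.linalg.solve(M, B)
    Mc = np.linalg.solve(M, c[..., None])[..., 0]
    Sxx = Axx - np.einsum("gqi,gqj->ij", B, MB)
    Sxy = Axy - np.einsum("gqi,gq->i", B, Mc)
    Syy = Ayy - np.einsum("gq,gq->", c, Mc)
    try:
        beta = np.linalg.solve(Sxx, Sxy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = Syy - Sxy @ beta
    if rss <= 0:
        return np.inf, None
    sigma2 = rss / n
    m2ll = n * (LOG2PI + np.log(sigma2) + 1.0) + logdet.sum()
    return m2ll, (beta, sigma2, Sxx, L)


def fit_gaussian_lmm(y, X, groups, Z, names=None,
                     re_structure: str = "intercept_slope",
                     theta0: np.ndarray | None = None) -> MixedFit:
    """ML fit of y = X beta + Z_g b_g + eps with b_g ~ N(0, sigma^2 L L').

    ``groups`` holds integer-encodable group labels; ``Z`` the random-effects
    design (column of ones, plus the trial covariate when the structure
    includes a slope).  The relative Cholesky factor L is optimised by
    Nelder-Mead from several starts; fixed effects and residual variance
    are profiled out in closed form.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n, p = X.shape
    q = Z.shape[1]
    stats = _group_stats(y, X, Z, codes, labels.size)
    args = (q, n) + stats

    def objective(theta):
        return _gaussian_profiled(theta, *args)[0]

    n_theta = q * (q + 1) // 2
    if theta0 is not None:
        # warm start (permutation loops): one local optimisation suffices
        starts = [np.asarray(theta0, dtype=float)]
    elif q == 1:
        starts = [np.array([0.5]), np.array([0.05])]
    else:
        starts = [np.array([0.5, 0.0, 0.5]), np.array([0.05, 0.0, 0.05])]
    best = None
    for s0 in starts:
        res = optimize.minimize(objective, s0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8,
                                         "maxiter": 400 * n_theta})
        if best is None or res.fun < best.fun:
            best = res
    m2ll, parts = _gaussian_profiled(best.x, *args)
    converged = bool(np.isfinite(m2ll)) and parts is not None
    if not converged:
        raise FloatingPointError("Gaussian LMM deviance not finite at optimum")
    beta, sigma2, Sxx, L = parts
    cov = sigma2 * np.linalg.inv(Sxx)
    k = p + n_theta + 1
    loglik = -0.5 * m2ll
    return MixedFit(beta=beta, se=np.sqrt(np.diag(cov)),
                    names=list(names) if names is not None else
                    [f"x{i}" for i in range(p)],
                    loglik=float(loglik), aic=float(2 * k - 2 * loglik),
                    k=k, n_obs=n, theta=np.asarray(best.x, dtype=float),
                    sigma2=float(sigma2), converged=converged and best.success,
                    re_structure=re_structure, outcome="gaussian")


# ---------------------------------------------------------------- binomial

def _pirls(y, X, Zlist, L, codes_list, beta0=None, u0=None,
           max_iter: int = 60, tol: float = 1e-9):
    """Penalised IRLS over (beta, u) for fixed covariance factor L.

    Returns beta, u (stacked spherical effects), eta, and the per-group
    log-det terms of the Laplace correction.
    """
    n, p = X.shape
    q = L.shape[0]
    G = len(Zlist)
    nb = p + G * q
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    u = np.zeros(G * q) if u0 is None else u0.copy()

    ZL = [Zg @ L for Zg in Zlist]

    def eta_of(beta, u):
        eta = X @ beta
        for g in range(G):
            eta[codes_list[g]] += ZL[g] @ u[g * q:(g + 1) * q]
        return eta

    def penalised_ll(eta, u):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        return float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu) - 0.5 * u @ u)

    eta = eta_of(beta, u)
    obj = penalised_ll(eta, u)
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = np.zeros((nb, nb))
        rhs = np.zeros(nb)
        Xw = X * w[:, None]
        A[:p, :p] = X.T @ Xw
        rhs[:p] = Xw.T @ z
        for g in range(G):
            m = codes_list[g]
            Vg = ZL[g]
            Vw = Vg * w[m][:, None]
            s = slice(p + g * q, p + (g + 1) * q)
            A[s, s] = Vg.T @ Vw + np.eye(q)
            A[:p, s] = Xw[m].T @ Vg
            A[s, :p] = A[:p, s].T
            rhs[s] = Vw.T @ z[m]
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return None
        beta_new, u_new = sol[:p], sol[p:]
        # step-halving on the penalised log-likelihood
        step = 1.0
        for _ in range(20):
            bt = beta + step * (beta_new - beta)
            ut = u + step * (u_new - u)
            eta_t = eta_of(bt, ut)
            obj_t = penalised_ll(eta_t, ut)
            if obj_t >= obj - 1e-12:
                break
            step *= 0.5
        delta = max(np.max(np.abs(bt - beta)), np.max(np.abs(ut - u)))
        beta, u, eta, obj = bt, ut, eta_t, obj_t
        if delta < tol:
            break

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    logdet = 0.0
    info_beta = X.T @ (X * w[:, None])
    for g in range(G):
        m = codes_list[g]
        Vg = ZL[g]
        Mg = Vg.T @ (Vg * w[m][:, None]) + np.eye(q)
        sign, ld = np.linalg.slogdet(Mg)
        if sign <= 0:
            return None
        logdet += ld
    ll = penalised_ll(eta, u) - 0.5 * logdet
    return beta, u, eta, ll, info_beta


def fit_binomial_glmm(y, X, groups, Z, names=None,
                      re_structure: str = "intercept_slope") -> MixedFit:
    """Laplace-approximate ML fit of a logistic mixed model.

    The inner penalised IRLS solves for the fixed effects and the spherical
    random effects jointly at a given covariance factor; the outer
    Nelder-Mead maximises the Laplace log-likelihood over the factor's
    lower-triangular parameters.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n, p = X.shape
    q = Z.shape[1]
    G = labels.size
    codes_list = [np.nonzero(codes == g)[0] for g in range(G)]
    Zlist = [Z[m] for m in codes_list]
    n_theta = q * (q + 1) // 2

    state = {"beta": None, "u": None}

    def objective(theta):
        L = _chol_from_theta(np.asarray(theta, dtype=float), q)
        out = _pirls(y, X, Zlist, L, codes_list,
                     beta0=state["beta"], u0=state["u"])
        if out is None:
            return np.inf
        beta, u, eta, ll, _ = out
        state["beta"], state["u"] = beta, u
        return -2.0 * ll

    s0 = np.zeros(n_theta)
    s0[np.cumsum([0] + list(range(2, q + 1)))[:q]] = 0.3  # diagonal entries
    res = optimize.minimize(objective, s0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6,
                                     "maxiter": 300 * n_theta})
    L = _chol_from_theta(res.x, q)
    out = _pirls(y, X, Zlist, L, codes_list, beta0=state["beta"], u0=state["u"])
    if out is None:
        raise FloatingPointError("binomial GLMM did not converge")
    beta, u, eta, ll, info_beta = out
    try:
        cov = np.linalg.inv(info_beta)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    k = p + n_theta
    return MixedFit(beta=beta, se=se,
                    names=list(names) if names is not None else
                    [f"x{i}" for i in range(p)],
                    loglik=float(ll), aic=float(2 * k - 2 * ll),
                    k=k, n_obs=n, theta=np.asarray(res.x, dtype=float),
                    sigma2=None, converged=bool(res.success),
                    re_structure=re_structure, outcome="binomial")
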