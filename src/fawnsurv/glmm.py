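"""Maximum-likelihood logistic regression with crossed Gaussian random intercepts.

The random effects are written in scaled form, b_g = sigma_g * v_g with
v_g ~ N(0, I), so the variance parameters enter the design smoothly and
sigma_g = 0 is an ordinary interior limit (the fit then collapses to plain
logistic regression). For fixed sigmas the joint penalized log-likelihood is
maximized over (beta, v) by damped Newton; the marginal likelihood is the
Laplace approximation

    l(sigma) = J(beta_hat, v_hat) - 0.5 * logdet(H_vv)

with H_vv the v-block of the penalized Hessian at the mode. The outer
problem over the sigmas is solved by bounded quasi-Newton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["MixedLogitFit", "fit_mixed_logit", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MixedLogitFit:
    """Fitted crossed random-intercept logistic model."""

    coef_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    re_names: list[str]
    re_sd: np.ndarray  # sigma per grouping factor
    re_modes: dict[str, np.ndarray]  # conditional modes b_g = sigma_g * v_g
    loglik: float  # Laplace-approximate marginal log-likelihood
    n_obs: int
    converged: bool
    fitted: np.ndarray | None = None  # conditional probabilities at the mode
    response: np.ndarray | None = None

    def diagnostics(self) -> "pd.DataFrame":
        """Standardized (Pearson) residuals vs fitted probabilities."""
        if self.fitted is None:
            raise ValueError("fit carries no fitted values")
        resid = (self.response - self.fitted) / np.sqrt(self.fitted * (1 - self.fitted))
        return pd.DataFrame({"fitted": self.fitted, "std_residual": resid})

    @property
    def re_var(self) -> dict[str, float]:
        return {g: float(s**2) for g, s in zip(self.re_names, self.re_sd)}

    def params(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.coef))


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    big = eta > 30
    out[big] = eta[big]
    out[~big] = np.log1p(np.exp(eta[~big]))
    return out


class _Problem:
    def __init__(self, y, X, group_codes, group_sizes):
        self.y = y
        self.X = X
        self.codes = group_codes  # list of int arrays
        self.sizes = group_sizes  # list of ints
        self.n, self.p = X.shape
        self.q = int(sum(group_sizes))
        self.offsets = np.concatenate([[0], np.cumsum(group_sizes)]).astype(int)

    def eta(self, beta, vs, sigmas):
        eta = self.X @ beta
        for codes, v, s in zip(self.codes, vs, sigmas):
            eta = eta + s * v[codes]
        return eta

    def split_v(self, v_flat):
        return [v_flat[self.offsets[g] : self.offsets[g + 1]] for g in range(len(self.sizes))]

    def penalized_loglik(self, beta, v_flat, sigmas):
        vs = self.split_v(v_flat)
        eta = self.eta(beta, vs, sigmas)
        ll = float(self.y @ eta - _log1pexp(eta).sum())
        return ll - 0.5 * float(v_flat @ v_flat)

    def newton(self, beta, v_flat, sigmas, tol=1e-10, max_iter=100):
        """Damped Newton over u = (beta, v). Returns (beta, v, H, mu)."""
        p, q = self.p, self.q
        u = np.concatenate([beta, v_flat])
        J = self.penalized_loglik(u[:p], u[p:], sigmas)
        for _ in range(max_iter):
            beta, v_flat = u[:p], u[p:]
            vs = self.split_v(v_flat)
            eta = self.eta(beta, vs, sigmas)
            mu = _expit(eta)
            w = mu * (1.0 - mu)
            resid = self.y - mu

            grad = np.empty(p + q)
            grad[:p] = self.X.T @ resid
            for g, (codes, s) in enumerate(zip(self.codes, sigmas)):
                sl = slice(p + self.offsets[g], p + self.offsets[g + 1])
                grad[sl] = s * np.bincount(codes, weights=resid, minlength=self.sizes[g]) - vs[g]

            H = self._hessian(w, sigmas)
            try:
                cf = linalg.cho_factor(H)
                step = linalg.cho_solve(cf, grad)
            except linalg.LinAlgError:
                H = H + 1e-6 * np.eye(p + q)
                step = linalg.solve(H, grad, assume_a="pos")

            if np.max(np.abs(grad)) < tol:
                return u[:p], u[p:], H, mu
            # backtracking line search on the penalized log-likelihood
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                J_new = self.penalized_loglik(u_new[:p], u_new[p:], sigmas)
                if J_new >= J - 1e-12:
                    break
                t *= 0.5
            if abs(J_new - J) < 1e-13 * (1 + abs(J)):
                u, J = u_new, J_new
                break
            u, J = u_new, J_new
        beta, v_flat = u[:p], u[p:]
        vs = self.split_v(v_flat)
        eta = self.eta(beta, vs, sigmas)
        mu = _expit(eta)
        grad_norm = float(np.max(np.abs(self.X.T @ (self.y - mu))))
        if grad_norm > 1e-4:
            raise ConvergenceError(f"inner Newton did not converge (|grad|={grad_norm:.2e})")
        return beta, v_flat, self._hessian(mu * (1 - mu), sigmas), mu

    def _hessian(self, w, sigmas):
        """Penalized negative Hessian over (beta, v): block-assembled, dense."""
        p, q = self.p, self.q
        H = np.zeros((p + q, p + q))
        Xw = self.X * w[:, None]
        H[:p, :p] = self.X.T @ Xw
        G = len(self.sizes)
        for g in range(G):
            codes_g, s_g, m_g = self.codes[g], sigmas[g], self.sizes[g]
            sl_g = slice(p + self.offsets[g], p + self.offsets[g + 1])
            # beta x v_g
            cross = np.stack(
                [np.bincount(codes_g, weights=Xw[:, j], minlength=m_g) for j in range(p)]
            )
            H[:p, sl_g] = s_g * cross
            H[sl_g, :p] = H[:p, sl_g].T
            # v_g x v_g
            diag = np.bincount(codes_g, weights=w, minlength=m_g)
            H[sl_g, sl_g] = s_g**2 * np.diag(diag) + np.eye(m_g)
            # v_g x v_h crossed blocks
            for h in range(g + 1, G):
                codes_h, s_h, m_h = self.codes[h], sigmas[h], self.sizes[h]
                sl_h = slice(p + self.offsets[h], p + self.offsets[h + 1])
                flat = np.bincount(codes_g * m_h + codes_h, weights=w, minlength=m_g * m_h)
                block = s_g * s_h * flat.reshape(m_g, m_h)
                H[sl_g, sl_h] = block
                H[sl_h, sl_g] = block.T
        return H

    def laplace_loglik(self, sigmas, warm):
        beta, v_flat, H, _ = self.newton(warm[0], warm[1], sigmas)
        J = self.penalized_loglik(beta, v_flat, sigmas)
        sign, logdet = np.linalg.slogdet(H[self.p :, self.p :])
        if sign <= 0:
            raise ConvergenceError("v-block Hessian not positive definite")
        return J - 0.5 * logdet, (beta, v_flat, H)


def fit_mixed_logit(
    y: np.ndarray,
    X: np.ndarray,
    coef_names: list[str],
    groups: dict[str, np.ndarray],
    re_sd_fixed: dict[str, float] | None = None,
    sd_bound: float = 5.0,
) -> MixedLogitFit:
    """Fit a logistic GLMM with crossed random intercepts by Laplace ML.

    Parameters
    ----------
    y : 0/1 response.
    X : fixed-effects design (include the intercept column yourself).
    groups : mapping of grouping-factor name to integer codes per row.
    re_sd_fixed : pin the random-effect SDs instead of estimating them
        (``{"fawn": 0.0, "year": 0.0}`` reduces to plain logistic).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    re_names = list(groups)
    codes_list, sizes = [], []
    for name in re_names:
        codes, _ = pd.factorize(np.asarray(groups[name]))
        codes_list.append(codes.astype(np.int64))
        sizes.append(int(codes.max()) + 1 if len(codes) else 0)
    prob = _Problem(y, X, codes_list, sizes)

    mu0 = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    beta0 = np.zeros(X.shape[1])
    # crude intercept start if a constant column exists
    const_cols = np.where(np.ptp(X, axis=0) == 0)[0]
    if len(const_cols):
        beta0[const_cols[0]] = np.log(mu0 / (1 - mu0)) / X[0, const_cols[0]]
    v0 = np.zeros(prob.q)
    warm = [beta0, v0]

    if re_sd_fixed is not None:
        sigmas = np.array([float(re_sd_fixed[g]) for g in re_names])
        ll, (beta, v_flat, H) = prob.laplace_loglik(sigmas, warm)
        converged = True
    else:
        state = {}

        def neg_ll(sig):
            ll, sol = prob.laplace_loglik(np.maximum(sig, 0.0), warm)
            warm[0], warm[1] = sol[0], sol[1]
            state["sol"] = sol
            state["sig"] = np.maximum(sig, 0.0)
            return -ll

        res = optimize.minimize(
            neg_ll,
            x0=np.full(len(re_names), 0.3),
            method="L-BFGS-B",
            bounds=[(0.0, sd_bound)] * len(re_names),
            options={"ftol": 1e-10, "gtol": 1e-7, "eps": 1e-4, "maxiter": 100},
        )
        converged = bool(res.success)
        sigmas = np.maximum(res.x, 0.0)
        ll, (beta, v_flat, H) = prob.laplace_loglik(sigmas, warm)

    p = X.shape[1]
    cov = linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    if np.any(se == 0) or np.any(~np.isfinite(se)):
        raise ConvergenceError("non-positive standard errors; fit is degenerate")
    if np.max(np.abs(beta)) > 15:
        warnings.warn("very large coefficients: possible (quasi-)separation", stacklevel=2)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    vs = prob.split_v(v_flat)
    re_modes = {g: s * v for g, s, v in zip(re_names, sigmas, vs)}
    fitted = _expit(prob.eta(beta, vs, sigmas))
    return MixedLogitFit(
        coef_names=list(coef_names),
        coef=beta,
        se=se,
        zvalues=z,
        pvalues=pvals,
        re_names=re_names,
        re_sd=sigmas,
        re_modes=re_modes,
        loglik=float(ll),
        n_obs=len(y),
        converged=converged,
        fitted=fitted,
        response=y,
    )
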