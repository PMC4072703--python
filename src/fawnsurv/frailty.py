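"""Cox proportional hazards with crossed Gaussian log-frailties.

Penalized partial likelihood in the Ripatti-Palmgren style: random effects
are written b_g = sigma_g * v_g, v_g ~ N(0, I); for fixed sigmas the Efron
partial likelihood minus the v-penalty is maximized over (beta, v) by damped
Newton, and the integrated (marginal) log-likelihood is the Laplace
approximation

    l(sigma) = PL(beta_hat, v_hat) - 0.5 * v_hat'v_hat - 0.5 * logdet(K_vv)

with K_vv the v-block of the penalized negative Hessian at the mode. The
outer problem over the sigmas is a bounded quasi-Newton search; sigma = 0
recovers the ordinary Cox fit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["FrailtyCoxFit", "fit_frailty_cox", "breslow_baseline"]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FrailtyCoxFit:
    term_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    re_names: list[str]
    re_sd: np.ndarray
    re_modes: dict[str, np.ndarray]  # b_g = sigma_g * v_g, in factorized level order
    re_levels: dict[str, np.ndarray]
    loglik: float  # Laplace-integrated partial log-likelihood
    n_obs: int
    n_events: int
    converged: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def re_var(self) -> dict[str, float]:
        return {g: float(s**2) for g, s in zip(self.re_names, self.re_sd)}


class _CoxProblem:
    """Efron partial likelihood with value/gradient/Hessian in eta."""

    def __init__(self, time, event, X, group_codes, group_sizes):
        order = np.lexsort((-event, time))  # by time; deaths before censorings at ties
        self.order = order
        self.time = np.asarray(time, dtype=float)[order]
        self.event = np.asarray(event, dtype=int)[order]
        self.X = np.asarray(X, dtype=float)[order]
        self.codes = [np.asarray(c)[order] for c in group_codes]
        self.sizes = group_sizes
        self.n, self.p = self.X.shape
        self.q = int(sum(group_sizes))
        self.offsets = np.concatenate([[0], np.cumsum(group_sizes)]).astype(int)
        # unique event times and their member indices (in sorted order)
        death_idx = np.flatnonzero(self.event == 1)
        self.event_blocks = []  # (risk_start, death_indices)
        if len(death_idx):
            death_times = self.time[death_idx]
            for tau in np.unique(death_times):
                D = death_idx[death_times == tau]
                risk_start = int(np.searchsorted(self.time, tau, side="left"))
                self.event_blocks.append((risk_start, D))

    # -- design helpers ------------------------------------------------
    def full_design(self, sigmas):
        """Dense scaled design A = [X, sigma_g * Z_g ...]; fine at this scale."""
        A = np.zeros((self.n, self.p + self.q))
        A[:, : self.p] = self.X
        for g, (codes, s) in enumerate(zip(self.codes, sigmas)):
            A[np.arange(self.n), self.p + self.offsets[g] + codes] = s
        return A

    def eta(self, u, sigmas):
        e = self.X @ u[: self.p]
        for g, (codes, s) in enumerate(zip(self.codes, sigmas)):
            e = e + s * u[self.p + self.offsets[g] + codes]
        return e

    # -- Efron quantities ----------------------------------------------
    def pl_parts(self, eta, A=None):
        """Return (pl, grad_eta, w_diag, outer_vecs).

        ``outer_vecs`` holds A'pi_l for every Efron step l when A is given,
        so the eta-Hessian contraction A'H A = A'diag(w)A - sum outer^2 can
        be assembled by the caller.
        """
        eta = eta - eta.max()  # rescale for overflow safety; PL is shift-invariant up to consts
        r = np.exp(eta)
        B = A * r[:, None] if A is not None else None
        # suffix sums
        csum = np.cumsum(r[::-1])[::-1]
        CB = np.cumsum(B[::-1], axis=0)[::-1] if A is not None else None

        pl = 0.0
        grad = self.event.astype(float).copy()
        w = np.zeros(self.n)
        outer_vecs = []
        q_cum = 0.0  # running sum of 1/s_l over event times processed so far
        # iterate event times in increasing order; accumulate Q via prefix logic:
        # process in increasing time order, assign Q(t_i) afterwards
        qs = []  # (risk_start, q_tau)
        for risk_start, D in self.event_blocks:
            d = len(D)
            s_R = csum[risk_start]
            s_D = r[D].sum()
            C_R = CB[risk_start] if A is not None else None
            C_D = B[D].sum(axis=0) if A is not None else None
            q_tau = 0.0
            l_over_s = 0.0
            for l in range(d):
                frac = l / d
                s_l = s_R - frac * s_D
                pl -= np.log(s_l)
                q_tau += 1.0 / s_l
                l_over_s += frac / s_l
                if A is not None:
                    outer_vecs.append((C_R - frac * C_D) / s_l)
            pl += eta[D].sum()
            qs.append((risk_start, q_tau))
            # death-specific diagonal correction
            w[D] -= r[D] * l_over_s
            grad[D] += r[D] * l_over_s
        # Q(t_i): for each observation, sum of q_tau over event times with risk_start <= i
        starts = np.array([s for s, _ in qs], dtype=int)
        qvals = np.array([q for _, q in qs])
        if len(starts):
            cumq = np.cumsum(qvals)
            # number of event blocks whose risk set contains obs i: blocks with risk_start <= i
            k = np.searchsorted(starts, np.arange(self.n), side="right")
            Q = np.where(k > 0, cumq[np.maximum(k - 1, 0)], 0.0)
        else:
            Q = np.zeros(self.n)
        w += r * Q
        grad -= r * Q
        return pl, grad, w, outer_vecs

    def penalized_pl(self, u, sigmas):
        eta = self.eta(u, sigmas)
        pl, *_ = self.pl_parts(eta)
        v = u[self.p :]
        return pl - 0.5 * float(v @ v)

    def newton(self, u, sigmas, tol=1e-9, max_iter=200):
        m = self.p + self.q
        A = self.full_design(sigmas)
        J = self.penalized_pl(u, sigmas)
        K = None
        for _ in range(max_iter):
            eta = self.eta(u, sigmas)
            _, g_eta, w, outers = self.pl_parts(eta, A)
            grad = A.T @ g_eta
            grad[self.p :] -= u[self.p :]
            K = (A * w[:, None]).T @ A
            for vvec in outers:
                K -= np.outer(vvec, vvec)
            K[self.p :, self.p :] += np.eye(self.q)
            K = 0.5 * (K + K.T)
            if np.max(np.abs(grad)) < tol:
                return u, K
            try:
                step = linalg.solve(K + 1e-10 * np.eye(m), grad, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.solve(K + 1e-6 * np.eye(m), grad)
            t = 1.0
            J_new = None
            for _ in range(40):
                u_new = u + t * step
                J_new = self.penalized_pl(u_new, sigmas)
                if J_new >= J - 1e-12:
                    break
                t *= 0.5
            if abs(J_new - J) < 1e-13 * (1 + abs(J)) and np.max(np.abs(grad)) < 1e-7:
                u, J = u_new, J_new
                break
            u, J = u_new, J_new
        else:
            eta = self.eta(u, sigmas)
            _, g_eta, _, _ = self.pl_parts(eta, A)
            grad = A.T @ g_eta
            grad[self.p :] -= u[self.p :]
            if np.max(np.abs(grad)) > 1e-4:
                raise ConvergenceError(
                    f"Cox inner Newton stalled (|grad|={np.max(np.abs(grad)):.2e})"
                )
        # refresh Hessian at the final point
        eta = self.eta(u, sigmas)
        _, _, w, outers = self.pl_parts(eta, A)
        K = (A * w[:, None]).T @ A
        for vvec in outers:
            K -= np.outer(vvec, vvec)
        K[self.p :, self.p :] += np.eye(self.q)
        return u, 0.5 * (K + K.T)

    def laplace(self, sigmas, warm):
        u, K = self.newton(warm.copy(), sigmas)
        J = self.penalized_pl(u, sigmas)
        Kvv = K[self.p :, self.p :]
        sign, logdet = np.linalg.slogdet(Kvv)
        if sign <= 0:
            raise ConvergenceError("frailty Hessian block not positive definite")
        return J - 0.5 * logdet, u, K


def fit_frailty_cox(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    term_names: list[str],
    groups: dict[str, np.ndarray],
    re_sd_fixed: dict[str, float] | None = None,
    sd_bound: float = 3.0,
) -> FrailtyCoxFit:
    """Fit the frailty Cox model; see module docstring.

    ``X`` may have zero columns (frailty-only null model). ``re_sd_fixed``
    pins the frailty SDs (zeros reduce to a plain Cox fit).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if event.sum() < 1 and X.shape[1] > 0:
        raise ValueError("no events: cannot fit a Cox model")
    re_names = list(groups)
    codes_list, sizes, levels = [], [], {}
    for name in re_names:
        codes, uniques = pd.factorize(np.asarray(groups[name]))
        codes_list.append(codes.astype(np.int64))
        sizes.append(int(codes.max()) + 1 if len(codes) else 0)
        levels[name] = np.asarray(uniques)
    prob = _CoxProblem(time, event, X, codes_list, sizes)
    u0 = np.zeros(prob.p + prob.q)

    if re_sd_fixed is not None:
        sigmas = np.array([float(re_sd_fixed[g]) for g in re_names])
        ll, u, K = prob.laplace(sigmas, u0)
        converged = True
    else:
        warm = [u0]

        def neg_ll(sig):
            ll, u, _ = prob.laplace(np.maximum(sig, 0.0), warm[0])
            warm[0] = u
            return -ll

        res = optimize.minimize(
            neg_ll,
            x0=np.full(len(re_names), 0.3),
            method="L-BFGS-B",
            bounds=[(0.0, sd_bound)] * len(re_names),
            options={"ftol": 1e-9, "gtol": 1e-6, "eps": 1e-4, "maxiter": 60},
        )
        converged = bool(res.success)
        sigmas = np.maximum(res.x, 0.0)
        ll, u, K = prob.laplace(sigmas, warm[0])

    p = prob.p
    beta = u[:p]
    if p:
        cov = linalg.inv(K)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        if np.any(se == 0) or np.any(~np.isfinite(se)):
            raise ConvergenceError("non-positive standard errors in Cox fit")
        z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(z))
    else:
        se = np.zeros(0)
        z = np.zeros(0)
        pvals = np.zeros(0)
    vs = [u[p + prob.offsets[g] : p + prob.offsets[g + 1]] for g in range(len(re_names))]
    re_modes = {g: s * v for g, s, v in zip(re_names, sigmas, vs)}
    return FrailtyCoxFit(
        term_names=list(term_names),
        coef=beta,
        se=se,
        zvalues=z,
        pvalues=pvals,
        re_names=re_names,
        re_sd=sigmas,
        re_modes=re_modes,
        re_levels=levels,
        loglik=float(ll),
        n_obs=prob.n,
        n_events=int(event.sum()),
        converged=converged,
    )


def breslow_baseline(time, event, eta) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative-baseline estimator for linear predictor ``eta``.

    Returns (times, S0) with S0(0) = 1 and S0 non-increasing; S0 refers to
    eta = 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time)
    time, event, eta = time[order], event[order], eta[order]
    r = np.exp(eta)
    csum = np.cumsum(r[::-1])[::-1]
    taus, H = [0.0], [0.0]
    death_idx = np.flatnonzero(event == 1)
    for tau in np.unique(time[death_idx]):
        D = death_idx[time[death_idx] == tau]
        risk_start = int(np.searchsorted(time, tau, side="left"))
        taus.append(float(tau))
        H.append(H[-1] + len(D) / csum[risk_start])
    return np.asarray(taus), np.exp(-np.asarray(H))
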