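"""Linear mixed models by profiled maximum likelihood.

A compact ML engine for random intercept-and-slope models with arbitrary
fixed-effect designs: the fixed effects are profiled out by generalized
least squares at each variance-parameter point, and the profile
log-likelihood is maximised over the log-Cholesky factor of the
random-effects covariance and the log residual variance with L-BFGS.
Subjects are batched by observation count so all per-subject linear algebra
is vectorised.

Used two ways: as the estimation engine behind the class-stratified growth
curves (where many refits are needed for pruning and simulation studies)
and as an independent reference for the single-class limit of the EM-based
mixture fit in :mod:`lctraj.lclmm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMFit:
    """ML fit of a linear mixed model with random intercept + slope."""

    coef: pd.Series  # fixed effects
    cov: pd.DataFrame  # GLS covariance of the fixed effects
    B: np.ndarray  # random-effects covariance
    sigma2: float
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    phi: np.ndarray | None = None  # packed variance parameters (warm starts)

    # aliases used by the single-class oracle comparisons
    @property
    def theta(self) -> np.ndarray:
        return self.coef.to_numpy()

    @property
    def cov_theta(self) -> np.ndarray:
        return self.cov.to_numpy()


def _chol_from_packed(phi: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(phi[idx]) if i == j else phi[idx]
            idx += 1
    return L


def _profile(phi: np.ndarray, batches, p: int, k: int):
    """GLS fixed effects and profile log-likelihood at variance point phi."""
    nk = k * (k + 1) // 2
    L = _chol_from_packed(phi[:nk], k)
    B = L @ L.T
    sigma2 = float(np.exp(np.clip(phi[nk], -40.0, 40.0)))

    A = np.zeros((p, p))
    rhs = np.zeros(p)
    pieces = []
    for Y, X, Z in batches:
        m = Y.shape[1]
        V = np.einsum("smk,kl,snl->smn", Z, B, Z) + sigma2 * np.eye(m)[None]
        Vinv = np.linalg.inv(V)
        _, logdet = np.linalg.slogdet(V)
        XtVi = np.einsum("smp,smn->spn", X, Vinv)
        A += np.einsum("spn,snq->pq", XtVi, X)
        rhs += np.einsum("spn,sn->p", XtVi, Y)
        pieces.append((Y, X, Vinv, logdet, m))
    theta = np.linalg.solve(A, rhs)

    loglik = 0.0
    for Y, X, Vinv, logdet, m in pieces:
        r = Y - np.einsum("smp,p->sm", X, theta)
        quad = np.einsum("sm,smn,sn->s", r, Vinv, r)
        loglik += float(np.sum(-0.5 * (m * _LOG2PI + logdet + quad)))
    return loglik, theta, A, B, sigma2


def _batches_from_frame(
    df: pd.DataFrame, ycol: str, xcols, subject_col: str, tcol: str
):
    dfs = df.sort_values([subject_col, tcol])
    sizes = dfs.groupby(subject_col, sort=True).size()
    batches = []
    for m in sorted(sizes.unique()):
        ids_m = sizes.index[sizes == m]
        sub = dfs[dfs[subject_col].isin(ids_m)]
        S = len(ids_m)
        Y = sub[ycol].to_numpy(dtype=float).reshape(S, m)
        X = sub[list(xcols)].to_numpy(dtype=float).reshape(S, m, len(xcols))
        t = sub[tcol].to_numpy(dtype=float).reshape(S, m)
        Z = np.stack([np.ones_like(t), t], axis=-1)
        batches.append((Y, X, Z))
    return batches, int(sizes.size)


def _chol_derivs(phi: np.ndarray, k: int):
    """dB/dphi_j for every log-Cholesky coordinate."""
    L = _chol_from_packed(phi, k)
    derivs = []
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            dL = np.zeros((k, k))
            dL[i, j] = L[i, j] if i == j else 1.0
            derivs.append(dL @ L.T + L @ dL.T)
            idx += 1
    return derivs


def _neg_loglik_grad(phi: np.ndarray, batches, p: int, k: int):
    """Negative profile log-likelihood and its gradient.

    By the envelope theorem the gradient of the profiled likelihood with
    respect to the variance parameters equals the partial derivative at the
    GLS fixed-effect solution:
    d l / d phi_j = -0.5 sum_i [tr(Vinv dV) - r' Vinv dV Vinv r].
    """
    nk = k * (k + 1) // 2
    loglik, theta, _, B, sigma2 = _profile(phi, batches, p, k)
    dBs = _chol_derivs(phi[:nk], k)

    grad = np.zeros(nk + 1)
    for Y, X, Z in batches:
        m = Y.shape[1]
        V = np.einsum("smk,kl,snl->smn", Z, B, Z) + sigma2 * np.eye(m)[None]
        Vinv = np.linalg.inv(V)
        r = Y - np.einsum("smp,p->sm", X, theta)
        vr = np.einsum("smn,sn->sm", Vinv, r)
        W = np.einsum("smk,smn,snl->skl", Z, Vinv, Z)  # Z' Vinv Z
        u = np.einsum("smk,sm->sk", Z, vr)  # Z' Vinv r
        for j, dB in enumerate(dBs):
            tr = np.einsum("skl,lk->s", W, dB)
            quad = np.einsum("sk,kl,sl->s", u, dB, u)
            grad[j] += -0.5 * float((tr - quad).sum())
        # sigma2 coordinate: dV = sigma2 * I (chain rule through log)
        tr_s = sigma2 * np.einsum("smm->s", Vinv)
        quad_s = sigma2 * np.einsum("sm,sm->s", vr, vr)
        grad[nk] += -0.5 * float((tr_s - quad_s).sum())
    return -loglik, -grad


def _maximize(batches, p: int, k: int, n_obs: int, maxiter: int, phi0=None):
    if phi0 is None:
        y_all = np.concatenate([b[0].reshape(-1) for b in batches])
        var = max(float(np.var(y_all)), 1e-8)
        phi0 = []
        for i in range(k):
            for j in range(i + 1):
                phi0.append(0.5 * np.log(0.5 * var / (100.0**i)) if i == j else 0.0)
        phi0.append(np.log(0.5 * var))
    phi0 = np.asarray(phi0)

    res = minimize(
        _neg_loglik_grad,
        phi0,
        args=(batches, p, k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
    )
    loglik, theta, A, B, sigma2 = _profile(res.x, batches, p, k)
    return loglik, theta, np.linalg.inv(A), B, sigma2, bool(res.success), res.x


def fit_lmm(
    df: pd.DataFrame,
    ycol: str,
    xcols,
    subject_col: str = "subject_id",
    tcol: str = "t",
    maxiter: int = 500,
    phi0=None,
) -> LMMFit:
    """ML linear mixed model on a long-format frame.

    ``xcols`` are the fixed-effect columns (including any intercept column);
    the random part is always (1, t) per subject.  ``phi0`` warm-starts the
    variance-parameter search (e.g. from a previous fit of a nested model).
    """
    xcols = list(xcols)
    batches, n_subjects = _batches_from_frame(df, ycol, xcols, subject_col, tcol)
    loglik, theta, cov, B, sigma2, ok, phi = _maximize(
        batches, len(xcols), 2, len(df), maxiter, phi0=phi0
    )
    return LMMFit(
        coef=pd.Series(theta, index=xcols),
        cov=pd.DataFrame(cov, index=xcols, columns=xcols),
        B=B,
        sigma2=sigma2,
        loglik=loglik,
        n_obs=len(df),
        n_subjects=n_subjects,
        converged=ok,
        phi=phi,
    )


def profile_ml_lmm(design, maxiter: int = 500) -> LMMFit:
    """ML fit on a prebuilt :class:`~lctraj.lclmm.DesignData` (single class).

    The fixed-effect vector stacks the polynomial block first, then the
    shared covariates — the same layout as the G = 1 mixture fit.
    """
    batches = []
    for b in design.batches:
        X = np.concatenate([b.X2, b.X1], axis=2)
        n_i = b.mask.sum(axis=1)
        for m in np.unique(n_i):  # strip padding: real visits come first
            sel = n_i == m
            batches.append((b.Y[sel][:, :m], X[sel][:, :m], b.Z[sel][:, :m]))
    p = design.degree + 1 + design.q
    names = [f"t^{k}" for k in range(design.degree + 1)] + list(design.shared_names)
    loglik, theta, cov, B, sigma2, ok, phi = _maximize(
        batches, p, design.n_random, design.n_obs, maxiter
    )
    return LMMFit(
        coef=pd.Series(theta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        B=B,
        sigma2=sigma2,
        loglik=loglik,
        n_obs=design.n_obs,
        n_subjects=design.n_subjects,
        converged=ok,
        phi=phi,
    )
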