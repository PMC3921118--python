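"""Latent class linear mixed model (growth mixture model) on backward time.

The model: subject i with n_i observations Y_i belongs to latent class g
with probability pi_g.  Conditional on class,

    Y_i = X2_i delta_g + X1_i beta + Z_i b_i + eps_i,

where X2_i holds the class-specific polynomial in backward time
(1, t, ..., t^D), X1_i the shared confounders (age at time zero, sex, phase
indicators) whose effects are constrained equal across classes, Z_i = (1, t)
the random intercept-and-slope design, b_i ~ N(0, B) and
eps_i ~ N(0, sigma2 I).  Marginally Y_i | g ~ N(X2_i delta_g + X1_i beta,
Z_i B Z_i' + sigma2 I), and the observed-data likelihood is the pi-weighted
mixture over classes.

Estimation is by EM treating both the class label and the random effects as
missing data: the E-step yields posterior class weights and conditional
random-effect moments, the M-step updates pi, the fixed effects (weighted
least squares) and the variance components (closed form).  Every M-step
maximises the same E-step Q function, so the observed log-likelihood is
non-decreasing across iterations.  Class enumeration uses BIC subject to a
minimum modal class share, and subjects are classified to their modal
posterior class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LCLMMSpec:
    """Model specification for the latent class linear mixed model."""

    outcome_name: str = "bmi"
    degree: int = 3
    shared_covariates: tuple[str, ...] = ("age_t0", "sex", "phase")
    n_classes: int = 3
    random_slope: bool = True

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.n_classes < 1:
            raise ValueError("number of classes must be >= 1")
        overlap = {"t", "intercept"} & set(self.shared_covariates)
        if overlap:
            raise ValueError(
                f"shared covariates overlap class-specific terms: {overlap}"
            )

    def with_classes(self, g: int) -> "LCLMMSpec":
        return LCLMMSpec(
            outcome_name=self.outcome_name,
            degree=self.degree,
            shared_covariates=self.shared_covariates,
            n_classes=g,
            random_slope=self.random_slope,
        )


@dataclass
class _Batch:
    """Stacked per-subject arrays, zero-padded to a common visit count.

    Padded visit slots have Y = 0 and all design rows 0, so they contribute
    nothing to quadratic forms or normal equations; the log-density picks up
    a known additive constant per padded slot that :func:`_batch_loglik`
    removes.
    """

    ids: np.ndarray  # (S,) subject ids
    Y: np.ndarray  # (S, m)
    X2: np.ndarray  # (S, m, D+1) class-specific polynomial design
    X1: np.ndarray  # (S, m, q) shared-covariate design
    Z: np.ndarray  # (S, m, k) random-effects design
    mask: np.ndarray  # (S, m) True at real observations
    n_pad: np.ndarray  # (S,) padded slots per subject

    @property
    def m(self) -> int:
        return self.Y.shape[1]


@dataclass
class DesignData:
    """Per-subject design structures, padded to a common visit count."""

    batches: list[_Batch]
    subject_ids: np.ndarray  # canonical row order of posterior matrices
    shared_names: tuple[str, ...]
    degree: int
    n_random: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return int(sum(b.mask.sum() for b in self.batches))

    @property
    def q(self) -> int:
        return len(self.shared_names)

    def row_index(self) -> dict:
        return {sid: i for i, sid in enumerate(self.subject_ids)}


@dataclass
class LCLMMParams:
    """Parameter point of the model."""

    pi: np.ndarray  # (G,)
    delta: np.ndarray  # (G, D+1)
    beta: np.ndarray  # (q,)
    B: np.ndarray  # (k, k) random-effects covariance
    sigma2: float

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    def validate(self) -> None:
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a strictly positive simplex vector")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        try:
            np.linalg.cholesky(self.B)
        except np.linalg.LinAlgError as err:
            raise ValueError("random-effects covariance must be SPD") from err


def n_free_params(G: int, degree: int, q: int, n_random: int = 2) -> int:
    """Free-parameter count: (G-1) mixing + G(D+1) class-specific + q shared
    + k(k+1)/2 covariance + 1 residual."""
    return (G - 1) + G * (degree + 1) + q + n_random * (n_random + 1) // 2 + 1


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """Bayesian Information Criterion: -2 loglik + p log N (N = subjects)."""
    if n_params < 1 or n_subjects < 1:
        raise ValueError("n_params and n_subjects must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_subjects)


# ---------------------------------------------------------------------------
# Design construction


def build_design(dataset, spec: LCLMMSpec) -> DesignData:
    """Build per-subject design structures from a long-format dataset.

    ``dataset`` is a :class:`~lctraj.cohort.LongitudinalDataset` or a
    DataFrame with columns ``subject_id``, ``t``, the outcome, and the
    shared covariates.  ``age_t0`` (age at time zero) is derived as
    ``age - t`` when absent; ``phase`` expands to indicator columns with the
    earliest phase as reference.  Records with a missing outcome or
    covariate are omitted; subjects left with no usable record are excluded
    with a logged warning.
    """
    df = dataset.records.copy() if hasattr(dataset, "records") else dataset.copy()
    if "age_t0" in spec.shared_covariates and "age_t0" not in df.columns:
        df["age_t0"] = df["age"] - df["t"]

    shared_cols: list[str] = []
    for name in spec.shared_covariates:
        if name == "phase":
            levels = sorted(df["phase"].unique())
            for lev in levels[1:]:  # earliest phase is the reference
                col = f"phase_{lev}"
                df[col] = (df["phase"] == lev).astype(float)
                shared_cols.append(col)
        else:
            shared_cols.append(name)

    needed = ["subject_id", "t", spec.outcome_name, *shared_cols]
    usable = df[needed].dropna()
    n_dropped_subjects = df["subject_id"].nunique() - usable["subject_id"].nunique()
    if n_dropped_subjects > 0:
        logger.warning(
            "%d subject(s) excluded: no usable record for outcome %r",
            n_dropped_subjects,
            spec.outcome_name,
        )

    usable = usable.sort_values(["subject_id", "t"])
    sizes = usable.groupby("subject_id", sort=True).size()
    subject_ids = sizes.index.to_numpy()
    n_random = 2 if spec.random_slope else 1

    S = len(subject_ids)
    m_max = int(sizes.max())
    q = len(shared_cols)
    visit_idx = usable.groupby("subject_id", sort=True).cumcount().to_numpy()
    row_of = {sid: i for i, sid in enumerate(subject_ids)}
    rows = usable["subject_id"].map(row_of).to_numpy()

    mask = np.zeros((S, m_max), dtype=bool)
    mask[rows, visit_idx] = True
    t = np.zeros((S, m_max))
    t[rows, visit_idx] = usable["t"].to_numpy()
    Y = np.zeros((S, m_max))
    Y[rows, visit_idx] = usable[spec.outcome_name].to_numpy()
    X2 = np.stack([t**k for k in range(spec.degree + 1)], axis=-1)
    X2[~mask] = 0.0  # kill the padded t^0 = 1 entries
    X1 = np.zeros((S, m_max, q))
    if q:
        X1[rows, visit_idx] = usable[shared_cols].to_numpy()
    Z = np.stack([np.ones_like(t), t], axis=-1)[..., :n_random]
    Z[~mask] = 0.0
    batch = _Batch(
        ids=subject_ids, Y=Y, X2=X2, X1=X1, Z=Z,
        mask=mask, n_pad=(m_max - sizes.to_numpy()),
    )

    return DesignData(
        batches=[batch],
        subject_ids=subject_ids,
        shared_names=tuple(shared_cols),
        degree=spec.degree,
        n_random=n_random,
    )


# ---------------------------------------------------------------------------
# Likelihood and EM


def _batch_loglik(
    batch: _Batch, params: LCLMMParams, want_moments: bool = False
):
    """Per-subject class-conditional log densities for one batch.

    Returns ``logdens`` (S, G); with ``want_moments`` also the conditional
    random-effect means ``bhat`` (S, G, k), the shared conditional
    covariance ``C`` (S, k, k) and ``trZCZ`` (S,).
    """
    S, m = batch.Y.shape
    G = params.n_classes
    V = (
        np.einsum("smk,kl,snl->smn", batch.Z, params.B, batch.Z)
        + params.sigma2 * np.eye(m)[None]
    )
    sign, logdet = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        raise ValueError("marginal covariance not positive definite")
    Vinv = np.linalg.inv(V)

    mean_shared = np.einsum("smq,q->sm", batch.X1, params.beta)
    mean_class = np.einsum("smp,gp->sgm", batch.X2, params.delta)
    resid = batch.Y[:, None, :] - mean_shared[:, None, :] - mean_class  # (S,G,m)
    rV = np.einsum("sgm,smn->sgn", resid, Vinv)
    quad = (rV * resid).sum(axis=2)
    # padded slots inflate the padded log-density by a known constant
    pad_corr = 0.5 * batch.n_pad * (_LOG2PI + np.log(params.sigma2))
    logdens = -0.5 * (m * _LOG2PI + logdet[:, None] + quad) + pad_corr[:, None]
    if not want_moments:
        return logdens

    ZB = np.einsum("sml,lk->smk", batch.Z, params.B)  # (S, m, k)
    # bhat_{ig} = B Z' Vinv r_{ig}
    BZtVinv = np.einsum("smk,smn->skn", ZB, Vinv)  # (S, k, m)
    bhat = np.einsum("skm,sgm->sgk", BZtVinv, resid)
    C = params.B[None] - np.einsum("skm,sml->skl", BZtVinv, ZB)
    trZCZ = np.einsum("smk,skl,sml->s", batch.Z, C, batch.Z)
    return logdens, bhat, C, trZCZ


def marginal_loglik(params: LCLMMParams, design: DesignData, spec=None) -> float:
    """Observed-data log-likelihood: sum_i log sum_g pi_g N(Y_i; mu_ig, V_i)."""
    params.validate()
    logpi = np.log(params.pi)
    total = 0.0
    for batch in design.batches:
        logdens = _batch_loglik(batch, params)
        total += float(logsumexp(logdens + logpi[None, :], axis=1).sum())
    return total


def _e_step(params: LCLMMParams, design: DesignData):
    """Posterior class weights plus conditional random-effect moments."""
    logpi = np.log(np.maximum(params.pi, 1e-300))
    loglik = 0.0
    per_batch = []
    for batch in design.batches:
        logdens, bhat, C, trZCZ = _batch_loglik(batch, params, want_moments=True)
        joint = logdens + logpi[None, :]
        norm = logsumexp(joint, axis=1)
        loglik += float(norm.sum())
        w = np.exp(joint - norm[:, None])
        per_batch.append((w, bhat, C, trZCZ))
    return loglik, per_batch


def _m_step(params: LCLMMParams, design: DesignData, per_batch) -> LCLMMParams:
    G = params.n_classes
    P = design.degree + 1
    q = design.q
    k = design.n_random
    dim = G * P + q

    # class proportions
    wsum = np.zeros(G)
    n_total = 0
    for (w, *_), batch in zip(per_batch, design.batches):
        wsum += w.sum(axis=0)
        n_total += len(batch.ids)
    pi = np.maximum(wsum / n_total, 1e-12)
    pi = pi / pi.sum()

    # fixed effects: weighted LS of (Y - Z bhat) on [class blocks | shared]
    A = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    for (w, bhat, _, _), batch in zip(per_batch, design.batches):
        Ytil = batch.Y[:, None, :] - np.einsum("smk,sgk->sgm", batch.Z, bhat)
        X2tX2 = np.einsum("smp,smr->spr", batch.X2, batch.X2)
        X2tX1 = np.einsum("smp,smq->spq", batch.X2, batch.X1)
        for g in range(G):
            sl = slice(g * P, (g + 1) * P)
            A[sl, sl] += np.einsum("s,spr->pr", w[:, g], X2tX2)
            if q:
                blk = np.einsum("s,spq->pq", w[:, g], X2tX1)
                A[sl, G * P :] += blk
                A[G * P :, sl] += blk.T
            rhs[sl] += np.einsum("s,smp,sm->p", w[:, g], batch.X2, Ytil[:, g])
        if q:
            A[G * P :, G * P :] += np.einsum("smq,smr->qr", batch.X1, batch.X1)
            rhs[G * P :] += np.einsum("smq,sgm,sg->q", batch.X1, Ytil, w)
    # classes with (numerically) no posterior mass keep their coefficients
    alive = wsum > 1e-8 * n_total
    keep = np.concatenate(
        [np.repeat(alive, P), np.ones(q, dtype=bool)]
    )
    theta = np.concatenate([params.delta.ravel(), params.beta])
    sub = np.ix_(keep, keep)
    theta[keep] = np.linalg.solve(A[sub], rhs[keep])
    delta = theta[: G * P].reshape(G, P)
    beta = theta[G * P :]

    # variance components
    Bnew = np.zeros((k, k))
    rss = 0.0
    n_obs = 0
    for (w, bhat, C, trZCZ), batch in zip(per_batch, design.batches):
        Bnew += np.einsum("sg,sgk,sgl->kl", w, bhat, bhat)
        Bnew += C.sum(axis=0)  # sum_g w_ig = 1 per subject
        mean_shared = np.einsum("smq,q->sm", batch.X1, beta)
        mean_class = np.einsum("smp,gp->sgm", batch.X2, delta)
        r = (
            batch.Y[:, None, :]
            - mean_shared[:, None, :]
            - mean_class
            - np.einsum("smk,sgk->sgm", batch.Z, bhat)
        )
        rss += float(np.einsum("sg,sgm,sgm->", w, r, r))
        rss += float(trZCZ.sum())
        n_obs += int(batch.mask.sum())
    Bnew /= n_total
    Bnew = 0.5 * (Bnew + Bnew.T)
    sigma2 = rss / n_obs
    return LCLMMParams(pi=pi, delta=delta, beta=beta, B=Bnew, sigma2=max(sigma2, 1e-10))


def _run_em(
    params: LCLMMParams,
    design: DesignData,
    tol: float,
    max_iter: int,
) -> tuple[LCLMMParams, list[float], bool]:
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        loglik, per_batch = _e_step(params, design)
        if trace and loglik < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            logger.warning("EM log-likelihood decreased: %r -> %r", trace[-1], loglik)
        if trace and abs(loglik - trace[-1]) < tol * max(1.0, abs(trace[-1])):
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        params = _m_step(params, design, per_batch)
    return params, trace, converged


# ---------------------------------------------------------------------------
# Initialization


def _single_class_start(design: DesignData) -> LCLMMParams:
    """Pooled-OLS start for the G=1 model with heuristic variance split."""
    P = design.degree + 1
    q = design.q
    dim = P + q
    A = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    for batch in design.batches:
        X = np.concatenate([batch.X2, batch.X1], axis=2).reshape(-1, dim)
        y = batch.Y.reshape(-1)
        A += X.T @ X
        rhs += X.T @ y
    theta = np.linalg.solve(A, rhs)
    # split residual variance between subject level and observation level
    rss = 0.0
    for batch in design.batches:
        X = np.concatenate([batch.X2, batch.X1], axis=2).reshape(-1, dim)
        r = batch.Y.reshape(-1) - X @ theta
        r[~batch.mask.reshape(-1)] = 0.0
        rss += float(r @ r)
    var = rss / max(design.n_obs - dim, 1)
    k = design.n_random
    B = np.diag([0.5 * var, 0.01 * var][:k])
    return LCLMMParams(
        pi=np.ones(1),
        delta=theta[:P].reshape(1, P),
        beta=theta[P:],
        B=B,
        sigma2=0.5 * var,
    )


def _subject_means(design: DesignData) -> np.ndarray:
    means = []
    for batch in design.batches:
        means.append(batch.Y.sum(axis=1) / batch.mask.sum(axis=1))
    order = np.argsort(np.concatenate([b.ids for b in design.batches]))
    return np.concatenate(means)[order]


def _quantile_start(
    design: DesignData, base: LCLMMParams, G: int
) -> LCLMMParams:
    """Deterministic start: split subjects into G quantile groups of their
    mean outcome and offset the class intercepts accordingly."""
    mu = _subject_means(design)
    edges = np.quantile(mu, np.linspace(0, 1, G + 1))
    delta = np.tile(base.delta[0], (G, 1))
    overall = mu.mean()
    for g in range(G):
        lo, hi = edges[g], edges[g + 1]
        sel = (mu >= lo) & (mu <= hi) if g == G - 1 else (mu >= lo) & (mu < hi)
        if sel.any():
            delta[g, 0] += mu[sel].mean() - overall
    return LCLMMParams(
        pi=np.full(G, 1.0 / G),
        delta=delta,
        beta=base.beta.copy(),
        B=base.B.copy(),
        sigma2=base.sigma2,
    )


def _subject_features(design: DesignData) -> np.ndarray:
    """Per-subject (level at t = 0, slope) from individual OLS lines."""
    feats = []
    for batch in design.batches:
        t = batch.X2[:, :, 1]
        y = batch.Y
        w = batch.mask.astype(float)
        n_i = w.sum(axis=1, keepdims=True)
        tbar = (t * w).sum(axis=1, keepdims=True) / n_i
        ybar = (y * w).sum(axis=1, keepdims=True) / n_i
        denom = (w * (t - tbar) ** 2).sum(axis=1)
        slope = np.where(
            denom > 1e-12,
            (w * (t - tbar) * (y - ybar)).sum(axis=1) / np.maximum(denom, 1e-12),
            0.0,
        )
        level = ybar[:, 0] - slope * tbar[:, 0]
        feats.append(np.column_stack([level, slope]))
    order = np.argsort(np.concatenate([b.ids for b in design.batches]))
    return np.concatenate(feats, axis=0)[order]


def _start_from_labels(
    design: DesignData, base: LCLMMParams, G: int, labels: np.ndarray
) -> LCLMMParams:
    """Class-specific start from a hard subject partition: per-class
    polynomial OLS on the shared-covariate-adjusted outcome, class shares
    as the mixing start."""
    P = design.degree + 1
    delta = np.tile(base.delta[0], (G, 1))
    pi = np.full(G, 1.0 / G)
    row_of = design.row_index()
    for g in range(G):
        A = np.zeros((P, P))
        rhs = np.zeros(P)
        n_g = 0
        for batch in design.batches:
            sel = np.array([labels[row_of[sid]] == g for sid in batch.ids])
            if not sel.any():
                continue
            X = batch.X2[sel].reshape(-1, P)
            resid = (
                batch.Y[sel] - np.einsum("smq,q->sm", batch.X1[sel], base.beta)
            ).reshape(-1)
            A += X.T @ X
            rhs += X.T @ resid
            n_g += int(sel.sum())
        if n_g > P:
            try:
                delta[g] = np.linalg.solve(A + 1e-8 * np.eye(P), rhs)
            except np.linalg.LinAlgError:
                pass
        pi[g] = max(n_g, 1)
    pi = pi / pi.sum()
    return LCLMMParams(
        pi=pi, delta=delta, beta=base.beta.copy(), B=base.B.copy(), sigma2=base.sigma2
    )


def _kmeans_start(
    design: DesignData, base: LCLMMParams, G: int, rng: np.random.Generator
) -> LCLMMParams:
    """Cluster subjects on (level, slope) features and fit per-cluster
    polynomial means as the class-specific start."""
    from scipy.cluster.vq import kmeans2

    feats = _subject_features(design)
    z = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, labels = kmeans2(z, G, minit="++", seed=rng, missing="warn")
    return _start_from_labels(design, base, G, labels)


def _tail_start(
    design: DesignData, base: LCLMMParams, G: int, tail_share: float
) -> LCLMMParams:
    """Start targeting small extreme classes: the top (G-1) bins of
    ``tail_share`` of subjects by mean level each seed one minority class,
    the remainder the majority class."""
    mu = _subject_means(design)
    order = np.argsort(mu)
    N = len(mu)
    labels = np.zeros(N, dtype=int)
    cut = N
    for g in range(G - 1, 0, -1):
        n_g = max(int(round(tail_share * N)), design.degree + 2)
        labels[order[cut - n_g : cut]] = g
        cut -= n_g
    return _start_from_labels(design, base, G, labels)


def _perturbed_start(
    design: DesignData, base: LCLMMParams, G: int, rng: np.random.Generator
) -> LCLMMParams:
    sd = float(np.std(_subject_means(design)))
    delta = np.tile(base.delta[0], (G, 1))
    delta[:, 0] += rng.normal(0.0, 2.0 * sd, size=G)
    if delta.shape[1] > 1:
        delta[:, 1] += rng.normal(0.0, 0.1 * sd, size=G)
    return LCLMMParams(
        pi=np.full(G, 1.0 / G),
        delta=delta,
        beta=base.beta.copy(),
        B=base.B.copy(),
        sigma2=base.sigma2,
    )


# ---------------------------------------------------------------------------
# Optional quasi-Newton polish of the EM solution


def _pack(params: LCLMMParams, k: int) -> np.ndarray:
    G = params.n_classes
    eta = np.log(params.pi[:-1] / params.pi[-1]) if G > 1 else np.empty(0)
    L = np.linalg.cholesky(params.B)
    tril = []
    for i in range(k):
        for j in range(i + 1):
            tril.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.concatenate(
        [eta, params.delta.ravel(), params.beta, tril, [np.log(params.sigma2)]]
    )


def _unpack(x: np.ndarray, G: int, P: int, q: int, k: int) -> LCLMMParams:
    pos = 0
    if G > 1:
        eta = np.concatenate([x[: G - 1], [0.0]])
        pi = np.exp(eta - logsumexp(eta))
        pos = G - 1
    else:
        pi = np.ones(1)
    delta = x[pos : pos + G * P].reshape(G, P)
    pos += G * P
    beta = x[pos : pos + q]
    pos += q
    L = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(x[pos]) if i == j else x[pos]
            pos += 1
    return LCLMMParams(
        pi=pi, delta=delta, beta=beta, B=L @ L.T, sigma2=float(np.exp(x[pos]))
    )


def _chol_derivs(phi: np.ndarray, k: int) -> list[np.ndarray]:
    """dB/dphi for the log-Cholesky coordinates, in packing order."""
    L = np.zeros((k, k))
    idx = 0
    coords = []
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(phi[idx]) if i == j else phi[idx]
            coords.append((i, j))
            idx += 1
    out = []
    for i, j in coords:
        dL = np.zeros((k, k))
        dL[i, j] = L[i, j] if i == j else 1.0
        out.append(dL @ L.T + L @ dL.T)
    return out


def _mixture_neg_loglik_grad(x: np.ndarray, design: DesignData, G: int):
    """Negative mixture log-likelihood and analytic gradient.

    Uses the EM gradient identity: the score of the observed-data
    likelihood is the posterior-weighted sum of class-conditional scores.
    """
    P = design.degree + 1
    q = design.q
    k = design.n_random
    nk = k * (k + 1) // 2
    params = _unpack(x, G, P, q, k)
    logpi = np.log(np.maximum(params.pi, 1e-300))
    dBs = _chol_derivs(x[(G - 1) + G * P + q : (G - 1) + G * P + q + nk], k)

    loglik = 0.0
    g_eta = np.zeros(G)
    g_delta = np.zeros((G, P))
    g_beta = np.zeros(q)
    g_phi = np.zeros(nk + 1)
    for batch in design.batches:
        m = batch.m
        V = (
            np.einsum("smk,kl,snl->smn", batch.Z, params.B, batch.Z)
            + params.sigma2 * np.eye(m)[None]
        )
        Vinv = np.linalg.inv(V)
        _, logdet = np.linalg.slogdet(V)
        mean_shared = np.einsum("smq,q->sm", batch.X1, params.beta)
        mean_class = np.einsum("smp,gp->sgm", batch.X2, params.delta)
        resid = batch.Y[:, None, :] - mean_shared[:, None, :] - mean_class
        rV = np.einsum("sgm,smn->sgn", resid, Vinv)  # V^{-1} r per class
        quad = (rV * resid).sum(axis=2)
        pad_corr = 0.5 * batch.n_pad * (_LOG2PI + np.log(params.sigma2))
        logdens = -0.5 * (m * _LOG2PI + logdet[:, None] + quad) + pad_corr[:, None]
        joint = logdens + logpi[None, :]
        norm = logsumexp(joint, axis=1)
        loglik += float(norm.sum())
        w = np.exp(joint - norm[:, None])

        g_eta += (w - params.pi[None, :]).sum(axis=0)
        g_delta += np.einsum("sg,smp,sgm->gp", w, batch.X2, rV)
        if q:
            g_beta += np.einsum("sg,smq,sgm->q", w, batch.X1, rV)
        W = np.einsum("smk,smn,snl->skl", batch.Z, Vinv, batch.Z)
        u = np.einsum("smk,sgm->sgk", batch.Z, rV)  # Z' Vinv r per class
        for j, dB in enumerate(dBs):
            tr = np.einsum("skl,lk->s", W, dB)
            quad_d = np.einsum("sgk,kl,sgl,sg->s", u, dB, u, w)
            g_phi[j] += -0.5 * float((tr - quad_d).sum())
        # log sigma2: dV = sigma2 * I on the real slots only
        tr_s = params.sigma2 * np.einsum("smm->s", Vinv) - (
            batch.n_pad * 1.0
        )  # padded diagonal entries contribute sigma2 * (1/sigma2) each
        quad_s = params.sigma2 * np.einsum("sgm,sgm,sg->s", rV, rV, w)
        g_phi[nk] += -0.5 * float((tr_s - quad_s).sum())

    grad = np.concatenate([g_eta[: G - 1], g_delta.ravel(), g_beta, g_phi])
    return -loglik, -grad


def _polish(params: LCLMMParams, design: DesignData, maxiter: int = 300) -> LCLMMParams:
    """Quasi-Newton refinement of the mixture log-likelihood from the EM
    solution, in the log-Cholesky / multinomial-logit parameterization."""
    from scipy.optimize import minimize

    G, P, q, k = (
        params.n_classes,
        design.degree + 1,
        design.q,
        design.n_random,
    )
    x0 = _pack(params, k)
    res = minimize(
        _mixture_neg_loglik_grad,
        x0,
        args=(design, G),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
    )
    if -res.fun < -_mixture_neg_loglik_grad(x0, design, G)[0]:
        return params  # keep EM solution if the polish went downhill
    return _unpack(res.x, G, P, q, k)


# ---------------------------------------------------------------------------
# Fit container and public fitting API


@dataclass
class LCLMMFit:
    """Estimated latent class linear mixed model."""

    spec: LCLMMSpec
    pi: np.ndarray
    delta: np.ndarray
    beta: np.ndarray
    B: np.ndarray
    sigma2: float
    loglik: float
    bic: float
    n_params: int
    posterior: pd.DataFrame  # subjects x classes
    assignment: pd.Series  # modal class (1-based), indexed by subject
    converged: bool
    n_iter: int
    n_starts: int
    loglik_trace: list[float] = field(default_factory=list)
    shared_names: tuple[str, ...] = ()

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    @property
    def class_counts(self) -> pd.Series:
        return self.assignment.value_counts().reindex(
            range(1, self.n_classes + 1), fill_value=0
        )

    @property
    def modal_shares(self) -> np.ndarray:
        return self.class_counts.to_numpy() / len(self.assignment)

    def params(self) -> LCLMMParams:
        return LCLMMParams(
            pi=self.pi, delta=self.delta, beta=self.beta, B=self.B, sigma2=self.sigma2
        )

    def average_posterior_table(self) -> pd.DataFrame:
        """Mean posterior probability vector within each modal class."""
        rows = []
        for g in range(1, self.n_classes + 1):
            sel = self.assignment == g
            rows.append(
                self.posterior[sel].mean(axis=0)
                if sel.any()
                else pd.Series(np.nan, index=self.posterior.columns)
            )
        tbl = pd.DataFrame(rows, index=[f"class_{g}" for g in range(1, self.n_classes + 1)])
        tbl.index.name = "modal_class"
        return tbl

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "outcome": self.spec.outcome_name,
                "n_classes": self.n_classes,
                "degree": self.spec.degree,
                "pi": self.pi.tolist(),
                "delta": self.delta.tolist(),
                "beta": dict(zip(self.shared_names, self.beta.tolist())),
                "B": self.B.tolist(),
                "sigma2": self.sigma2,
                "loglik": self.loglik,
                "bic": self.bic,
                "n_params": self.n_params,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n_starts": self.n_starts,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _canonical_order(params: LCLMMParams, design: DesignData) -> LCLMMParams:
    """Relabel classes in descending modal-assignment size (ties: larger pi,
    then lower original index)."""
    logpi = np.log(np.maximum(params.pi, 1e-300))
    counts = np.zeros(params.n_classes, dtype=int)
    for batch in design.batches:
        logdens = _batch_loglik(batch, params)
        modal = np.argmax(logdens + logpi[None, :], axis=1)
        counts += np.bincount(modal, minlength=params.n_classes)
    order = np.lexsort((np.arange(params.n_classes), -params.pi, -counts))
    return LCLMMParams(
        pi=params.pi[order],
        delta=params.delta[order],
        beta=params.beta,
        B=params.B,
        sigma2=params.sigma2,
    )


def fit_lclmm(
    data,
    spec: LCLMMSpec,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    polish: bool = True,
) -> LCLMMFit:
    """Fit the latent class linear mixed model by multi-start EM.

    ``data`` is a LongitudinalDataset, a long-format DataFrame, or a
    prebuilt :class:`DesignData`.  The best of ``n_starts`` initialisations
    is returned: up to four deterministic starts (equal-quantile split,
    top-5% and top-15% tail splits of subject mean levels, k-means on
    per-subject level/slope features) followed by seeded random
    perturbations of the single-class fit.  Classes are relabelled in
    descending class size.  ``converged`` is False when no start met the
    relative log-likelihood tolerance; a warning is logged in that case.
    With ``polish`` (default) each EM solution is refined by a quasi-Newton
    pass on the mixture log-likelihood with analytic gradients.
    """
    design = data if isinstance(data, DesignData) else build_design(data, spec)
    G = spec.n_classes
    if design.n_subjects < G * (spec.degree + 2):
        raise ValueError(
            f"too few subjects ({design.n_subjects}) for {G} classes of "
            f"degree {spec.degree}"
        )

    base = _single_class_start(design)
    rng = np.random.default_rng(seed)

    best = None
    if G == 1:
        starts = [base]
    else:
        deterministic = [
            _quantile_start(design, base, G),
            _tail_start(design, base, G, 0.05),
            _tail_start(design, base, G, 0.15),
            _kmeans_start(design, base, G, rng),
        ]
        starts = deterministic[:n_starts]
        for _ in range(max(n_starts - len(deterministic), 0)):
            starts.append(_perturbed_start(design, base, G, rng))
    for start in starts:
        params, trace, conv = _run_em(start, design, tol=tol, max_iter=max_iter)
        if polish:
            params = _polish(params, design)
            ll = marginal_loglik(params, design)
            if ll >= trace[-1]:
                trace = trace + [ll]
                conv = True
        if best is None or trace[-1] > best[1][-1]:
            best = (params, trace, conv)
    params, trace, converged = best
    if not converged:
        logger.warning(
            "no EM start converged within %d iterations (tol %g)", max_iter, tol
        )
    params = _canonical_order(params, design)

    posterior, assignment, _ = posterior_probs(params, design)
    p = n_free_params(G, spec.degree, design.q, design.n_random)
    loglik = trace[-1]
    return LCLMMFit(
        spec=spec,
        pi=params.pi,
        delta=params.delta,
        beta=params.beta,
        B=params.B,
        sigma2=params.sigma2,
        loglik=loglik,
        bic=bic(loglik, p, design.n_subjects),
        n_params=p,
        posterior=posterior,
        assignment=assignment,
        converged=converged,
        n_iter=len(trace),
        n_starts=len(starts),
        loglik_trace=trace,
        shared_names=design.shared_names,
    )


def posterior_probs(fit_or_params, data, spec: LCLMMSpec | None = None):
    """Posterior class probabilities, modal assignment and the
    average-posterior table for the supplied data.

    Returns ``(posterior, assignment, avg_table)``: an N x G DataFrame of
    probabilities p_ig = pi_g phi_g(Y_i) / sum_h pi_h phi_h(Y_i) whose rows
    sum to 1, a 1-based modal class Series (posterior ties broken toward
    the lower class index), and the G x G table of mean posterior vectors
    within each modal class.
    """
    if isinstance(fit_or_params, LCLMMFit):
        params = fit_or_params.params()
        spec = fit_or_params.spec
    else:
        params = fit_or_params
    design = data if isinstance(data, DesignData) else build_design(data, spec)

    logpi = np.log(np.maximum(params.pi, 1e-300))
    rows = np.concatenate([b.ids for b in design.batches])
    probs = []
    for batch in design.batches:
        logdens = _batch_loglik(batch, params)
        joint = logdens + logpi[None, :]
        probs.append(np.exp(joint - logsumexp(joint, axis=1)[:, None]))
    probs = np.concatenate(probs, axis=0)
    order = np.argsort(rows)
    posterior = pd.DataFrame(
        probs[order],
        index=pd.Index(rows[order], name="subject_id"),
        columns=[f"class_{g}" for g in range(1, params.n_classes + 1)],
    )
    assignment = pd.Series(
        np.argmax(posterior.to_numpy(), axis=1) + 1,
        index=posterior.index,
        name="modal_class",
    )
    avg_rows = []
    for g in range(1, params.n_classes + 1):
        sel = assignment == g
        avg_rows.append(
            posterior[sel].mean(axis=0)
            if sel.any()
            else pd.Series(np.nan, index=posterior.columns)
        )
    avg = pd.DataFrame(
        avg_rows, index=[f"class_{g}" for g in range(1, params.n_classes + 1)]
    )
    avg.index.name = "modal_class"
    return posterior, assignment, avg


def select_num_classes(
    data,
    spec_family: LCLMMSpec,
    G_range: Sequence[int] = (1, 2, 3, 4, 5),
    min_share: float = 0.02,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    polish: bool = True,
) -> tuple[int, dict[int, LCLMMFit], pd.DataFrame]:
    """Enumerate the number of latent classes by BIC under a minimum
    modal-class-share rule.

    Each candidate G in ``G_range`` is fitted; fits whose smallest modal
    class holds less than ``min_share`` of subjects are disqualified (kept
    in the report with the reason).  Among qualifying fits the lowest BIC
    wins.  Raises if no candidate qualifies.
    """
    if len(G_range) == 0:
        raise ValueError("G_range must be non-empty")
    design = (
        data
        if isinstance(data, DesignData)
        else build_design(data, spec_family.with_classes(1))
    )
    fits: dict[int, LCLMMFit] = {}
    rows = []
    for G in G_range:
        fit = fit_lclmm(
            design,
            spec_family.with_classes(G),
            n_starts=n_starts,
            tol=tol,
            max_iter=max_iter,
            seed=seed + G,
            polish=polish,
        )
        fits[G] = fit
        share = float(fit.modal_shares.min())
        qualified = share >= min_share
        rows.append(
            {
                "G": G,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "bic": fit.bic,
                "min_modal_share": share,
                "converged": fit.converged,
                "qualified": qualified,
                "reason": ""
                if qualified
                else f"smallest class share {share:.4f} < {min_share}",
            }
        )
    report = pd.DataFrame(rows).set_index("G")
    qualifying = report[report["qualified"]]
    if qualifying.empty:
        raise ValueError(
            f"no candidate model satisfies the minimum class share {min_share}"
        )
    selected = int(qualifying["bic"].idxmin())
    return selected, fits, report
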