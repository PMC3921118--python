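"""Class-stratified growth curves of cardiometabolic risk factors.

For each outcome a single joint linear mixed model is fitted across all
groups (the latent BMI classes plus the diabetes-free reference) with
group-specific polynomial time trends, shared confounder adjustments and a
random intercept-and-slope per subject.  Quadratic and cubic time terms in
the diabetes groups are pruned hierarchically when non-significant at the
5% level; the diabetes-free group is always linear in time, since its time
zero is simply the end of follow-up.  Hypothetical-profile predictions with
95% confidence bands and pairwise curve-contrast F-tests (does the curve of
group differences deviate from the zero line?) operate on the joint fixed-
effect covariance.

Skewed outcomes are fitted on the natural-log scale, per the conventional
list: fasting and 2-hour insulin, HOMA-%B, HOMA-IR, adiponectin, IL-1Ra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lctraj.lmm import fit_lmm

logger = logging.getLogger(__name__)

GROUP_FREE = "diabetes-free"

#: Outcomes fitted on the natural-log scale by default.
LOG_OUTCOMES = frozenset(
    {
        "fasting_insulin",
        "insulin_2h",
        "homa_b",
        "homa_ir",
        "adiponectin",
        "il1ra",
    }
)


@dataclass
class ContrastTest:
    """Pairwise curve-contrast F-test between two groups."""

    group_pair: tuple[str, str]
    F_statistic: float
    df_num: int
    df_den: int
    p_value: float


@dataclass
class GrowthCurveFit:
    """Joint per-outcome growth-curve fit across groups.

    ``coef``/``cov``/``degrees`` describe the pruned model used for
    reporting and prediction; ``full_coef``/``full_cov``/``full_degrees``
    keep the unpruned companion fit (every diabetes group at the maximal
    degree) on which curve contrasts are evaluated — contrasting pruned
    models would condition on terms retained for their significance and
    inflate the test.
    """

    outcome: str
    transform: str  # "identity" or "log"
    degrees: dict[str, int]  # retained polynomial degree per group
    coef: pd.Series  # fixed effects, named "<group>|t^k" and shared columns
    cov: pd.DataFrame  # fixed-effect covariance
    shared_names: tuple[str, ...]
    sigma2: float
    re_cov: np.ndarray
    n_obs: int
    n_subjects: int
    loglik: float
    full_degrees: dict[str, int] | None = None
    full_coef: pd.Series | None = None
    full_cov: pd.DataFrame | None = None

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.degrees)

    @property
    def df_den(self) -> int:
        return self.n_obs - len(self.coef)

    def term_name(self, group: str, k: int) -> str:
        return f"{group}|t^{k}"

    def coefficient_table(self) -> pd.DataFrame:
        """Per-group time coefficients with SEs (absent terms as NaN)."""
        max_deg = max(self.degrees.values())
        rows = []
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.coef.index)
        for g, deg in self.degrees.items():
            row: dict[str, float] = {"group": g}
            for k in range(max_deg + 1):
                name = self.term_name(g, k)
                row[f"t^{k}"] = self.coef.get(name, np.nan)
                row[f"se(t^{k})"] = se.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows).set_index("group")


def _group_columns(degrees: dict[str, int]) -> list[tuple[str, int, str]]:
    cols = []
    for g, deg in degrees.items():
        for k in range(deg + 1):
            cols.append((g, k, f"{g}|t^{k}"))
    return cols


def _build_matrix(
    df: pd.DataFrame, degrees: dict[str, int], shared_names: Sequence[str]
) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for g, k, name in _group_columns(degrees):
        X[name] = np.where(df["group"] == g, df["t"] ** k, 0.0)
    for name in shared_names:
        X[name] = df[name].to_numpy(dtype=float)
    return X


def _prepare_frame(
    outcome: str,
    dataset,
    class_labels: pd.Series,
    adjustments: Sequence[str],
    transform: str,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    df = dataset.records.copy() if hasattr(dataset, "records") else dataset.copy()
    if "age_t0" not in df.columns:
        df["age_t0"] = df["age"] - df["t"]
    df["group"] = df["subject_id"].map(class_labels)
    df = df[df["group"].notna()]

    shared: list[str] = ["age_t0", "sex"]
    levels = sorted(df["phase"].unique())
    for lev in levels[1:]:
        col = f"phase_{lev}"
        df[col] = (df["phase"] == lev).astype(float)
        shared.append(col)
    shared.extend(adjustments)

    needed = ["subject_id", "t", "group", outcome, *shared]
    df = df[needed].dropna()
    if transform == "log":
        bad = df[outcome] <= 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-positive value(s) of {outcome} dropped "
                "before log transform",
                stacklevel=3,
            )
            df = df[~bad]
        df = df.assign(**{outcome: np.log(df[outcome])})
    return df, tuple(shared)


def _fit_joint(df, X, outcome, phi0=None):
    frame = pd.concat(
        [df[["subject_id", "t", outcome]].reset_index(drop=True),
         X.reset_index(drop=True)],
        axis=1,
    )
    return fit_lmm(frame, outcome, list(X.columns), phi0=phi0)


def fit_growth_curve(
    outcome: str,
    dataset,
    class_labels: pd.Series,
    max_degree: int = 3,
    prune_alpha: float = 0.05,
    adjustments: Sequence[str] = (),
    transform: str | None = None,
) -> GrowthCurveFit:
    """Fit the joint class-stratified growth curve for one outcome.

    ``class_labels`` maps subject_id to a group label; the label
    ``"diabetes-free"`` marks the reference group, which is forced linear in
    time.  Diabetes groups start at ``max_degree`` and lose their highest-
    order time term (one per refit, largest p first) while its two-sided
    Wald p-value is at or above ``prune_alpha``; lower-order terms are never
    dropped below a retained higher-order term.  ``transform`` defaults to
    natural log for the conventional skewed-outcome list.
    """
    if transform is None:
        transform = "log" if outcome in LOG_OUTCOMES else "identity"
    df, shared = _prepare_frame(outcome, dataset, class_labels, adjustments, transform)
    if df.empty:
        raise ValueError(f"no usable records for outcome {outcome!r}")

    groups = [g for g in sorted(df["group"].unique()) if g != GROUP_FREE]
    if GROUP_FREE in set(df["group"]):
        groups.append(GROUP_FREE)
    if len(groups) < 2:
        raise ValueError("outcome must be observed in at least two groups")

    n_subj = df.groupby("group")["subject_id"].nunique()
    degrees: dict[str, int] = {}
    for g in groups:
        if g == GROUP_FREE:
            degrees[g] = 1
            continue
        deg = max_degree
        while deg > 1 and n_subj[g] < deg + 2:
            deg -= 1
        if deg < max_degree:
            logger.warning(
                "group %r has %d subjects; degree reduced to %d", g, n_subj[g], deg
            )
        degrees[g] = deg

    phi0 = None
    full = None
    while True:
        X = _build_matrix(df, degrees, shared)
        res = _fit_joint(df, X, outcome, phi0=phi0)
        phi0 = res.phi
        if full is None:
            full = (dict(degrees), res.coef, res.cov)  # unpruned companion
        se = np.sqrt(np.diag(res.cov.to_numpy()))
        pvals = pd.Series(
            2.0 * stats.norm.sf(np.abs(res.coef.to_numpy() / se)), index=X.columns
        )
        droppable = []
        for g, deg in degrees.items():
            if g == GROUP_FREE or deg <= 1:
                continue
            name = f"{g}|t^{deg}"
            if pvals[name] >= prune_alpha:
                droppable.append((pvals[name], g))
        if not droppable:
            break
        _, worst = max(droppable)
        degrees[worst] -= 1

    return GrowthCurveFit(
        outcome=outcome,
        transform=transform,
        degrees=degrees,
        coef=res.coef,
        cov=res.cov,
        shared_names=shared,
        sigma2=res.sigma2,
        re_cov=res.B,
        n_obs=len(df),
        n_subjects=df["subject_id"].nunique(),
        loglik=res.loglik,
        full_degrees=full[0],
        full_coef=full[1],
        full_cov=full[2],
    )


def predict_curve(
    fit: GrowthCurveFit,
    profile: Mapping[str, float],
    group: str,
    t_grid: Sequence[float],
    back_transform: bool = False,
) -> pd.DataFrame:
    """Mean curve and 95% confidence band for a hypothetical profile.

    ``profile`` must supply every shared covariate of the fit (e.g. a male
    of 60 years at time zero in the reference phase: ``{"age_t0": 60,
    "sex": 1, "phase_5": 0, ...}``).  Log-scale fits are reported on the log
    scale unless ``back_transform`` is set, which exponentiates mean and
    band (a median curve on the natural scale).
    """
    if group not in fit.degrees:
        raise KeyError(f"unknown group label: {group!r}")
    missing = [s for s in fit.shared_names if s not in profile]
    if missing:
        raise KeyError(f"profile is missing covariates: {missing}")
    t = np.asarray(t_grid, dtype=float)
    deg = fit.degrees[group]
    X = pd.DataFrame(0.0, index=range(len(t)), columns=fit.coef.index)
    for k in range(deg + 1):
        X[fit.term_name(group, k)] = t**k
    for s in fit.shared_names:
        X[s] = float(profile[s])
    mean = X.to_numpy() @ fit.coef.to_numpy()
    var = np.einsum("ij,jk,ik->i", X.to_numpy(), fit.cov.to_numpy(), X.to_numpy())
    half = 1.96 * np.sqrt(np.maximum(var, 0.0))
    out = pd.DataFrame({"t": t, "mean": mean, "lo": mean - half, "hi": mean + half})
    if back_transform and fit.transform == "log":
        out[["mean", "lo", "hi"]] = np.exp(out[["mean", "lo", "hi"]])
    return out


def curve_contrast_test(
    fit: GrowthCurveFit, group_a: str, group_b: str
) -> ContrastTest:
    """F-test of the curve of contrasts between two groups against the zero
    line (no difference in intercept or any time term).

    The contrast spans the union of the two groups' time terms and is
    evaluated on the unpruned joint fit, whose covariance supplies the
    variance block of every contrasted term; a term structurally absent
    from a group (the always-linear diabetes-free reference) contributes a
    coefficient of exactly zero with no sampling variance.  The Wald
    statistic ``c' [L V L']^{-1} c / q`` is referred to F(q, n_obs -
    n_fixed).
    """
    degrees = fit.full_degrees if fit.full_degrees is not None else fit.degrees
    coef = fit.full_coef if fit.full_coef is not None else fit.coef
    cov = fit.full_cov if fit.full_cov is not None else fit.cov
    for g in (group_a, group_b):
        if g not in degrees:
            raise KeyError(f"unknown group label: {g!r}")
    q = max(degrees[group_a], degrees[group_b]) + 1
    names = list(coef.index)
    L = np.zeros((q, len(names)))
    for k in range(q):
        for g, sign in ((group_a, 1.0), (group_b, -1.0)):
            name = fit.term_name(g, k)
            if name in coef.index:
                L[k, names.index(name)] = sign
    c = L @ coef.to_numpy()
    Vc = L @ cov.to_numpy() @ L.T
    try:
        sol = np.linalg.solve(Vc, c)
    except np.linalg.LinAlgError as err:
        bad = int(np.argmin(np.diag(Vc)))
        raise np.linalg.LinAlgError(
            f"singular contrast covariance at term t^{bad} for pair "
            f"({group_a}, {group_b})"
        ) from err
    F = float(c @ sol) / q
    df_den = fit.n_obs - len(coef)
    p = float(stats.f.sf(F, q, df_den)) if F > 0 else 1.0
    return ContrastTest(
        group_pair=(group_a, group_b),
        F_statistic=F,
        df_num=q,
        df_den=df_den,
        p_value=p,
    )
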