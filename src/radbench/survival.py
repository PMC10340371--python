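"""Pooled, cohort-stratified Cox proportional hazards analysis.

Cohorts are pooled into up to four analysis groups crossing outcome type
(first recurrence FR, overall survival OS) with radiotherapy status (RT,
noRT).  Within a group, the Cox model is stratified by cohort: each cohort
keeps its own baseline hazard while the signature coefficient is shared.
Scores are z-scored within the group so the reported hazard ratio is per one
standard deviation of the score.

The partial likelihood is maximized by Newton-Raphson with step-halving;
tied event times use the Efron correction by default (Breslow available).
A vectorized single-covariate path (:func:`cox_scan`) fits thousands of
univariate models simultaneously for genome-wide scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthdata import ClinicalCohortSet
from .signatures import ScoreVector

GROUP_LABELS = ("FR_RT", "FR_noRT", "OS_RT", "OS_noRT")
MONOTONE_BETA = 20.0


@dataclass
class AnalysisGroup:
    """One pooled outcome x treatment group.

    ``patients`` is indexed by sample id with columns time, event,
    cohort_id (the Cox stratum) and rt; ``covariates`` holds columns added
    by :func:`attach_cohort_covariate`.
    """

    label: str
    patients: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(f"unknown group label: {self.label}")

    @property
    def strata(self) -> pd.Series:
        return self.patients["cohort_id"]

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return int(self.patients["event"].sum())


@dataclass
class CoxResult:
    """Hazard ratio per SD with Wald CI/p for the score coefficient."""

    beta: float
    se: float
    hr_per_sd: float
    ci_lower: float
    ci_upper: float
    p: float
    n: int
    n_events: int
    converged: bool
    loglik: float = np.nan
    diagnostics: str = ""
    covariate_results: dict = field(default_factory=dict)


def group_patients(cohorts: ClinicalCohortSet) -> list[AnalysisGroup]:
    """Pool cohorts into the outcome x treatment groups (empty ones omitted)."""
    cl = cohorts.clinical
    groups = []
    for outcome in ("FR", "OS"):
        for rt in (1, 0):
            mask = (cl["outcome_type"] == outcome) & (cl["rt"] == rt)
            if not mask.any():
                continue
            label = f"{outcome}_{'RT' if rt else 'noRT'}"
            groups.append(AnalysisGroup(label=label, patients=cl.loc[mask]))
    return groups


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd


def attach_cohort_covariate(group: AnalysisGroup, covariate_name: str,
                            values: pd.Series,
                            applicable_cohorts: list[str]) -> AnalysisGroup:
    """Add a covariate defined only in some cohorts.

    The column is centered within each applicable cohort; patients outside
    ``applicable_cohorts`` receive 0, which after centering is equivalent to
    cohort-mean imputation and contributes nothing to the partial likelihood
    gradient for those strata.
    """
    pats = group.patients
    col = np.zeros(len(pats))
    for cid in applicable_cohorts:
        mask = (pats["cohort_id"] == cid).to_numpy()
        if not mask.any():
            continue
        ids = pats.index[mask]
        missing = ids.difference(values.index)
        if len(missing):
            raise ValueError(
                f"covariate {covariate_name!r} missing for patients "
                f"{list(missing[:5])} in cohort {cid}")
        v = values.loc[ids].to_numpy(dtype=float)
        col[mask] = v - v.mean()
    cov = pd.DataFrame({covariate_name: col}, index=pats.index)
    if group.covariates is not None:
        cov = pd.concat([group.covariates, cov], axis=1)
    return AnalysisGroup(label=group.label, patients=pats, covariates=cov)


# ---------------------------------------------------------------- internals

def _prep_stratum(time: np.ndarray, event: np.ndarray):
    """Sort by time; precompute risk-set starts and tied-event groups."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    groups = []
    for tt in np.unique(t[e]):
        start = int(np.searchsorted(t, tt, side="left"))
        members = np.nonzero((t == tt) & e)[0]
        groups.append((start, members))
    return order, groups


def _stratum_derivs(beta: np.ndarray, Xs: np.ndarray, groups, ties: str):
    """(loglik, gradient, information) for one pre-sorted stratum."""
    p = Xs.shape[1]
    eta = Xs @ beta
    th = np.exp(eta)
    thX = th[:, None] * Xs
    thXX = thX[:, :, None] * Xs[:, None, :]
    S0 = np.cumsum(th[::-1])[::-1]
    S1 = np.cumsum(thX[::-1], axis=0)[::-1]
    S2 = np.cumsum(thXX[::-1], axis=0)[::-1]
    ll, g, info = 0.0, np.zeros(p), np.zeros((p, p))
    for start, mem in groups:
        d = len(mem)
        S0r, S1r, S2r = S0[start], S1[start], S2[start]
        ll += eta[mem].sum()
        g += Xs[mem].sum(axis=0)
        if ties == "efron" and d > 1:
            s0 = th[mem].sum()
            s1 = thX[mem].sum(axis=0)
            s2 = thXX[mem].sum(axis=0)
            for l in range(d):
                f = l / d
                D = S0r - f * s0
                N1 = S1r - f * s1
                N2 = S2r - f * s2
                ll -= np.log(D)
                g -= N1 / D
                info += N2 / D - np.outer(N1, N1) / D**2
        else:  # breslow, or untied events (identical under both rules)
            ll -= d * np.log(S0r)
            g -= d * S1r / S0r
            info += d * (S2r / S0r - np.outer(S1r, S1r) / S0r**2)
    return ll, g, info


def _cox_newton(time, event, X, strata, ties="efron", max_iter=50,
                tol=1e-9):
    """Stratified Cox Newton-Raphson with step-halving."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    strata = np.asarray(strata)
    prepped = []
    for s in pd.unique(strata):
        mask = strata == s
        if event[mask].sum() == 0:
            continue  # no events: stratum contributes nothing
        order, groups = _prep_stratum(time[mask], event[mask])
        prepped.append((X[mask][order], groups))
    if not prepped:
        raise ValueError("no events in any stratum (all patients censored)")

    def derivs(b):
        ll, g, info = 0.0, np.zeros(p), np.zeros((p, p))
        for Xs, groups in prepped:
            l, gg, ii = _stratum_derivs(b, Xs, groups, ties)
            ll += l
            g += gg
            info += ii
        return ll, g, info

    beta = np.zeros(p)
    ll, g, info = derivs(beta)
    converged = False
    diagnostics = ""
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            diagnostics = "singular information matrix"
            break
        new_beta, new = beta + step, None
        for h in range(30):
            new = derivs(new_beta)
            if new[0] >= ll - 1e-12:
                break
            new_beta = beta + step / 2.0 ** (h + 1)
        delta = new[0] - ll
        beta, (ll, g, info) = new_beta, new
        if abs(delta) < tol:
            converged = True
            break
    if np.any(np.abs(beta) > MONOTONE_BETA):
        converged = False
        diagnostics = diagnostics or "monotone likelihood (|beta| > 20)"
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return beta, se, ll, converged, diagnostics


def fit_cox(group: AnalysisGroup, scores: ScoreVector | pd.Series,
            covariates: pd.DataFrame | None = None,
            ties: str = "efron", zscore_scores: bool = True,
            zscore_scope: str = "group") -> CoxResult:
    """HR per SD of the (z-scored) signature score in a stratified Cox model.

    Scores are standardized within the pooled analysis group by default;
    ``zscore_scope='cohort'`` standardizes within each cohort instead.
    Covariates attached to the group (or passed explicitly) enter as
    additional columns; their coefficients are reported in
    ``covariate_results``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method: {ties}")
    if zscore_scope not in ("group", "cohort"):
        raise ValueError(f"unknown zscore_scope: {zscore_scope}")
    vals = scores.values if isinstance(scores, ScoreVector) else scores
    pats = group.patients
    missing = pats.index.difference(vals.index)
    if len(missing):
        raise ValueError(f"scores missing for patients: {list(missing[:5])}")
    x = vals.loc[pats.index].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite score values")
    if pats["event"].sum() == 0:
        raise ValueError(f"group {group.label}: all patients censored")
    if zscore_scores:
        if zscore_scope == "group":
            x = zscore(x)
        else:
            x = x.copy()
            for cid in pats["cohort_id"].unique():
                m = (pats["cohort_id"] == cid).to_numpy()
                x[m] = zscore(x[m])

    cov_names: list[str] = []
    dropped: list[str] = []
    cols = [x]
    cov = group.covariates
    if covariates is not None:
        cov = covariates if cov is None else pd.concat([cov, covariates], axis=1)
    if cov is not None:
        for name in cov.columns:
            col = cov[name].loc[pats.index].to_numpy(dtype=float)
            if np.ptp(col) == 0:  # constant column carries no information
                dropped.append(name)
                continue
            cols.append(col)
            cov_names.append(name)
    X = np.column_stack(cols)

    beta, se, ll, converged, diag = _cox_newton(
        pats["time"].to_numpy(), pats["event"].to_numpy(), X,
        pats["cohort_id"].to_numpy(), ties=ties)
    b0, s0 = float(beta[0]), float(se[0])
    zstat = b0 / s0
    with np.errstate(over="ignore"):
        hr = float(np.exp(b0))
        ci_lo = float(np.exp(b0 - 1.96 * s0))
        ci_hi = float(np.exp(b0 + 1.96 * s0))
    cov_results = {
        name: {"beta": float(beta[i + 1]), "se": float(se[i + 1]),
               "p": float(2 * norm.sf(abs(beta[i + 1] / se[i + 1])))}
        for i, name in enumerate(cov_names)}
    for name in dropped:
        cov_results[name] = {"beta": 0.0, "se": float("nan"),
                             "p": float("nan")}
    return CoxResult(
        beta=b0, se=s0, hr_per_sd=hr,
        ci_lower=ci_lo, ci_upper=ci_hi,
        p=float(2 * norm.sf(abs(zstat))),
        n=group.n, n_events=group.n_events,
        converged=converged, loglik=float(ll), diagnostics=diag,
        covariate_results=cov_results)


def cox_scan(time, event, Z, strata, ties: str = "efron",
             max_iter: int = 40, tol: float = 1e-9):
    """Vectorized univariate stratified Cox fits for many covariates at once.

    ``Z`` is an n x G matrix (one column per candidate covariate, typically
    z-scored gene expression).  Returns (beta, se, p, converged) arrays of
    length G.  Untied events use a fully vectorized risk-set formulation;
    tied event times fall back to the Efron/Breslow group loop.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    Z = np.asarray(Z, dtype=float)
    n, G = Z.shape
    strata = np.asarray(strata)

    prepped = []
    for s in pd.unique(strata):
        mask = strata == s
        if event[mask].sum() == 0:
            continue
        order, groups = _prep_stratum(time[mask], event[mask])
        Zs = Z[mask][order]
        starts = np.array([g[0] for g in groups], dtype=int)
        mems = [g[1] for g in groups]
        untied = all(len(m) == 1 for m in mems)
        ev_idx = (np.concatenate(mems) if untied and mems
                  else np.array([], dtype=int))
        prepped.append((Zs, groups, starts, ev_idx, untied))
    if not prepped:
        raise ValueError("no events in any stratum (all patients censored)")

    beta = np.zeros(G)
    info = np.full(G, np.nan)
    last_step = np.zeros(G)
    for _ in range(max_iter):
        g = np.zeros(G)
        I = np.zeros(G)
        for Zs, groups, starts, ev_idx, untied in prepped:
            eta = Zs * beta[None, :]
            np.clip(eta, -500, 500, out=eta)
            th = np.exp(eta)
            thZ = th * Zs
            thZZ = thZ * Zs
            S0 = np.cumsum(th[::-1], axis=0)[::-1]
            S1 = np.cumsum(thZ[::-1], axis=0)[::-1]
            S2 = np.cumsum(thZZ[::-1], axis=0)[::-1]
            if untied or ties == "breslow":
                if untied:
                    counts = np.ones(len(starts))[:, None]
                    num = Zs[ev_idx]
                else:
                    counts = np.array([len(m) for _, m in groups])[:, None]
                    num = np.vstack([Zs[m].sum(axis=0) for _, m in groups])
                S0r, S1r, S2r = S0[starts], S1[starts], S2[starts]
                ratio = S1r / S0r
                g += (num - counts * ratio).sum(axis=0)
                I += (counts * (S2r / S0r - ratio**2)).sum(axis=0)
            else:
                for start, mem in groups:
                    d = len(mem)
                    S0r, S1r, S2r = S0[start], S1[start], S2[start]
                    g += Zs[mem].sum(axis=0)
                    if d == 1:
                        ratio = S1r / S0r
                        g -= ratio
                        I += S2r / S0r - ratio**2
                        continue
                    s0 = th[mem].sum(axis=0)
                    s1 = thZ[mem].sum(axis=0)
                    s2 = thZZ[mem].sum(axis=0)
                    for l in range(d):
                        f = l / d
                        D = S0r - f * s0
                        N1 = S1r - f * s1
                        g -= N1 / D
                        I += (S2r - f * s2) / D - (N1 / D) ** 2
        info = I
        safe_I = np.where(I > 1e-12, I, np.inf)
        step = np.clip(g / safe_I, -1.0, 1.0)
        beta = np.clip(beta + step, -25.0, 25.0)
        last_step = np.abs(step)
        if last_step.max() < tol:
            break

    se = np.where(info > 1e-12, 1.0 / np.sqrt(np.where(info > 1e-12, info, 1.0)),
                  np.nan)
    with np.errstate(invalid="ignore"):
        p = 2 * norm.sf(np.abs(beta / se))
    converged = (last_step < 1e-6) & (np.abs(beta) <= MONOTONE_BETA) & (info > 1e-12)
    return beta, se, p, converged
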