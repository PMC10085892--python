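"""Model estimation from person-year panels.

Fits GLMs of the published forms by iteratively-reweighted least squares
under quasi-likelihood (no integer-response requirement for the Poisson
variance family), with step-halving to keep identity-link Poisson/Gamma
fitted means positive. Standard errors are one-way cluster-robust
sandwich estimates grouped by participant with a G/(G-1) small-sample
factor. Bidirectional stepwise selection tests covariate blocks with
cluster-robust Wald tests at a fixed significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_spec import CoefficientSet, ModelTerm, Service
from .predictor import design_matrix

__all__ = [
    "FitResult", "SelectionTrace", "fitting_terms", "fit_glm", "fit_irls",
    "fit_two_part", "compare_candidates", "stepwise_select",
    "hosmer_lemeshow", "park_slope", "SingularDesignError",
]

FAMILIES = ("gaussian", "poisson", "gamma", "binomial")
LINKS = ("identity", "log", "logit")
# variance power: V(mu) = mu ** power (binomial handled separately)
_VAR_POWER = {"gaussian": 0.0, "poisson": 1.0, "gamma": 2.0}


class SingularDesignError(np.linalg.LinAlgError):
    def __init__(self, terms: Sequence[str]):
        self.terms = list(terms)
        super().__init__(f"singular design; collinear terms: {self.terms}")


@dataclass
class FitResult:
    coefficients: dict[str, float]
    cluster_robust_se: dict[str, float]
    family: str
    link: str
    n_obs: int
    n_clusters: int
    converged: bool
    diagnostics: dict = dc_field(default_factory=dict)
    cov: Optional[np.ndarray] = None  # cluster-robust, term order
    term_names: list[str] = dc_field(default_factory=list)
    dropped_terms: list[str] = dc_field(default_factory=list)

    def coef_array(self) -> np.ndarray:
        return np.asarray([self.coefficients[t] for t in self.term_names])


@dataclass
class SelectionTrace:
    steps: list[tuple[int, str, str, float]]  # (step, add|drop, group, p)
    final_groups: list[str]
    final_fit: Optional[FitResult] = None


# ------------------------------------------------------------------ families

def _inv_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(eta)
    if link == "logit":
        return 1.0 / (1.0 + np.exp(-eta))
    raise ValueError(f"unknown link {link!r}")


def _link_fun(mu: np.ndarray, link: str) -> np.ndarray:
    if link == "identity":
        return mu
    if link == "log":
        return np.log(mu)
    if link == "logit":
        return np.log(mu / (1.0 - mu))
    raise ValueError(f"unknown link {link!r}")


def _dmu_deta(eta: np.ndarray, mu: np.ndarray, link: str) -> np.ndarray:
    if link == "identity":
        return np.ones_like(eta)
    if link == "log":
        return mu
    return mu * (1.0 - mu)  # logit


def _variance(mu: np.ndarray, family: str) -> np.ndarray:
    if family == "binomial":
        return mu * (1.0 - mu)
    power = _VAR_POWER[family]
    if power == 0.0:
        return np.ones_like(mu)
    return mu ** power


def _safe_mu(mu: np.ndarray, family: str, floor: float) -> np.ndarray:
    """Clamp fitted means into the family's variance-function domain.

    Under the identity link the mean can be driven to (or past) zero for a
    few extreme rows; flooring the mean inside V(mu) keeps the IRLS
    weights finite so the quasi-score equation stays smooth.
    """
    if family in ("poisson", "gamma"):
        return np.maximum(mu, floor)
    if family == "binomial":
        return np.clip(mu, 1e-10, 1.0 - 1e-10)
    return mu


def _deviance(y: np.ndarray, mu: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.sum((y - mu) ** 2))
    if family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))
    if family == "gamma":
        return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))
    # binomial (0/1 responses)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y > 0.5, np.log(mu), np.log(1.0 - mu))
    return float(-2.0 * np.sum(ll))


# ---------------------------------------------------------------------- IRLS

def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        keep: list[int] = []
        bad: list[str] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
            else:
                bad.append(names[j])
        raise SingularDesignError(bad)


def fit_irls(X: np.ndarray, y: np.ndarray, family: str, link: str,
             clusters: np.ndarray, names: Optional[Sequence[str]] = None,
             max_iter: int = 100, tol: float = 1e-9,
             mu_floor: float = 1.0
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, float]:
    """Quasi-likelihood IRLS with step-halving.

    ``mu_floor`` bounds the variance function away from zero for the
    Poisson/Gamma families under the identity link (in response units;
    the default of 1 is negligible for annual costs in pounds). Returns
    (beta, cluster-robust covariance, fitted mu, converged, deviance).
    Assumes column 0 of X is the intercept.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    _check_rank(X, names)

    ybar = float(np.mean(y))
    if family == "binomial":
        ybar = min(max(ybar, 1e-6), 1.0 - 1e-6)
    elif family in ("poisson", "gamma"):
        ybar = max(ybar, mu_floor)
    beta = np.zeros(p)
    beta[0] = _link_fun(np.asarray([ybar]), link)[0]
    eta = X @ beta
    mu = _inv_link(eta, link)
    dev = _deviance(y, _safe_mu(mu, family, mu_floor), family)

    converged = False
    for _ in range(max_iter):
        mu_s = _safe_mu(mu, family, mu_floor)
        d = _dmu_deta(eta, mu_s, link)
        V = _variance(mu_s, family)
        w = d ** 2 / np.maximum(V, 1e-300)
        z = eta + (y - mu) / np.where(d == 0, 1e-300, d)
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            raise SingularDesignError(names)
        # step-halve on non-finite or clearly increasing deviance
        step = 1.0
        accepted = False
        for _half in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = _inv_link(eta_c, link)
            if np.all(np.isfinite(mu_c)):
                dev_c = _deviance(y, _safe_mu(mu_c, family, mu_floor),
                                  family)
                if math.isfinite(dev_c) and \
                        dev_c <= dev + 1e-6 * (abs(dev) + 1.0):
                    accepted = True
                    break
            step *= 0.5
        if not accepted:
            break
        delta_dev = abs(dev - dev_c)
        delta_beta = float(np.max(np.abs(cand - beta))
                           / (np.max(np.abs(beta)) + 1.0))
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        if delta_dev <= tol * (abs(dev) + 0.1) or delta_beta <= 1e-10:
            converged = True
            break

    cov = _cluster_cov(X, y, mu, eta, family, link, clusters, mu_floor)
    return beta, cov, mu, converged, dev


def _cluster_cov(X: np.ndarray, y: np.ndarray, mu: np.ndarray,
                 eta: np.ndarray, family: str, link: str,
                 clusters: np.ndarray, mu_floor: float = 1.0) -> np.ndarray:
    mu_s = _safe_mu(mu, family, mu_floor)
    d = _dmu_deta(eta, mu_s, link)
    V = np.maximum(_variance(mu_s, family), 1e-300)
    w = d ** 2 / V
    bread = np.linalg.inv(X.T @ (X * w[:, None]))
    scores = X * ((y - mu) * d / V)[:, None]
    codes, _ = pd.factorize(clusters)
    G = int(codes.max()) + 1
    sg = np.zeros((G, X.shape[1]))
    np.add.at(sg, codes, scores)
    meat = sg.T @ sg
    factor = G / (G - 1) if G > 1 else 1.0
    return factor * bread @ meat @ bread


# ------------------------------------------------------------------- fitting

def fitting_terms(model: CoefficientSet,
                  drop_groups: Sequence[str] = ("censoring",)
                  ) -> list[ModelTerm]:
    """Estimable term list for a published model.

    Merged temporal categories are folded into the preceding term (shared
    coefficient, union of levels), and the unpublished censoring covariate
    is dropped.
    """
    out: list[ModelTerm] = []
    for t in model.terms:
        if t.group in drop_groups:
            continue
        if t.merged_with_preceding and out and out[-1].field == t.field:
            prev = out[-1]
            out[-1] = replace(prev, levels=prev.levels + t.levels)
            continue
        out.append(t)
    return out


def _resolve_response(panel, response: str) -> tuple[pd.DataFrame, str]:
    df = panel.data if hasattr(panel, "data") else panel
    if response == "primary_cost":
        if "primary_excluded" in df.columns:
            df = df[df["primary_excluded"] != "yes"]
        return df, "primary_gbp"
    if response == "hospital_conditional_cost":
        df = df[df["hospital_any"] == "yes"]
        return df, "hospital_gbp"
    if response in df.columns:  # raw column name
        return df, response
    raise ValueError(f"unknown response {response!r}")


def _drop_degenerate(X: np.ndarray, terms: Sequence[ModelTerm]
                     ) -> tuple[np.ndarray, list[ModelTerm], list[str]]:
    keep, dropped = [], []
    for j, t in enumerate(terms):
        if t.kind != "intercept" and np.ptp(X[:, j]) == 0.0:
            dropped.append(t.name)
        else:
            keep.append(j)
    return X[:, keep], [terms[j] for j in keep], dropped


def _drop_separated(X: np.ndarray, terms: list[ModelTerm], y: np.ndarray
                    ) -> tuple[np.ndarray, list[ModelTerm], list[str]]:
    """Drop binary columns whose active rows have a constant 0/1 outcome
    (quasi-separation: the logistic MLE for them does not exist)."""
    keep, dropped = [], []
    for j, t in enumerate(terms):
        col = X[:, j]
        is_binary = t.kind != "intercept" and np.isin(col, (0.0, 1.0)).all()
        if is_binary:
            active = y[col == 1.0]
            if active.size > 0 and active.min() == active.max():
                dropped.append(t.name)
                continue
        keep.append(j)
    return X[:, keep], [terms[j] for j in keep], dropped


def fit_glm(panel, response: str, terms: Sequence[ModelTerm],
            family: str = "poisson", link: str = "identity",
            cluster_field: str = "person_id") -> FitResult:
    """Fit one GLM with cluster-robust standard errors.

    ``response`` is ``primary_cost`` (rows with registration gaps
    excluded), ``hospital_conditional_cost`` (rows with any hospital cost)
    or a raw column name. Zero-variance design columns are dropped with a
    notice in ``dropped_terms``.
    """
    df, ycol = _resolve_response(panel, response)
    y = df[ycol].to_numpy(dtype=float)
    if family in ("poisson", "gamma") and np.any(y < 0):
        raise ValueError("negative responses not allowed for this family")
    if family == "gamma" and np.any(y <= 0):
        raise ValueError("gamma family requires strictly positive responses")
    X, names = design_matrix(df, None, terms=terms)
    X, used, dropped = _drop_degenerate(X, list(terms))
    if family == "binomial":
        X, used, separated = _drop_separated(X, used, y)
        dropped += separated
    names = [t.name for t in used]
    clusters = df[cluster_field].to_numpy()
    n_clusters = int(pd.unique(clusters).size)
    if n_clusters < 2:
        raise ValueError("need >= 2 clusters")

    beta, cov, mu, converged, dev = fit_irls(X, y, family, link, clusters,
                                             names)
    se = np.sqrt(np.diag(cov))
    resid = y - mu
    pearson = float(np.sum(resid ** 2 / np.maximum(
        _variance(mu, family), 1e-300)))
    dof = max(len(y) - len(names), 1)
    diagnostics = {
        "deviance": dev,
        "pearson_dispersion": pearson / dof,
        "quasi_aic": dev + 2 * len(names),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "mae": float(np.mean(np.abs(resid))),
        "pred_obs_corr": (float(np.corrcoef(mu, y)[0, 1])
                          if np.ptp(mu) > 0 else float("nan")),
    }
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        cluster_robust_se=dict(zip(names, se.tolist())),
        family=family, link=link, n_obs=len(y), n_clusters=n_clusters,
        converged=converged, diagnostics=diagnostics, cov=cov,
        term_names=names, dropped_terms=dropped)


def fit_two_part(panel, part1_model: CoefficientSet,
                 part2_model: CoefficientSet,
                 cluster_field: str = "person_id",
                 part2_family: str = "poisson",
                 part2_link: str = "identity"
                 ) -> tuple[FitResult, FitResult]:
    """Fit the hospital two-part model.

    Part 1 is a logistic regression for the any-cost indicator, fitted on
    annual periods where incurring cost is not certain (same-year-CRV
    periods are excluded, matching the published certainty rule); part 2
    is fitted on periods with any cost.
    """
    df = panel.data if hasattr(panel, "data") else panel
    if "hospital_any" not in df.columns:
        raise ValueError("panel has no hospital_any column")

    mask = np.ones(len(df), dtype=bool)
    for rule in part1_model.certainty_rules:
        mask &= (df[rule.when_field] != rule.when_level).to_numpy()
    df1 = df[mask].copy()
    df1["_any"] = (df1["hospital_any"] == "yes").astype(float)
    y1 = df1["_any"].to_numpy()
    terms1 = fitting_terms(part1_model)
    if y1.min() == y1.max():
        raise ValueError("part-1 outcome is constant (complete separation)")
    part1_fit = fit_glm(df1, "_any", terms1, family="binomial", link="logit",
                        cluster_field=cluster_field)
    if y1.mean() > 0.999:
        part1_fit.diagnostics["separation_warning"] = True
    p_hat = _inv_link(
        design_matrix(df1, None, terms=[t for t in terms1 if t.name in
                                        part1_fit.coefficients])[0]
        @ part1_fit.coef_array(), "logit")
    hl_stat, hl_p = hosmer_lemeshow(y1, p_hat)
    part1_fit.diagnostics["hosmer_lemeshow"] = hl_stat
    part1_fit.diagnostics["hosmer_lemeshow_p"] = hl_p

    if (df["hospital_any"] == "yes").sum() == 0:
        raise ValueError("no rows with hospital costs; part 2 sample empty")
    part2_fit = fit_glm(panel, "hospital_conditional_cost",
                        fitting_terms(part2_model), family=part2_family,
                        link=part2_link, cluster_field=cluster_field)
    return part1_fit, part2_fit


# -------------------------------------------------------------- diagnostics

def park_slope(y: np.ndarray, mu: np.ndarray) -> float:
    """Modified Park test: slope of log squared residuals on log fitted
    means (slope ~0 Gaussian-consistent, ~1 Poisson, ~2 Gamma)."""
    r2 = (y - mu) ** 2
    ok = (mu > 0) & (r2 > 0)
    if ok.sum() < 3:
        return float("nan")
    lx = np.log(mu[ok])
    ly = np.log(r2[ok])
    if np.ptp(lx) == 0:
        return float("nan")
    return float(np.polyfit(lx, ly, 1)[0])


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, n_groups: int = 10
                    ) -> tuple[float, float]:
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_groups)
    stat = 0.0
    used = 0
    for idx in splits:
        if len(idx) == 0:
            continue
        o = float(np.sum(y[idx]))
        e = float(np.sum(p[idx]))
        n = len(idx)
        if e <= 0 or e >= n:
            continue
        stat += (o - e) ** 2 / e + ((n - o) - (n - e)) ** 2 / (n - e)
        used += 1
    dof = max(used - 2, 1)
    return stat, float(stats.chi2.sf(stat, dof))


def compare_candidates(panel, response: str, terms: Sequence[ModelTerm],
                       candidates: Optional[Sequence[tuple[str, str]]] = None,
                       k_folds: int = 5,
                       cluster_field: str = "person_id") -> pd.DataFrame:
    """Rank candidate family/link pairs for a cost response.

    Per candidate: deviance-based quasi-AIC, cluster-wise cross-validated
    RMSE/MAE, predicted-vs-observed correlation and the modified Park-test
    slope. Ranking: Park consistency (|slope - variance power|), ties
    broken by CV RMSE then by parsimony (all candidates share a term set,
    so parsimony only matters for externally supplied lists).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if candidates is None:
        candidates = [(f, l) for f in ("gaussian", "poisson", "gamma")
                      for l in ("identity", "log")]
    df, ycol = _resolve_response(panel, response)
    clusters = df[cluster_field].to_numpy()
    codes, uniq = pd.factorize(clusters)
    fold_of_cluster = np.arange(len(uniq)) % k_folds
    fold = fold_of_cluster[codes]

    rows = []
    for family, link in candidates:
        try:
            fit = fit_glm(df, ycol, terms, family=family, link=link,
                          cluster_field=cluster_field)
            if not fit.converged:
                raise RuntimeError("did not converge")
            used = [t for t in terms if t.name in fit.coefficients]
            X, _ = design_matrix(df, None, terms=used)
            y = df[ycol].to_numpy(dtype=float)
            mu = _inv_link(X @ fit.coef_array(), link)
            slope = park_slope(y, mu)
            se_cv, ae_cv = [], []
            for k in range(k_folds):
                tr, te = fold != k, fold == k
                b, _, _, _, _ = fit_irls(X[tr], y[tr], family, link,
                                         clusters[tr])
                pred = _inv_link(X[te] @ b, link)
                se_cv.append((y[te] - pred) ** 2)
                ae_cv.append(np.abs(y[te] - pred))
            rows.append({
                "family": family, "link": link, "converged": True,
                "quasi_aic": fit.diagnostics["quasi_aic"],
                "cv_rmse": float(np.sqrt(np.mean(np.concatenate(se_cv)))),
                "cv_mae": float(np.mean(np.concatenate(ae_cv))),
                "pred_obs_corr": fit.diagnostics["pred_obs_corr"],
                "park_slope": slope,
                "park_gap": abs(slope - _VAR_POWER[family]),
                "n_terms": len(used),
            })
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            rows.append({"family": family, "link": link, "converged": False,
                         "notice": str(exc)})
    out = pd.DataFrame(rows)
    ok = out[out["converged"]].sort_values(
        ["park_gap", "cv_rmse", "n_terms"]).reset_index(drop=True)
    failed = out[~out["converged"]].reset_index(drop=True)
    return pd.concat([ok, failed], ignore_index=True)


# ----------------------------------------------------------------- stepwise

def _wald_group_p(fit: FitResult, group_names: Sequence[str]) -> float:
    idx = [fit.term_names.index(n) for n in group_names
           if n in fit.term_names]
    if not idx:
        return 1.0
    b = fit.coef_array()[idx]
    V = fit.cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(stat, len(idx)))


def stepwise_select(panel, response: str, full_terms: Sequence[ModelTerm],
                    alpha: float = 0.01, family: str = "poisson",
                    link: str = "identity",
                    cluster_field: str = "person_id",
                    max_steps: int = 200) -> SelectionTrace:
    """Bidirectional stepwise selection over covariate blocks.

    Categorical covariates enter and leave as blocks (all their levels
    together, via the term ``group``); the intercept is never dropped.
    Backward: drop the block with the largest cluster-robust Wald p-value
    if it is >= alpha. Forward: re-admit the excluded block with the
    smallest p-value if it is < alpha. Ties are broken by canonical term
    order, making runs deterministic.
    """
    groups: list[str] = []
    members: dict[str, list[ModelTerm]] = {}
    for t in full_terms:
        if t.group not in members:
            members[t.group] = []
            groups.append(t.group)
        members[t.group].append(t)
    if "intercept" not in members:
        raise ValueError("full term set must include the intercept")
    droppable = [g for g in groups if g != "intercept"]

    included = set(groups)
    steps: list[tuple[int, str, str, float]] = []
    seen: set[frozenset] = {frozenset(included)}
    step_no = 0

    def fit_for(gs: set) -> FitResult:
        terms = [t for g in groups if g in gs for t in members[g]]
        return fit_glm(panel, response, terms, family=family, link=link,
                       cluster_field=cluster_field)

    current = fit_for(included)
    while step_no < max_steps:
        # backward elimination
        worst_g, worst_p = None, -1.0
        for g in droppable:
            if g not in included:
                continue
            p = _wald_group_p(current, [t.name for t in members[g]])
            if p > worst_p + 1e-15:
                worst_g, worst_p = g, p
        if worst_g is not None and worst_p >= alpha:
            cand = included - {worst_g}
            if frozenset(cand) in seen:
                break
            included = cand
            seen.add(frozenset(included))
            step_no += 1
            steps.append((step_no, "drop", worst_g, worst_p))
            current = fit_for(included)
            continue
        # forward selection
        best_g, best_p = None, 2.0
        for g in droppable:
            if g in included:
                continue
            try:
                trial = fit_for(included | {g})
            except (ValueError, np.linalg.LinAlgError):
                continue
            p = _wald_group_p(trial, [t.name for t in members[g]])
            if p < best_p - 1e-15:
                best_g, best_p = g, p
        if best_g is not None and best_p < alpha:
            cand = included | {best_g}
            if frozenset(cand) in seen:
                break
            included = cand
            seen.add(frozenset(included))
            step_no += 1
            steps.append((step_no, "add", best_g, best_p))
            current = fit_for(included)
            continue
        break

    return SelectionTrace(steps=steps,
                          final_groups=[g for g in groups if g in included],
                          final_fit=current)
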