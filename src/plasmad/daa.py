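"""Per-analyte differential abundance: OLS association, three-stage gating,
sample-size-weighted Stouffer meta-analysis, BH-FDR, and tertile odds ratios.

Status coding is CO=0 / AD=1 throughout, so a positive effect means higher
abundance in AD.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from plasmad.datamodel import ProteomicsMatrix

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_at_draw", "sex")


def _design_matrix(samples: pd.DataFrame, covariates, include_cohort: bool) -> pd.DataFrame:
    """Build the shared design: intercept, status, covariates (+ cohort dummies)."""
    sub = samples[samples["clinical_status"].isin(["CO", "AD"])]
    design = pd.DataFrame(index=sub.index)
    design["intercept"] = 1.0
    design["status"] = (sub["clinical_status"] == "AD").astype(float)
    for cov in covariates:
        if cov == "sex":
            design["sex"] = (sub["sex"] == "male").astype(float)
        else:
            design[cov] = pd.to_numeric(sub[cov])
    if include_cohort:
        dummies = pd.get_dummies(sub["cohort"], prefix="cohort", drop_first=True, dtype=float)
        design = pd.concat([design, dummies], axis=1)
    return design


def _ols_status_term(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on X; returns (beta, se, two-sided p) for column 1 (status)."""
    n, k = X.shape
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        return np.nan, np.nan, np.nan
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0:
        return float(beta[1]), np.nan, np.nan
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[1]), float(se), float(p)


def fit_analyte_regression(
    matrix,
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    include_cohort: bool = False,
    min_per_arm: int = 10,
) -> pd.DataFrame:
    """Per-analyte OLS of (z-normalized) abundance on AD status + covariates.

    ``matrix`` may be a :class:`ProteomicsMatrix` or a samples x analytes
    DataFrame.  Complete-case analysis per analyte; analytes with fewer than
    ``min_per_arm`` complete cases in either arm, or a rank-deficient design,
    are skipped with a warning.

    Returns a DataFrame with columns ``analyte_id, effect, se, p, n,
    direction``.
    """
    values = matrix.values if isinstance(matrix, ProteomicsMatrix) else matrix
    design = _design_matrix(samples, covariates, include_cohort)
    common = values.index.intersection(design.index)
    if common.empty:
        raise ValueError("no samples shared between matrix and metadata")
    values = values.loc[common]
    design = design.loc[common]
    complete_design = design.notna().all(axis=1).to_numpy()
    X_all = design.to_numpy(dtype=float)
    Y = values.to_numpy(dtype=float)
    status = X_all[:, 1]

    rows = []
    skipped = 0
    finite_y = np.isfinite(Y)
    no_missing = bool(finite_y.all()) and bool(complete_design.all())
    if no_missing:
        # fast path: one shared design for every analyte
        n, k = X_all.shape
        xtx_inv = np.linalg.inv(X_all.T @ X_all)
        betas = xtx_inv @ (X_all.T @ Y)
        resid = Y - X_all @ betas
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            tvals = betas[1, :] / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        for j, aid in enumerate(values.columns):
            rows.append((aid, betas[1, j], se[j], pvals[j], n))
    else:
        for j, aid in enumerate(values.columns):
            ok = finite_y[:, j] & complete_design
            y = Y[ok, j]
            X = X_all[ok]
            s = status[ok]
            if (s == 1).sum() < min_per_arm or (s == 0).sum() < min_per_arm:
                skipped += 1
                continue
            beta, se_j, p = _ols_status_term(X, y)
            if not np.isfinite(se_j):  # rank-deficient or degenerate design
                skipped += 1
                log.warning("skipping %s: rank-deficient or degenerate design", aid)
                continue
            rows.append((aid, beta, se_j, p, len(y)))
    if skipped:
        log.warning("skipped %d analyte(s) with too few complete cases", skipped)
    out = pd.DataFrame(rows, columns=["analyte_id", "effect", "se", "p", "n"])
    out["direction"] = np.sign(out["effect"]).astype(int)
    return out


def three_stage_select(
    discovery: pd.DataFrame, replication: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep analytes with discovery p < alpha, replication p < alpha, and
    matching effect sign; returns the merged table with stage columns."""
    merged = discovery.merge(
        replication, on="analyte_id", suffixes=("_disc", "_rep"), how="inner"
    )
    if merged.empty:
        raise ValueError("no analytes shared between discovery and replication")
    keep = (
        (merged["p_disc"] < alpha)
        & (merged["p_rep"] < alpha)
        & (np.sign(merged["effect_disc"]) == np.sign(merged["effect_rep"]))
        & (np.sign(merged["effect_disc"]) != 0)
    )
    out = merged[keep].reset_index(drop=True)
    out["stage"] = "replicated"
    return out


def meta_analyze(discovery: pd.DataFrame, replication: pd.DataFrame) -> pd.DataFrame:
    """Sample-size-weighted Stouffer combination of two association tables.

    z_i = sign(effect_i) * Phi^-1(1 - p_i/2); Z = sum(sqrt(n_i) z_i) /
    sqrt(sum n_i); combined two-sided p = 2 Phi(-|Z|).  p-values of exactly 0
    are clamped to the smallest positive float with a warning.
    """
    merged = discovery.merge(
        replication, on="analyte_id", suffixes=("_disc", "_rep"), how="inner"
    )
    if merged.empty:
        raise ValueError("no analytes shared between stages")
    tiny = np.finfo(float).tiny
    zs = []
    for tag in ("disc", "rep"):
        p = merged[f"p_{tag}"].to_numpy(dtype=float)
        if (p <= 0).any():
            log.warning("clamping %d p-value(s) of 0 to tiny", int((p <= 0).sum()))
            p = np.clip(p, tiny, 1.0)
        z = np.sign(merged[f"effect_{tag}"].to_numpy()) * stats.norm.isf(p / 2.0)
        zs.append(z)
    w = np.sqrt(np.column_stack([merged["n_disc"], merged["n_rep"]]).astype(float))
    Z = (w[:, 0] * zs[0] + w[:, 1] * zs[1]) / np.sqrt((w**2).sum(axis=1))
    p_comb = 2.0 * stats.norm.sf(np.abs(Z))
    n_tot = merged["n_disc"] + merged["n_rep"]
    effect = (
        merged["effect_disc"] * merged["n_disc"] + merged["effect_rep"] * merged["n_rep"]
    ) / n_tot
    return pd.DataFrame(
        {
            "analyte_id": merged["analyte_id"],
            "z": Z,
            "p": np.clip(p_comb, tiny, 1.0),
            "effect": effect,
            "n": n_tot,
            "direction": np.sign(Z).astype(int),
        }
    )


def bh_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with an explicit test universe ``m``.

    ``m`` defaults to ``len(pvals)`` and must be at least that; q values are
    returned in input order, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclasses.dataclass
class OddsRatioResult:
    analyte_id: str
    or_value: float
    ci_low: float
    ci_high: float
    transformed_or: float
    n_tertile1: int
    n_tertile3: int
    p: float
    separation: bool = False


def _tertile_assignment(values: pd.Series) -> pd.Series:
    """Rank-based tertiles (1/2/3), ties broken stably by sample id."""
    ordered = values.reset_index()
    ordered.columns = ["sample_id", "value"]
    ordered = ordered.sort_values(["value", "sample_id"], kind="stable")
    n = len(ordered)
    thirds = np.concatenate(
        [np.full(len(chunk), i + 1) for i, chunk in enumerate(np.array_split(np.arange(n), 3))]
    )
    return pd.Series(thirds, index=ordered["sample_id"].to_numpy()).reindex(values.index)


def tertile_odds_ratio(
    matrix,
    samples: pd.DataFrame,
    analyte: str,
    covariates=DEFAULT_COVARIATES,
    include_cohort: bool = False,
    min_per_cell: int = 5,
) -> OddsRatioResult:
    """Logistic OR of AD comparing top vs bottom tertile of one analyte.

    Tertile boundaries come from the pooled CO+AD distribution; the middle
    tertile is excluded.  OR = exp(coefficient of the 3rd-tertile indicator)
    with a Wald 95% CI; ``transformed_or = max(OR, 1/OR)``.
    """
    values = matrix.values if isinstance(matrix, ProteomicsMatrix) else matrix
    design = _design_matrix(samples, covariates, include_cohort)
    sub = pd.concat([values[analyte].rename("value"), design], axis=1, join="inner").dropna()
    tert = _tertile_assignment(sub["value"])
    sub = sub[tert.isin([1, 3])]
    tert = tert.loc[sub.index]
    y = sub["status"]
    for t in (1, 3):
        n_case = int(((tert == t) & (y == 1)).sum())
        n_ctrl = int(((tert == t) & (y == 0)).sum())
        if n_case < min_per_cell or n_ctrl < min_per_cell:
            raise ValueError(
                f"tertile {t} has {n_case} cases / {n_ctrl} controls "
                f"(need >= {min_per_cell} each)"
            )
    X = sub.drop(columns=["value", "status"]).copy()
    X.insert(1, "tertile3", (tert == 3).astype(float))
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = fit.params["tertile3"]
        se = fit.bse["tertile3"]
        pval = fit.pvalues["tertile3"]
        if not np.isfinite(se) or se > 50:
            raise np.linalg.LinAlgError
    except Exception:
        separation = True
        fit = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
        coef = fit.params["tertile3"]
        se, pval = np.inf, np.nan
    or_value = float(np.exp(coef))
    lo = float(np.exp(coef - 1.959963984540054 * se))
    hi = float(np.exp(coef + 1.959963984540054 * se))
    return OddsRatioResult(
        analyte_id=analyte,
        or_value=or_value,
        ci_low=lo,
        ci_high=hi,
        transformed_or=max(or_value, 1.0 / or_value),
        n_tertile1=int((tert == 1).sum()),
        n_tertile3=int((tert == 3).sum()),
        p=float(pval) if np.isfinite(se) else np.nan,
        separation=separation,
    )


def run_three_stage(
    discovery_matrix,
    discovery_samples,
    replication_matrix,
    replication_samples,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    m_total: int | None = None,
    covariates=DEFAULT_COVARIATES,
    min_per_arm: int = 10,
) -> dict:
    """Convenience pipeline: discovery + replication regressions, gating,
    meta-analysis, and BH over the meta p-values with universe ``m_total``.

    Returns a dict with ``discovery``, ``replication``, ``selected``,
    ``meta`` (with ``fdr_q`` column) and ``significant`` tables.
    """
    disc = fit_analyte_regression(
        discovery_matrix, discovery_samples, covariates, min_per_arm=min_per_arm
    )
    rep = fit_analyte_regression(
        replication_matrix,
        replication_samples,
        covariates,
        include_cohort=replication_samples["cohort"].nunique() > 1,
        min_per_arm=min_per_arm,
    )
    selected = three_stage_select(disc, rep, alpha=alpha)
    if m_total is None:
        m_total = len(disc)
    out = {"discovery": disc, "replication": rep, "selected": selected}
    if selected.empty:
        meta = pd.DataFrame(
            columns=["analyte_id", "z", "p", "effect", "n", "direction", "fdr_q"]
        )
    else:
        sel_ids = selected["analyte_id"]
        meta = meta_analyze(
            disc[disc["analyte_id"].isin(sel_ids)], rep[rep["analyte_id"].isin(sel_ids)]
        )
        meta["fdr_q"] = bh_adjust(meta["p"].to_numpy(), m=m_total)
    out["meta"] = meta
    out["significant"] = meta[meta["fdr_q"] < fdr_q].reset_index(drop=True)
    return out
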