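"""Sparse predictive-panel selection and frozen transfer evaluation.

Pipeline: stratified train/test split -> cross-validated L1 logistic path
over a descending lambda grid (covariates unpenalized) -> the
"90%-of-best" lambda rule -> unpenalized logistic refit with age + sex ->
a frozen model (weights + cutoff + standardization constants) applied to
any dataset without re-estimation -> plain or matched-undersampled metric
evaluation and horizon AUCs.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

_UNPEN_SCALE = 1e3  # scaling trick: huge column scale makes the L1 penalty negligible


def split_train_test(
    samples: pd.DataFrame,
    train_frac: float = 0.7,
    stratify_by: str = "clinical_status",
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified split: round(train_frac * n) of each stratum goes to train.

    Nearest-integer rounding per stratum; deterministic under ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for _, group in samples.groupby(stratify_by, sort=True):
        ids = np.array(group.index)
        if len(ids) < 2:
            raise ValueError(f"stratum with fewer than 2 samples ({len(ids)})")
        n_train = int(np.floor(train_frac * len(ids) + 0.5))
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return train_ids, test_ids


@dataclasses.dataclass
class LassoPath:
    lambdas: np.ndarray          # strictly decreasing
    cv_perf: np.ndarray          # mean validation performance per lambda
    cv_perf_folds: np.ndarray    # (n_lambda, k_folds)
    selected: list               # per-lambda analyte set from the full-train fit
    metric: str                  # "auc" or "deviance"


def _l1_logistic(X_pen, X_unpen, y, lam, seed=0):
    """L1-penalized logistic with unpenalized covariate columns.

    Equivalent to minimizing (1/n) sum loss + lam * sum|beta_pen|; covariates
    escape the penalty via a large column rescale.  Returns (coef_pen,
    coef_unpen, intercept).
    """
    n = len(y)
    X = np.hstack([X_pen, X_unpen * _UNPEN_SCALE]) if X_unpen.size else X_pen
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        intercept_scaling=100.0,
        max_iter=1000,
        tol=1e-5,
        random_state=seed,
    )
    clf.fit(X, y)
    coef = clf.coef_.ravel()
    p = X_pen.shape[1]
    coef_pen = coef[:p]
    coef_unpen = coef[p:] * _UNPEN_SCALE
    return coef_pen, coef_unpen, float(clf.intercept_[0])


def _predict_linear(X_pen, X_unpen, coef_pen, coef_unpen, intercept):
    eta = X_pen @ coef_pen + intercept
    if X_unpen.size:
        eta = eta + X_unpen @ coef_unpen
    return eta


def _validation_perf(eta, y, metric):
    prob = 1.0 / (1.0 + np.exp(-eta))
    if metric == "auc":
        return roc_auc_score(y, prob)
    # explained binomial deviance relative to the null model on the fold
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    ll = np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob))
    pbar = np.clip(np.mean(y), eps, 1 - eps)
    ll0 = np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar))
    return (ll - ll0) / (-ll0)


def lasso_path_cv(
    X: pd.DataFrame,
    y,
    covariates: pd.DataFrame | None = None,
    k_folds: int = 5,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-2,
    metric: str = "auc",
    dfmax: int | None = 150,
    seed: int = 0,
) -> LassoPath:
    """Cross-validated L1 logistic path over candidate analytes.

    ``X`` holds candidate analyte values (rows = samples); ``covariates``
    (e.g. age, sex) are included unpenalized.  Predictors are standardized
    within each training fold only.  ``metric`` is the validation measure
    recorded per lambda: "auc" (default) or "deviance" (explained binomial
    deviance).
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate analyte")
    if metric not in ("auc", "deviance"):
        raise ValueError(f"unknown metric {metric!r}")
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < k_folds:
        raise ValueError("a class has fewer samples than folds")
    Xv = X.to_numpy(dtype=float)
    Cv = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((len(y), 0))

    def _standardize(train_block, *blocks):
        # missing cells impute to the training mean, i.e. 0 after standardizing
        mu = np.nanmean(train_block, axis=0)
        sd = np.nanstd(train_block, axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return [np.nan_to_num((b - mu) / sd) for b in blocks]

    # glmnet-style grid anchored at the smallest lambda zeroing everything
    Xs_full, = _standardize(Xv, Xv)
    resid = y - y.mean()
    lam_max = np.abs(Xs_full.T @ resid).max() / len(y)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    folds = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_data = []
    for tr, va in folds.split(Xv, y):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold contains a single class")
        Xtr, Xva = _standardize(Xv[tr], Xv[tr], Xv[va])
        if Cv.shape[1]:
            Ctr, Cva = _standardize(Cv[tr], Cv[tr], Cv[va])
        else:
            Ctr, Cva = Cv[tr], Cv[va]
        fold_data.append((Xtr, Xva, Ctr, Cva, y[tr], y[va]))

    Xs, = _standardize(Xv, Xv)
    Cs, = _standardize(Cv, Cv) if Cv.shape[1] else (Cv,)
    perf_rows = []
    selected = []
    kept_lambdas = []
    for lam in lambdas:
        # full-train fit defines the selected set; also drives the dfmax stop
        cp, _, _ = _l1_logistic(Xs, Cs, y, lam, seed)
        active = list(X.columns[np.abs(cp) > 1e-10])
        if dfmax is not None and len(active) > dfmax and kept_lambdas:
            break  # glmnet-style early exit: path already denser than useful
        row = np.empty(k_folds)
        for f, (Xtr, Xva, Ctr, Cva, ytr, yva) in enumerate(fold_data):
            fcp, fcu, fb0 = _l1_logistic(Xtr, Ctr, ytr, lam, seed)
            eta = _predict_linear(Xva, Cva, fcp, fcu, fb0)
            row[f] = _validation_perf(eta, yva, metric)
        perf_rows.append(row)
        selected.append(active)
        kept_lambdas.append(lam)
    perf = np.vstack(perf_rows)
    return LassoPath(
        lambdas=np.asarray(kept_lambdas),
        cv_perf=perf.mean(axis=1),
        cv_perf_folds=perf,
        selected=selected,
        metric=metric,
    )


def select_lambda_90(
    path: LassoPath, retention: float = 0.90, baseline: float = 0.0
) -> tuple[float, list]:
    """Largest lambda retaining ``retention`` of the best CV performance.

    ``baseline`` anchors the retention scale: with the default 0 the rule is
    the absolute ratio (perf >= retention * max); for an AUC path a baseline
    of 0.5 retains 90% of the performance *above chance*, i.e. perf >=
    baseline + retention * (max - baseline).  Returns ``(lambda_star,
    selected_analytes_at_lambda_star)``.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    if path.lambdas.size == 0:
        raise ValueError("empty path")
    threshold = baseline + retention * (path.cv_perf.max() - baseline)
    for i in range(len(path.lambdas)):  # descending lambda order
        if path.cv_perf[i] >= threshold:
            return float(path.lambdas[i]), list(path.selected[i])
    raise AssertionError("unreachable: the max always satisfies the threshold")


@dataclasses.dataclass
class FrozenPanelModel:
    """A fitted panel: analyte weights + covariates + cutoff, frozen for transfer."""

    analyte_ids: list
    coefficients: dict           # name -> weight, incl. covariates
    intercept: float
    cutoff: float                # probability units
    standardization: dict        # analyte -> {"mean": mu, "sd": sd}
    covariates: list
    metadata: dict = dataclasses.field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame, covariates: pd.DataFrame | None = None):
        eta = np.full(len(X), self.intercept)
        for aid in self.analyte_ids:
            st = self.standardization[aid]
            z = (X[aid].to_numpy(dtype=float) - st["mean"]) / st["sd"]
            eta = eta + self.coefficients[aid] * np.nan_to_num(z)  # missing -> train mean
        for cov in self.covariates:
            if covariates is None or cov not in covariates.columns:
                raise ValueError(f"missing covariate {cov!r}")
            eta = eta + self.coefficients[cov] * covariates[cov].to_numpy(dtype=float)
        return eta

    def predict_proba(self, X, covariates=None) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X, covariates)))

    def predict_positive(self, X, covariates=None) -> np.ndarray:
        return self.predict_proba(X, covariates) >= self.cutoff

    def coefficient_hash(self) -> int:
        items = tuple(sorted(self.coefficients.items())) + (self.intercept, self.cutoff)
        return hash(items)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FrozenPanelModel":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


def refit_and_freeze(
    X: pd.DataFrame,
    y,
    covariates: pd.DataFrame,
    selected,
    cutoff_rule: str = "youden",
    seed: int = 0,
) -> FrozenPanelModel:
    """Unpenalized logistic refit of the selected analytes + covariates.

    Selected analytes are standardized with training means/sds (stored in the
    frozen model); covariates enter as-is (sex must already be numeric 0/1).
    ``cutoff_rule``: "youden" (J-maximizing training ROC threshold) or "p50"
    (probability 0.5).  On separation, a tiny-ridge fallback is used and the
    model flagged.
    """
    if cutoff_rule not in ("youden", "p50"):
        raise ValueError(f"unknown cutoff_rule {cutoff_rule!r}")
    y = np.asarray(y, dtype=float)
    selected = sorted(selected)
    stand = {}
    cols = {}
    for aid in selected:
        v = X[aid].to_numpy(dtype=float)
        mu, sd = float(np.nanmean(v)), float(np.nanstd(v, ddof=0))
        sd = sd if sd > 0 else 1.0
        stand[aid] = {"mean": mu, "sd": sd}
        cols[aid] = np.nan_to_num((v - mu) / sd)
    design = pd.DataFrame(cols, index=X.index)
    for cov in covariates.columns:
        design[cov] = covariates[cov].to_numpy(dtype=float)
    design.insert(0, "intercept", 1.0)
    flagged = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=500)
        params = fit.params
        if not np.all(np.isfinite(fit.bse)) or np.abs(params).max() > 1e3:
            raise np.linalg.LinAlgError("separation")
    except Exception as exc:
        log.warning("logistic refit flagged (%s); tiny-ridge fallback", exc)
        flagged = True
        clf = LogisticRegression(l1_ratio=0.0, C=1e4, max_iter=5000)
        clf.fit(design.drop(columns="intercept"), y)
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_.ravel()]), index=design.columns
        )
    coefficients = {name: float(params[name]) for name in design.columns if name != "intercept"}
    model = FrozenPanelModel(
        analyte_ids=selected,
        coefficients=coefficients,
        intercept=float(params["intercept"]),
        cutoff=0.5,
        standardization=stand,
        covariates=list(covariates.columns),
        metadata={"seed": seed, "n_train": int(len(y)), "flagged": flagged},
    )
    if cutoff_rule == "youden":
        prob = model.predict_proba(X, covariates)
        fpr, tpr, thresholds = roc_curve(y, prob)
        j = tpr - fpr
        best = np.argmax(j)
        cutoff = float(thresholds[best])
        model.cutoff = float(np.clip(cutoff, 1e-6, 1 - 1e-6))
    return model


@dataclasses.dataclass
class EvaluationReport:
    mode: str
    metrics: pd.DataFrame  # rows: metric; columns: value (plain) or mean/min/max

    def value(self, metric: str, stat: str = "value") -> float:
        return float(self.metrics.loc[metric, stat])


_METRICS = ("auc", "accuracy", "sensitivity", "specificity", "npv", "ppv")


def _metric_row(y, prob, cutoff):
    pred = prob >= cutoff
    y = np.asarray(y, dtype=bool)
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())

    def _safe(num, den):
        return num / den if den else np.nan

    return {
        "auc": roc_auc_score(y, prob) if 0 < y.sum() < len(y) else np.nan,
        "accuracy": _safe(tp + tn, len(y)),
        "sensitivity": _safe(tp, tp + fn),
        "specificity": _safe(tn, tn + fp),
        "npv": _safe(tn, tn + fn),
        "ppv": _safe(tp, tp + fp),
    }


def evaluate_model(
    model: FrozenPanelModel,
    X: pd.DataFrame,
    covariates: pd.DataFrame,
    labels,
    mode: str = "plain",
    n_iter: int = 100,
    match: tuple = ("sex",),
    match_frame: pd.DataFrame | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate a frozen model without re-estimation.

    ``plain`` computes each metric once at the frozen cutoff.  ``undersampled``
    draws, per iteration, equal-size case/control subsets with exactly matched
    composition over the ``match`` columns (taken from ``match_frame`` or
    ``covariates``), without replacement, and reports mean/min/max.
    """
    y = np.asarray(labels, dtype=float)
    prob = model.predict_proba(X, covariates)
    if mode == "plain":
        row = _metric_row(y, prob, model.cutoff)
        metrics = pd.DataFrame({"value": pd.Series(row)}).loc[list(_METRICS)]
        return EvaluationReport(mode="plain", metrics=metrics)
    if mode != "undersampled":
        raise ValueError(f"unknown mode {mode!r}")

    source = match_frame if match_frame is not None else covariates
    cells = source[list(match)].astype(str).agg("|".join, axis=1).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_iter):
        take = []
        for cell in np.unique(cells):
            case_idx = np.where((cells == cell) & (y == 1))[0]
            ctrl_idx = np.where((cells == cell) & (y == 0))[0]
            m = min(len(case_idx), len(ctrl_idx))
            if m == 0:
                continue
            take.append(rng.choice(case_idx, m, replace=False))
            take.append(rng.choice(ctrl_idx, m, replace=False))
        if not take:
            raise ValueError("too few samples to match composition")
        idx = np.concatenate(take)
        ys, ps = y[idx], prob[idx]
        assert (ys == 1).sum() == (ys == 0).sum()
        rows.append(_metric_row(ys, ps, model.cutoff))
    frame = pd.DataFrame(rows)
    metrics = pd.DataFrame(
        {"mean": frame.mean(), "min": frame.min(), "max": frame.max()}
    ).loc[list(_METRICS)]
    return EvaluationReport(mode="undersampled", metrics=metrics)


def horizon_auc(
    model: FrozenPanelModel,
    X: pd.DataFrame,
    covariates: pd.DataFrame,
    durations,
    events,
    horizons=(5.0, 10.0, 15.0),
) -> dict[float, float]:
    """AUC of frozen-model scores for conversion within each horizon (years).

    Positives: converters with event time <= h.  Negatives: subjects followed
    at least h years without conversion by h.  Censored-before-h
    non-converters are excluded.  A horizon with an empty class yields a
    missing entry with a warning.
    """
    prob = model.predict_proba(X, covariates)
    dur = np.asarray(durations, dtype=float)
    ev = np.asarray(events, dtype=int)
    out: dict[float, float] = {}
    for h in horizons:
        pos = (ev == 1) & (dur <= h)
        neg = (dur >= h) & ~pos
        keep = pos | neg
        if pos.sum() == 0 or neg.sum() == 0:
            log.warning("horizon %.1f: no positives or no negatives; skipped", h)
            continue
        out[float(h)] = float(roc_auc_score(pos[keep], prob[keep]))
    return out
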