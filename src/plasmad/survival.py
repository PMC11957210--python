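"""Time-to-event construction, Cox models, Kaplan-Meier summaries, and
CDR-SB decline slopes with rank-sum group comparison."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


def build_time_to_event(
    samples: pd.DataFrame,
    cdr_visits: pd.DataFrame,
    onset: pd.Series | None = None,
    onset_rule: str = "midpoint",
    baseline_window_years: float = 1.0,
) -> pd.DataFrame:
    """Construct (duration, event) for cognitively-normal-at-draw subjects.

    Eligibility: the CDR visit nearest the draw age must have CDR = 0 and
    the subject needs at least one later assessment.  Converters (any later
    visit with CDR > 0) get ``duration = onset_age - age_at_draw`` and
    ``event = 1``; non-converters are censored at their last CDR visit.
    Onset age comes from ``onset`` (sample_id -> age) when supplied,
    otherwise from the midpoint between the last CDR=0 visit and the first
    CDR>0 visit (``onset_rule="midpoint"``) or that first CDR>0 visit itself
    (``onset_rule="first_positive"``).  Subjects with non-positive duration
    (onset before draw) are excluded with a warning.
    """
    if onset_rule not in ("midpoint", "first_positive"):
        raise ValueError(f"unknown onset_rule {onset_rule!r}")
    rows = []
    excluded = 0
    visits_by_subject = dict(tuple(cdr_visits.groupby("sample_id")))
    for sid, rec in samples.iterrows():
        visits = visits_by_subject.get(sid)
        if visits is None or len(visits) < 2:
            continue
        visits = visits.sort_values("visit_age", kind="stable")
        draw_age = float(rec["age_at_draw"])
        nearest = (visits["visit_age"] - draw_age).abs().idxmin()
        if visits.loc[nearest, "cdr_global"] != 0:
            continue
        if abs(visits.loc[nearest, "visit_age"] - draw_age) > baseline_window_years:
            continue
        post = visits[visits["visit_age"] > visits.loc[nearest, "visit_age"]]
        if post.empty:
            continue
        positive = post[post["cdr_global"] > 0]
        if not positive.empty:
            if onset is not None and sid in onset.index and np.isfinite(onset.loc[sid]):
                onset_age = float(onset.loc[sid])
            else:
                first_pos = float(positive["visit_age"].iloc[0])
                if onset_rule == "midpoint":
                    prior_normal = visits[
                        (visits["visit_age"] < first_pos) & (visits["cdr_global"] == 0)
                    ]
                    last_normal = float(prior_normal["visit_age"].iloc[-1])
                    onset_age = 0.5 * (last_normal + first_pos)
                else:
                    onset_age = first_pos
            duration = onset_age - draw_age
            event = 1
        else:
            duration = float(visits["visit_age"].iloc[-1]) - draw_age
            event = 0
        if duration <= 0:
            excluded += 1
            log.warning("excluding %s: non-positive duration %.3f", sid, duration)
            continue
        rows.append((sid, duration, event))
    if excluded:
        log.warning("excluded %d subject(s) with non-positive duration", excluded)
    out = pd.DataFrame(rows, columns=["sample_id", "duration", "event"]).set_index("sample_id")
    keep_cols = [c for c in ("age_at_draw", "sex") if c in samples.columns]
    return out.join(samples[keep_cols])


@dataclasses.dataclass
class CoxResult:
    exposure: str
    ln_hr: float
    se: float
    p: float
    n: int
    n_events: int
    flagged: bool = False


def cox_regression(
    inputs: pd.DataFrame,
    exposure: str,
    covariates=("age_at_draw", "sex"),
    min_events: int = 10,
) -> CoxResult:
    """Cox partial-likelihood fit (Efron ties) for one exposure + covariates.

    ``inputs`` needs ``duration``, ``event``, the exposure column and the
    covariates.  Monotone likelihood / separation is flagged rather than
    raised.
    """
    df = inputs[["duration", "event", exposure, *covariates]].dropna().copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "male").astype(float)
    n_events = int(df["event"].sum())
    if n_events < min_events:
        raise ValueError(f"only {n_events} events (need >= {min_events})")
    cph = CoxPHFitter()
    flagged = False
    try:
        cph.fit(df, duration_col="duration", event_col="event")
        ln_hr = float(cph.params_[exposure])
        se = float(cph.standard_errors_[exposure])
        p = float(cph.summary.loc[exposure, "p"])
        if not np.isfinite(se) or se > 50 or abs(ln_hr) > 20:
            flagged = True
    except Exception as exc:  # monotone likelihood, singular information, ...
        log.warning("Cox fit flagged for %s: %s", exposure, exc)
        cph = CoxPHFitter(penalizer=1e-4)
        cph.fit(df, duration_col="duration", event_col="event")
        ln_hr = float(cph.params_[exposure])
        se = float(cph.standard_errors_[exposure])
        p = float(cph.summary.loc[exposure, "p"])
        flagged = True
    return CoxResult(
        exposure=exposure, ln_hr=ln_hr, se=se, p=p, n=len(df), n_events=n_events,
        flagged=flagged,
    )


def per_analyte_cox(
    inputs: pd.DataFrame,
    analyte_values: pd.DataFrame,
    covariates=("age_at_draw", "sex"),
    min_events: int = 10,
) -> pd.DataFrame:
    """Run :func:`cox_regression` for every analyte column; returns a table."""
    rows = []
    for aid in analyte_values.columns:
        df = inputs.join(analyte_values[aid].rename("exposure"), how="inner")
        try:
            res = cox_regression(df, "exposure", covariates, min_events)
        except ValueError:
            continue
        rows.append((aid, res.ln_hr, res.se, res.p, res.n, res.n_events, res.flagged))
    return pd.DataFrame(
        rows, columns=["analyte_id", "ln_hr", "se", "p", "n", "n_events", "flagged"]
    )


def cox_score_test(durations, events, group) -> tuple[float, float]:
    """Score test at beta=0 for a single binary covariate, no tie handling.

    Independent of the partial-likelihood fitter; with distinct event times
    this equals the log-rank test.  Returns (chi2, two-sided p).
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(group, dtype=float)
    order = np.argsort(d, kind="stable")
    d, e, x = d[order], e[order], x[order]
    U = 0.0
    I = 0.0
    for i in np.where(e == 1)[0]:
        at_risk = d >= d[i]
        n_r = at_risk.sum()
        xbar = x[at_risk].mean()
        U += x[i] - xbar
        I += (x[at_risk] ** 2).mean() - xbar**2
    if I <= 0:
        return 0.0, 1.0
    chi2 = U**2 / I
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def km_summary(inputs: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Product-limit survival estimates with at-risk counts at event times."""
    frames = []
    if group is None:
        groups = [("all", inputs)]
    else:
        groups = list(inputs.groupby(group))
    for label, df in groups:
        if df.empty:
            raise ValueError(f"empty group {label!r}")
        km = KaplanMeierFitter()
        km.fit(df["duration"], df["event"])
        table = km.event_table.copy()
        surv = km.survival_function_["KM_estimate"]
        out = pd.DataFrame(
            {
                "group": label,
                "time": table.index,
                "at_risk": table["at_risk"].to_numpy(),
                "events": table["observed"].to_numpy(),
                "censored": table["censored"].to_numpy(),
                "survival": surv.reindex(table.index).to_numpy(),
            }
        )
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def cdr_sb_slope(
    cdr_visits: pd.DataFrame,
    draw_info: pd.Series,
    window_days: float = 180.0,
) -> tuple[pd.DataFrame, int]:
    """Per-subject CDR-SB slope (units/year) from initial to last record.

    The initial record is the visit closest to the draw age within
    ``window_days`` on either side (ties broken toward the pre-draw record);
    the last record is the latest visit.  Subjects failing the window or with
    no later record are excluded and counted.
    """
    window_years = window_days / DAYS_PER_YEAR
    rows = []
    excluded = 0
    for sid, visits in cdr_visits.groupby("sample_id"):
        if sid not in draw_info.index:
            excluded += 1
            continue
        draw_age = float(draw_info.loc[sid])
        visits = visits.sort_values("visit_age", kind="stable")
        delta = visits["visit_age"] - draw_age
        in_window = visits[delta.abs() <= window_years]
        if in_window.empty:
            excluded += 1
            continue
        dist = (in_window["visit_age"] - draw_age).abs()
        best = dist.min()
        candidates = in_window[np.isclose(dist, best)]
        pre = candidates[candidates["visit_age"] <= draw_age]
        initial = (pre if not pre.empty else candidates).iloc[0]
        later = visits[visits["visit_age"] > initial["visit_age"]]
        if later.empty:
            excluded += 1
            continue
        last = later.iloc[-1]
        span = float(last["visit_age"] - initial["visit_age"])
        rows.append(
            (
                sid,
                float(initial["cdr_sb"]),
                span,
                (float(last["cdr_sb"]) - float(initial["cdr_sb"])) / span,
                len(visits),
            )
        )
    out = pd.DataFrame(
        rows, columns=["sample_id", "baseline_cdr_sb", "years_spanned", "slope", "n_visits"]
    ).set_index("sample_id")
    return out, excluded


def compare_slopes(
    slopes: pd.Series, group_labels: pd.Series, exact_max_n: int = 25
) -> tuple[float, pd.DataFrame]:
    """Two-sided Wilcoxon rank-sum comparison of slopes between two groups.

    Exact when combined n <= ``exact_max_n`` and there are no ties; normal
    approximation with tie correction otherwise.  Returns (p, per-group
    summary with n/mean/median).
    """
    labels = pd.Series(group_labels).reindex(slopes.index)
    uniq = [u for u in pd.unique(labels.dropna())]
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    a = slopes[labels == uniq[0]].dropna().to_numpy()
    b = slopes[labels == uniq[1]].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    summary = pd.DataFrame(
        {
            "group": uniq,
            "n": [len(a), len(b)],
            "mean": [a.mean(), b.mean()],
            "median": [np.median(a), np.median(b)],
        }
    )
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        log.warning("all slope values identical; p = 1")
        return 1.0, summary
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), summary
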