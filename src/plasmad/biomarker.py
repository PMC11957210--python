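"""Gaussian-mixture dichotomization of continuous biomarkers and AT status.

A two-component univariate Gaussian mixture (unequal variances) is fitted to
z-scored biomarker values; the dichotomization cutoff is the point between
the two component means where the posterior membership probabilities are
equal, back-transformed to the raw scale.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

POSITIVITY_DIRECTIONS = ("high_is_positive", "low_is_positive")

#: conventional positivity directions for the supported biomarker columns
DEFAULT_DIRECTIONS = {
    "csf_abeta42": "low_is_positive",
    "csf_ptau181": "high_is_positive",
    "pet_composite": "high_is_positive",
    "plasma_ptau217": "high_is_positive",
}


@dataclasses.dataclass
class BiomarkerCutoff:
    means: tuple[float, float]     # component means on the z scale, ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    cutoff_z: float
    cutoff_raw: float
    positivity_direction: str
    degenerate: bool = False
    bic_preferred_components: int = 2


def _posterior_log_ratio(x, w, mu, sd):
    return (
        np.log(w[0]) + stats.norm.logpdf(x, mu[0], sd[0])
        - np.log(w[1]) - stats.norm.logpdf(x, mu[1], sd[1])
    )


def fit_gmm_cutoff(
    values,
    positivity_direction: str,
    seed: int = 0,
    min_n: int = 50,
    max_iter: int = 500,
) -> BiomarkerCutoff:
    """Fit a 2-component GMM to z-scored values and locate the equal-posterior
    cutoff between the component means.

    The raw-scale cutoff is recovered by inverting the z-transform.  A
    degenerate fit (component weight < 0.01, or BIC preferring a single
    component) is flagged, not raised.
    """
    if positivity_direction not in POSITIVITY_DIRECTIONS:
        raise ValueError(f"unknown positivity_direction {positivity_direction!r}")
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < min_n:
        raise ValueError(f"need >= {min_n} non-missing values, got {len(vals)}")
    center, scale = vals.mean(), vals.std(ddof=1)
    if scale <= 0:
        raise ValueError("zero variance in biomarker values")
    z = ((vals - center) / scale).reshape(-1, 1)

    def _fit(k):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            init_params="kmeans",
            n_init=3,
            max_iter=max_iter,
            random_state=seed,
        ).fit(z)
        return gm

    gm = _fit(2)
    if not gm.converged_:
        raise RuntimeError("EM did not converge within max_iter")
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.ravel()[order])
    w = gm.weights_[order]

    bics = {k: _fit(k).bic(z) for k in (1, 2, 3)}
    preferred = min(bics, key=bics.get)
    degenerate = bool(w.min() < 0.01 or preferred == 1)
    if degenerate:
        log.warning(
            "degenerate mixture fit (min weight %.3g, BIC prefers %d component(s))",
            w.min(), preferred,
        )

    lo, hi = mu[0] + 1e-9, mu[1] - 1e-9
    if hi <= lo:
        cutoff_z = float(mu.mean())
    else:
        f = lambda x: _posterior_log_ratio(x, w, mu, sd)
        if f(lo) * f(hi) < 0:
            cutoff_z = float(optimize.brentq(f, lo, hi, xtol=1e-12))
        else:
            # extreme weights can push the equal-posterior point outside the
            # inter-mean interval; fall back to the in-interval minimizer
            grid = np.linspace(lo, hi, 1001)
            cutoff_z = float(grid[np.argmin(np.abs(f(grid)))])
    return BiomarkerCutoff(
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        weights=(float(w[0]), float(w[1])),
        cutoff_z=cutoff_z,
        cutoff_raw=float(cutoff_z * scale + center),
        positivity_direction=positivity_direction,
        degenerate=degenerate,
        bic_preferred_components=int(preferred),
    )


def dichotomize(values, cutoff: BiomarkerCutoff) -> pd.Series:
    """Map raw biomarker values to positivity (True/False; NaN stays missing)."""
    v = pd.Series(values, dtype=float)
    if cutoff.positivity_direction == "low_is_positive":
        out = v < cutoff.cutoff_raw
    else:
        out = v > cutoff.cutoff_raw
    return out.where(v.notna(), other=pd.NA)


def assign_biomarker_status(samples: pd.DataFrame, cutoffs: dict) -> pd.DataFrame:
    """Per-sample biomarker positivity calls plus the AT contrast label.

    ``cutoffs`` maps biomarker column -> fitted :class:`BiomarkerCutoff`.
    A+ comes from ``csf_abeta42`` (low positive); T+ from ``csf_ptau181``;
    ``at_status`` is ``A+T+`` / ``A-T-`` with discordant pairs (excluded from
    the AT contrast) labelled ``discordant``.  Missing inputs yield missing
    statuses, not errors.
    """
    out = pd.DataFrame(index=samples.index)
    for col, cutoff in cutoffs.items():
        if col not in samples.columns:
            continue
        out[f"{col}_positive"] = dichotomize(samples[col], cutoff)
    a = out.get("csf_abeta42_positive")
    t = out.get("csf_ptau181_positive")
    if a is not None and t is not None:
        status = pd.Series(pd.NA, index=samples.index, dtype=object)
        both = a.notna() & t.notna()
        status[both & a.eq(True) & t.eq(True)] = "A+T+"
        status[both & a.eq(False) & t.eq(False)] = "A-T-"
        status[both & (a.astype(object) != t.astype(object))] = "discordant"
        out["at_status"] = status
    return out
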