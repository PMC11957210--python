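"""Cross-study replication statistics.

Sign concordance between an internal association table and an external
study's summary statistics, exact binomial enrichment of concordant
directions (computed in log space so far-tail p-values stay accurate),
effect-size correlation, and intersection-pattern summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)


def direction_concordance(
    internal: pd.DataFrame,
    external: pd.DataFrame,
    id_col: str = "analyte_id",
    internal_effect: str = "effect",
    external_effect: str = "effect",
) -> tuple[int, int, pd.DataFrame]:
    """Count direction agreement between two effect tables.

    Returns ``(n, k, matched)`` where ``n`` is the number of ids present in
    both tables with nonzero effects (exact zeros carry no sign and are
    excluded, logged), and ``k`` the number with matching sign.  For survival
    studies the external effect should be ln(HR), which shares the sign
    convention.
    """
    merged = internal[[id_col, internal_effect]].merge(
        external[[id_col, external_effect]],
        on=id_col,
        suffixes=("_int", "_ext"),
    )
    if merged.empty:
        raise ValueError("no overlapping ids between internal and external tables")
    cols = merged.columns.tolist()
    int_col = cols[1]
    ext_col = cols[2]
    nonzero = (merged[int_col] != 0) & (merged[ext_col] != 0)
    n_zero = int((~nonzero).sum())
    if n_zero:
        log.info("excluding %d pair(s) with an exact-zero effect", n_zero)
    matched = merged[nonzero].copy()
    matched["concordant"] = np.sign(matched[int_col]) == np.sign(matched[ext_col])
    n = len(matched)
    k = int(matched["concordant"].sum())
    return n, k, matched


def _log_binom_sf(k: int, n: int, p0: float) -> float:
    """log P(X >= k) for X ~ Binomial(n, p0), exact via log-gamma summation."""
    if k <= 0:
        return 0.0
    i = np.arange(k, n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(p0)
        + (n - i) * np.log1p(-p0)
    )
    return float(logsumexp(logpmf))


def binomial_enrichment(
    k: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> tuple[float, float]:
    """Fold-enrichment and exact binomial p for k concordant out of n.

    ``fold = k / (n * p0)``.  ``alternative="greater"`` gives the exact upper
    tail P(X >= k); ``"two_sided"`` (defined for the symmetric null p0=0.5)
    gives 2*min(P(X >= k), P(X <= k)) capped at 1.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    fold = k / (n * p0) if n else np.nan
    upper = np.exp(_log_binom_sf(k, n, p0))
    if alternative == "greater":
        return fold, float(min(upper, 1.0))
    if alternative == "two_sided":
        lower = 1.0 - np.exp(_log_binom_sf(k + 1, n, p0))
        return fold, float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError(f"unknown alternative {alternative!r}")


def effect_correlation(
    internal: pd.DataFrame,
    external: pd.DataFrame,
    subset: str = "external_nominal",
    id_col: str = "analyte_id",
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Pearson correlation of internal vs external effects.

    ``subset="external_nominal"`` restricts to pairs with external p < alpha
    (the convention used when reporting against prior studies);
    ``subset="all"`` uses every overlapping pair.
    """
    cols = [id_col, "effect"] + (["p"] if "p" in external.columns else [])
    merged = internal[[id_col, "effect"]].merge(
        external[cols], on=id_col, suffixes=("_int", "_ext")
    )
    if subset == "external_nominal":
        if "p" not in merged.columns:
            raise ValueError("external table lacks a 'p' column for nominal subsetting")
        merged = merged[merged["p"] < alpha]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    merged = merged.dropna(subset=["effect_int", "effect_ext"])
    if len(merged) < 3:
        raise ValueError(f"fewer than 3 pairs after subsetting (got {len(merged)})")
    r, p = stats.pearsonr(merged["effect_int"], merged["effect_ext"])
    return float(r), float(p), len(merged)


def overlap_summary(named_sets: dict) -> dict[tuple, int]:
    """Counts per exclusive membership pattern (UpSet-style).

    Keys are sorted tuples of set names; patterns partition the union of all
    ids, so the counts sum to ``len(union)``.
    """
    names = sorted(named_sets)
    sets = {name: set(named_sets[name]) for name in names}
    union = set().union(*sets.values()) if sets else set()
    patterns: dict[tuple, int] = {}
    for item in union:
        key = tuple(name for name in names if item in sets[name])
        patterns[key] = patterns.get(key, 0) + 1
    return patterns
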