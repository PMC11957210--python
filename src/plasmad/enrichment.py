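"""Over-representation tests and Cauchy-combination module ranking.

Hypergeometric upper-tail enrichment of a hit list against user-supplied
gene sets, the aggregated Cauchy combination of p-values, and ranking of
(externally constructed) network modules by their combined enrichment for
up- and down-regulated signature subsets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from plasmad.daa import bh_adjust

log = logging.getLogger(__name__)

ACAT_EPS = 1e-15


def hypergeometric_enrichment(hits, sets, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``hits`` against each set.

    Each set is intersected with the universe first; ``hits`` must be a
    subset of ``universe``.  ``fold = (k/|hits|) / (|set|/|universe|)`` and
    ``p = P(X >= k)`` for X hypergeometric(|universe|, |set|, |hits|); BH is
    applied across the tested sets.
    """
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit list")
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in sets.items():
        inset = set(members) & universe
        n = len(inset)
        k = len(inset & hits)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        fold = (k / N) / (n / M) if n else 0.0
        rows.append((name, M, n, N, k, fold, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "universe_size", "set_size", "hit_size", "overlap", "fold", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else out["p"]
    return out


def acat_combine(pvals, weights=None) -> float:
    """Aggregated Cauchy combination: T = sum w_i tan((0.5 - p_i) pi),
    combined p = 0.5 - arctan(T / sum w) / pi.

    Inputs at exactly 0 or 1 are clamped to the working range with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any((p <= 0) | (p >= 1)):
        log.warning("clamping %d boundary p-value(s) for ACAT", int(((p <= 0) | (p >= 1)).sum()))
        # p ~ 1 would contribute tan -> -inf and swamp every other component;
        # follow the reference ACAT treatment (1 -> 1 - 1/d) for d > 1
        high = 1.0 - (1.0 / p.size if p.size > 1 else ACAT_EPS)
        p = np.clip(p, ACAT_EPS, high)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0) or w.size != p.size:
            raise ValueError("weights must be positive and match p-values in length")
    T = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    combined = 0.5 - np.arctan(T / w.sum()) / np.pi
    return float(np.clip(combined, 0.0, 1.0))


def rank_modules(modules, signature_up, signature_down, universe) -> pd.DataFrame:
    """Rank protein modules by ACAT-combined enrichment for up/down signatures.

    ``modules`` maps module id -> member proteins.  For each module the
    upper-tail hypergeometric p is computed separately against the
    up-regulated and down-regulated signature subsets, combined by ACAT, and
    modules are ranked by combined p ascending (ties broken by module id).
    Modules disjoint from the universe get p = 1 entries.
    """
    universe = set(universe)
    sig_up = set(signature_up) & universe
    sig_down = set(signature_down) & universe
    M = len(universe)
    rows = []
    for mod_id, members in modules.items():
        inset = set(members) & universe
        n = len(inset)
        ps = {}
        for tag, sig in (("up", sig_up), ("down", sig_down)):
            if n == 0 or not sig:
                ps[tag] = 1.0
            else:
                k = len(inset & sig)
                ps[tag] = float(min(stats.hypergeom.sf(k - 1, M, n, len(sig)), 1.0))
        combined = acat_combine([ps["up"], ps["down"]])
        rows.append((mod_id, n, ps["up"], ps["down"], combined))
    out = pd.DataFrame(
        rows, columns=["module_id", "module_size_in_universe", "p_up", "p_down", "p_acat"]
    )
    out = out.sort_values(["p_acat", "module_id"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
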