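"""Hypergeometric metabolite-set enrichment (MSEA, over-representation).

For a pathway with K annotated compounds in a background of N, and a
differential set of n compounds of which k fall in the pathway, the
enrichment p-value is the upper hypergeometric tail P(X >= k).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_tail", "msea", "shared_pathways"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def msea(diff_set: set, background: set, pathway_map: dict[str, set],
         alpha: float = 0.05) -> pd.DataFrame:
    """Per-pathway over-representation of a differential compound set.

    ``pathway_map`` maps pathway id -> compound set; membership is
    restricted to the background (all detected, annotated compounds).
    Pathways without background members are skipped.  Results are sorted
    ascending by p; the headline significance flag uses raw p < alpha, a
    BH-adjusted column is reported alongside.
    """
    if not diff_set <= background:
        raise ValueError("differential set must be a subset of the background")
    if not diff_set:
        logger.warning("msea: empty differential set")
        return pd.DataFrame(columns=["pathway_id", "N", "K", "n", "k",
                                     "p", "q", "significant"])
    N, n = len(background), len(diff_set)
    rows = []
    for pw, members in sorted(pathway_map.items()):
        members = members & background
        if not members:
            continue
        K = len(members)
        k = len(members & diff_set)
        rows.append((pw, N, K, n, k, hypergeom_tail(k, K, n, N)))
    out = pd.DataFrame(rows, columns=["pathway_id", "N", "K", "n", "k", "p"])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    return out.sort_values(["p", "pathway_id"], kind="mergesort",
                           ignore_index=True)


def shared_pathways(results: dict[str, pd.DataFrame],
                    alpha: float = 0.05) -> set[str]:
    """Pathways significant (raw p < alpha) in every comparison."""
    if len(results) < 2:
        raise ValueError("need >= 2 comparisons to intersect")
    sets = [set(df.loc[df["p"] < alpha, "pathway_id"]) for df in results.values()]
    return set.intersection(*sets)
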