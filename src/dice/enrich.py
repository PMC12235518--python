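"""Phase VI: hypergeometric over-representation analysis (ORA).

Given a query gene list (e.g. the DiCE genes), a collection of annotation
sets and a background universe, each set is tested for over-representation
with the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(M, K, n)

where M is the universe size, K the set size within the universe, n the
query size and k the observed overlap.  P-values are BH-adjusted across
all tested sets; sets with q < 0.05 (configurable) are called enriched.
An optional EASE variant tests P(X >= k - 1), the conservative overlap
statistic some annotation servers use.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .dea import bh_adjust
from .errors import DiceInputError
from .io import GeneSetCollection

logger = logging.getLogger("dice")

__all__ = ["hypergeom_upper_tail", "ora"]


def hypergeom_upper_tail(k: int, K: int, n: int, M: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n).

    M: universe size; K: annotated genes in the universe; n: query size;
    k: overlap.  Computed via the survival function (log-space internally),
    so tiny tail probabilities are stable.
    """
    if not (0 <= K <= M and 0 <= n <= M and 0 <= k <= min(n, K)):
        raise DiceInputError(
            f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, M={M}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, M, K, n))


def ora(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    fdr: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set, against ``universe``.

    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe and skipped if empty afterwards.
    Returns one row per tested set, sorted by p ascending, with columns
    ``k K n M p q enriched``.
    """
    universe = set(universe)
    M = len(universe)
    if M == 0:
        raise DiceInputError("ora: empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning(
            "ora: dropping %d query gene(s) outside the universe", len(outside)
        )
    query &= universe
    n = len(query)
    if n == 0:
        raise DiceInputError("ora: query is empty after intersection with the universe")

    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & in_universe)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_eff, K, n, M)
        rows.append({"set": name, "k": k, "K": K, "n": n, "M": M, "p": p})
    if not rows:
        raise DiceInputError("ora: no gene set overlaps the universe")
    res = pd.DataFrame(rows).set_index("set")
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["enriched"] = res["q"] < fdr
    res = res.sort_values(by=["p", "q"], kind="mergesort")
    logger.info(
        "phase6: %d / %d sets enriched at FDR < %g", int(res["enriched"].sum()),
        len(res), fdr,
    )
    return res
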