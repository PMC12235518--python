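"""Phase V: rank-product ensemble scoring and the mean-centrality filter.

Genes are ranked in descending order of |delta| separately for betweenness
and eigenvector centrality (average ranks for ties), each ranking is
normalized to [0, 1] via (N - r) / (N - 1) — so the top gene maps to
exactly 1 and the bottom to exactly 0 — and the ensemble score is the
product of the two normalized ranks.  Note the deliberate consequence of
this normalization: finishing last in either measure zeroes the product.

Genes whose raw centralities sit below the per-(measure, condition) mean
are flagged as excluded; by default ("all_below") a gene is excluded only
when it is below the mean for every measure in every condition — the most
conservative reading — with a stricter "either_measure_below" mode that
excludes a gene as soon as one measure is below its mean in both
conditions.  Means are computed over all network genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DiceInputError, EmptyResultError

logger = logging.getLogger("dice")

__all__ = [
    "rank_descending",
    "normalize_ranks",
    "ensemble_score",
    "centrality_mean_filter",
    "dice_genes",
]

_MEASURES = ("betweenness", "eigen")
_CONDITIONS = ("c1", "c2")


def rank_descending(values) -> np.ndarray:
    """Descending average-tie ranks: rank 1 = largest value."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DiceInputError("rank_descending: need at least 2 values")
    return rankdata(-v, method="average")


def normalize_ranks(ranks, n: int) -> np.ndarray:
    """Map ranks in [1, N] to [0, 1]: norm = (N - r) / (N - 1).

    Rank 1 maps to exactly 1 (highest importance), rank N to exactly 0.
    """
    r = np.asarray(ranks, dtype=float)
    if n < 2:
        raise DiceInputError("normalize_ranks: need N >= 2")
    if ((r < 1) | (r > n)).any():
        raise DiceInputError(f"normalize_ranks: ranks outside [1, {n}]")
    return (n - r) / (n - 1)


def ensemble_score(norm_betweenness, norm_eigenvector) -> np.ndarray:
    """Product of the two normalized ranks, per gene."""
    nb = np.asarray(norm_betweenness, dtype=float)
    ne = np.asarray(norm_eigenvector, dtype=float)
    if nb.shape != ne.shape:
        raise DiceInputError("ensemble_score: measures have different lengths")
    return nb * ne


def centrality_mean_filter(
    cent: pd.DataFrame, mode: str = "all_below"
) -> pd.DataFrame:
    """Flag genes whose raw centralities fall below the per-column means.

    ``cent`` is the Phase-IV table with columns ``{measure}_{condition}``
    for measure in (betweenness, eigen) and condition in (c1, c2).  Returns
    a frame with boolean ``excluded`` and a string ``exclusion_reason``.

    all_below
        Exclude iff centrality < mean for every measure in every condition.
    either_measure_below
        Exclude iff some single measure is below its mean in both
        conditions.
    """
    if mode not in ("all_below", "either_measure_below"):
        raise DiceInputError(f"unknown exclusion mode {mode!r}")
    below = {}
    for m in _MEASURES:
        for c in _CONDITIONS:
            col = f"{m}_{c}"
            below[(m, c)] = cent[col] < cent[col].mean()
    if mode == "all_below":
        excluded = np.logical_and.reduce([below[k].to_numpy() for k in below])
        reason = "below mean for all measures in all conditions"
    else:
        per_measure = [
            (below[(m, "c1")] & below[(m, "c2")]).to_numpy() for m in _MEASURES
        ]
        excluded = np.logical_or.reduce(per_measure)
        reason = "a measure below its mean in both conditions"
    out = pd.DataFrame(index=cent.index.copy())
    out["excluded"] = excluded
    out["exclusion_reason"] = np.where(excluded, reason, "")
    return out


def dice_genes(
    cent: pd.DataFrame,
    de: pd.DataFrame | None = None,
    exclusion_mode: str = "all_below",
) -> pd.DataFrame:
    """Assemble the final DiCE gene table.

    Takes the Phase-IV centrality table (and optionally the DE table, for
    direction labels and log2FC/q columns) and returns one row per network
    gene with ranks, normalized ranks, ensemble score, exclusion flag and —
    for non-excluded genes — the final DiCE rank (1 = best).  The table is
    sorted non-excluded first, by ensemble score descending, ties broken by
    larger delta_betweenness then gene symbol.
    """
    n = len(cent)
    if n < 2:
        raise DiceInputError("dice_genes: need at least 2 network genes")
    out = cent[["delta_betweenness", "delta_eigenvector"]].copy()
    rank_b = rank_descending(out["delta_betweenness"].to_numpy())
    rank_e = rank_descending(out["delta_eigenvector"].to_numpy())
    out["rank_b"] = rank_b
    out["rank_e"] = rank_e
    out["norm_b"] = normalize_ranks(rank_b, n)
    out["norm_e"] = normalize_ranks(rank_e, n)
    out["ensemble_score"] = ensemble_score(out["norm_b"], out["norm_e"])

    flags = centrality_mean_filter(cent, mode=exclusion_mode)
    out["excluded"] = flags["excluded"]
    out["exclusion_reason"] = flags["exclusion_reason"]

    if de is not None:
        lfc = de["log2FC"].reindex(out.index)
        out["log2FC"] = lfc
        out["q"] = de["q"].reindex(out.index)
        out["direction"] = np.select(
            [lfc > 0, lfc < 0], ["up", "down"], default="flat"
        )
        out.loc[lfc.isna(), "direction"] = "na"
    else:
        out["log2FC"] = np.nan
        out["q"] = np.nan
        out["direction"] = "na"

    if not (~out["excluded"]).any():
        raise EmptyResultError(
            "every network gene was excluded by the mean-centrality filter"
        )

    # strict total order: non-excluded first, score desc, delta_b desc, symbol
    index_name = out.index.name or "gene"
    out = (
        out.rename_axis(index_name)
        .reset_index()
        .sort_values(
            by=["excluded", "ensemble_score", "delta_betweenness", index_name],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
        .set_index(index_name)
    )
    final = np.full(len(out), np.nan)
    final[~out["excluded"].to_numpy()] = np.arange(1, int((~out["excluded"]).sum()) + 1)
    out["final_rank"] = final

    n_kept = int((~out["excluded"]).sum())
    logger.info("phase5: %d DiCE genes (of %d network genes)", n_kept, n)
    cols = [
        "direction", "log2FC", "q",
        "delta_betweenness", "delta_eigenvector",
        "rank_b", "rank_e", "norm_b", "norm_e",
        "ensemble_score", "excluded", "exclusion_reason", "final_rank",
    ]
    return out[cols]
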