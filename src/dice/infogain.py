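"""Phase II: information-gain filtering of the candidate pool.

Each gene's expression profile is discretized into bins; the information
gain is the reduction in class-label entropy (bits) obtained by
partitioning the samples on those bins:

    D      = -sum_i (S_i / N) * log2(S_i / N)          (dataset entropy)
    WE(g)  =  sum_v (|N_v| / N) * entropy(N_v)          (weighted entropy)
    IG(g)  =  D - WE(g)

Genes whose IG strictly exceeds the pool mean are kept.  Discretization is
equal-frequency by default (10 bins, fewer for small cohorts), which makes
IG invariant under monotone transforms of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea import CandidatePool
from .errors import DiceInputError

logger = logging.getLogger("dice")

__all__ = [
    "IGResult",
    "dataset_entropy",
    "discretize",
    "information_gain",
    "ig_filter",
    "default_bins",
]


@dataclass
class IGResult:
    """Per-gene information gain plus the above-mean keep decision."""

    dataset_entropy: float
    table: pd.DataFrame  # index gene; columns IG, kept
    method: str
    bins: int

    @property
    def kept_genes(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector, with 0*log2(0) = 0."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def dataset_entropy(labels) -> float:
    """Entropy (bits) of the class-label distribution."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DiceInputError("dataset_entropy: empty label list")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts.astype(float))


def default_bins(n_samples: int, n_distinct: int | None = None, ceiling: int = 10) -> int:
    """Default bin count: min(ceiling, n_samples // 3[, n_distinct]), floor 2.

    The ``n_samples // 3`` term keeps a handful of samples per bin in small
    cohorts; ``n_distinct`` (when given) stops binning finer than the data.
    """
    b = min(ceiling, n_samples // 3)
    if n_distinct is not None:
        b = min(b, n_distinct)
    return max(2, b)


def discretize(values, method: str = "equal_frequency", bins: int = 10) -> np.ndarray:
    """Assign each sample to an expression-level bin.

    equal_frequency
        Rank-based bins whose sizes differ by at most one sample (ties are
        split by stable sample order).
    equal_width
        Bins of equal width spanning [min, max].
    distinct
        Each distinct numeric value is its own level (no binning).

    Constant vectors collapse to a single bin regardless of method.
    """
    x = np.asarray(values, dtype=float)
    if method == "distinct":
        _, labels = np.unique(x, return_inverse=True)
        return labels
    if bins < 2:
        raise DiceInputError(f"discretize: bins must be >= 2, got {bins}")
    n = x.size
    if np.unique(x).size == 1:
        return np.zeros(n, dtype=int)
    if method == "equal_frequency":
        if n < bins:
            raise DiceInputError(
                f"discretize: equal_frequency needs >= {bins} samples, got {n}"
            )
        order = np.argsort(x, kind="stable")
        labels = np.empty(n, dtype=int)
        for b, chunk in enumerate(np.array_split(order, bins)):
            labels[chunk] = b
        return labels
    if method == "equal_width":
        edges = np.linspace(x.min(), x.max(), bins + 1)
        labels = np.digitize(x, edges[1:-1], right=False)
        return labels
    raise DiceInputError(f"discretize: unknown method {method!r}")


def information_gain(gene_bins, labels) -> float:
    """IG (bits) of a binned gene profile with respect to the class labels."""
    b = np.asarray(gene_bins)
    y = np.asarray(labels)
    if b.size != y.size:
        raise DiceInputError(
            f"information_gain: length mismatch ({b.size} bins vs {y.size} labels)"
        )
    D = dataset_entropy(y)
    n = y.size
    _, b_idx = np.unique(b, return_inverse=True)
    _, y_idx = np.unique(y, return_inverse=True)
    contingency = np.zeros((b_idx.max() + 1, y_idx.max() + 1))
    np.add.at(contingency, (b_idx, y_idx), 1.0)
    weighted = sum(
        (row.sum() / n) * _entropy_from_counts(row) for row in contingency
    )
    ig = D - weighted
    # clamp tiny negative rounding error
    return float(max(ig, 0.0))


def ig_filter(
    pool: CandidatePool,
    labels,
    method: str = "equal_frequency",
    bins: int | None = None,
) -> IGResult:
    """Score every pool gene by IG and keep those strictly above the mean.

    If every gene ties (so that nothing is strictly above the mean) all
    genes are retained, with a warning, so the pipeline never silently
    empties.
    """
    if len(pool) == 0:
        raise DiceInputError("ig_filter: empty candidate pool")
    labels = np.asarray(labels)
    n = labels.size
    if bins is None:
        bins = default_bins(n)
    D = dataset_entropy(labels)
    igs = np.array([
        information_gain(
            discretize(pool.zscores.loc[g].to_numpy(), method=method, bins=bins),
            labels,
        )
        for g in pool.genes
    ])
    mean_ig = igs.mean()
    kept = igs > mean_ig
    if not kept.any():
        logger.warning(
            "ig_filter: no gene strictly exceeds the mean IG (%.4g); retaining all %d",
            mean_ig, len(pool),
        )
        kept = np.ones_like(kept, dtype=bool)
    table = pd.DataFrame(
        {"IG": igs, "kept": kept}, index=pd.Index(pool.genes, name="gene")
    )
    logger.info(
        "phase2: %d / %d genes exceed the mean IG (%.4f bits; dataset entropy %.4f)",
        int(kept.sum()), len(pool), mean_ig, D,
    )
    return IGResult(dataset_entropy=D, table=table, method=method, bins=bins)
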