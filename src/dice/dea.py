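"""Phase I: candidate gene pool from relaxed differential-expression cutoffs.

An external DE table (limma/edgeR output) is the recommended input; the
built-in fallback is an ordinary Welch two-sample t-test on log-scale
expression (paired t-test when the design is paired), with
Benjamini-Hochberg adjustment.  Candidate selection applies the relaxed
cutoffs (strictly below the p/q cutoff, |log2FC| strictly above the
fold-change cutoff) and z-scores the candidate rows for the downstream
information-gain and network phases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DiceInputError, EmptyResultError
from .io import Config, ExpressionMatrix, validate_de_table

logger = logging.getLogger("dice")

__all__ = ["CandidatePool", "internal_de", "bh_adjust", "select_candidates", "zscore_rows"]


@dataclass
class CandidatePool:
    """Genes passing the Phase-I cutoffs plus their z-scored expression."""

    genes: list[str]
    thresholds: dict
    zscores: pd.DataFrame  # candidates x samples, row-wise z-scored

    def __len__(self) -> int:
        return len(self.genes)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` clipped to 1, mapped back to the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DiceInputError("bh_adjust: empty p-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DiceInputError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def internal_de(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fallback differential-expression test.

    Per gene: ``log2FC = mean(condition2) - mean(condition1)`` on the log
    scale; p from Welch's t-test, or a paired t-test on per-pair differences
    when the design is paired; q by Benjamini-Hochberg.

    Degenerate genes are handled deterministically: zero variance in both
    groups (or zero variance of paired differences around zero) gives p = 1;
    a non-zero constant paired difference is a p -> 0 limit, recorded as 0.
    """
    c1, c2 = matrix.conditions  # type: ignore[misc]
    s1, s2 = matrix.samples_of(c1), matrix.samples_of(c2)
    if len(s1) < 2 or len(s2) < 2:
        raise DiceInputError(
            f"internal_de requires >= 2 samples per condition (got {len(s1)}, {len(s2)})"
        )
    x1 = matrix.values[s1].to_numpy(dtype=float)
    x2 = matrix.values[s2].to_numpy(dtype=float)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)

    if matrix.is_paired():
        # order condition-2 samples to match condition-1 pairs
        pair_to_s2 = {matrix.pair_of[s]: s for s in s2}  # type: ignore[index]
        ordered_s2 = [pair_to_s2[matrix.pair_of[s]] for s in s1]  # type: ignore[index]
        if len(ordered_s2) < 2:
            raise DiceInputError("paired internal_de requires >= 2 complete pairs")
        d = matrix.values[ordered_s2].to_numpy(dtype=float) - x1
        with warnings.catch_warnings():
            # degenerate (near-constant) genes are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_rel(
                matrix.values[ordered_s2].to_numpy(dtype=float), x1, axis=1
            )
        sd_d = d.std(axis=1, ddof=1)
        degenerate = sd_d == 0
        const_zero = degenerate & (np.abs(d.mean(axis=1)) == 0)
        const_nonzero = degenerate & ~const_zero
        p = np.where(const_zero, 1.0, p)
        # constant non-zero difference: the t statistic diverges, p -> 0
        p = np.where(const_nonzero, 0.0, p)
        if const_nonzero.any():
            logger.warning(
                "internal_de: %d gene(s) with constant non-zero paired difference; p set to 0",
                int(const_nonzero.sum()),
            )
    else:
        with warnings.catch_warnings():
            # degenerate (near-constant) genes are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
        flat = (x1.std(axis=1, ddof=1) == 0) & (x2.std(axis=1, ddof=1) == 0)
        p = np.where(flat, 1.0, p)
        if flat.any():
            logger.warning(
                "internal_de: %d gene(s) with zero variance in both groups; p set to 1",
                int(flat.sum()),
            )
    p = np.nan_to_num(p, nan=1.0)
    de = pd.DataFrame(
        {"log2FC": log2fc, "p": p, "q": bh_adjust(p)},
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return validate_de_table(de)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring with sample standard deviation (ddof=1).

    Constant rows map to all-zero rows (with a warning) so that downstream
    correlations stay defined.
    """
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("zscore_rows: %d constant row(s) mapped to zeros", int(flat.sum()))
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def select_candidates(
    de: pd.DataFrame, matrix: ExpressionMatrix, config: Config
) -> CandidatePool:
    """Apply the relaxed Phase-I cutoffs and z-score the candidate rows.

    A gene qualifies when its p (or q, per the config) is strictly below the
    cutoff and, if a fold-change cutoff is configured, |log2FC| is strictly
    above it.  Genes in the DE table but absent from the matrix are ignored.
    """
    validate_de_table(de)
    if config.candidate_p is not None:
        stat_col, cutoff = "p", config.candidate_p
    else:
        stat_col, cutoff = "q", config.candidate_q
    mask = de[stat_col] < cutoff
    if config.candidate_lfc is not None:
        mask &= de["log2FC"].abs() > config.candidate_lfc
    candidates = [g for g in de.index[mask] if g in set(matrix.gene_ids)]
    # preserve matrix row order for reproducible output
    order = {g: i for i, g in enumerate(matrix.gene_ids)}
    candidates.sort(key=order.__getitem__)
    if not candidates:
        raise EmptyResultError(
            f"no genes pass {stat_col} < {cutoff}"
            + (f" and |log2FC| > {config.candidate_lfc}" if config.candidate_lfc is not None else "")
            + "; consider looser cutoffs"
        )
    thresholds = {
        "stat": stat_col,
        "cutoff": cutoff,
        "lfc_cutoff": config.candidate_lfc,
    }
    z = zscore_rows(matrix.values.loc[candidates])
    logger.info("phase1: %d / %d genes enter the candidate pool", len(candidates), len(de))
    return CandidatePool(genes=candidates, thresholds=thresholds, zscores=z)
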