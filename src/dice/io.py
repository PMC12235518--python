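"""Domain containers, file readers/writers and run configuration.

All tabular I/O is plain TSV with headers.  Gene identifiers are treated as
opaque, case-sensitive symbols; no alias mapping is attempted.  Expression
values are assumed to be on a log scale (log-intensities or log-normalized
counts) throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import DiceInputError, EmptyResultError

logger = logging.getLogger("dice")

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "GeneSetCollection",
    "Config",
    "load_expression",
    "load_de_table",
    "load_edge_list",
    "load_gene_sets",
    "validate_de_table",
    "write_table",
    "FLOAT_FORMAT",
]

#: Float formatting used by every writer.  ``None`` selects pandas'
#: shortest-round-trip repr: byte-identical across platforms and lossless,
#: so tables written by one phase can be re-read to replay downstream
#: phases exactly.
FLOAT_FORMAT = None


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples log-expression table with a two-condition design.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    condition_of
        Mapping from sample id to condition label (exactly two distinct
        labels across all samples).
    pair_of
        Optional mapping from sample id to a pair identifier for paired
        designs (e.g. tumor and adjacent normal from the same patient).
        When present, every pair identifier must occur exactly once per
        condition.
    conditions
        The two condition labels in a fixed order ``(condition1,
        condition2)``.  Fold changes downstream are condition2 versus
        condition1.  Defaults to order of first appearance.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    pair_of: dict[str, str] | None = None
    conditions: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.conditions is None:
            seen: list[str] = []
            for s in self.values.columns:
                c = self.condition_of.get(s)
                if c is not None and c not in seen:
                    seen.append(c)
            if len(seen) != 2:
                raise DiceInputError(
                    f"expected exactly two conditions, found {seen!r}"
                )
            self.conditions = (seen[0], seen[1])

    # -- basic accessors ----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def is_paired(self) -> bool:
        return self.pair_of is not None

    # -- validation ---------------------------------------------------------

    def validate(self, min_samples_per_condition: int = 3) -> "ExpressionMatrix":
        """Check structural invariants; raise :class:`DiceInputError` on failure."""
        idx = self.values.index
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise DiceInputError(f"duplicate gene ids: {dup_genes}")
        cols = self.values.columns
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise DiceInputError(f"duplicate sample ids: {dup_samples}")
        missing = [s for s in cols if s not in self.condition_of]
        if missing:
            raise DiceInputError(f"samples without condition assignment: {missing}")
        labels = {self.condition_of[s] for s in cols}
        if len(labels) != 2:
            raise DiceInputError(
                f"expected exactly two conditions among samples, found {sorted(labels)}"
            )
        for cond in self.conditions:  # type: ignore[union-attr]
            n = len(self.samples_of(cond))
            if n < min_samples_per_condition:
                raise DiceInputError(
                    f"condition {cond!r} has {n} samples; "
                    f"at least {min_samples_per_condition} required"
                )
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DiceInputError("expression matrix contains non-finite values")
        if self.pair_of is not None:
            for cond in self.conditions:  # type: ignore[union-attr]
                pairs = [self.pair_of[s] for s in self.samples_of(cond)]
                dupes = {p for p in pairs if pairs.count(p) > 1}
                if dupes:
                    raise DiceInputError(
                        f"pair ids occur more than once in condition {cond!r}: {sorted(dupes)}"
                    )
            p1 = {self.pair_of[s] for s in self.samples_of(self.conditions[0])}
            p2 = {self.pair_of[s] for s in self.samples_of(self.conditions[1])}
            if p1 != p2:
                raise DiceInputError(
                    "paired design: pair ids do not match across conditions "
                    f"({sorted(p1 ^ p2)} unmatched)"
                )
        return self

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[genes],
            condition_of=self.condition_of,
            pair_of=self.pair_of,
            conditions=self.conditions,
        )


# ---------------------------------------------------------------------------
# Edge lists (PPI scaffold)
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected, confidence-scored gene-pair list (STRING-style).

    ``edges`` has columns ``gene1``, ``gene2``, ``confidence``; each
    unordered pair appears once (``gene1 < gene2`` lexicographically) and
    self-loops are disallowed.  ``scale`` records whether confidences are on
    the STRING combined-score scale (0-1000) or the unit scale (0-1).
    """

    edges: pd.DataFrame
    scale: str = "unit"  # "unit" or "string"

    def __post_init__(self) -> None:
        if self.scale not in ("unit", "string"):
            raise DiceInputError(f"unknown confidence scale {self.scale!r}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return set(self.edges["gene1"]).union(self.edges["gene2"])

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene1"], self.edges["gene2"]))

    def filter(self, confidence_cutoff: float) -> "EdgeList":
        """Edges at or above a cutoff given on the unit (0-1) scale."""
        cutoff = confidence_cutoff * 1000.0 if self.scale == "string" else confidence_cutoff
        kept = self.edges[self.edges["confidence"] >= cutoff].reset_index(drop=True)
        if kept.empty:
            raise EmptyResultError(
                f"no edges left after confidence filtering at {confidence_cutoff}"
            )
        return EdgeList(edges=kept, scale=self.scale)


def _canonical_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops, order endpoints, collapse duplicates keeping max score."""
    df = df[df["gene1"] != df["gene2"]].copy()
    swap = df["gene1"] > df["gene2"]
    df.loc[swap, ["gene1", "gene2"]] = df.loc[swap, ["gene2", "gene1"]].to_numpy()
    df = (
        df.groupby(["gene1", "gene2"], as_index=False, sort=True)["confidence"]
        .max()
    )
    return df.reset_index(drop=True)


def make_edge_list(
    pairs: Iterable[tuple[str, str]],
    confidences: Iterable[float] | float = 1.0,
    scale: str | None = None,
) -> EdgeList:
    """Build a canonical :class:`EdgeList` from pairs and confidences."""
    pairs = list(pairs)
    if np.isscalar(confidences):
        confidences = [float(confidences)] * len(pairs)  # type: ignore[arg-type]
    df = pd.DataFrame(
        {
            "gene1": [p[0] for p in pairs],
            "gene2": [p[1] for p in pairs],
            "confidence": list(confidences),  # type: ignore[arg-type]
        }
    )
    df = _canonical_edges(df)
    if scale is None:
        scale = "string" if (len(df) and df["confidence"].max() > 1.0) else "unit"
    return EdgeList(edges=df, scale=scale)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise DiceInputError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """All tunable pipeline settings, with the defaults used throughout.

    Exactly one of ``candidate_p`` / ``candidate_q`` should be set; the
    other must be None.  All thresholds use strict inequalities (p or q
    strictly below the cutoff, |log2FC| strictly above).
    """

    # Phase I
    candidate_p: float | None = None
    candidate_q: float | None = 0.05
    candidate_lfc: float | None = 0.5
    min_samples_per_condition: int = 3
    # Phase II
    ig_method: str = "equal_frequency"  # equal_frequency | equal_width | distinct
    ig_bins: int | None = None  # None -> min(10, n_samples // 3, n_distinct)
    # Phase III
    ppi_confidence: float = 0.4  # on the unit scale; x1000 for STRING files
    # Phase IV
    eigen_weight: str = "affinity"  # affinity | unweighted
    eigen_tol: float = 1e-10
    eigen_max_iter: int = 5000
    # Phase V
    exclusion_mode: str = "all_below"  # all_below | either_measure_below
    # Phase VI
    enrich_fdr: float = 0.05
    ease: bool = False
    universe: str = "network"  # network | expressed
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.candidate_p is not None and self.candidate_q is not None:
            raise DiceInputError("set only one of candidate_p / candidate_q")
        if self.candidate_p is None and self.candidate_q is None:
            raise DiceInputError("one of candidate_p / candidate_q must be set")
        for name, lo, hi in (
            ("candidate_p", 0.0, 1.0),
            ("candidate_q", 0.0, 1.0),
            ("ppi_confidence", 0.0, 1.0),
            ("enrich_fdr", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise DiceInputError(f"{name}={v} outside [{lo}, {hi}]")
        if self.candidate_lfc is not None and self.candidate_lfc < 0:
            raise DiceInputError("candidate_lfc must be non-negative")
        if self.ig_method not in ("equal_frequency", "equal_width", "distinct"):
            raise DiceInputError(f"unknown ig_method {self.ig_method!r}")
        if self.ig_bins is not None and self.ig_bins < 2:
            raise DiceInputError("ig_bins must be >= 2")
        if self.eigen_weight not in ("affinity", "unweighted"):
            raise DiceInputError(f"unknown eigen_weight {self.eigen_weight!r}")
        if self.exclusion_mode not in ("all_below", "either_measure_below"):
            raise DiceInputError(f"unknown exclusion_mode {self.exclusion_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DiceInputError(f"unknown config keys: {sorted(unknown)}")
        # An explicit p cutoff in a YAML file overrides the default q cutoff.
        if "candidate_p" in raw and raw["candidate_p"] is not None:
            raw.setdefault("candidate_q", None)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_expression(
    expr_path: str | Path,
    groups_path: str | Path,
    min_samples_per_condition: int = 3,
) -> ExpressionMatrix:
    """Read an expression TSV and a sample-to-condition table.

    The expression file has a first column named ``gene`` and one column per
    sample.  The groups file has columns ``sample``, ``condition`` and an
    optional ``pair``.  Samples present in only one of the two files are
    dropped with a warning; structural problems (duplicates, fewer than two
    conditions, too few samples) raise :class:`DiceInputError`.
    """
    expr = pd.read_csv(expr_path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if expr.columns[0] != "gene":
        raise DiceInputError(
            f"expression file must have first column 'gene', got {expr.columns[0]!r}"
        )
    dup = expr["gene"][expr["gene"].duplicated()].unique().tolist()
    if dup:
        raise DiceInputError(f"duplicate gene ids in {expr_path}: {dup}")
    expr = expr.set_index("gene")
    expr.index.name = "gene"

    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    required = {"sample", "condition"}
    if not required.issubset(groups.columns):
        raise DiceInputError(
            f"groups file must have columns sample, condition; got {list(groups.columns)}"
        )
    dup = groups["sample"][groups["sample"].duplicated()].unique().tolist()
    if dup:
        raise DiceInputError(f"duplicate sample ids in {groups_path}: {dup}")

    matrix_samples = list(expr.columns)
    group_samples = list(groups["sample"])
    only_matrix = [s for s in matrix_samples if s not in set(group_samples)]
    only_groups = [s for s in group_samples if s not in set(matrix_samples)]
    if only_matrix:
        logger.warning(
            "dropping %d sample(s) present in the matrix but not in the groups file: %s",
            len(only_matrix), only_matrix,
        )
        expr = expr.drop(columns=only_matrix)
    if only_groups:
        logger.warning(
            "dropping %d sample(s) present in the groups file but not in the matrix: %s",
            len(only_groups), only_groups,
        )
        groups = groups[~groups["sample"].isin(only_groups)]

    condition_of = dict(zip(groups["sample"], groups["condition"]))
    pair_of = None
    if "pair" in groups.columns and groups["pair"].notna().any():
        pair_of = dict(zip(groups["sample"], groups["pair"]))

    # condition order = first appearance in the groups file
    seen: list[str] = []
    for c in groups["condition"]:
        if c not in seen:
            seen.append(c)
    if len(seen) != 2:
        raise DiceInputError(f"expected exactly two conditions, found {seen}")

    matrix = ExpressionMatrix(
        values=expr.astype(float),
        condition_of=condition_of,
        pair_of=pair_of,
        conditions=(seen[0], seen[1]),
    )
    return matrix.validate(min_samples_per_condition)


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-gene differential-expression table (log2FC, p, q)."""
    for col in ("log2FC", "p", "q"):
        if col not in de.columns:
            raise DiceInputError(f"DE table missing column {col!r}")
    dup = de.index[de.index.duplicated()].unique().tolist()
    if dup:
        raise DiceInputError(f"duplicate genes in DE table: {dup}")
    for col in ("p", "q"):
        v = de[col].to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any() or np.isnan(v).any():
            raise DiceInputError(f"DE table column {col!r} outside [0, 1]")
    return de


def load_de_table(path: str | Path) -> pd.DataFrame:
    """Read an external DE table: TSV with header ``gene log2FC p [q]``.

    When ``q`` is absent it is computed by Benjamini-Hochberg adjustment of
    ``p`` across all rows.
    """
    from .dea import bh_adjust  # local import to avoid a cycle

    de = pd.read_csv(path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    if "gene" not in de.columns:
        raise DiceInputError(f"DE table {path} must have a 'gene' column")
    de = de.set_index("gene")
    if "q" not in de.columns:
        de["q"] = bh_adjust(de["p"].to_numpy(dtype=float))
    return validate_de_table(de)


_STRING_COLUMNS = {"protein1", "protein2", "combined_score"}


def load_edge_list(path: str | Path, confidence_cutoff: float = 0.0) -> EdgeList:
    """Read a PPI edge list and filter by confidence.

    Accepts either a generic 3-column TSV (``gene1  gene2  score``, header
    optional) or the STRING protein-links dialect (whitespace-separated,
    header ``protein1 protein2 combined_score``).  The confidence scale is
    auto-detected: any score above 1 means the STRING 0-1000 scale, and a
    cutoff given on the unit scale is multiplied by 1000.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first:
        raise DiceInputError(f"{path}: empty file")

    sep = r"\s+" if " " in first and "\t" not in first else "\t"
    tokens = first.replace("\t", " ").split()
    has_header = False
    if _STRING_COLUMNS.issubset(set(tokens)):
        has_header = True
        df = pd.read_csv(path, sep=sep, dtype={"protein1": str, "protein2": str}, float_precision="round_trip")
        df = df.rename(
            columns={"protein1": "gene1", "protein2": "gene2", "combined_score": "confidence"}
        )[["gene1", "gene2", "confidence"]]
    else:
        if len(tokens) >= 3 and tokens[0].lower() in ("gene1", "gene_a", "genea", "node1"):
            has_header = True
        df = pd.read_csv(
            path, sep=sep, header=0 if has_header else None,
            names=["gene1", "gene2", "confidence"], usecols=[0, 1, 2],
            dtype={0: str, 1: str}, float_precision="round_trip",
        )
    bad = df.index[pd.to_numeric(df["confidence"], errors="coerce").isna()]
    if len(bad):
        line = int(bad[0]) + (2 if has_header else 1)
        raise DiceInputError(f"{path}: unparseable score at line {line}")
    df["confidence"] = df["confidence"].astype(float)

    scale = "string" if df["confidence"].max() > 1.0 else "unit"
    cutoff = confidence_cutoff * 1000.0 if scale == "string" else confidence_cutoff
    df = df[df["confidence"] >= cutoff]
    df = _canonical_edges(df)
    if df.empty:
        raise EmptyResultError(
            f"{path}: no edges left after confidence filtering at {confidence_cutoff}"
        )
    return EdgeList(edges=df, scale=scale)


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member1<TAB>member2...``"""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DiceInputError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no members"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise DiceInputError(
                    f"{path}:{lineno}: gene set {name!r} has no members"
                )
            if name in sets:
                raise DiceInputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if not sets:
        raise DiceInputError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = "gene") -> None:
    """Write a DataFrame as TSV with deterministic float formatting."""
    df.to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT,
        index=index_label is not None, index_label=index_label,
        lineterminator="\n",
    )


def write_expression(matrix: ExpressionMatrix, expr_path: str | Path, groups_path: str | Path) -> None:
    """Write an :class:`ExpressionMatrix` as the expression + groups TSV pair."""
    write_table(matrix.values, expr_path, index_label="gene")
    rows = {"sample": matrix.sample_ids,
            "condition": [matrix.condition_of[s] for s in matrix.sample_ids]}
    if matrix.pair_of is not None:
        rows["pair"] = [matrix.pair_of[s] for s in matrix.sample_ids]
    pd.DataFrame(rows).to_csv(groups_path, sep="\t", index=False, lineterminator="\n")


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    edges.edges.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )
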