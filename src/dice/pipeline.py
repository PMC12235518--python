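"""End-to-end orchestration of the six pipeline phases.

``run_pipeline`` executes Phases I-VI in order on validated inputs,
optionally writing each phase's table before the next begins, and returns
a :class:`RunManifest` recording the configuration, the per-phase retained
gene counts (the "funnel"), and the output paths.  All randomness flows
from the single config seed; the phases themselves are deterministic, so a
run with fixed inputs and config is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .centrality import centrality_table
from .dea import internal_de, select_candidates
from .enrich import ora
from .ensemble import dice_genes
from .errors import DiceError
from .infogain import ig_filter
from .io import (
    Config,
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    write_table,
)
from .network import build_weighted_networks

logger = logging.getLogger("dice")

__all__ = ["RunManifest", "PipelineResult", "run_pipeline"]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    counts: dict[str, int]
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "counts": self.counts,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class PipelineResult:
    """All per-phase tables plus the manifest."""

    de: pd.DataFrame
    candidates: list[str]
    ig: pd.DataFrame
    networks: tuple
    centrality: pd.DataFrame
    dice: pd.DataFrame
    enrichment: pd.DataFrame | None
    manifest: RunManifest

    @property
    def dice_gene_list(self) -> list[str]:
        kept = self.dice[~self.dice["excluded"]]
        return list(kept.index)


def run_pipeline(
    config: Config,
    matrix: ExpressionMatrix,
    edges: EdgeList,
    de: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run Phases I-VI and return every intermediate and final table.

    ``de`` may be a precomputed differential-expression table (the
    recommended path); otherwise the internal Welch/paired t-test fallback
    is used.  ``gene_sets`` enables Phase VI; without it enrichment is
    skipped.  With ``outdir`` set, each phase's table is written (TSV)
    before the next phase begins, and the manifest is written last.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def write(name: str, df: pd.DataFrame, index_label: str = "gene") -> None:
        if out is None:
            return
        path = out / f"{name}.tsv"
        write_table(df, path, index_label=index_label)
        outputs[name] = path.name

    def fail(phase: str, err: DiceError) -> DiceError:
        err.args = (f"[{phase}] {err.args[0]}",) + err.args[1:]
        return err

    matrix.validate(config.min_samples_per_condition)

    # Phase I ---------------------------------------------------------------
    try:
        if de is None:
            logger.info("phase1: no external DE table; using the internal fallback test")
            de = internal_de(matrix)
        pool = select_candidates(de, matrix, config)
    except DiceError as e:
        raise fail("phase1_dea", e)
    write("de_table", de)
    write("candidates", pool.zscores)

    # Phase II --------------------------------------------------------------
    labels = [matrix.condition_of[s] for s in pool.zscores.columns]
    try:
        ig = ig_filter(pool, labels, method=config.ig_method, bins=config.ig_bins)
    except DiceError as e:
        raise fail("phase2_ig", e)
    write("ig_table", ig.table)

    # Phase III -------------------------------------------------------------
    try:
        net1, net2 = build_weighted_networks(edges, set(ig.kept_genes), matrix)
    except DiceError as e:
        raise fail("phase3_network", e)
    if out is not None:
        for net in (net1, net2):
            rows = [
                {"gene1": a, "gene2": b, "cc": d["cc"], "distance": d["distance"]}
                for a, b, d in sorted(net.graph.edges(data=True))
            ]
            df = pd.DataFrame(rows)
            path = out / f"network_{net.condition}.tsv"
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
            outputs[f"network_{net.condition}"] = path.name

    # Phase IV --------------------------------------------------------------
    try:
        cent = centrality_table(
            net1, net2,
            eigen_weight=config.eigen_weight,
            tol=config.eigen_tol,
            max_iter=config.eigen_max_iter,
        )
    except DiceError as e:
        raise fail("phase4_centrality", e)
    write("centrality", cent)

    # Phase V ---------------------------------------------------------------
    try:
        dice = dice_genes(cent, de=de, exclusion_mode=config.exclusion_mode)
    except DiceError as e:
        raise fail("phase5_ensemble", e)
    write("dice_genes", dice)

    # Phase VI --------------------------------------------------------------
    enrichment = None
    if gene_sets is not None:
        universe = (
            set(cent.index) if config.universe == "network" else set(matrix.gene_ids)
        )
        kept = dice.index[~dice["excluded"]]
        try:
            enrichment = ora(
                kept, gene_sets, universe, fdr=config.enrich_fdr, ease=config.ease
            )
        except DiceError as e:
            raise fail("phase6_enrichment", e)
        write("enrichment", enrichment, index_label="set")

    counts = {
        "genes_in_matrix": len(matrix.gene_ids),
        "phase1_candidates": len(pool),
        "phase2_ig_kept": len(ig.kept_genes),
        "phase3_network_genes": len(cent),
        "phase5_dice_genes": int((~dice["excluded"]).sum()),
    }
    manifest = RunManifest(
        config=config.to_dict(), counts=counts, version=__version__,
        seed=config.seed, outputs=outputs,
    )
    if out is not None:
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
    logger.info("pipeline funnel: %s", counts)
    return PipelineResult(
        de=de, candidates=pool.genes, ig=ig.table, networks=(net1, net2),
        centrality=cent, dice=dice, enrichment=enrichment, manifest=manifest,
    )
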