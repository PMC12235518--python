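# dice-net

**Differential centrality-ensemble (DiCE) gene prioritization** for
two-condition expression studies.

Conventional differential expression analysis (DEA) ranks genes by how much
their mean expression changes between two conditions — tumor vs. normal,
treated vs. untreated — and applies cutoffs such as q < 0.05 and
|log2FC| > 1. Genes whose *role in the molecular network* changes, while
their expression barely moves, are invisible to this lens: a hub whose
co-expression with its interaction partners collapses can matter more than
a gene whose level doubles. `dice-net` implements a six-phase pipeline that
ranks genes by how much their **network centrality** shifts between
conditions, using a protein–protein interaction (PPI) scaffold weighted by
condition-specific expression correlations. It is aimed at computational
biologists prioritizing candidate genes or biomarkers from a gene × sample
expression matrix plus a STRING-style PPI edge list.

## Method

1. **Candidate pool (Phase I).** DEA with deliberately relaxed cutoffs
   (e.g. p < .05, or no filter at all) builds a large candidate pool;
   an external limma/edgeR table can be supplied, or a built-in Welch /
   paired t-test with Benjamini–Hochberg FDR is used. Candidate rows are
   z-scored.
2. **Information-gain filter (Phase II).** With dataset entropy
   `D = −Σᵢ (Sᵢ/N)·log₂(Sᵢ/N)` over the condition labels, each gene's
   discretized expression partitions the samples into bins `v`, and
   `IG(g) = D − Σᵥ (|Nᵥ|/N)·entropy(Nᵥ)`. Genes with IG strictly above
   the pool mean are kept.
3. **Condition-specific weighted networks (Phase III).** The PPI scaffold,
   restricted to kept genes (confidence ≥ 0.4 by default, STRING 0–1000 or
   unit scale auto-detected; unconnected genes dropped), is weighted per
   condition by the Pearson correlation c.c. of each edge's endpoints.
   Each edge carries a distance `1 − |c.c.|` and an affinity `|c.c.|`.
4. **Differential centrality (Phase IV).** Per condition: weighted
   betweenness centrality over shortest paths on the distances (normalized
   by (n−1)(n−2)/2), and eigenvector centrality of the affinity-weighted
   adjacency (power iteration, unit Euclidean norm). Per gene: the
   absolute cross-condition differences Δb and Δe.
5. **Ensemble ranking (Phase V).** Genes are ranked in descending order of
   each |Δ|, ranks are normalized to [0, 1] via `(N − r)/(N − 1)` (1 = most
   changed), and the ensemble score is the **product of normalized
   ranks** — a rank-product that rewards genes consistently high in both
   measures. Genes whose raw centralities sit below the per-measure,
   per-condition mean everywhere are excluded; the survivors, ordered by
   score, are the DiCE genes.
6. **Enrichment (Phase VI).** Hypergeometric over-representation of the
   DiCE genes in user-supplied GMT gene sets (upper tail P(X ≥ k), BH FDR,
   enriched at q < 0.05).

A synthetic-data module generates two-condition studies over a scale-free
scaffold with planted *rewired* hub genes (large correlation shifts, subtle
fold changes) and planted conventional DEGs, so every stage is testable
without any external download.

## Worked example

```bash
python examples/01_full_pipeline.py
```

simulates the default study (300 genes, 60 samples per condition, 10
rewired hub genes with |log2FC| = 0.3, 20 DEGs at |log2FC| = 1) and runs
the pipeline wide open at Phase I:

```
gene funnel per phase: {'genes_in_matrix': 300, 'phase1_candidates': 300,
 'phase2_ig_kept': 42, 'phase3_network_genes': 29, 'phase5_dice_genes': 12}
planted rewired genes: ['G003', 'G007', 'G010', 'G038', 'G039', 'G040', 'G044', 'G063', 'G081', 'G144']
rewired genes inside the DiCE top 30: ['G007', 'G010', 'G038', 'G039', 'G144']
rewired genes found by strict-cutoff DEA (q<0.05, |log2FC|>1): []
```

The funnel shows each phase narrowing the list (300 → 42 → 29 → 12). Half
of the planted rewired genes reach the top of the DiCE ranking at this
seed (the median across seeds is 8/10; see below), while strict-cutoff DEA
recovers **none of them** — their fold changes are ~0.3, far below any
conventional threshold. The top-ranked gene `G010` is a rewired hub with
log2FC ≈ 0.29 and ensemble score 0.93.

The same run is available from the shell:

```bash
dice simulate --genes 300 --samples 60 --rewired 10 --degs 20 --seed 13 --out fix/
dice run --expr fix/expression.tsv --groups fix/groups.tsv --ppi fix/edges.tsv \
         --p 1.0 --out results/
```

Other entry points: `dice candidates | ig | network | centrality | rank |
enrich` mirror the phases individually, and `examples/02–04` demonstrate
the information-gain arithmetic, differential centrality on a toy network,
and enrichment.

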