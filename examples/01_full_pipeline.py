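"""Run the full DiCE pipeline on a simulated two-condition study.

Simulates 300 genes over a scale-free interaction scaffold with 10 planted
"rewired" hub genes (their edge correlations collapse in the case
condition while their expression barely moves) and 20 conventional DEGs,
then runs all six phases and reports how well the ranking recovers the
planted rewired genes.
"""

import dice

matrix, truth = dice.simulate_study(seed=13)
config = dice.Config(candidate_p=1.0, candidate_q=None, candidate_lfc=None, seed=13)
result = dice.run_pipeline(config, matrix, truth.scaffold)

print("gene funnel per phase:", result.manifest.counts)

top30 = result.dice_gene_list[:30]
rewired = set(truth.planted_rewired)
print(f"planted rewired genes: {sorted(rewired)}")
print(f"rewired genes inside the DiCE top 30: {sorted(rewired & set(top30))}")

de = result.de
strict = set(de.index[(de["q"] < 0.05) & (de["log2FC"].abs() > 1)])
print(f"rewired genes found by strict-cutoff DEA (q<0.05, |log2FC|>1): "
      f"{sorted(rewired & strict)}")

print("\ntop of the DiCE table:")
print(result.dice.head(8)[["direction", "log2FC", "ensemble_score", "final_rank"]])

# The funnel counts show how each phase narrows the gene list; the two
# recovery lines are the method's point: genes whose *network role* changes
# are ranked highly by differential centrality even though their expression
# shift is far below any conventional DEG threshold.
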