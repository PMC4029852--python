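# co2prof

Multi-stage inference for short, ordered-condition expression series —
the kind of design produced by growing plants under an ambient and two
elevated CO₂ concentrations (T0 < T1 < T2) with three biological
replicates each and profiling leaf transcriptomes on arrays.  With only
three replicates per condition, each analysis stage has to borrow
strength across genes; `co2prof` implements the full chain as a tested,
reusable Python library with a CLI:

1. **Moderated differential expression (RVM F-test).**  Each gene's
   residual precision 1/σ² is modelled as Gamma(a, scale b) across genes.
   The residual mean square then satisfies s²·ab ~ F(m, 2a), (a, b) are
   fitted by marginal maximum likelihood, and the moderated statistic
   F̃ = MS_between / σ̃² with σ̃² = (m·s² + 2/b)/(m + 2a) is referred to
   F(k−1, m+2a) — the prior adds 2a denominator degrees of freedom.
   Genes pass at p < 0.05 and Benjamini–Hochberg q < 0.05.
2. **Model-profile clustering (series test of cluster).**  Each selected
   gene's log2-ratio vector (anchored at T0) is assigned to the most
   Pearson-correlated of 16 integer model profiles such as (0, 1, 0).
   The null assignment count permutes the condition positions of every
   vector (all 3! orderings, re-anchored); profile significance is the
   upper binomial tail P(X ≥ assigned), X ~ Binomial(total,
   expected/total), computed in log space.
3. **Gene-set enrichment.**  Hypergeometric upper-tail p plus the
   enrichment ratio Re = (k/n)/(K/N), with the dual screen p < 0.05 and
   Re > 5 for GO-style namespaces.
4. **Signal-transduction network.**  Directed, typed catalog relations
   (activation, phosphorylation, …) are kept only between significantly
   co-expressed gene pairs; key genes are ranked by normalized
   betweenness centrality, then degree.
5. **qPCR validation.**  2^-ΔΔCt fold changes against a reference gene
   and control condition, and Pearson concordance with array log2 fold
   changes.

A seeded synthetic-data generator (`co2prof.synthetic`) reproduces the
exact statistical structure these stages assume — gamma-distributed
precisions, planted profiles, planted enriched categories, a planted
high-betweenness bridge gene, and Ct tables consistent with the planted
fold changes — so the whole pipeline is testable offline with known
ground truth.

## Worked example

```python
from co2prof import (PipelineConfig, SyntheticConfig, run_pipeline)

result = run_pipeline(PipelineConfig(
    out_dir="demo_out", seed=1,
    synth=SyntheticConfig(n_genes=5000, seed=1),
))
print(result.significant_profiles)
print(result.key_genes.head(3).to_string(index=False))
```

prints (stage logs omitted):

```
[12, 6, 16, 5, 10]
  gene  degree  indegree  outdegree       bc
g04903      11         0         11 0.013775
g04676       3         2          1 0.001142
g00135      2          1          1 0.000761
```

The five significant profiles are exactly the planted profile mix
(profile 12 = transient up at T1, 6 = transient down, 16/10 = opposite
reversals, 5 = sustained up), and the top-ranked network gene `g04903`
is the planted bridge: the only node connecting the two interaction
cliques, hence the highest betweenness.  `demo_out/` holds one TSV per
stage plus `manifest.json` recording every threshold, the seed and
output checksums; rerunning with the same seed reproduces the files
byte for byte.

The same stages are available as subcommands:

```bash
co2prof synth --out-dir demo_data --seed 1
co2prof detest --expression demo_data/expression.tsv --sample-sheet demo_data/samples.csv
co2prof run --config pipeline.yaml
```

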