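# ovgenes

Detection, classification and co-expression analysis of **overlapping
protein-coding genes**.

Overlapping genes — two gene loci whose genomic intervals share at least one
base on the same chromosome — are the norm in compact viral and bacterial
genomes but also occur in mammals: roughly a quarter of human protein-coding
genes overlap a neighbour. Because overlapping partners share chromatin
context, and head-to-head pairs may share a bidirectional promoter, their
expression tends to be coincident across samples and tissues. `ovgenes` is a
pipeline for quantifying exactly that, aimed at genome-annotation and
transcriptomics researchers:

1. **filter** — curate an Ensembl/BioMart-style annotation down to distinct,
   described protein-coding genes on the primary assembly (scaffolds,
   duplicated gene names, readthrough transcripts and undescribed novel
   genes removed, with an auditable per-stage report);
2. **detect** — partition genes into overlap clusters: connected components
   of the pairwise-overlap graph (overlap = ≥ 1 shared bp, strand-agnostic),
   found with a per-chromosome sweep line and classed as paired, triple,
   quadruple, quintuple or above-sextuple;
3. **classify** — for paired clusters, order each pair as frontal/lateral
   (Gene_F starts first) and assign the strand-orientation subtype
   — 5′-tandem (→ →), convergent (→ ←), divergent (← →), 3′-tandem (← ←) —
   together with all structural metrics: gene lengths, the overlapping
   interval `F.end − L.start + 1` (0 for embedded pairs, where the lateral
   gene lies entirely inside the frontal), the block length
   `L.end − F.start + 1`, and distances to the nearest up/downstream genes;
4. **associate** — given a genes × samples RPKM matrix with a
   sample → tissue map, compute for every pair (and an equally sized random
   non-overlapping control group) the Spearman correlation ρ, a
   lateral-on-frontal linear regression (slope, R², slope-test p),
   Benjamini–Hochberg q-values within groups, Mann–Whitney /
   Kruskal–Wallis comparisons of expression level between subtypes,
   Fisher-z comparisons of group correlations, and the cross-tissue
   variance of per-tissue ρ used to flag tissue-specific pairs.

A first-class synthetic-data generator plants overlap clusters, subtype
mixes and per-pair, per-tissue rank correlations with known ground truth,
so the entire pipeline runs and is tested without any external downloads.

## Worked example

```python
from ovgenes import (AnnotationConfig, ExpressionConfig, ExpressionPair,
                     associate, filter_genes, find_overlap_clusters,
                     generate_annotation, generate_expression,
                     group_association_summary, pairs_from_clusters,
                     sample_control_pairs)

records, truth = generate_annotation(AnnotationConfig(), seed=7)
genes, _ = filter_genes(records)
pwm = pairs_from_clusters(find_overlap_clusters(genes), genes)
pairs = [ExpressionPair(p.pair_id, p.gene_F, p.gene_L, p.subtype)
         for p, _ in pwm]
controls = sample_control_pairs(truth.planted_singletons, len(pairs), seed=7)
matrix = generate_expression(pairs + controls, ExpressionConfig(), seed=7)
results = associate(pairs + controls, matrix)
summary = group_association_summary(results, pairs + controls, matrix)
print(summary["group_summary"][["n_pairs", "median_rho", "pct_significant"]])
```

prints

```
            n_pairs  median_rho  pct_significant
group
convergent       20       0.311           90.000
tandem3           4       0.362          100.000
tandem5           4       0.259           75.000
divergent        16       0.611          100.000
control          44      -0.010           13.636
```

The generator plants ρ = 0.6 for divergent pairs, 0.3 for the other
subtypes and 0 for controls, plus a lower expression level for overlapping
genes: the divergent group recovers the highest median correlation, the
control group sits at ρ ≈ 0 with few significant regressions, and the
expression comparison in `summary["expression_comparison"]` gives mean RPKM
2.53 (overlapping) vs 3.60 (control), rank-sum p ≈ 0.004.

The `examples/` directory has one short script per capability (filtering,
clustering, pair metrics, association, tissue variance, full pipeline), and
the same flow is scriptable from the shell:

```bash
ovgenes simulate --seed 7 --out sim/
ovgenes run-all --annotation sim/annotation.tsv \
    --expression sim/expression.tsv --tissues sim/tissues.tsv \
    --seed 7 --out run/
```

Every stage writes plain TSV; a rerun with the same config and inputs is
byte-identical.

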