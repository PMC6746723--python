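# Methods

## Coordinates and the overlap model

Gene boundaries are gene-level `(start, end)` positions, 1-based and
inclusive at both ends, as exported by Ensembl/BioMart; transcript and exon
structure is deliberately ignored. Two genes overlap iff they lie on the
same chromosome and `a.start ≤ b.end and b.start ≤ a.end` — a single shared
base counts, pure adjacency (`a.end + 1 == b.start`) does not. Overlap is
strand-agnostic: the convergent and divergent subtypes span both strands by
construction, so strand can play no role in detection. BED output converts
to 0-based half-open coordinates (`start − 1, end`).

An overlap **cluster** is a maximal connected component of the pairwise
overlap graph, not a clique: a long gene can bridge two genes that never
touch, and real annotations contain protocadherin-style blocks of 15–22
genes whose outer members are disjoint. Detection is a per-chromosome sweep
line over genes sorted by `(start, end, gene_id)`: a gene joins the open
cluster iff its start does not exceed the running maximum end, which yields
exactly the connected-component partition restricted to components of
size ≥ 2. An O(n²) union-find over the pairwise predicate serves as the
independent oracle in tests. Output order (chromosomes in natural order,
then span start) and member order are fully deterministic, and the
partition is invariant under input permutation.

## Filtering cascade

Stage order is fixed: biotype → non-primary assembly → duplicated gene
name → readthrough → novel-without-description → explicit exclusion list;
each removed record is charged to the first stage that catches it, so the
report identity `retained = input − Σ removed` holds on any input. Choices
where curation practice leaves room:

- *Duplicated names*: among records sharing a gene symbol the
  lexicographically smallest stable ID is kept — deterministic and
  reproducible, standing in for manual curation.
- *Readthrough*: an explicit flag column, or the token "readthrough"
  (case-insensitive) in the description; anything subtler belongs in the
  exclusion list, which also covers external cross-checks (e.g. against an
  NCBI accession mapping) without any download step.
- *Novel without description*: empty description **and** no official
  symbol.
- *Primary chromosomes*: autosomes 1–22 plus X and Y by default; MT
  excluded (configurable).
- Strand encodings `+/-` and `1/-1` are both accepted and normalised;
  anything else is rejected.

## Pair ordering, subtype and metrics

In a size-2 cluster the frontal gene (Gene_F) is the one with the smaller
start; ties go to the larger end (the containing gene), then to the smaller
gene_id. The subtype is a pure function of the (frontal, lateral) strands:
`(+,+) → tandem5`, `(+,-) → convergent`, `(-,+) → divergent`,
`(-,-) → tandem3`.

Metrics use inclusive-coordinate arithmetic (`length = end − start + 1`).
A pair is **embedded** when `L.end ≤ F.end`; embedded pairs are assigned
overlap interval 0 by convention (they have no two-sided shared boundary
region in the partial-overlap sense) and fall in the dedicated 100% bin of
the overlap-percentile histogram; they stay inside their strand-derived
subtype rather than forming a fifth class. For non-embedded pairs
`overlap = F.end − L.start + 1` and the identity
`length_F + length_L − overlap = block_length` with
`block_length = L.end − F.start + 1` holds exactly (tested over ≥ 10,000
generated pairs). Neighbour distances are simple coordinate differences to
the nearest gene entirely upstream of F / downstream of L (any strand, any
cluster membership, the pair itself excluded), so abutting genes sit at
distance 1; they are absent at chromosome ends. The per-chromosome mean
overlap interval is summarised both as the spread of chromosome means and
as the pair-weighted grand mean, since either averaging is defensible.

## Association statistics

- **Per pair**: Spearman ρ across all samples plus an ordinary
  least-squares regression of the lateral gene's expression on the frontal
  gene's (the genomically ordered orientation; configurable). R² and the
  slope-test p-value come from the same fit. RPKM values enter rank
  statistics untransformed (ranks are invariant under monotone maps);
  regression can optionally use log2(RPKM + 1), off by default. A
  zero-variance gene makes ρ undefined; such pairs are excluded listwise
  from group summaries with a count, never imputed.
- **Significance**: the headline per-group "% significant pairs" uses the
  raw regression p < α (α = 0.05); Benjamini–Hochberg q-values within each
  group are computed and reported alongside. `bh_adjust` implements the
  step-up rule `q_(i) = min_{j≥i} m·p_(j)/j` capped at 1 and is verified
  against a brute-force over-thresholds oracle and statsmodels.
- **Rank-sum test**: exact null distribution when both samples have ≤ 8
  tie-free observations, tie-corrected normal approximation otherwise;
  fully degenerate input returns p = 1 with the midrange statistic.
  Kruskal–Wallis (tie-corrected, via scipy) compares expression across the
  four subtypes, with all-pairwise rank-sum post hoc tests BH-corrected
  across the six comparisons.
- **Group correlation comparison**: per-pair ρ values are Fisher
  z-transformed; groups are compared by the difference of mean z with
  variance `1/(k·(n̄−3))` per group (k pairs, n̄ samples per correlation),
  two-sided normal p. Because pair correlations within a group are not
  strictly independent, a rank-sum test on the z values is emitted as a
  robustness check.
- **Control group**: a uniformly random, disjoint pairing of
  `2 × n_pairs` non-overlapping genes drawn without replacement from the
  filtered, expression-matched gene pool, seeded and deterministic. The
  expression-level comparison of overlapping vs control genes is run with
  the gene as sampling unit (default) and with pair means as a variant.
- **Tissue variance**: per pair, Spearman ρ within every tissue having at
  least `min_samples_per_tissue` samples (default 10); the cross-tissue
  variance is the `ddof=1` variance of those ρ, absent with < 2 usable
  tissues. The high-variance flag uses mean + 3·SD of the variance
  distribution across pairs by default (configurable); the flagged count is
  always computed, never hard-coded.

## Synthetic data generator

The generator is the test bed for every stage and defines the default
study conditions:

- **Genome**: 5 chromosomes (6–12 Mb), 44 paired clusters with subtype
  counts 4/20/16/4 (tandem5/convergent/divergent/tandem3 — the
  convergent+divergent-dominated mix observed in human annotations at
  roughly 1/40 scale), 8 triples, 2 quadruples, 1 quintuple, 1 sextuple,
  160 singletons. Gene lengths are log-normal (median 20 kb, σ = 0.8 on the
  log scale); about 24% of pairs are embedded. Pairs are laid out so the
  lateral gene starts strictly inside the frontal gene; larger clusters are
  transitive chains. Consecutive units are separated by ≥ 2 bp, so the
  post-filter overlap partition equals the planted truth exactly — this is
  what makes exact recovery tests meaningful. Filter-bait records
  (scaffolds, non-coding biotypes, duplicated names, readthroughs,
  undescribed novels) are always emitted so the cascade is exercised in
  every end-to-end run.
- **Expression**: five tissues named after a cell-line compendium panel
  (breast, CNS, haematopoietic, large intestine, lung) with 13/18/44/18/47
  samples — the original 545-line panel's proportions at about quarter
  scale. Per pair and tissue a bivariate normal latent is drawn with
  Pearson correlation `r = 2·sin(π·ρ_s/6)`, the exact inverse of the
  normal-copula Spearman map `ρ_s = (6/π)·asin(r/2)`, then pushed through
  `exp(μ_g + σ·z)` to a non-negative RPKM-like scale; rank correlation
  survives the monotone link exactly, so the planted ρ_s is the population
  Spearman. Defaults plant ρ = 0.6 for divergent pairs, 0.3 for the other
  subtypes, 0 for controls, and subtract 0.34 from overlapping genes'
  log-mean so controls sit at a higher RPKM level (mean ratio ≈ 1.4).

What the generator does **not** emulate: realistic human gene-length and
expression-level distributions beyond the log-normal defaults, ties/zeros
typical of lowly expressed genes, correlated gene neighbourhoods beyond the
planted pair structure, isoforms, or sequence content. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under a clean copula model, not robustness to every artefact of real
RNA-Seq compendia.

## Numerical and degenerate-input conventions

Sorting ties broken by `(start, end, gene_id)` everywhere for determinism;
empty inputs produce empty (header-only) outputs rather than errors where
the contract allows; variance of fewer than two values is reported as
absent (`None`/NaN), not 0; Fisher's z refuses |r| = 1 and n ≤ 3; BH
validates p ∈ [0, 1]. All randomness flows through
`numpy.random.default_rng(seed)`; for a fixed seed the association stage is
bit-reproducible and a pipeline rerun is byte-identical.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale as a matter of
design: the default genome (~313 records), 200 random instances of 20–320
genes plus two ~5,000-gene generator instances for the clustering oracle
check, 4 × 2,500 pairs for the structural identity, 100 seeds for subtype
recovery, 100 replicates × 500 samples for correlation recovery and a
200-pair null at 500 samples for type-I calibration.

## Known limitations

- Cluster subtype taxonomy applies to pairs only; clusters of size ≥ 3 get
  a size class but no orientation labels.
- The Fisher-z group comparison treats per-pair correlations as
  independent, which overlapping neighbourhoods may mildly violate; the
  accompanying rank-sum check is the guard.
- Per-rep recovery of a planted Spearman ρ from n samples is limited by the
  estimator's sampling SD (≈ `sqrt(1/(n−1))` near ρ = 0, i.e. ~0.045 at
  n = 500); recovery claims tighter than that are not achievable at that
  sample size and are not made by the generator.
- The filtering cascade trusts annotation text fields (description,
  symbol) for readthrough/novel detection; annotations with different
  conventions should use the exclusion-list mechanism.
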