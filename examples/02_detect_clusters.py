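"""Detecting overlapping-gene clusters.

Overlap is strand-agnostic sharing of at least one base; clusters are
connected components of the pairwise-overlap graph, so two genes that never
touch can still share a cluster through a common partner (transitivity).
"""

from ovgenes import GeneRecord, find_overlap_clusters, cluster_size_distribution

genes = [
    # a chain: A-B overlap, B-C overlap, A-C do not -> one triple cluster
    GeneRecord("A", "1", 1, 100, "+", gene_name="A", description="d"),
    GeneRecord("B", "1", 50, 150, "-", gene_name="B", description="d"),
    GeneRecord("C", "1", 140, 200, "+", gene_name="C", description="d"),
    # an isolated gene -> no cluster
    GeneRecord("D", "1", 300, 400, "+", gene_name="D", description="d"),
    # a pair touching in exactly one base (500) -> still an overlap
    GeneRecord("E", "2", 100, 500, "+", gene_name="E", description="d"),
    GeneRecord("F", "2", 500, 900, "-", gene_name="F", description="d"),
]

clusters = find_overlap_clusters(genes)
for c in clusters:
    print(f"{c.cluster_id}: chr{c.chromosome} {c.size_class:10s} "
          f"span {c.span_start}-{c.span_end} members {','.join(c.members)}")

print()
print("gene counts per chromosome and size class:")
print(cluster_size_distribution(clusters))
# The triple {A,B,C} counts 3 genes, the pair {E,F} counts 2; D overlaps
# nothing and belongs to no cluster.
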