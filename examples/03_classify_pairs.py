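"""Classifying a paired overlap and computing its structural metrics.

The frontal gene (Gene_F) starts first; the subtype follows the strand
orientations of (frontal, lateral): tandem5 (+,+), convergent (+,-),
divergent (-,+), tandem3 (-,-).
"""

from ovgenes import GeneRecord, find_overlap_clusters, pairs_from_clusters

genes = [
    GeneRecord("UP", "1", 10, 99, "+", gene_name="UP", description="d"),
    GeneRecord("F", "1", 100, 500, "+", gene_name="F", description="d"),
    GeneRecord("L", "1", 400, 900, "-", gene_name="L", description="d"),
    GeneRecord("DN", "1", 903, 1200, "+", gene_name="DN", description="d"),
    # an embedded pair: the lateral gene lies entirely inside the frontal
    GeneRecord("F2", "2", 1_000, 10_000, "-", gene_name="F2", description="d"),
    GeneRecord("L2", "2", 2_000, 3_000, "-", gene_name="L2", description="d"),
]

clusters = find_overlap_clusters(genes)
for pair, m in pairs_from_clusters(clusters, genes):
    print(f"pair {pair.pair_id}: F={pair.gene_F} L={pair.gene_L} "
          f"subtype={pair.subtype}")
    print(f"  lengths F/L       : {m.length_F} / {m.length_L} bp")
    print(f"  overlap interval  : {m.overlap_interval} bp"
          + ("  (embedded: defined as 0)" if m.embedded else ""))
    print(f"  block length      : {m.block_length} bp")
    print(f"  distance to up/down neighbour: {m.distance_F} / {m.distance_L}")
    if not m.embedded:
        assert m.length_F + m.length_L - m.overlap_interval == m.block_length

# For the first pair: 401 + 501 - 101 = 801 bp block; the upstream gene ends
# at 99 and F starts at 100, so distance_F = 1 (abutting neighbours).
# The second pair is tandem3 and embedded: overlap interval 0, 100% bin.
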