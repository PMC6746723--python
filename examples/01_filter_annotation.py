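"""Filtering a gene annotation down to curated protein-coding genes.

Builds a small annotation containing records that each stage of the cascade
should remove — a scaffold-placed gene, a non-coding biotype, a duplicated
gene name, a readthrough transcript and an undescribed novel gene — and
prints the per-stage removal counts.
"""

from ovgenes import GeneRecord, filter_genes

records = [
    GeneRecord("ENSG001", "1", 1_000, 9_000, "+", gene_name="ALPHA",
               description="alpha subunit"),
    GeneRecord("ENSG002", "1", 20_000, 30_000, "-", gene_name="BETA",
               description="beta subunit"),
    # scaffold / assembly-exception chromosome name
    GeneRecord("ENSG003", "KI270728.1", 500, 4_000, "+", gene_name="SCAF1",
               description="patch-placed copy"),
    # non-protein-coding biotype
    GeneRecord("ENSG004", "2", 5_000, 8_000, "+", biotype="lincRNA",
               gene_name="LINC1", description="long non-coding RNA"),
    # duplicated gene name: the lexicographically larger ID is dropped
    GeneRecord("ENSG005", "2", 40_000, 50_000, "+", gene_name="ALPHA",
               description="alpha subunit, second locus"),
    # readthrough transcript, recognised from its description
    GeneRecord("ENSG006", "3", 1_000, 90_000, "+", gene_name="GENE1-GENE2",
               description="GENE1-GENE2 readthrough"),
    # novel gene: no symbol, no description
    GeneRecord("ENSG007", "3", 100_000, 110_000, "-"),
]

genes, report = filter_genes(records)

print("filter report:")
for stage, count in report.as_dict().items():
    print(f"  {stage:32s} {count}")
print("retained gene IDs:", [g.gene_id for g in genes])

# Each bait is charged to exactly one stage, and
# retained = input - sum(removed): here 7 records in, 5 removed, 2 kept.
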