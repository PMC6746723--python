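import numpy as np
import pytest

from ovgenes.annotation import GeneRecord, filter_genes
from ovgenes.clusters import find_overlap_clusters
from ovgenes.expression import ExpressionPair, sample_control_pairs
from ovgenes.pairs import pairs_from_clusters
from ovgenes.simulate import (
    AnnotationConfig, ExpressionConfig, generate_annotation, generate_expression,
)


def make_gene(gene_id, start, end, strand="+", chrom="1", **kw):
    kw.setdefault("gene_name", f"N{gene_id}")
    kw.setdefault("description", f"gene {gene_id}")
    return GeneRecord(
        gene_id=gene_id, chromosome=chrom, start=start, end=end,
        strand=strand, **kw,
    )


@pytest.fixture
def gene():
    """Factory for minimal valid GeneRecords."""
    return make_gene


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A default synthetic genome run through filter + detect + classify."""
    records, truth = generate_annotation(AnnotationConfig(), seed=11)
    genes, report = filter_genes(records)
    clusters = find_overlap_clusters(genes)
    pwm = pairs_from_clusters(clusters, genes)
    return {
        "records": records,
        "truth": truth,
        "genes": genes,
        "report": report,
        "clusters": clusters,
        "pairs_with_metrics": pwm,
    }


@pytest.fixture(scope="session")
def expression_dataset(synthetic_dataset):
    """Expression matrix + overlap and control pairs for the session genome."""
    truth = synthetic_dataset["truth"]
    pwm = synthetic_dataset["pairs_with_metrics"]
    pairs = [ExpressionPair(p.pair_id, p.gene_F, p.gene_L, p.subtype)
             for p, _ in pwm]
    singles = list(truth.planted_singletons)
    matrix = generate_expression(
        pairs, ExpressionConfig(), seed=11, extra_genes=singles, truth=truth,
    )
    controls = sample_control_pairs(singles, len(pairs), seed=11)
    matrix_with_controls = generate_expression(
        pairs + controls, ExpressionConfig(), seed=11, truth=truth,
    )
    return {
        "pairs": pairs,
        "controls": controls,
        "matrix": matrix_with_controls,
        "truth": truth,
    }
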