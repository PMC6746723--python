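"""Overlapping-gene cluster detection.

Two genes overlap when their 1-based inclusive intervals share at least one
base on the same chromosome; strand is ignored (head-to-head and tail-to-tail
overlaps span both strands).  A cluster is a maximal connected component of
the pairwise-overlap graph — membership is transitive, so a 22-gene
protocadherin-style block counts as one cluster even though its outermost
genes never touch each other.

Detection is a per-chromosome sweep line: with genes sorted by start, a gene
joins the open cluster iff its start does not pass the running maximum end.
This is exactly the connected-component partition restricted to components
of size >= 2 (singletons are non-overlapping genes and are discarded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GeneRecord, chromosome_sort_key

__all__ = [
    "OverlapCluster",
    "SIZE_CLASSES",
    "size_class",
    "overlaps",
    "find_overlap_clusters",
    "cluster_size_distribution",
    "size_class_percentages",
]

#: Cluster size classes, in increasing-size order.
SIZE_CLASSES = ("paired", "triple", "quadruple", "quintuple", "above_sextuple")


def size_class(n: int) -> str:
    """Map a cluster size (>=2) to its class label; >=6 pools into one class."""
    if n < 2:
        raise ValueError(f"cluster size must be >= 2, got {n}")
    if n <= 5:
        return SIZE_CLASSES[n - 2]
    return "above_sextuple"


@dataclass(frozen=True)
class OverlapCluster:
    """A maximal set of >=2 mutually connected overlapping genes."""

    cluster_id: str
    chromosome: str
    members: tuple[str, ...]  # gene_ids, ascending (start, end, gene_id)
    span_start: int
    span_end: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def size_class(self) -> str:
        return size_class(self.size)


def overlaps(a: GeneRecord, b: GeneRecord) -> bool:
    """True iff the two genes share >= 1 bp on the same chromosome.

    Pure adjacency (``a.end + 1 == b.start``) is not overlap; a single
    shared base is.  Strand plays no role.
    """
    return (
        a.chromosome == b.chromosome
        and a.start <= b.end
        and b.start <= a.end
    )


def _sorted_chrom_genes(genes: Sequence[GeneRecord]) -> dict[str, list[GeneRecord]]:
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return by_chrom


def find_overlap_clusters(genes: Sequence[GeneRecord]) -> list[OverlapCluster]:
    """Partition genes into overlap clusters (connected components, size >= 2).

    Output order is deterministic: chromosomes in natural order, clusters by
    span start within each chromosome.  Cluster IDs are assigned in that
    order as ``OVC00001``, ``OVC00002``, ...
    """
    by_chrom = _sorted_chrom_genes(genes)
    raw: list[tuple[str, list[GeneRecord]]] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        open_members: list[GeneRecord] = []
        max_end = -1
        for g in by_chrom[chrom]:
            if open_members and g.start <= max_end:
                open_members.append(g)
                max_end = max(max_end, g.end)
            else:
                if len(open_members) >= 2:
                    raw.append((chrom, open_members))
                open_members = [g]
                max_end = g.end
        if len(open_members) >= 2:
            raw.append((chrom, open_members))

    clusters = []
    for idx, (chrom, members) in enumerate(raw, start=1):
        clusters.append(
            OverlapCluster(
                cluster_id=f"OVC{idx:05d}",
                chromosome=chrom,
                members=tuple(g.gene_id for g in members),
                span_start=min(g.start for g in members),
                span_end=max(g.end for g in members),
            )
        )
    return clusters


def cluster_size_distribution(clusters: Sequence[OverlapCluster]) -> pd.DataFrame:
    """Gene counts per (chromosome x size class), with margin totals.

    Counts genes, not clusters: one triple cluster contributes 3 to its
    chromosome's ``triple`` cell.  A ``total`` row and column are appended;
    the grand total is the number of overlapping genes.
    """
    chroms = sorted({c.chromosome for c in clusters}, key=chromosome_sort_key)
    table = pd.DataFrame(0, index=chroms, columns=list(SIZE_CLASSES), dtype=int)
    for c in clusters:
        table.loc[c.chromosome, c.size_class] += c.size
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "chromosome"
    return table


def size_class_percentages(gene_counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of overlapping genes in each size class.

    ``gene_counts`` maps size-class label to the number of genes in clusters
    of that class; percentages are of the summed total.
    """
    total = sum(gene_counts.values())
    if total == 0:
        return {k: 0.0 for k in gene_counts}
    return {k: 100.0 * v / total for k, v in gene_counts.items()}
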