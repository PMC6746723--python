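"""Classification and structural metrics of paired (size-2) overlap clusters.

Within a pair the *frontal* gene (Gene_F) is the one with the smaller start
coordinate and the *lateral* gene (Gene_L) the other; ties on start go to the
larger end (the containing gene), then to the smaller gene_id.  The four
subtypes follow the (frontal, lateral) strand orientations:

================  ==========  =========================================
subtype           strands     biology
================  ==========  =========================================
tandem5 (5'-tandem)  + +      co-oriented, lateral downstream
convergent           + -      tail-to-tail, 3' ends overlap
divergent            - +      head-to-head, candidate shared promoter
tandem3 (3'-tandem)  - -      co-oriented on the reverse strand
================  ==========  =========================================

Structural metrics (all bp, 1-based inclusive arithmetic):

* ``length = end - start + 1``
* ``block_length = L.end - F.start + 1`` (frontal start to lateral end)
* ``overlap_interval = F.end - L.start + 1`` for partial overlaps; defined
  as 0 for *embedded* pairs (lateral entirely inside frontal,
  ``L.end <= F.end``), which by convention have "no overlapping interval"
* ``distance_F`` / ``distance_L``: simple coordinate difference to the
  nearest fully-upstream / fully-downstream gene, so abutting neighbours
  are at distance 1; absent at chromosome ends.

For non-embedded pairs the identity
``length_F + length_L - overlap_interval == block_length`` holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, chromosome_sort_key
from .clusters import OverlapCluster

__all__ = [
    "SUBTYPES",
    "OverlapPair",
    "PairMetrics",
    "order_pair",
    "classify_subtype",
    "compute_pair_metrics",
    "pairs_from_clusters",
    "pairs_table",
    "summarize_pairs",
    "PCT_BIN_LABELS",
]

SUBTYPES = ("tandem5", "convergent", "divergent", "tandem3")

_SUBTYPE_OF_STRANDS = {
    ("+", "+"): "tandem5",
    ("+", "-"): "convergent",
    ("-", "+"): "divergent",
    ("-", "-"): "tandem3",
}


@dataclass(frozen=True)
class OverlapPair:
    pair_id: str
    gene_F: str
    gene_L: str
    subtype: str


@dataclass(frozen=True)
class PairMetrics:
    length_F: int
    length_L: int
    overlap_interval: int
    block_length: int
    embedded: bool
    overlap_pct_of_L: float
    distance_F: Optional[int] = None
    distance_L: Optional[int] = None


def order_pair(
    cluster: OverlapCluster, genes_by_id: Mapping[str, GeneRecord]
) -> OverlapPair:
    """Assign frontal/lateral roles in a size-2 cluster and classify it."""
    if cluster.size != 2:
        raise ValueError(
            f"order_pair requires a size-2 cluster, got size {cluster.size}"
        )
    a, b = (genes_by_id[m] for m in cluster.members)
    # frontal: smaller start; tie -> larger end (containing gene); tie -> id
    if (a.start, -a.end, a.gene_id) <= (b.start, -b.end, b.gene_id):
        f, l = a, b
    else:
        f, l = b, a
    return OverlapPair(
        pair_id=cluster.cluster_id,
        gene_F=f.gene_id,
        gene_L=l.gene_id,
        subtype=classify_subtype(f, l),
    )


def classify_subtype(frontal: GeneRecord, lateral: GeneRecord) -> str:
    """Four-way strand-orientation subtype of an ordered (frontal, lateral) pair."""
    return _SUBTYPE_OF_STRANDS[(frontal.strand, lateral.strand)]


def compute_pair_metrics(
    pair: OverlapPair,
    genes_by_id: Mapping[str, GeneRecord],
    chromosome_genes: Sequence[GeneRecord],
) -> PairMetrics:
    """All structural quantities for one ordered pair.

    ``chromosome_genes`` is the full filtered gene set of the pair's
    chromosome (any order); the nearest-neighbour distances consider every
    gene there except the pair itself, regardless of strand or of the
    neighbour's own cluster membership.
    """
    f = genes_by_id[pair.gene_F]
    l = genes_by_id[pair.gene_L]
    embedded = l.end <= f.end
    overlap = 0 if embedded else f.end - l.start + 1
    block = l.end - f.start + 1
    pct = 100.0 if embedded else 100.0 * overlap / l.length

    up_end = None
    down_start = None
    pair_ids = {f.gene_id, l.gene_id}
    for g in chromosome_genes:
        if g.gene_id in pair_ids:
            continue
        if g.end < f.start and (up_end is None or g.end > up_end):
            up_end = g.end
        if g.start > l.end and (down_start is None or g.start < down_start):
            down_start = g.start

    return PairMetrics(
        length_F=f.length,
        length_L=l.length,
        overlap_interval=overlap,
        block_length=block,
        embedded=embedded,
        overlap_pct_of_L=pct,
        distance_F=None if up_end is None else f.start - up_end,
        distance_L=None if down_start is None else down_start - l.end,
    )


def pairs_from_clusters(
    clusters: Sequence[OverlapCluster],
    genes: Sequence[GeneRecord],
) -> list[tuple[OverlapPair, PairMetrics]]:
    """Order, classify and measure every size-2 cluster."""
    genes_by_id = {g.gene_id: g for g in genes}
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out = []
    for cl in clusters:
        if cl.size != 2:
            continue
        pair = order_pair(cl, genes_by_id)
        metrics = compute_pair_metrics(pair, genes_by_id, by_chrom[cl.chromosome])
        out.append((pair, metrics))
    return out


def pairs_table(
    pairs_with_metrics: Sequence[tuple[OverlapPair, PairMetrics]],
    genes: Sequence[GeneRecord],
) -> pd.DataFrame:
    """Flat per-pair table (one row per pair) for output and summaries."""
    genes_by_id = {g.gene_id: g for g in genes}
    rows = []
    for pair, m in pairs_with_metrics:
        f = genes_by_id[pair.gene_F]
        rows.append({
            "pair_id": pair.pair_id,
            "chromosome": f.chromosome,
            "gene_F": pair.gene_F,
            "gene_L": pair.gene_L,
            "subtype": pair.subtype,
            "length_F": m.length_F,
            "length_L": m.length_L,
            "overlap_interval": m.overlap_interval,
            "block_length": m.block_length,
            "embedded": m.embedded,
            "overlap_pct_of_L": m.overlap_pct_of_L,
            "distance_F": m.distance_F,
            "distance_L": m.distance_L,
        })
    cols = ["pair_id", "chromosome", "gene_F", "gene_L", "subtype",
            "length_F", "length_L", "overlap_interval", "block_length",
            "embedded", "overlap_pct_of_L", "distance_F", "distance_L"]
    return pd.DataFrame(rows, columns=cols)


#: Overlap-percentile bins: ten half-open decades plus a dedicated
#: 100% category holding the embedded pairs.
PCT_BIN_LABELS = [f"[{10 * i}-{10 * (i + 1)})" for i in range(10)] + ["100 (embedded)"]


def _pct_bin(pct: float, embedded: bool) -> str:
    if embedded:
        return PCT_BIN_LABELS[-1]
    idx = min(int(pct // 10), 9)
    return PCT_BIN_LABELS[idx]


def _minmaxmean(values) -> dict:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return {"n": 0, "min": math.nan, "max": math.nan,
                "mean": math.nan, "sd": math.nan}
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
    }


def summarize_pairs(
    pairs_with_metrics: Sequence[tuple[OverlapPair, PairMetrics]],
    genes: Sequence[GeneRecord],
) -> dict[str, pd.DataFrame]:
    """Summary tables over all pairs.

    Returns a dict with three DataFrames:

    ``metrics_summary``
        min/max/mean/SD of gene lengths (all, frontal, lateral), overlap
        interval (embedded counted as 0), block length, the neighbour
        distances, and the per-chromosome mean overlap interval (summarised
        both as the spread of chromosome means and, via the plain
        ``overlap_interval`` row, as the pair-weighted grand mean).
    ``chromosome_subtypes``
        per-chromosome gene counts (2 per pair) for each subtype, the
        subtotal, the chromosome's total gene count from ``genes``, and the
        percentage of that chromosome's genes in paired overlaps.
    ``pct_histogram``
        counts of pairs per overlap-percentile bin, per subtype and total.
    """
    df = pairs_table(pairs_with_metrics, genes)

    # --- Table-1-style metric summary -------------------------------------
    rows = {}
    all_lengths = list(df["length_F"]) + list(df["length_L"])
    rows["gene_length"] = _minmaxmean(all_lengths)
    rows["length_F"] = _minmaxmean(df["length_F"])
    rows["length_L"] = _minmaxmean(df["length_L"])
    rows["overlap_interval"] = _minmaxmean(df["overlap_interval"])
    rows["block_length"] = _minmaxmean(df["block_length"])
    rows["distance_F"] = _minmaxmean(df["distance_F"].dropna())
    rows["distance_L"] = _minmaxmean(df["distance_L"].dropna())
    if len(df):
        chrom_means = df.groupby("chromosome")["overlap_interval"].mean()
        rows["mean_overlap_interval_by_chromosome"] = _minmaxmean(chrom_means)
    metrics_summary = pd.DataFrame(rows).T
    metrics_summary.index.name = "metric"

    # --- Table-2-style chromosome x subtype distribution ------------------
    chrom_totals: dict[str, int] = {}
    for g in genes:
        chrom_totals[g.chromosome] = chrom_totals.get(g.chromosome, 0) + 1
    chroms = sorted(chrom_totals, key=chromosome_sort_key)
    dist = pd.DataFrame(0, index=chroms, columns=list(SUBTYPES), dtype=int)
    for _, row in df.iterrows():
        dist.loc[row["chromosome"], row["subtype"]] += 2  # genes, not pairs
    dist["subtotal"] = dist.sum(axis=1)
    dist["total_genes"] = [chrom_totals[c] for c in chroms]
    dist["pct_overlapping"] = 100.0 * dist["subtotal"] / dist["total_genes"]
    total = dist.sum(axis=0)
    total["pct_overlapping"] = (
        100.0 * total["subtotal"] / total["total_genes"] if total["total_genes"] else 0.0
    )
    dist.loc["total"] = total
    dist.index.name = "chromosome"

    # --- overlap-percentile histogram -------------------------------------
    hist = pd.DataFrame(0, index=PCT_BIN_LABELS, columns=list(SUBTYPES), dtype=int)
    for _, row in df.iterrows():
        hist.loc[_pct_bin(row["overlap_pct_of_L"], row["embedded"]), row["subtype"]] += 1
    hist["total"] = hist.sum(axis=1)
    hist.index.name = "overlap_pct_of_L_bin"

    return {
        "metrics_summary": metrics_summary,
        "chromosome_subtypes": dist,
        "pct_histogram": hist,
    }
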