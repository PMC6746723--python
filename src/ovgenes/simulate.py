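"""Synthetic annotation and expression fixtures with known ground truth.

The generator emulates the shape of a curated human-style gene annotation
and an RPKM expression compendium at desk scale, so that every pipeline
stage (filtering, cluster detection, pair classification, association) can
be exercised end to end and its output checked against the planted truth.

Annotation side
---------------
Overlap clusters of configurable sizes are planted on multiple chromosomes
with an explicit geometry: pairs get a strand-orientation subtype and an
embedded/partial layout, larger clusters are built as transitive chains
(consecutive genes overlap; distant members need not).  Consecutive planted
units are separated by >= 2 bp, so the post-filter overlap structure equals
the planted truth exactly.  "Filter bait" records — scaffold chromosomes,
non-protein-coding biotypes, duplicated gene names, readthrough and
novel-without-description genes — are always included so the filtering
cascade does real work in every run.

Expression side
---------------
Per pair and tissue, a latent bivariate normal is drawn whose Pearson
correlation is chosen so the *rank* correlation hits the planted target
(Spearman-Pearson map for bivariate normals: rho_s = (6/pi) asin(r/2),
inverted as r = 2 sin(pi rho_s / 6)); the latents are pushed through an
exponential link to a non-negative RPKM-like scale.  Rank correlation is
invariant under that strictly increasing map, so the target survives
exactly in distribution.  Unpaired genes are independent, and overlapping
genes can carry a mean shift relative to controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord
from .expression import ExpressionMatrix, ExpressionPair, CONTROL_GROUP
from .pairs import SUBTYPES

__all__ = [
    "AnnotationConfig",
    "ExpressionConfig",
    "PlantedCluster",
    "SyntheticTruth",
    "generate_annotation",
    "generate_expression",
    "latent_pearson_for_spearman",
]


@dataclass
class AnnotationConfig:
    """Layout of the synthetic genome.

    ``cluster_counts`` maps cluster size (>= 2) to the number of clusters of
    that size; ``subtype_counts`` allocates the size-2 clusters across the
    four strand-orientation subtypes and must sum to ``cluster_counts[2]``.
    Gene lengths are log-normal; inter-unit gaps uniform in
    ``[min_gap, max_gap]``.  Defaults plant a small multi-chromosome genome
    with the subtype mix skewed toward convergent/divergent pairs and about
    a quarter of pairs embedded, echoing the composition reported for the
    human annotation at roughly 1/40 scale.
    """

    chromosomes: dict = field(default_factory=lambda: {
        "1": 12_000_000, "2": 10_000_000, "3": 9_000_000,
        "4": 8_000_000, "X": 6_000_000,
    })
    cluster_counts: dict = field(default_factory=lambda: {2: 44, 3: 8, 4: 2, 5: 1, 6: 1})
    subtype_counts: dict = field(default_factory=lambda: {
        "tandem5": 4, "convergent": 20, "divergent": 16, "tandem3": 4,
    })
    embedded_fraction: float = 0.24
    n_singletons: int = 160
    gene_length_log_mean: float = math.log(20_000.0)
    gene_length_log_sd: float = 0.8
    min_gene_length: int = 200
    min_gap: int = 2
    max_gap: int = 20_000
    # filter baits (all removed by the cascade except one of each duplicate
    # name couple, which survives as a singleton)
    n_scaffold_records: int = 4
    n_non_protein_coding: int = 5
    n_duplicate_name_couples: int = 3
    n_readthrough: int = 3
    n_novel_without_description: int = 4

    def validate(self) -> None:
        n_paired = self.cluster_counts.get(2, 0)
        if sum(self.subtype_counts.values()) != n_paired:
            raise ValueError(
                f"subtype_counts sum to {sum(self.subtype_counts.values())} "
                f"but {n_paired} paired clusters requested"
            )
        unknown = set(self.subtype_counts) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes: {unknown}")
        if not 0.0 <= self.embedded_fraction <= 1.0:
            raise ValueError("embedded_fraction must lie in [0, 1]")
        for size in self.cluster_counts:
            if size < 2:
                raise ValueError("cluster sizes must be >= 2")


@dataclass(frozen=True)
class PlantedCluster:
    chromosome: str
    members: tuple[str, ...]           # gene_ids, ascending start
    subtype: Optional[str] = None      # size-2 clusters only
    embedded: Optional[bool] = None    # size-2 clusters only

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    seed: int
    planted_clusters: list = field(default_factory=list)
    planted_singletons: list = field(default_factory=list)
    planted_rho: dict = field(default_factory=dict)       # (pair_id, tissue) -> rho
    planted_group_shift: float = 0.0
    config: dict = field(default_factory=dict)

    def subtype_of(self, members) -> Optional[str]:
        key = frozenset(members)
        for cl in self.planted_clusters:
            if frozenset(cl.members) == key:
                return cl.subtype
        return None

    def cluster_partition(self) -> set[frozenset]:
        return {frozenset(cl.members) for cl in self.planted_clusters}


_SUBTYPE_STRANDS = {
    "tandem5": ("+", "+"),
    "convergent": ("+", "-"),
    "divergent": ("-", "+"),
    "tandem3": ("-", "-"),
}


def _draw_length(rng, cfg: AnnotationConfig) -> int:
    ln = rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd)
    return max(cfg.min_gene_length, int(ln))


def _pair_geometry(rng, cfg: AnnotationConfig, embedded: bool) -> tuple[int, int, int]:
    """Return (len_F, len_L, lateral start offset) for a pair at origin 0."""
    while True:
        lf = _draw_length(rng, cfg)
        ll = _draw_length(rng, cfg)
        if embedded:
            if ll <= lf - 2:          # strictly inside, distinct start
                offset = int(rng.integers(1, lf - ll + 1))
                return lf, ll, offset
        else:
            lo = max(1, lf - ll + 1)  # lateral must end past the frontal end
            hi = lf - 1               # and start inside the frontal gene
            if lo <= hi:
                offset = int(rng.integers(lo, hi + 1))
                return lf, ll, offset


def generate_annotation(
    config: Optional[AnnotationConfig] = None,
    seed: int = 0,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Build a synthetic annotation whose post-filter overlap structure is
    exactly the planted truth; deterministic per seed."""
    cfg = config or AnnotationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, config=asdict(cfg))

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"OVG{counter:05d}"

    # --- build the unit list (clusters + singletons), then scatter --------
    units = []  # each: ("pair", subtype, embedded) | ("cluster", size) | ("singleton",)
    for subtype, n in cfg.subtype_counts.items():
        for _ in range(n):
            embedded = bool(rng.random() < cfg.embedded_fraction)
            units.append(("pair", subtype, embedded))
    for size, n in sorted(cfg.cluster_counts.items()):
        if size == 2:
            continue
        units.extend([("cluster", size)] * n)
    units.extend([("singleton",)] * cfg.n_singletons)
    rng.shuffle(units)

    chrom_names = list(cfg.chromosomes)
    cursors = {c: int(rng.integers(1, 10_000)) for c in chrom_names}
    records: list[GeneRecord] = []

    def place_gene(chrom, start, end, strand, name_suffix="") -> GeneRecord:
        gid = next_id()
        rec = GeneRecord(
            gene_id=gid,
            chromosome=chrom,
            start=start,
            end=end,
            strand=strand,
            biotype="protein_coding",
            gene_name=f"SYN{gid[3:]}{name_suffix}",
            description=f"synthetic protein-coding gene {gid}",
        )
        records.append(rec)
        return rec

    for i, unit in enumerate(units):
        chrom = chrom_names[i % len(chrom_names)]
        length_limit = cfg.chromosomes[chrom]
        cursor = cursors[chrom]

        if unit[0] == "pair":
            _, subtype, embedded = unit
            lf, ll, offset = _pair_geometry(rng, cfg, embedded)
            sf, ef = cursor, cursor + lf - 1
            sl, el = cursor + offset, cursor + offset + ll - 1
            strand_f, strand_l = _SUBTYPE_STRANDS[subtype]
            if max(ef, el) > length_limit:
                raise ValueError(
                    f"chromosome {chrom} too short for the requested clusters"
                )
            f = place_gene(chrom, sf, ef, strand_f)
            l = place_gene(chrom, sl, el, strand_l)
            truth.planted_clusters.append(PlantedCluster(
                chromosome=chrom, members=(f.gene_id, l.gene_id),
                subtype=subtype, embedded=embedded,
            ))
            unit_end = max(ef, el)
        elif unit[0] == "cluster":
            size = unit[1]
            members = []
            start = cursor
            max_end = start - 1
            prev_start = start - 1
            for j in range(size):
                gl = _draw_length(rng, cfg)
                if j == 0:
                    s = start
                else:
                    # overlap the running region; strictly increasing starts
                    s = int(rng.integers(prev_start + 1, max_end + 1))
                e = s + gl - 1
                if e > length_limit:
                    raise ValueError(
                        f"chromosome {chrom} too short for the requested clusters"
                    )
                g = place_gene(chrom, s, e, "+" if rng.random() < 0.5 else "-")
                members.append(g.gene_id)
                prev_start = s
                max_end = max(max_end, e)
            truth.planted_clusters.append(PlantedCluster(
                chromosome=chrom, members=tuple(members),
            ))
            unit_end = max_end
        else:  # singleton
            gl = _draw_length(rng, cfg)
            e = cursor + gl - 1
            if e > length_limit:
                raise ValueError(
                    f"chromosome {chrom} too short for the requested clusters"
                )
            g = place_gene(chrom, cursor, e, "+" if rng.random() < 0.5 else "-")
            truth.planted_singletons.append(g.gene_id)
            unit_end = e

        cursors[chrom] = unit_end + int(
            rng.integers(max(2, cfg.min_gap), cfg.max_gap + 1)
        )

    # --- filter baits ------------------------------------------------------
    def bait_pos(chrom):
        cursor = cursors[chrom]
        gl = _draw_length(rng, cfg)
        cursors[chrom] = cursor + gl + int(rng.integers(2, cfg.max_gap + 1))
        return cursor, cursor + gl - 1

    for k in range(cfg.n_scaffold_records):
        s, e = 1_000 * (k + 1), 1_000 * (k + 1) + 5_000
        gid = next_id()
        records.append(GeneRecord(
            gene_id=gid, chromosome=f"KI27{700 + k}.1", start=s, end=e,
            strand="+", biotype="protein_coding",
            gene_name=f"SCAF{k}", description="scaffold-placed gene",
        ))
    for k in range(cfg.n_non_protein_coding):
        chrom = chrom_names[k % len(chrom_names)]
        s, e = bait_pos(chrom)
        gid = next_id()
        records.append(GeneRecord(
            gene_id=gid, chromosome=chrom, start=s, end=e, strand="-",
            biotype="lincRNA", gene_name=f"LNC{k}",
            description="non-coding bait",
        ))
    for k in range(cfg.n_duplicate_name_couples):
        chrom = chrom_names[k % len(chrom_names)]
        s, e = bait_pos(chrom)
        keep = place_gene(chrom, s, e, "+")
        # the duplicate shares the name; larger gene_id, so it is the one
        # removed — its coordinates may overlap the survivor harmlessly
        gid = next_id()
        records.append(GeneRecord(
            gene_id=gid, chromosome=chrom, start=s + 5, end=e + 5, strand="+",
            biotype="protein_coding", gene_name=keep.gene_name,
            description="duplicated-name bait",
        ))
        truth.planted_singletons.append(keep.gene_id)
    for k in range(cfg.n_readthrough):
        chrom = chrom_names[k % len(chrom_names)]
        s, e = bait_pos(chrom)
        gid = next_id()
        records.append(GeneRecord(
            gene_id=gid, chromosome=chrom, start=s, end=e, strand="+",
            biotype="protein_coding", gene_name=f"RT{k}A-RT{k}B",
            description=f"RT{k}A-RT{k}B readthrough",
        ))
    for k in range(cfg.n_novel_without_description):
        chrom = chrom_names[k % len(chrom_names)]
        s, e = bait_pos(chrom)
        gid = next_id()
        records.append(GeneRecord(
            gene_id=gid, chromosome=chrom, start=s, end=e, strand="-",
            biotype="protein_coding", gene_name=None, description=None,
        ))

    return records, truth


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionConfig:
    """Shape of the synthetic expression compendium.

    Default tissue panel mirrors a five-tissue cancer cell-line compendium
    (breast / CNS / haematopoietic / large intestine / lung) at about 1/4
    of the original 545 cell lines, keeping the tissue proportions.
    ``rho_by_group`` plants the target rank correlation per pair group,
    strongest for divergent (head-to-head) pairs and zero for controls;
    ``group_log_shift`` lowers the overlapping genes' log-mean so the
    control group sits at a higher RPKM level.
    """

    tissues: dict = field(default_factory=lambda: {
        "breast": 13, "CNS": 18, "H_L_Tissue": 44, "L_Intestine": 18, "lung": 47,
    })
    rho_by_group: dict = field(default_factory=lambda: {
        "tandem5": 0.3, "convergent": 0.3, "divergent": 0.6, "tandem3": 0.3,
        CONTROL_GROUP: 0.0,
    })
    #: optional per-pair or per-(pair, tissue) overrides of the planted rho
    rho_overrides: dict = field(default_factory=dict)
    base_log_mean: float = 1.0
    gene_log_sd: float = 0.8      # between-gene spread of log-mean expression
    noise_log_sd: float = 0.6     # within-gene across-sample spread
    group_log_shift: float = 0.34  # subtracted from overlapping genes' log-mean


def latent_pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of the bivariate-normal latent that yields the
    target Spearman correlation: inverse of rho_s = (6/pi) asin(r/2)."""
    if not -1.0 < rho_s < 1.0:
        raise ValueError(f"planted rank correlation must lie in (-1, 1), got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _target_rho(cfg: ExpressionConfig, pair: ExpressionPair, tissue: str) -> float:
    for key in ((pair.pair_id, tissue), pair.pair_id):
        if key in cfg.rho_overrides:
            return cfg.rho_overrides[key]
    return cfg.rho_by_group.get(pair.group, 0.0)


def generate_expression(
    pairs: Sequence[ExpressionPair],
    config: Optional[ExpressionConfig] = None,
    seed: int = 0,
    extra_genes: Sequence[str] = (),
    truth: Optional[SyntheticTruth] = None,
) -> ExpressionMatrix:
    """Draw an RPKM-like matrix with the planted per-pair correlations.

    Genes appearing in ``pairs`` are drawn as correlated couples (per
    tissue); ``extra_genes`` are independent.  If ``truth`` is given, the
    realized planted correlations are recorded in ``truth.planted_rho``.
    """
    cfg = config or ExpressionConfig()
    rng = np.random.default_rng(seed)

    samples: list[str] = []
    tissue_of: dict[str, str] = {}
    for tissue, n in cfg.tissues.items():
        for i in range(n):
            sid = f"{tissue}_{i + 1:03d}"
            samples.append(sid)
            tissue_of[sid] = tissue

    gene_order: dict[str, None] = {}
    for p in pairs:
        gene_order.setdefault(p.gene_a, None)
        gene_order.setdefault(p.gene_b, None)
    for g in extra_genes:
        gene_order.setdefault(g, None)
    genes = list(gene_order)
    paired_genes = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    overlapping_genes = {
        g for p in pairs if p.group != CONTROL_GROUP for g in (p.gene_a, p.gene_b)
    }

    mu = {}
    for g in genes:
        shift = cfg.group_log_shift if g in overlapping_genes else 0.0
        mu[g] = cfg.base_log_mean - shift + rng.normal(0.0, cfg.gene_log_sd)

    values = pd.DataFrame(
        np.zeros((len(genes), len(samples))), index=genes, columns=samples
    )

    col_of_tissue = {
        t: [s for s in samples if tissue_of[s] == t] for t in cfg.tissues
    }

    drawn = set()
    for p in pairs:
        if p.gene_a in drawn or p.gene_b in drawn:
            raise ValueError(
                f"gene reused across pairs: {p.pair_id} "
                "(each gene may belong to at most one pair)"
            )
        for tissue, cols in col_of_tissue.items():
            rho_s = _target_rho(cfg, p, tissue)
            r = latent_pearson_for_spearman(rho_s)
            n = len(cols)
            z = rng.multivariate_normal(
                [0.0, 0.0], [[1.0, r], [r, 1.0]], size=n
            )
            values.loc[p.gene_a, cols] = np.exp(mu[p.gene_a] + cfg.noise_log_sd * z[:, 0])
            values.loc[p.gene_b, cols] = np.exp(mu[p.gene_b] + cfg.noise_log_sd * z[:, 1])
            if truth is not None:
                truth.planted_rho[(p.pair_id, tissue)] = rho_s
        drawn.update((p.gene_a, p.gene_b))

    for g in genes:
        if g in drawn:
            continue
        z = rng.normal(0.0, 1.0, size=len(samples))
        values.loc[g] = np.exp(mu[g] + cfg.noise_log_sd * z)

    if truth is not None:
        truth.planted_group_shift = cfg.group_log_shift
    return ExpressionMatrix(values, tissue_of)
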