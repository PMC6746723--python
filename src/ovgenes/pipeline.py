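"""End-to-end pipeline: filter -> detect -> classify -> associate.

Each stage reads and writes plain TSV, so any stage can be rerun in
isolation on saved outputs and a full run is reproducible byte-for-byte
from its config snapshot (written next to the outputs as JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__ as _version
from .annotation import (
    PRIMARY_CHROMOSOMES, filter_genes, read_gene_annotation, write_gene_table,
)
from .clusters import find_overlap_clusters, cluster_size_distribution, OverlapCluster
from .expression import (
    CONTROL_GROUP, ExpressionPair, associate, group_association_summary,
    load_expression, match_pairs, sample_control_pairs,
    subtype_expression_tests, tissue_variance_analysis,
)
from .pairs import pairs_from_clusters, pairs_table, summarize_pairs

__all__ = ["RunConfig", "run_pipeline", "write_clusters", "read_clusters",
           "results_table"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; JSON-serializable."""

    annotation: str
    out_dir: str
    annotation_format: str = "tsv"
    expression: Optional[str] = None
    tissue_map: Optional[str] = None
    exclusion_ids_file: Optional[str] = None
    primary_chromosomes: list = field(
        default_factory=lambda: sorted(PRIMARY_CHROMOSOMES)
    )
    alpha: float = 0.05
    seed: int = 0
    min_samples_per_tissue: int = 10
    variance_threshold: Optional[float] = None
    log_transform_regression: bool = False
    n_control_pairs: Optional[int] = None  # default: match the overlap pairs

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def write_clusters(clusters: Sequence[OverlapCluster], path) -> None:
    rows = [{
        "cluster_id": c.cluster_id,
        "chromosome": c.chromosome,
        "size": c.size,
        "size_class": c.size_class,
        "span_start": c.span_start,
        "span_end": c.span_end,
        "members": ",".join(c.members),
    } for c in clusters]
    pd.DataFrame(rows, columns=["cluster_id", "chromosome", "size", "size_class",
                                "span_start", "span_end", "members"]
                 ).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> list[OverlapCluster]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        OverlapCluster(
            cluster_id=row.cluster_id,
            chromosome=row.chromosome,
            members=tuple(row.members.split(",")),
            span_start=int(row.span_start),
            span_end=int(row.span_end),
        )
        for row in df.itertuples()
    ]


def results_table(results) -> pd.DataFrame:
    """Flatten AssociationResults into the associations TSV layout."""
    return pd.DataFrame([{
        "pair_id": r.pair_id,
        "group": r.group,
        "n_samples": r.n_samples,
        "defined": r.defined,
        "rho": r.rho,
        "rho_p": r.rho_p,
        "slope": r.slope,
        "intercept": r.intercept,
        "r_squared": r.r_squared,
        "reg_p": r.reg_p,
        "q_value": r.q_value,
        "significant_raw": r.significant_raw,
        "significant_q": r.significant_q,
    } for r in results])


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    The association stage runs only when an expression matrix (and tissue
    map) is configured.  Any stage failure propagates with the stage named
    in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"ovgenes {_version}", f"seed {config.seed}"]

    def log(msg):
        log_lines.append(msg)

    try:
        records = read_gene_annotation(
            config.annotation, format=config.annotation_format
        )
        exclusion = None
        if config.exclusion_ids_file:
            exclusion = {
                line.strip()
                for line in Path(config.exclusion_ids_file).read_text().splitlines()
                if line.strip()
            }
        genes, report = filter_genes(
            records,
            primary_chromosomes=config.primary_chromosomes,
            exclusion_ids=exclusion,
        )
        write_gene_table(genes, out / "filtered_genes.tsv")
        (out / "filter_report.json").write_text(
            json.dumps(report.as_dict(), indent=2) + "\n"
        )
        log(f"filter: {report.input_records} in, {report.retained} retained")
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    try:
        clusters = find_overlap_clusters(genes)
        write_clusters(clusters, out / "clusters.tsv")
        cluster_size_distribution(clusters).to_csv(
            out / "size_distribution.tsv", sep="\t"
        )
        n_overlapping = sum(c.size for c in clusters)
        log(f"detect: {len(clusters)} clusters, {n_overlapping} overlapping genes")
    except Exception as exc:
        raise RuntimeError(f"stage 'detect' failed: {exc}") from exc

    try:
        pwm = pairs_from_clusters(clusters, genes)
        ptable = pairs_table(pwm, genes)
        ptable.to_csv(out / "pairs.tsv", sep="\t", index=False)
        summaries = summarize_pairs(pwm, genes)
        summaries["metrics_summary"].to_csv(out / "pair_metrics_summary.tsv", sep="\t")
        summaries["chromosome_subtypes"].to_csv(
            out / "chromosome_subtypes.tsv", sep="\t"
        )
        summaries["pct_histogram"].to_csv(out / "overlap_pct_histogram.tsv", sep="\t")
        log(f"classify: {len(pwm)} pairs")
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    if config.expression:
        try:
            if not config.tissue_map:
                raise FileNotFoundError("tissue map path not configured")
            for p in (config.expression, config.tissue_map):
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
            matrix = load_expression(config.expression, config.tissue_map)

            ov_pairs = [
                ExpressionPair(row.pair_id, row.gene_F, row.gene_L, row.subtype)
                for row in ptable.itertuples()
            ]
            matched, match_report = match_pairs(ov_pairs, matrix)
            clustered = {g for c in clusters for g in c.members}
            non_overlapping = [
                g.gene_id for g in genes
                if g.gene_id not in clustered and g.gene_id in matrix
            ]
            n_ctrl = config.n_control_pairs or len(matched)
            controls = sample_control_pairs(non_overlapping, n_ctrl, config.seed)
            all_pairs = matched + controls

            results = associate(
                all_pairs, matrix, alpha=config.alpha,
                log_transform=config.log_transform_regression,
            )
            results_table(results).to_csv(out / "associations.tsv", sep="\t",
                                          index=False)
            summary = group_association_summary(
                results, all_pairs, matrix, alpha=config.alpha
            )
            summary["group_summary"].to_csv(out / "group_summary.tsv", sep="\t")
            summary["cross_group_z"].to_csv(out / "cross_group_z.tsv", sep="\t",
                                            index=False)
            expr_tests = subtype_expression_tests(matched, matrix)
            expr_tests["posthoc"].to_csv(out / "subtype_expression_posthoc.tsv",
                                         sep="\t", index=False)
            tissue_assoc, threshold, per_tissue = tissue_variance_analysis(
                all_pairs, matrix,
                min_samples_per_tissue=config.min_samples_per_tissue,
                variance_threshold=config.variance_threshold,
            )
            pd.DataFrame([{
                "pair_id": ta.pair_id,
                "group": ta.group,
                "n_tissues": len(ta.per_tissue_rho),
                "cross_tissue_variance": ta.cross_tissue_variance,
                "high_variance": ta.high_variance,
                **{f"rho_{t}": r for t, r in ta.per_tissue_rho.items()},
            } for ta in tissue_assoc]).to_csv(
                out / "tissue_variance.tsv", sep="\t", index=False
            )
            per_tissue.to_csv(out / "per_tissue_expression.tsv", sep="\t",
                              index=False)
            (out / "association_report.json").write_text(json.dumps({
                "matched_pairs": match_report["matched"],
                "dropped_pairs": match_report["dropped"],
                "control_pairs": len(controls),
                "kruskal_wallis_H": expr_tests["H"],
                "kruskal_wallis_p": expr_tests["p_value"],
                "expression_comparison": summary["expression_comparison"],
                "variance_threshold": threshold,
                "n_high_variance": int(sum(ta.high_variance for ta in tissue_assoc)),
            }, indent=2) + "\n")
            log(f"associate: {len(matched)} matched pairs, {len(controls)} controls")
        except Exception as exc:
            raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    config.to_json(out / "run_config.json")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
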