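"""Expression association of overlapping gene pairs.

Consumes a genes x samples matrix of RPKM values (reads per kilobase per
million mapped reads; non-negative) with a sample -> tissue map, and
quantifies, for each gene pair:

* Spearman rank correlation of the two genes' expression across samples;
* a linear regression of the lateral (downstream-start) gene's expression
  on the frontal gene's expression, with slope test p-value and R^2;
* Benjamini-Hochberg q-values within each comparison family;
* per-tissue correlations and their cross-tissue variance, to flag pairs
  whose co-expression is tissue specific.

Group-level routines compare the overlapping-pair subtypes against a
randomly drawn non-overlapping control group: rank-based expression-level
tests (Mann-Whitney / Kruskal-Wallis with BH-corrected post hoc) and
Fisher-z comparisons of mean z-transformed correlations.

RPKM values are used untransformed for the rank-based statistics (ranks are
invariant under monotone maps); the regression can optionally run on
log2(RPKM + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ExpressionPair",
    "AssociationResult",
    "TissueAssociation",
    "load_expression",
    "match_pairs",
    "sample_control_pairs",
    "rank_sum_test",
    "kruskal_wallis",
    "pairwise_posthoc",
    "pair_association",
    "associate",
    "bh_adjust",
    "fisher_z_compare",
    "group_association_summary",
    "subtype_expression_tests",
    "tissue_variance_analysis",
    "CONTROL_GROUP",
]

CONTROL_GROUP = "control"


class ExpressionMatrix:
    """Genes x samples RPKM grid with a sample -> tissue map.

    Values must be finite and non-negative; every sample needs a tissue
    label.  Backed by a pandas DataFrame (``.values_df``), genes as rows.
    """

    def __init__(self, values: pd.DataFrame, tissue_of: Mapping[str, str]):
        arr = values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        missing = [s for s in values.columns if s not in tissue_of]
        if missing:
            raise ValueError(
                f"samples missing from tissue map: {', '.join(map(str, missing))}"
            )
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        self.values_df = values.astype(float)
        self.values_df.index.name = "gene_id"
        self.tissue_of = {s: tissue_of[s] for s in values.columns}

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values_df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values_df.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.tissue_of[s], None)
        return list(seen)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values_df.index

    def expression(self, gene_id: str) -> np.ndarray:
        return self.values_df.loc[gene_id].to_numpy(dtype=float)

    def tissue_samples(self, tissue: str) -> list[str]:
        return [s for s in self.sample_ids if self.tissue_of[s] == tissue]

    def to_tsv(self, matrix_path, tissue_map_path) -> None:
        self.values_df.to_csv(matrix_path, sep="\t", index_label="gene_id")
        pd.Series(self.tissue_of, name="tissue").rename_axis("sample_id").to_csv(
            tissue_map_path, sep="\t"
        )


def load_expression(matrix_path, tissue_map_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a two-column sample->tissue TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    tmap = pd.read_csv(tissue_map_path, sep="\t", index_col=0)
    tissue_of = tmap.iloc[:, 0].astype(str).to_dict()
    return ExpressionMatrix(values, tissue_of)


@dataclass(frozen=True)
class ExpressionPair:
    """A gene pair entering the association stage.

    ``gene_a`` is the frontal gene (regression predictor by default) and
    ``gene_b`` the lateral gene; for control pairs the roles are arbitrary.
    ``group`` is one of the four subtypes or ``"control"``.
    """

    pair_id: str
    gene_a: str
    gene_b: str
    group: str


def match_pairs(
    pairs: Sequence[ExpressionPair], matrix: ExpressionMatrix
) -> tuple[list[ExpressionPair], dict]:
    """Keep pairs whose two genes are both present in the matrix."""
    matched, dropped = [], []
    for p in pairs:
        missing = [g for g in (p.gene_a, p.gene_b) if g not in matrix]
        if missing:
            dropped.append((p.pair_id, missing))
        else:
            matched.append(p)
    report = {
        "input": len(pairs),
        "matched": len(matched),
        "dropped": len(dropped),
        "dropped_pairs": dropped,
    }
    return matched, report


def sample_control_pairs(
    non_overlapping_genes: Sequence[str],
    n_pairs: int,
    seed,
) -> list[ExpressionPair]:
    """Draw ``2 * n_pairs`` distinct genes and pair them at random.

    Sampling is uniform without replacement; ``seed`` may be an int or a
    ``numpy.random.Generator``.  Deterministic for a fixed seed.
    """
    genes = list(non_overlapping_genes)
    need = 2 * n_pairs
    if len(genes) < need:
        raise ValueError(
            f"need {need} non-overlapping genes for {n_pairs} control pairs, "
            f"only {len(genes)} available"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(genes), size=need, replace=False)
    return [
        ExpressionPair(
            pair_id=f"CTRL{i + 1:05d}",
            gene_a=genes[chosen[2 * i]],
            gene_b=genes[chosen[2 * i + 1]],
            group=CONTROL_GROUP,
        )
        for i in range(n_pairs)
    ]


# ---------------------------------------------------------------------------
# Rank-based tests
# ---------------------------------------------------------------------------

def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both samples have <= 8
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie correction.  Returns (U of x, two-sided p).
    Fully degenerate input (every value identical) gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and p across >= 3 groups."""
    if len(groups) < 3:
        raise ValueError(f"kruskal_wallis requires >= 3 groups, got {len(groups)}")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_posthoc(
    groups: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """All pairwise rank-sum tests with BH q-values across the comparisons."""
    names = list(groups)
    rows = []
    for a, b in combinations(names, 2):
        _, p = rank_sum_test(groups[a], groups[b])
        rows.append({"group_1": a, "group_2": b, "p_value": p})
    df = pd.DataFrame(rows, columns=["group_1", "group_2", "p_value"])
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_list())
    else:
        df["q_value"] = []
    return df


# ---------------------------------------------------------------------------
# Per-pair association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    pair_id: str
    group: str
    n_samples: int
    defined: bool
    rho: float = math.nan
    rho_p: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    r_squared: float = math.nan
    reg_p: float = math.nan
    q_value: float = math.nan
    significant_raw: bool = False
    significant_q: bool = False


def pair_association(
    pair: ExpressionPair,
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    log_transform: bool = False,
    samples: Optional[Sequence[str]] = None,
) -> AssociationResult:
    """Spearman correlation and lateral-on-frontal regression for one pair.

    A gene with zero variance across the samples makes the rank correlation
    undefined; such results carry ``defined=False`` and are excluded from
    group summaries (counted, not imputed).
    """
    cols = list(samples) if samples is not None else matrix.sample_ids
    if len(cols) < 4:
        raise ValueError("pair_association requires >= 4 samples")
    x = matrix.values_df.loc[pair.gene_a, cols].to_numpy(dtype=float)
    y = matrix.values_df.loc[pair.gene_b, cols].to_numpy(dtype=float)

    res = AssociationResult(
        pair_id=pair.pair_id, group=pair.group, n_samples=len(cols), defined=True
    )
    if np.all(x == x[0]) or np.all(y == y[0]):
        res.defined = False
        return res

    rho, rho_p = stats.spearmanr(x, y)
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    reg = stats.linregress(x, y)
    res.rho = float(rho)
    res.rho_p = float(rho_p)
    res.slope = float(reg.slope)
    res.intercept = float(reg.intercept)
    res.r_squared = float(reg.rvalue ** 2)
    res.reg_p = float(reg.pvalue)
    res.significant_raw = res.reg_p < alpha
    return res


def associate(
    pairs: Sequence[ExpressionPair],
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    log_transform: bool = False,
) -> list[AssociationResult]:
    """Run :func:`pair_association` for every pair; BH-adjust within groups."""
    results = [
        pair_association(p, matrix, alpha=alpha, log_transform=log_transform)
        for p in pairs
    ]
    by_group: dict[str, list[AssociationResult]] = {}
    for r in results:
        if r.defined:
            by_group.setdefault(r.group, []).append(r)
    for members in by_group.values():
        qs = bh_adjust([r.reg_p for r in members])
        for r, q in zip(members, qs):
            r.q_value = float(q)
            r.significant_q = q < alpha
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, where p_(1..m) are the
    sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher-z test for the difference of two correlation coefficients.

    z_i = arctanh(r_i); the statistic is (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))
    with a standard-normal two-sided p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"sample sizes must exceed 3, got {n}")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z_stat))
    return float(z_stat), float(p)


# ---------------------------------------------------------------------------
# Group-level summaries
# ---------------------------------------------------------------------------

def _gene_level_means(
    matrix: ExpressionMatrix, genes: Iterable[str], samples=None
) -> np.ndarray:
    cols = list(samples) if samples is not None else matrix.sample_ids
    sub = matrix.values_df.loc[list(dict.fromkeys(genes)), cols]
    return sub.mean(axis=1).to_numpy(dtype=float)


def group_association_summary(
    results: Sequence[AssociationResult],
    pairs: Sequence[ExpressionPair],
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
) -> dict:
    """Per-group association summaries plus cross-group tests.

    Returns a dict with:

    ``group_summary`` — per group: pair counts, undefined-correlation count,
    median rho, mean/median R^2, and the split of significant (raw p < alpha)
    vs non-significant pairs (q-based split also reported).

    ``cross_group_z`` — Fisher-z comparisons of the mean z-transformed rho
    for every pair of groups (variance term uses the per-correlation sample
    count and the group size), plus a rank-sum test on the z values as a
    robustness check.

    ``expression_comparison`` — overlapping vs control RPKM level: rank-sum
    test on per-gene mean expression (default sampling unit) and on per-pair
    mean expression.
    """
    by_group: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)

    rows = []
    for group, members in by_group.items():
        defined = [r for r in members if r.defined]
        n_sig = sum(r.significant_raw for r in defined)
        n_sig_q = sum(r.significant_q for r in defined)
        rows.append({
            "group": group,
            "n_pairs": len(members),
            "n_undefined": len(members) - len(defined),
            "median_rho": float(np.median([r.rho for r in defined])) if defined else math.nan,
            "mean_r_squared": float(np.mean([r.r_squared for r in defined])) if defined else math.nan,
            "median_r_squared": float(np.median([r.r_squared for r in defined])) if defined else math.nan,
            "n_significant": n_sig,
            "pct_significant": 100.0 * n_sig / len(defined) if defined else math.nan,
            "n_significant_q": n_sig_q,
            "pct_significant_q": 100.0 * n_sig_q / len(defined) if defined else math.nan,
        })
    group_summary = pd.DataFrame(rows).set_index("group")

    # cross-group Fisher z on mean z-transformed rho
    z_by_group: dict[str, np.ndarray] = {}
    n_samp_by_group: dict[str, float] = {}
    for group, members in by_group.items():
        rhos = np.array([r.rho for r in members if r.defined and abs(r.rho) < 1.0])
        z_by_group[group] = np.arctanh(rhos)
        ns = [r.n_samples for r in members if r.defined]
        n_samp_by_group[group] = float(np.mean(ns)) if ns else math.nan
    zrows = []
    for a, b in combinations(z_by_group, 2):
        za, zb = z_by_group[a], z_by_group[b]
        if len(za) == 0 or len(zb) == 0:
            continue
        # SE of a mean of Fisher-z values: each z has variance 1/(n-3)
        var_a = (1.0 / (n_samp_by_group[a] - 3)) / len(za)
        var_b = (1.0 / (n_samp_by_group[b] - 3)) / len(zb)
        z_stat = (za.mean() - zb.mean()) / math.sqrt(var_a + var_b)
        p = 2.0 * stats.norm.sf(abs(z_stat))
        _, rank_p = rank_sum_test(za, zb) if (len(za) > 0 and len(zb) > 0) else (math.nan, math.nan)
        zrows.append({
            "group_1": a, "group_2": b,
            "mean_z_1": float(za.mean()), "mean_z_2": float(zb.mean()),
            "z_stat": float(z_stat), "p_value": float(p),
            "rank_sum_p": float(rank_p),
        })
    cross_group_z = pd.DataFrame(
        zrows, columns=["group_1", "group_2", "mean_z_1", "mean_z_2",
                        "z_stat", "p_value", "rank_sum_p"]
    )

    # overlapping vs control expression level
    ov_pairs = [p for p in pairs if p.group != CONTROL_GROUP]
    ctrl_pairs = [p for p in pairs if p.group == CONTROL_GROUP]
    expression_comparison: dict = {}
    if ov_pairs and ctrl_pairs:
        ov_genes = [g for p in ov_pairs for g in (p.gene_a, p.gene_b)]
        ctrl_genes = [g for p in ctrl_pairs for g in (p.gene_a, p.gene_b)]
        ov_means = _gene_level_means(matrix, ov_genes)
        ctrl_means = _gene_level_means(matrix, ctrl_genes)
        u, p_gene = rank_sum_test(ov_means, ctrl_means)
        pair_means_ov = [
            float(_gene_level_means(matrix, (p.gene_a, p.gene_b)).mean())
            for p in ov_pairs
        ]
        pair_means_ctrl = [
            float(_gene_level_means(matrix, (p.gene_a, p.gene_b)).mean())
            for p in ctrl_pairs
        ]
        _, p_pair = rank_sum_test(pair_means_ov, pair_means_ctrl)
        expression_comparison = {
            "mean_rpkm_overlapping": float(np.mean(ov_means)),
            "mean_rpkm_control": float(np.mean(ctrl_means)),
            "gene_level_p": float(p_gene),
            "pair_level_p": float(p_pair),
        }

    return {
        "group_summary": group_summary,
        "cross_group_z": cross_group_z,
        "expression_comparison": expression_comparison,
    }


def subtype_expression_tests(
    pairs: Sequence[ExpressionPair],
    matrix: ExpressionMatrix,
) -> dict:
    """Kruskal-Wallis across subtype expression levels plus BH post hoc.

    The sampling unit is the gene: each gene's mean RPKM across samples,
    grouped by its pair's subtype.  Returns the H statistic, its p-value and
    the pairwise post-hoc table (rank-sum p with BH q across comparisons).
    """
    groups: dict[str, list[float]] = {}
    for p in pairs:
        if p.group == CONTROL_GROUP:
            continue
        means = _gene_level_means(matrix, (p.gene_a, p.gene_b))
        groups.setdefault(p.group, []).extend(map(float, means))
    if len(groups) < 3:
        raise ValueError("subtype_expression_tests requires >= 3 subtypes present")
    h, p_kw = kruskal_wallis(list(groups.values()))
    posthoc = pairwise_posthoc(groups)
    return {"H": h, "p_value": p_kw, "posthoc": posthoc}


# ---------------------------------------------------------------------------
# Tissue-specific association
# ---------------------------------------------------------------------------

@dataclass
class TissueAssociation:
    pair_id: str
    group: str
    per_tissue_rho: dict = field(default_factory=dict)
    per_tissue_n: dict = field(default_factory=dict)
    cross_tissue_variance: Optional[float] = None
    high_variance: bool = False


def tissue_variance_analysis(
    pairs: Sequence[ExpressionPair],
    matrix: ExpressionMatrix,
    min_samples_per_tissue: int = 10,
    variance_threshold: Optional[float] = None,
) -> tuple[list[TissueAssociation], float, pd.DataFrame]:
    """Per-tissue correlations and their cross-tissue variance per pair.

    For each pair, Spearman rho is computed separately within every tissue
    that has at least ``min_samples_per_tissue`` samples (tissues where
    either gene has zero variance are skipped); the cross-tissue variance is
    the sample variance of those rho values, absent with < 2 usable tissues.

    ``variance_threshold`` defaults to mean + 3*SD of the variance
    distribution over all pairs with a defined variance; pairs above it are
    flagged ``high_variance``.  Also returns a per-tissue rank-sum
    comparison of overlapping vs control gene-level expression.

    Returns ``(tissue_associations, threshold_used, per_tissue_comparison)``.
    """
    usable_tissues = [
        t for t in matrix.tissues
        if len(matrix.tissue_samples(t)) >= min_samples_per_tissue
    ]
    out = []
    for p in pairs:
        ta = TissueAssociation(pair_id=p.pair_id, group=p.group)
        for t in usable_tissues:
            cols = matrix.tissue_samples(t)
            x = matrix.values_df.loc[p.gene_a, cols].to_numpy(dtype=float)
            y = matrix.values_df.loc[p.gene_b, cols].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = stats.spearmanr(x, y)
            ta.per_tissue_rho[t] = float(rho)
            ta.per_tissue_n[t] = len(cols)
        if len(ta.per_tissue_rho) >= 2:
            ta.cross_tissue_variance = float(
                np.var(list(ta.per_tissue_rho.values()), ddof=1)
            )
        out.append(ta)

    variances = np.array([
        ta.cross_tissue_variance for ta in out
        if ta.cross_tissue_variance is not None
    ])
    if variance_threshold is None:
        if variances.size >= 2:
            variance_threshold = float(variances.mean() + 3.0 * variances.std(ddof=1))
        else:
            variance_threshold = math.inf
    for ta in out:
        ta.high_variance = (
            ta.cross_tissue_variance is not None
            and ta.cross_tissue_variance > variance_threshold
        )

    # per-tissue overlapping-vs-control expression comparison
    ov_genes = [g for p in pairs if p.group != CONTROL_GROUP for g in (p.gene_a, p.gene_b)]
    ctrl_genes = [g for p in pairs if p.group == CONTROL_GROUP for g in (p.gene_a, p.gene_b)]
    rows = []
    if ov_genes and ctrl_genes:
        for t in usable_tissues:
            cols = matrix.tissue_samples(t)
            ov = _gene_level_means(matrix, ov_genes, cols)
            ctrl = _gene_level_means(matrix, ctrl_genes, cols)
            _, pval = rank_sum_test(ov, ctrl)
            rows.append({
                "tissue": t,
                "n_samples": len(cols),
                "mean_rpkm_overlapping": float(ov.mean()),
                "mean_rpkm_control": float(ctrl.mean()),
                "rank_sum_p": float(pval),
            })
    comparison = pd.DataFrame(
        rows, columns=["tissue", "n_samples", "mean_rpkm_overlapping",
                       "mean_rpkm_control", "rank_sum_p"]
    )
    return out, variance_threshold, comparison
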