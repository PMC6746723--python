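"""Expression matrix I/O, statistics primitives, and association summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ovgenes.expression import (
    CONTROL_GROUP, ExpressionMatrix, ExpressionPair, associate, bh_adjust,
    fisher_z_compare, group_association_summary, kruskal_wallis, load_expression,
    match_pairs, pair_association, pairwise_posthoc, rank_sum_test,
    sample_control_pairs, subtype_expression_tests, tissue_variance_analysis,
)
from _oracles import bh_over_thresholds, enumerate_mannwhitney


def toy_matrix(values, tissues=None):
    n_genes, n_samples = np.asarray(values).shape
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    tissue_of = tissues or {s: "t1" for s in samples}
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            tissue_of)


# ---------------------------------------------------------------------------
# matrix container and I/O
# ---------------------------------------------------------------------------

def test_matrix_rejects_negative_values():
    with pytest.raises(ValueError, match="negative"):
        toy_matrix([[1.0, -0.1], [0.0, 2.0]])


def test_matrix_rejects_sample_without_tissue():
    df = pd.DataFrame([[1.0, 2.0]], index=["G0"], columns=["S0", "S1"])
    with pytest.raises(ValueError, match="S1"):
        ExpressionMatrix(df, {"S0": "t1"})


def test_matrix_round_trip(tmp_path):
    m = toy_matrix(np.arange(12, dtype=float).reshape(3, 4))
    m.to_tsv(tmp_path / "e.tsv", tmp_path / "t.tsv")
    back = load_expression(tmp_path / "e.tsv", tmp_path / "t.tsv")
    pd.testing.assert_frame_equal(back.values_df, m.values_df)
    assert back.tissue_of == m.tissue_of


def test_match_pairs_reports_missing_genes():
    m = toy_matrix([[1.0, 2.0, 3.0, 4.0]] * 2)
    pairs = [ExpressionPair("P1", "G0", "G1", "divergent"),
             ExpressionPair("P2", "G0", "MISSING", "convergent")]
    matched, report = match_pairs(pairs, m)
    assert [p.pair_id for p in matched] == ["P1"]
    assert report["dropped_pairs"] == [("P2", ["MISSING"])]


def test_control_sampling_partition_and_determinism():
    genes = [f"g{i}" for i in range(10)]
    pairs1 = sample_control_pairs(genes, 5, seed=42)
    pairs2 = sample_control_pairs(genes, 5, seed=42)
    assert pairs1 == pairs2
    used = [g for p in pairs1 for g in (p.gene_a, p.gene_b)]
    assert sorted(used) == sorted(genes)  # disjoint pairs cover all 10
    with pytest.raises(ValueError, match="12"):
        sample_control_pairs(genes, 6, seed=0)


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def test_rank_sum_exact_small_sample():
    _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_rank_sum_identical_samples():
    _, p = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert p == pytest.approx(1.0, abs=0.05)


def test_rank_sum_degenerate_constant_input():
    _, p = rank_sum_test([5, 5, 5], [5, 5])
    assert p == 1.0


def test_rank_sum_detects_large_shift():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 200)
    y = rng.normal(3, 1, 200)
    _, p = rank_sum_test(x, y)
    assert p < 0.001


def test_rank_sum_exact_branch_matches_enumeration():
    rng = np.random.default_rng(3)
    for n1, n2 in [(2, 5), (4, 4), (6, 3)]:
        vals = rng.permutation(20)[: n1 + n2].astype(float)
        x, y = vals[:n1], vals[n1:]
        _, p = rank_sum_test(x, y)
        _, p_oracle = enumerate_mannwhitney(x, y)
        assert p == pytest.approx(p_oracle, abs=1e-12)


def test_kruskal_hand_computed_example():
    h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert h == pytest.approx(7.2)


def test_kruskal_requires_three_groups():
    with pytest.raises(ValueError, match=">= 3"):
        kruskal_wallis([[1, 2], [3, 4]])


def test_posthoc_flags_the_shifted_group():
    rng = np.random.default_rng(5)
    groups = {
        "a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50),
        "c": rng.normal(2.5, 1, 50),
    }
    table = pairwise_posthoc(groups)
    involving_c = table[(table.group_1 == "c") | (table.group_2 == "c")]
    others = table[(table.group_1 != "c") & (table.group_2 != "c")]
    assert involving_c["q_value"].max() < others["q_value"].min()


# ---------------------------------------------------------------------------
# per-pair association
# ---------------------------------------------------------------------------

def test_perfect_linear_monotone_association():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    m = toy_matrix(np.vstack([x, 2 * x]))
    res = pair_association(ExpressionPair("P", "G0", "G1", "divergent"), m)
    assert res.rho == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)
    assert res.r_squared == pytest.approx(1.0)


def test_perfect_anti_monotone_association():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    m = toy_matrix(np.vstack([x, 100 - x]))
    res = pair_association(ExpressionPair("P", "G0", "G1", "convergent"), m)
    assert res.rho == pytest.approx(-1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_zero_variance_gene_yields_undefined_result():
    m = toy_matrix([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
    res = pair_association(ExpressionPair("P", "G0", "G1", "control"), m)
    assert not res.defined
    assert math.isnan(res.rho)


def test_independent_genes_have_small_rho():
    rng = np.random.default_rng(17)
    hits = 0
    for rep in range(40):
        m = toy_matrix(rng.gamma(2.0, 1.0, size=(2, 500)))
        res = pair_association(ExpressionPair("P", "G0", "G1", "control"), m)
        hits += abs(res.rho) < 0.15
    assert hits >= 38  # 95% of reps, with slack for the small rep count


# ---------------------------------------------------------------------------
# BH and Fisher z
# ---------------------------------------------------------------------------

def test_bh_hand_computed_example():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_is_identity():
    assert bh_adjust([0.37]) == pytest.approx([0.37])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
def test_bh_matches_threshold_oracle_and_dominates_p(ps):
    q = bh_adjust(ps)
    assert np.allclose(q, bh_over_thresholds(ps), atol=1e-12)
    assert np.all(q >= np.asarray(ps) - 1e-15)
    order = np.argsort(ps)
    assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in p


def test_bh_agrees_with_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(2)
    p = rng.uniform(0, 1, 40)
    _, q_sm, _, _ = statsmodels.multipletests(p, method="fdr_bh")
    assert np.allclose(bh_adjust(p), q_sm)


def test_fisher_z_identical_correlations():
    z, p = fisher_z_compare(0.5, 100, 0.5, 250)
    assert z == 0.0 and p == pytest.approx(1.0)


def test_fisher_z_numeric_example():
    z, p = fisher_z_compare(0.5, 103, 0.0, 103)
    assert z == pytest.approx(3.884, abs=0.01)
    assert p == pytest.approx(1.03e-4, rel=0.05)


def test_fisher_z_antisymmetry_and_errors():
    z1, p1 = fisher_z_compare(0.6, 50, 0.2, 80)
    z2, p2 = fisher_z_compare(0.2, 80, 0.6, 50)
    assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)
    with pytest.raises(ValueError):
        fisher_z_compare(1.0, 50, 0.2, 80)
    with pytest.raises(ValueError):
        fisher_z_compare(0.5, 3, 0.2, 80)


# ---------------------------------------------------------------------------
# group summaries on the synthetic genome
# ---------------------------------------------------------------------------

def test_group_summary_recovers_planted_ordering(expression_dataset):
    pairs = expression_dataset["pairs"] + expression_dataset["controls"]
    matrix = expression_dataset["matrix"]
    results = associate(pairs, matrix)
    summary = group_association_summary(results, pairs, matrix)
    gs = summary["group_summary"]
    # divergent pairs planted at rho 0.6, other subtypes 0.3, control 0
    assert gs.loc["divergent", "median_rho"] == gs["median_rho"].max()
    assert gs.loc["control", "median_rho"] == gs["median_rho"].min()
    assert gs.loc["divergent", "pct_significant"] > gs.loc["control", "pct_significant"]
    # overlapping genes planted at a lower RPKM level than controls
    comp = summary["expression_comparison"]
    assert comp["mean_rpkm_overlapping"] < comp["mean_rpkm_control"]


def test_q_values_dominate_p_within_groups(expression_dataset):
    pairs = expression_dataset["pairs"] + expression_dataset["controls"]
    results = associate(pairs, expression_dataset["matrix"])
    for r in results:
        if r.defined:
            assert r.q_value >= r.reg_p - 1e-15


def test_subtype_expression_tests_shape(expression_dataset):
    out = subtype_expression_tests(
        expression_dataset["pairs"], expression_dataset["matrix"]
    )
    assert out["H"] >= 0
    assert len(out["posthoc"]) == 6  # 4 subtypes -> 6 comparisons
    assert (out["posthoc"]["q_value"] >= out["posthoc"]["p_value"] - 1e-15).all()


# ---------------------------------------------------------------------------
# tissue variance
# ---------------------------------------------------------------------------

def tissue_matrix(rhos_by_tissue, n_per_tissue=40, seed=0, n_background=30):
    """Pairs with planted per-tissue correlations via the package generator."""
    from ovgenes.simulate import ExpressionConfig, generate_expression

    tissues = {t: n_per_tissue for t in rhos_by_tissue[0]}
    pairs = [ExpressionPair(f"P{i}", f"A{i}", f"B{i}", "divergent")
             for i in range(len(rhos_by_tissue))]
    overrides = {}
    for i, rhos in enumerate(rhos_by_tissue):
        for t, r in rhos.items():
            overrides[(f"P{i}", t)] = r
    cfg = ExpressionConfig(tissues=tissues, rho_overrides=overrides)
    matrix = generate_expression(pairs, cfg, seed=seed)
    return pairs, matrix


def test_constant_planted_rho_gives_tiny_variance():
    tissues = {f"t{i}": 0.9 for i in range(5)}
    pairs, matrix = tissue_matrix([tissues] * 10, n_per_tissue=120, seed=3)
    out, _, _ = tissue_variance_analysis(pairs, matrix, min_samples_per_tissue=10)
    for ta in out:
        assert ta.cross_tissue_variance < 5e-3


def test_discordant_tissue_flagged_high_variance():
    constant = {f"t{i}": 0.9 for i in range(5)}
    flipped = dict(constant, t4=-0.5)
    layouts = [constant] * 19 + [flipped]
    pairs, matrix = tissue_matrix(layouts, n_per_tissue=60, seed=4)
    out, threshold, _ = tissue_variance_analysis(pairs, matrix)
    flags = {ta.pair_id: ta.high_variance for ta in out}
    assert flags["P19"]
    assert sum(flags.values()) == 1
    assert threshold < out[-1].cross_tissue_variance


def test_variance_invariant_under_tissue_label_permutation():
    constant = {"t0": 0.6, "t1": 0.2, "t2": -0.3}
    pairs, matrix = tissue_matrix([constant] * 3, n_per_tissue=30, seed=5)
    out1, _, _ = tissue_variance_analysis(pairs, matrix, min_samples_per_tissue=5)
    # permute the tissue labels attached to whole sample blocks
    remap = {"t0": "t1", "t1": "t2", "t2": "t0"}
    permuted = ExpressionMatrix(
        matrix.values_df, {s: remap[t] for s, t in matrix.tissue_of.items()}
    )
    out2, _, _ = tissue_variance_analysis(pairs, permuted, min_samples_per_tissue=5)
    for ta1, ta2 in zip(out1, out2):
        assert ta1.cross_tissue_variance == pytest.approx(
            ta2.cross_tissue_variance)


def test_too_few_tissues_leaves_variance_absent():
    pairs, matrix = tissue_matrix([{"t0": 0.5}] * 2, n_per_tissue=20, seed=6)
    out, _, _ = tissue_variance_analysis(pairs, matrix, min_samples_per_tissue=10)
    for ta in out:
        assert ta.cross_tissue_variance is None
        assert not ta.high_variance
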