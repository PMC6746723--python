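"""Flagging tissue-specific co-expression with cross-tissue variance.

Most overlapping pairs correlate similarly in every tissue; a pair whose
correlation flips sign in one tissue stands out as high-variance under the
default mean + 3*SD rule.
"""

from ovgenes import ExpressionConfig, ExpressionPair, generate_expression, \
    tissue_variance_analysis

tissues = {f"tissue_{i}": 80 for i in range(5)}
pairs = [ExpressionPair(f"P{j}", f"A{j}", f"B{j}", "divergent")
         for j in range(20)]

# every pair correlates at 0.8 in all tissues, except P19 in tissue_4
overrides = {(f"P{j}", t): 0.8 for j in range(20) for t in tissues}
overrides[("P19", "tissue_4")] = -0.5

cfg = ExpressionConfig(tissues=tissues, rho_overrides=overrides)
matrix = generate_expression(pairs, cfg, seed=3)

assoc, threshold, per_tissue = tissue_variance_analysis(pairs, matrix)
print(f"high-variance threshold (mean + 3 SD): {threshold:.4f}")
for ta in assoc:
    flag = "  <-- tissue-specific" if ta.high_variance else ""
    print(f"{ta.pair_id}: variance {ta.cross_tissue_variance:.4f}{flag}")

# Only P19 should be flagged: its per-tissue correlations are
# (0.8, 0.8, 0.8, 0.8, -0.5), a variance orders of magnitude above the
# sampling noise of the constant-correlation pairs.
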