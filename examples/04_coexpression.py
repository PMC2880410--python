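"""Coexpression validation of predicted histone-coregulated genes.

Generates a GNF-Atlas-like expression matrix (79 tissues x 2 technical
replicates; a 93-probe histone block, a 200-probe predicted block at
rho = 0.5 to the shared tissue profile, 2000 background probes), then
runs the full chain: preprocessing, maxCC against the histone block,
Welch's t between predicted and other probes, a 10,000-group empirical
null, BH-FDR at 0.05, and hypergeometric enrichment of the passers in
the predicted block.
"""

import promgram as pg
from promgram.coexpression import ExpressionMatrix, coexpression_analysis

spec = pg.ExpressionSpec()   # 93 + 200 + 2000 probes, 79 tissues x 2
values, groups, rep_map = pg.generate_expression(spec, seed=11)
print(f"raw matrix: {values.shape[0]} probes x {values.shape[1]} arrays")

res = coexpression_analysis(
    ExpressionMatrix(values, rep_map),
    histone_probes=list(groups.index[groups == "histone"]),
    predicted_probes=list(groups.index[groups == "predicted"]),
    seed=42,
)

t = res["ttest"]
print(f"mean maxCC: predicted {t['mean_predicted']:.3f} "
      f"(95% CI {t['ci_predicted'][0]:.3f}-{t['ci_predicted'][1]:.3f}), "
      f"other {t['mean_other']:.3f}")
print(f"Welch t = {t['t']:.2f}, p = {t['p_value']:.2e} "
      f"(negative t = predicted group more coexpressed)")

e = res["enrichment"]
print(f"FDR <= 0.05 passers: n = {e.n}, of which k = {e.k} in the "
      f"predicted block (K = {e.K} of N = {e.N})")
print(f"hypergeometric enrichment p = {e.p_value:.2e}, "
      f"Bonferroni-corrected {e.p_corrected:.2e}")
print("\nBoth validations fire: probes with promoter-grammar support are"
      "\nmore coexpressed with histones, and the most histone-coexpressed"
      "\nprobes are enriched for promoter-grammar support.")
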