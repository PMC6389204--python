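"""Moderated-t differential expression with planted fold changes.

Counts are normalized to log2 CPM, per-feature variances are shrunk toward a
common prior (empirical Bayes), p-values are BH-corrected, and calls require
a two-fold change with adjusted p < 0.05.
"""

import pandas as pd

from tekit.expression import call_de, moderated_t_test, normalize_logcpm
from tekit.simulate import simulate_two_group_counts

matrix, truth = simulate_two_group_counts(
    n_features=1000, n_per_group=3, frac_changed=0.1, fold=4.0, alpha=10.0, seed=4)
labels = pd.Series({c: c.rsplit(".r", 1)[0] for c in matrix.counts.columns})

expr = normalize_logcpm(matrix)
result = call_de(moderated_t_test(expr, labels), fc_threshold=2.0, alpha=0.05)

print(result.table["call"].value_counts().to_string())
print(f"\nshrinkage prior: d0 = {result.d0:.1f}, s0^2 = {result.s0_sq:.4f}")

up = result.table["call"] == "up"
sens = (up & truth).sum() / truth.sum()
fdr = (up & ~truth).sum() / max(1, up.sum())
print(f"sensitivity on planted 4-fold changes: {100 * sens:.1f}%")
print(f"realized false discovery rate:         {100 * fdr:.1f}%")
# With 3 vs 3 replicates and moderate biological noise (Gamma shape 10), the
# planted 4-fold features are called 'up' almost exhaustively while stable
# features stay uncalled.
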