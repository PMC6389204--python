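"""Classify TE integrants into cross-condition expression patterns.

Six conditions (wild-type, DNMT TKO, TET TKO; each control or Kap1
knockdown) define a space of expression patterns = partitions of the
condition groups into equal-mean blocks.  A conjugate Gamma-Gamma mixture is
fitted by EM and each integrant is assigned its posterior-best pattern;
repeat-family composition per pattern is scored with a hypergeometric test.
"""

import pandas as pd

from tekit.expression import normalize_logcpm
from tekit.patterns import (
    assign_patterns,
    family_enrichment,
    fit_gg_em,
    min_reads_filter,
    preset_patterns,
)
from tekit.quantify import CountMatrix
from tekit.simulate import SimConfig, simulate_counts

config = SimConfig(seed=8)
families = ["IAPEz", "MMERVK10C", "MERVL", "ETnERV"]
ids = [f"TE{i:05d}" for i in range(1200)]
family_labels = pd.Series([families[i % 4] for i in range(1200)], index=ids)

matrix, true_patterns = simulate_counts(config, ids)
kept = min_reads_filter(matrix.counts, min_total=20)
cpm = normalize_logcpm(CountMatrix(counts=kept, lib_sizes=matrix.lib_sizes)).cpm
groups = pd.Series({c: c.rsplit(".r", 1)[0] for c in cpm.columns})

specs = preset_patterns()
hyper, _, trace = fit_gg_em(cpm, groups, specs)
assignment = assign_patterns(cpm, groups, hyper, specs)

print(f"fitted hyperparameters: alpha={hyper.alpha:.2f} a0={hyper.a0:.2f} nu={hyper.nu:.3f}")
print(f"EM iterations: {len(trace)}, final log-likelihood {trace[-1]:.1f}")
print("\nintegrants per pattern (P0 stable, P1 uniform kd response, ...):")
print(assignment.best_pattern.value_counts().to_string())

accuracy = (assignment.best_pattern == true_patterns.loc[assignment.best_pattern.index]).mean()
print(f"\nplanted pattern recovered for {100 * accuracy:.1f}% of integrants")

enr = family_enrichment(assignment, family_labels.loc[assignment.best_pattern.index])
top = enr.nsmallest(3, "p")[["family", "pattern", "k", "n", "p", "fold"]]
print("\nstrongest family over-representations (raw hypergeometric p):")
print(top.to_string(index=False))
# Families were assigned round-robin here, so no real over-representation is
# expected; with biological data this table highlights which repeat families
# drive each expression pattern.
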