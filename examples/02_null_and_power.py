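"""Null distributions and detection power of the cross-population scan.

Draws gene-wise multinomial nulls to attach empirical p-values to combined
scores, and evaluates how detection power grows with cohort size.
"""

import numpy as np

from admixscan import null_simulation as ns

theta = {
    "POP_A": np.array([0.25, 0.55, 0.20]),
    "POP_B": np.array([0.25, 0.45, 0.30]),
    "POP_C": np.array([0.25, 0.35, 0.40]),
    "POP_D": np.array([0.25, 0.60, 0.15]),
}
h_tot = {pop: np.full(100, 200) for pop in theta}  # 100 genes, 200 haplotypes

ensemble = ns.genewise_null(h_tot, theta, R=100, seed=0)
print(f"null pool: {ensemble.pool().size} Fisher scores")
for observed in (10.0, 30.0, 60.0):
    p = ns.empirical_p(observed, ensemble)
    print(f"  observed F_CS = {observed:5.1f}  ->  empirical p = {p:.2e}")

print("\nPower to detect a locus at local fraction 0.45 vs background 0.25")
print("(four populations, alpha = 1e-4, 200 replicates):")
power = ns.power_analysis(
    0.45, theta, n_grid=[10, 100, 1000], R=200, alpha=1e-4, seed=1
)
print(power.to_string(index=False))
print("\nPower should rise from near zero at n = 10 diploids to ~1 by n = 100:")
print("cross-population evidence combination detects modest enrichment once")
print("each cohort contributes a few hundred assigned haplotypes.")
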