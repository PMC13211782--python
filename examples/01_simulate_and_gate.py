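"""Generate a calibrated synthetic ependymal-surface sample and gate it.

Draws 20,000 cells from the shipped subtype mixture (marker co-expression
calibrated so the planted population statistics equal the published ones),
binarizes the five gating markers at count >= 1, and partitions cells by
serial depletion in the order Prom1 -> Flt1 -> Sox2 -> Pdgfrb -> Vim.
Printed: each bin's recovered fraction next to the planted truth.  Values
agree to sampling noise (~0.5 % at this n), showing the partition recovers
the planted mixture.
"""

import ependymap as em
from ependymap.calibration import GATING_MARKERS

config = em.default_sim_config(n_cells=20_000, seed=1)
matrix = em.generate_expression(config)
truth = em.default_planted_truth(config)

binary = em.binarize(matrix, GATING_MARKERS)
table, assignment = em.serial_depletion(binary)
planted = truth.bin_fractions(GATING_MARKERS)

print(f"{'bin':<34}{'recovered':>10}{'planted':>10}")
for (_, row), p in zip(table.table.iterrows(), planted):
    print(f"{row['bin']:<34}{row['fraction']:>9.1%}{p:>10.1%}")
print(f"\ncoverage of the five named bins: {table.coverage:.1%} "
      f"(planted {1 - planted[-1]:.1%})")
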