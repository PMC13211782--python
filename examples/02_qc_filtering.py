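"""Apply the four-step QC filter chain and inspect what each rule removed.

The filter order follows the study's pre-processing: minimum genes per cell,
minimum cells per gene, a feature-count window, then a mitochondrial-UMI
cap.  The synthetic data is marker-panel-sized (~90 genes), so the example
scales the absolute gene-count thresholds accordingly; on transcriptome-wide
data the defaults (200 / 5 / 180–8000 / 10 %) apply unchanged.
"""

import ependymap as em

matrix = em.generate_expression(em.default_sim_config(n_cells=5_000, seed=2))
params = em.QCParams(min_genes_at_creation=3, min_cells_per_gene=5,
                     min_features=3, max_features=8000, max_mito_fraction=0.10)
filtered, report = em.apply_qc(matrix, params)

print(f"input:     {report.input_shape[0]} cells x {report.input_shape[1]} genes")
for rule in report.rules:
    print(f"  {rule['rule']:<28} removed {rule['n_removed']:>4} {rule['axis']}")
print(f"surviving: {report.surviving_shape[0]} cells x {report.surviving_shape[1]} genes")
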