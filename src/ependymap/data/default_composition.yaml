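# Default twelve-sector composition of the ependymal surface, in percent of
# all surface cells.  The CD133+ / CD133- stratum totals (67.6 / 32.4) follow
# the published split; the sub-sector values are SYNTHETIC package defaults,
# constructed to be consistent with the published co-label marginals
# (CD133+ cells co-labelled FLT1 40%, SOX2 34%, PDGFRB 12% of all cells;
# endo-peri overlap = 0.38 x pericyte marginal) since the per-sector values
# were not printed.  Sectors within a stratum are disjoint; the whole table
# sums to 100.
sectors_percent:
  CD133+:
    endothelial-like: 21.60
    Foxj1+: 20.16
    pericyte-like: 7.44
    endo-peri-like: 4.56
    Foxj1-endo-like: 13.84
  CD133-:
    endothelial-like: 8.90
    Foxj1+: 9.50
    pericyte-like: 5.25
    endo-peri-like: 1.50
    Foxj1-endo-like: 1.50
    Vim-only: 4.25
    negative-for-all: 1.50
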