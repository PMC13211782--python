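description: Calibrated default subtype mixture for the ependymal-surface simulator. observed_rates are
  post-capture positivity targets (fraction of cells of the component with count >= 1); the generator
  converts them to pre-dropout expression probabilities q = r/d with d = 1-(1-c)*exp(-(mean_count-1)*c).
  Weights and the five gating-marker rates are solved so the planted serial-depletion bins, Vim/Pdgfrb
  marginals and the Prom1|Flt1 and Flt1|Pdgfrb conditionals equal the published values exactly; the other
  panel rates are a synthetic construction.
mean_count: 20.0
default_capture_rate: 0.3
gating_markers:
- Prom1
- Flt1
- Sox2
- Pdgfrb
- Vim
profiles:
- name: multiciliated
  weight: 0.512244897959
  observed_rates:
    Prom1: 0.98
    Flt1: 0.842305866786
    Sox2: 0.19
    Pdgfrb: 0.007534374403
    Vim: 0.896652355628
    Foxj1: 0.15
    Cd24a: 0.5
    Pecam1: 0.5
    Sox17: 0.3
    Cldn5: 0.3
    Nes: 0.3
    Notch1: 0.3
    S100b: 0.25
    Acta2: 0.2
    Cspg4: 0.02
    Vtn: 0.05
    Actb: 0.98
    Malat1: 0.98
    Vps35: 0.9
    Ccn1: 0.05
    Gfap: 0.05
    Vcam1: 0.05
    Egfr: 0.05
- name: endothelial_like
  weight: 0.156500675862
  observed_rates:
    Prom1: 0.0
    Flt1: 0.98
    Sox2: 0.1
    Pdgfrb: 0.375229304503
    Vim: 0.85
    Pecam1: 0.85
    Sox17: 0.7
    Cldn5: 0.7
    Nes: 0.5
    Notch1: 0.5
    Foxj1: 0.05
    Cd24a: 0.1
    S100b: 0.1
    Acta2: 0.05
    Cspg4: 0.05
    Vtn: 0.1
    Actb: 0.98
    Malat1: 0.98
    Vps35: 0.9
    Ccn1: 0.05
    Gfap: 0.05
    Vcam1: 0.05
    Egfr: 0.05
- name: foxj1_ependymal
  weight: 0.151408206317
  observed_rates:
    Prom1: 0.0
    Flt1: 0.0
    Sox2: 0.98
    Pdgfrb: 0.01
    Vim: 0.85
    Foxj1: 0.9
    S100b: 0.8
    Acta2: 0.7
    Cd24a: 0.8
    Pecam1: 0.05
    Sox17: 0.05
    Cldn5: 0.05
    Nes: 0.1
    Notch1: 0.1
    Cspg4: 0.02
    Vtn: 0.05
    Actb: 0.98
    Malat1: 0.98
    Vps35: 0.9
    Ccn1: 0.05
    Gfap: 0.05
    Vcam1: 0.05
    Egfr: 0.05
- name: pericyte_like
  weight: 0.097860034012
  observed_rates:
    Prom1: 0.0
    Flt1: 0.0
    Sox2: 0.0
    Pdgfrb: 0.98
    Vim: 0.2
    Cspg4: 0.7
    Vtn: 0.8
    Pecam1: 0.1
    Sox17: 0.05
    Cldn5: 0.05
    Nes: 0.15
    Notch1: 0.1
    Foxj1: 0.02
    Cd24a: 0.05
    S100b: 0.05
    Acta2: 0.3
    Actb: 0.98
    Malat1: 0.98
    Vps35: 0.9
    Ccn1: 0.05
    Gfap: 0.05
    Vcam1: 0.05
    Egfr: 0.05
- name: vim_only
  weight: 0.060612090747
  observed_rates:
    Prom1: 0.0
    Flt1: 0.0
    Sox2: 0.0
    Pdgfrb: 0.0
    Vim: 0.98
    Foxj1: 0.02
    Cd24a: 0.05
    Pecam1: 0.05
    Sox17: 0.02
    Cldn5: 0.02
    Nes: 0.1
    Notch1: 0.05
    S100b: 0.05
    Acta2: 0.05
    Cspg4: 0.02
    Vtn: 0.02
    Actb: 0.98
    Malat1: 0.98
    Vps35: 0.9
    Ccn1: 0.05
    Gfap: 0.05
    Vcam1: 0.05
    Egfr: 0.05
- name: housekeeping_only
  weight: 0.021374095103
  observed_rates:
    Prom1: 0.0
    Flt1: 0.0
    Sox2: 0.0
    Pdgfrb: 0.0
    Vim: 0.0
    Foxj1: 0.0
    Cd24a: 0.0
    Pecam1: 0.0
    Sox17: 0.0
    Cldn5: 0.0
    Nes: 0.0
    Notch1: 0.0
    S100b: 0.0
    Acta2: 0.0
    Cspg4: 0.0
    Vtn: 0.0
    Actb: 0.98
    Malat1: 0.98
    Vps35: 0.9
    Ccn1: 0.05
    Gfap: 0.05
    Vcam1: 0.05
    Egfr: 0.05
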