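# Methods

## Problem setting

The ependymal surface of the adult mouse lateral ventricle is a mosaic of
cell subtypes — multi-ciliated CD133⁺ (*Prom1*) cells, endothelial-like
(*Flt1*/*Pecam1*/*Sox17*/*Cldn5*), pericyte-like (*Pdgfrb*/*Cspg4*/*Vtn*),
Foxj1⁺ ependymal (*Sox2*/*Foxj1*/*S100b*/*Acta2*/*Cd24a*) cells and their
overlap classes — measured two ways: single-cell RNA counts (binarized to
"expressing" calls) and layered whole-mount immunostaining counts. This
package implements the quantitative machinery connecting the two: a
generative model with planted truth, the QC and gating operations applied
to expression data, the estimators applied to z-stack counts, and the
reconstruction of the complete composition partition.

## Generative model

**Mixture.** Each cell draws a latent subtype *j* with weight *wⱼ*. Within
a subtype, each marker gene *m* is *expressed* independently with
probability *qⱼₘ*. An expressed marker carries `N = 1 + Poisson(mean_count − 1)`
transcripts (shifted Poisson: the simplest count model that preserves
positivity); each transcript is captured independently with probability
`capture_rate` (binomial thinning), emulating the low mRNA capture of
droplet scRNA-seq. Background genes, including a block of `mt-` prefixed
mitochondrial genes to exercise the QC mito filter, are independent
low-rate Poisson with the same thinning.

**Dropout-exact calibration.** The probability that an expressed marker is
detected at count ≥ 1 is closed-form:

    d = 1 − (1 − c)·exp(−(mean_count − 1)·c)

The shipped default profile stores *observed-scale* rates *r* (the target
positive fractions) and plants `q = r/d`, so the observed positivity of
every marker in every component equals *r* exactly, independent of the
capture rate (valid whenever `r ≤ d`; the builder raises otherwise).
Detection probability 1 is unreachable under finite-count thinning, which
is why calibration happens on the observed scale rather than by forcing
within-component rates to 1. With the defaults `capture_rate = 0.3` and
`mean_count = 20`, `d ≈ 0.9977`, comfortably above the largest target rate
(0.98).

**Solved default mixture.** Six components map onto the serial-depletion
bins (multiciliated, endothelial-like, Foxj1-ependymal, pericyte-like,
Vim-only, housekeeping-only). Components never express markers earlier
than their own in the gating order (zero upward leakage), which makes all
population statistics closed-form. Ten free parameters (six weights and
four co-expression rates) are solved by `scipy.optimize.fsolve` against ten
constraints: the five bin fractions 50.2/16.2/14.9/9.7/6.5 %, ΣW = 1, the
marginals P(Vim⁺) = 0.80 and P(Pdgfrb⁺) = 0.16, and the conditionals
P(Prom1⁺|Flt1⁺) = 0.723 and P(Flt1⁺|Pdgfrb⁺) = 0.38. Remaining
co-expression rates are fixed at plausible values consistent with the
study's secondary observations (Sox2 rate 0.19 within the multiciliated
component; near-zero Sox2∧Pdgfrb; high Vim co-rates). The solved table is
frozen in `data/default_profile.yaml`; a test re-runs the solver and
asserts agreement to 1e−9 and that the implied statistics match the target
values to 1e−8. Because the five bin fractions sum to 97.5 %, the planted
remainder is 2.5 %.

The housekeeping genes *Actb*/*Malat1* (and the pan marker *Vps35*) are
expressed at rate 0.98 in every component including the remainder, so the
remainder is a genuine "housekeeping-only" class. Subependymal-NSC panel
genes are present at low rates everywhere.

**FACS split.** Each cell is assigned to the PE (CD133-antibody-positive)
pool with a subtype-specific probability: 0.8 for the four EPE-like
components, 0.5 for Vim-only/housekeeping-only, 0.2 for optional
neuroblast-like spike-ins. The study states the direction of enrichment
but not magnitudes; these are package defaults.

**Z-stack generator.** Given a planted twelve-sector composition, every
staining channel (CD133 over all nuclei; within each CD133 stratum the
endothelial trio FLT1/CD31/NESTIN, the Foxj1 trio SOX2/FOXJ1/S100B,
PDGFRB, the three pairwise co-label channels, and VIM in the negative
stratum) gets, per field: a binomial number of stratum nuclei, a binomial
number of truly positive cells, and per-cell Bernoulli detection in each
optical layer; the merged projection counts a cell positive if seen in any
layer. Default detection is 1.0 per layer: Average 1 = (A+B+C+D)/4 is an
unbiased estimator of the planted rate only under full per-layer
detection — any per-layer miss biases all four layer rates (and hence every
estimator) low — so ideal detection is the reference condition for recovery
analyses. Depth-localised profiles (e.g. `{"CD133": (1.0, 1.0, 0.1)}`,
mimicking cilia visible only in the top layers) are available to reproduce
the qualitative layer-localisation observations and to study estimator
bias; `examples/03_zstack_estimators.py` demonstrates both regimes.

## QC

Four rules in the stated order: (1) cells with < 200 detected genes
(applied at object creation), (2) genes detected in < 5 cells, (3) cells
outside the 180–8000 feature window, (4) cells with mitochondrial UMI
fraction > 10 %. Under these defaults rule 3's lower arm is vacuous after
rule 1; both are kept, in order, for fidelity, and the report shows the
vacuous arm removing zero cells. "Features" are detected genes (count ≥ 1)
per cell; the mito fraction uses UMIs, not gene counts (the conventional
reading; the source is silent). The pass is single-shot, not a fixed-point
iteration — re-applying QC can in principle remove more cells after the
gene rule shrinks per-cell feature counts, so idempotence is a property of
well-separated data (asserted on the shipped fixture), not a theorem.
Doublet detection is out of scope; an external boolean exclusion mask is
accepted and applied first.

The synthetic data is marker-panel-sized (~90 genes), so the absolute
thresholds of rule 1/3 would remove every synthetic cell; example and
pipeline configurations scale those two thresholds down and say so. On
transcriptome-wide data the defaults apply unchanged.

## Gating

Positivity is raw count ≥ threshold, default 1 — the source reports
fractions of cells "expressing" a gene without a numeric cutoff, so the
threshold is prominent and configurable. Serial depletion is vectorised
first-match (argmax over booleans); an independent per-cell loop
implementation is kept as a test oracle. The remainder fraction is
order-invariant (a cell is in the remainder iff it expresses none of the
markers), which is asserted exactly over all 120 permutations of the five
markers; individual bin sizes depend on the order.

The twelve-class assignment splits on Prom1, then uses the representative
markers Flt1 (E), Sox2 (F) and Pdgfrb (P): exclusive classes E/F/P-only,
overlap classes E∧P (endo–peri, including the rare triple positives — a
documented tie-break) and E∧F (Foxj1–endo). F∧P cells get an explicit
Foxj1–peri audit label rather than a silent merge. Vim-only and
negative-for-all classes belong to the CD133⁻ stratum; their CD133⁺
counterparts are audit labels, since the published partition has no such
sectors. A label→label relabel map exposes the cluster-level convention of
folding endo–peri cells into the pericyte-like class. Microglia-like
spike-ins, when present in synthetic truth, are excluded before
composition via `exclude_by_truth`, mirroring their exclusion in the
source analysis.

## Z-stack estimators

Rates are pooled (Σ positives / Σ nuclei across fields); per-field rates
are available for mean ± SD reporting. Estimators per channel: Added =
(A+B+C)/3, Merged = D, Average 1 = (A+B+C+D)/4, and two readings of
Average 2. The as-printed expression (A+B+C)/3 + D/2 fails the identity
sanity check (A=B=C=D=r gives 1.5r) and can exceed 1; it is computed and
flagged, never silently used. The corrected reading ((A+B+C)/3 + D)/2 —
the mean of Added and Merged, matching the textual description of Average
2 as a mean — is the default "average2". Average 1 is the default
estimator downstream, as in the source. Channels missing a layer are
marked partial and yield NaN for estimators that need the missing layer.

## Composition reconstruction

The source prints the CD133⁺/CD133⁻ split (67.6/32.4 %) and describes the
sectors but not the sector arithmetic; the reconstruction here is the
package's own and is flagged as such. Within each stratum, group rates are
trio averages (arithmetic mean of the three markers); exclusive sectors
are parents minus their overlaps; overlap sectors stay explicit. The
CD133⁻ stratum adds Vim-only = VIM marginal − inclusion–exclusion coverage
of the three groups (the generator plants the VIM channel as exactly that
coverage plus the Vim-only sector, consistent with the observation that
VIM co-labels broadly), and negative-for-all = stratum total − everything
else. Negative intermediates (possible when noise makes an overlap exceed
its parent) are clipped to zero and recorded in the audit dict; the final
vector is renormalized to sum to exactly 1, with the pre-normalization
total reported as an audit number. The shipped default composition uses
the published stratum totals; its sub-sector values are synthetic defaults
consistent with the published co-label marginals (documented in
`data/default_composition.yaml`).

## Problem sizes and numerical choices

Recovery analyses use 50,000 cells for the expression pathway and 30
fields × 200 nuclei for the imaging pathway — the scales at which three
binomial standard errors resolve the planted values to well under one
percentage point; both run in seconds. Tolerances: exact assertions for
deterministic identities (partition cover, order-invariant remainder,
Bayes-symmetry to 1e−12, calibration residual < 1e−10); three binomial
standard errors for stochastic recovery. Ties and degenerate inputs:
empty matrices are legal QC inputs; conditionals with an empty condition
are NaN (undefined), not 0; zero-nucleus layers are reported missing;
all-zero reconstitutions raise.

## What the synthetic data does and does not show

The generator emulates the co-expression structure, dropout level, sort
enrichment and layered detection of the real experiments, with the
published percentages as planted truth. It does not emulate
transcriptome-wide expression programs, doublets, ambient RNA,
batch/animal effects, antibody-quality variation, or spatial correlation
between neighbouring cells in a field. Passing recovery tests therefore
demonstrates that the analysis operations are correct and unbiased under
the stated model — not that the model captures every property of the real
tissue. Cluster annotation, dimensionality reduction and differential
expression are deliberately out of scope; cluster labels, where needed,
come from synthetic truth or from the user.
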