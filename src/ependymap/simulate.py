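"""Synthetic single-cell counts, FACS splits, and z-stack count tables.

The generator plants a recoverable ground truth that mirrors the statistical
structure of the ependymal-surface study: a mixture of surface subtypes with
calibrated marker co-expression, transcript-level dropout from a low mRNA
capture rate, CD133-antibody (PE/NC) sort enrichment, and layer-by-layer
immunostaining detection with a merged projection.

Count model for an expressed marker: ``N = 1 + Poisson(mean_count - 1)``
transcripts, each captured independently with probability ``capture_rate``
(binomial thinning).  The expression event itself is Bernoulli with the
profile's ``marker_probs``.  Background genes are independent low-rate
Poisson, including a configurable block of ``mt-`` prefixed genes so that
mitochondrial-fraction QC has something to act on.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .calibration import GATING_MARKERS, PlantedTruth, detection_probability
from .matrix import LabeledExpressionMatrix

# Mouse mitochondrial gene symbols used for the synthetic mt- block.
MITO_GENE_NAMES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

#: Subtypes regarded as EPE-like for the default FACS enrichment map.
EPE_SUBTYPES = ("multiciliated", "endothelial_like", "foxj1_ependymal", "pericyte_like")


@dataclass
class SubtypeProfile:
    """One mixture component: a subtype with per-gene expression probabilities.

    ``marker_probs`` are pre-dropout probabilities that a cell of this subtype
    expresses each gene; ``mean_count`` is the mean transcript count per
    expressed marker (>= 1).
    """

    name: str
    weight: float
    marker_probs: Dict[str, float]
    mean_count: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"profile {self.name!r}: weight {self.weight} outside [0, 1]")
        for g, p in self.marker_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"profile {self.name!r}: marker_probs[{g!r}] = {p} outside [0, 1]")
        if self.mean_count < 1.0:
            raise ValueError(f"profile {self.name!r}: mean_count {self.mean_count} must be >= 1")


@dataclass
class SimConfig:
    """Configuration of the expression simulator."""

    n_cells: int
    profiles: List[SubtypeProfile]
    capture_rate: float = 0.3
    background_genes: int = 50
    mito_genes: int = 13
    background_rate: float = 0.2
    mito_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0.0 <= self.capture_rate <= 1.0:
            raise ValueError(f"capture_rate {self.capture_rate} outside [0, 1]")
        if not self.profiles:
            raise ValueError("profiles must be a non-empty list")
        total = sum(p.weight for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile weights must sum to 1 (got {total!r}); check the 'weight' fields")
        if self.mito_genes > len(MITO_GENE_NAMES):
            raise ValueError(f"at most {len(MITO_GENE_NAMES)} mito genes available")


# ----------------------------------------------------------------------
# Default calibrated profiles
# ----------------------------------------------------------------------
def _load_profile_table() -> dict:
    ref = importlib.resources.files("ependymap.data").joinpath("default_profile.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_profiles(capture_rate: float = 0.3, mean_count: Optional[float] = None) -> List[SubtypeProfile]:
    """The shipped calibrated mixture, converted to pre-dropout probabilities.

    The shipped table stores post-capture positivity targets ``r``; this
    builder plants ``q = r / d`` where ``d`` is the detection probability
    given expression under (``capture_rate``, ``mean_count``), so the observed
    positive fractions equal the calibrated targets at any capture rate for
    which ``r <= d``.
    """
    table = _load_profile_table()
    if mean_count is None:
        mean_count = float(table["mean_count"])
    d = detection_probability(capture_rate, mean_count)
    profiles = []
    for entry in table["profiles"]:
        probs = {}
        for gene, r in entry["observed_rates"].items():
            if r > d + 1e-12:
                raise ValueError(
                    f"capture_rate {capture_rate} too low to realise observed rate "
                    f"{r} for {gene!r} (detection probability {d:.6f}); raise "
                    "capture_rate or mean_count"
                )
            probs[gene] = min(1.0, r / d)
        profiles.append(
            SubtypeProfile(
                name=entry["name"],
                weight=float(entry["weight"]),
                marker_probs=probs,
                mean_count=mean_count,
            )
        )
    return profiles


def default_sim_config(n_cells: int = 50_000, seed: int = 0, capture_rate: float = 0.3) -> SimConfig:
    return SimConfig(
        n_cells=n_cells,
        profiles=default_profiles(capture_rate=capture_rate),
        capture_rate=capture_rate,
        seed=seed,
    )


def default_planted_truth(config: SimConfig) -> PlantedTruth:
    """Closed-form planted statistics for a config (observed scale)."""
    return PlantedTruth(config.profiles, config.capture_rate)


# ----------------------------------------------------------------------
# Expression generation
# ----------------------------------------------------------------------
def generate_expression(config: SimConfig) -> LabeledExpressionMatrix:
    """Draw a labelled cell×gene count matrix from the mixture model.

    Deterministic for a fixed ``SimConfig`` (including its ``seed``).
    """
    rng_assign, rng_expr, rng_count, rng_thin, rng_bg = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(5)
    ]
    n = config.n_cells
    weights = np.array([p.weight for p in config.profiles])
    subtype_idx = rng_assign.choice(len(config.profiles), size=n, p=weights / weights.sum())

    marker_genes: List[str] = []
    for p in config.profiles:
        for g in p.marker_probs:
            if g not in marker_genes:
                marker_genes.append(g)
    bg_genes = [f"Bg{i + 1:04d}" for i in range(config.background_genes)]
    mito = MITO_GENE_NAMES[: config.mito_genes]
    genes = marker_genes + bg_genes + mito

    prob_table = np.zeros((len(config.profiles), len(marker_genes)))
    mean_table = np.array([p.mean_count for p in config.profiles])
    for j, p in enumerate(config.profiles):
        for g, q in p.marker_probs.items():
            prob_table[j, marker_genes.index(g)] = q

    c = config.capture_rate
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    lam = np.maximum(mean_table[subtype_idx] - 1.0, 0.0)
    for m in range(len(marker_genes)):
        expressed = rng_expr.random(n) < prob_table[subtype_idx, m]
        if not expressed.any():
            continue
        pre = 1 + rng_count.poisson(lam[expressed])
        obs = rng_thin.binomial(pre, c) if c < 1.0 else pre
        keep = obs > 0
        if keep.any():
            r = np.flatnonzero(expressed)[keep]
            rows.append(r)
            cols.append(np.full(r.size, m))
            vals.append(obs[keep])

    # Background and mito genes: independent Poisson, then the same thinning.
    for offset, n_g, rate in [
        (len(marker_genes), len(bg_genes), config.background_rate),
        (len(marker_genes) + len(bg_genes), len(mito), config.mito_rate),
    ]:
        if n_g == 0:
            continue
        pre = rng_bg.poisson(rate, size=(n, n_g))
        obs = rng_thin.binomial(pre, c) if c < 1.0 else pre
        r, cc = np.nonzero(obs)
        if r.size:
            rows.append(r)
            cols.append(cc + offset)
            vals.append(obs[r, cc])

    if rows:
        counts = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, len(genes)),
            dtype=np.int64,
        ).tocsr()
    else:
        counts = sp.csr_matrix((n, len(genes)), dtype=np.int64)

    names = np.array([p.name for p in config.profiles])
    width = len(str(n))
    return LabeledExpressionMatrix(
        counts=counts,
        cell_ids=[f"cell_{i + 1:0{width}d}" for i in range(n)],
        gene_ids=genes,
        truth_subtype=names[subtype_idx],
        meta={"seed": config.seed, "capture_rate": c},
    )


# ----------------------------------------------------------------------
# FACS split
# ----------------------------------------------------------------------
def default_enrichment() -> Dict[str, float]:
    """PE-assignment probabilities per subtype for the CD133 sort emulation.

    The study reports direction only (EPE subtypes enriched in the PE
    fraction, neuroblasts in NC); magnitudes here are package defaults.
    """
    enr = {name: 0.8 for name in EPE_SUBTYPES}
    enr.update({"vim_only": 0.5, "housekeeping_only": 0.5, "neuroblast": 0.2})
    return enr


def generate_facs_split(
    matrix: LabeledExpressionMatrix,
    enrichment: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> LabeledExpressionMatrix:
    """Assign each cell to the PE (CD133+) or NC (CD133-) sorted pool.

    Each cell lands in PE with its subtype's enrichment probability.
    Requires ``truth_subtype``.
    """
    if matrix.truth_subtype is None:
        raise ValueError("generate_facs_split requires truth_subtype labels")
    enrichment = default_enrichment() if enrichment is None else dict(enrichment)
    for name, p in enrichment.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"enrichment[{name!r}] = {p} outside [0, 1]")
    subtypes = matrix.truth_subtype.to_numpy()
    missing = sorted(set(subtypes) - set(enrichment))
    if missing:
        raise ValueError(f"no enrichment probability for subtypes: {missing}")
    probs = np.array([enrichment[s] for s in subtypes])
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(len(probs)) < probs, "PE", "NC")
    return LabeledExpressionMatrix(
        counts=matrix.counts,
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        truth_subtype=subtypes,
        facs_fraction=labels,
        meta=dict(matrix.meta),
    )


# ----------------------------------------------------------------------
# Z-stack generation
# ----------------------------------------------------------------------
def generate_zstack(
    composition,
    detection: Optional[Mapping[str, Sequence[float]]] = None,
    n_fields: int = 30,
    cells_per_field: int = 200,
    seed: int = 0,
):
    """Simulate per-field layered immunostaining counts from a planted composition.

    ``composition`` is a twelve-sector :class:`~ependymap.gating.CompositionTable`
    (see :func:`ependymap.composition.default_composition`).  For every
    staining channel implied by the composition — CD133 over all nuclei, and
    the subgroup/overlap markers within each CD133 stratum — the generator
    draws, per field, the number of truly positive cells and their detection
    in each optical layer A (0 µm), B (−1 µm) and C (−2 µm); the merged
    projection D counts a cell positive if it was detected in any layer.

    ``detection`` maps marker name to per-layer detection probabilities
    ``(dA, dB, dC)`` given true positivity; the default is 1.0 everywhere,
    under which the Average 1 estimator is unbiased for the planted rate.
    """
    from .composition import channel_rates_from_composition
    from .zstack import LAYERS, ZStackCounts

    if n_fields < 1 or cells_per_field < 1:
        raise ValueError("n_fields and cells_per_field must both be >= 1")
    channels = channel_rates_from_composition(composition)
    detection = {} if detection is None else dict(detection)
    rng = np.random.default_rng(seed)

    records = []
    for f in range(n_fields):
        field_id = f"field_{f + 1:02d}"
        # Stratum nucleus counts are drawn once per field and shared across
        # that stratum's channels, as on a real co-stained field.
        stratum_n: Dict[str, int] = {"all": cells_per_field}
        for ch in channels:
            if ch.stratum not in stratum_n:
                stratum_n[ch.stratum] = int(rng.binomial(cells_per_field, ch.stratum_weight))
        for ch in channels:
            nuclei = stratum_n[ch.stratum]
            n_pos = int(rng.binomial(nuclei, ch.rate)) if nuclei else 0
            det = np.asarray(detection.get(ch.marker, (1.0, 1.0, 1.0)), dtype=float)
            if det.shape != (3,) or (det < 0).any() or (det > 1).any():
                raise ValueError(f"detection for {ch.marker!r} must be three probabilities in [0, 1]")
            seen = rng.random((n_pos, 3)) < det[None, :]
            layer_pos = seen.sum(axis=0)
            merged = int(seen.any(axis=1).sum())
            for layer, pos in zip(LAYERS[:3], layer_pos):
                records.append((field_id, ch.stratum, ch.marker, layer, int(pos), nuclei))
            records.append((field_id, ch.stratum, ch.marker, "D", merged, nuclei))

    frame = pd.DataFrame(
        records, columns=["field_id", "stratum", "marker", "layer", "positive", "nuclei"]
    )
    return ZStackCounts(frame)
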