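"""Cell and gene quality-control filters, applied in the study's stated order.

Rules, in order:

1. drop cells detecting fewer than ``min_genes_at_creation`` genes;
2. drop genes detected in fewer than ``min_cells_per_gene`` cells;
3. drop cells with fewer than ``min_features`` or more than ``max_features``
   detected genes;
4. drop cells whose mitochondrial UMI fraction exceeds ``max_mito_fraction``.

Under the defaults the lower arm of rule 3 (180) is vacuous after rule 1
(200); both are applied anyway, in order, and the report shows rule 3's
lower arm removing zero cells.  "Features" means detected genes (count >= 1)
per cell; the mitochondrial fraction is mito UMIs over total UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .matrix import LabeledExpressionMatrix


@dataclass
class QCParams:
    min_genes_at_creation: int = 200
    min_cells_per_gene: int = 5
    min_features: int = 180
    max_features: int = 8000
    max_mito_fraction: float = 0.10
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ValueError(
                f"min_features ({self.min_features}) must not exceed max_features ({self.max_features})"
            )
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError(f"max_mito_fraction {self.max_mito_fraction} outside [0, 1]")


@dataclass
class QCReport:
    """What each rule removed, in application order, plus surviving shape."""

    input_shape: Tuple[int, int]
    rules: List[dict] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    surviving_shape: Tuple[int, int] = (0, 0)

    def add(self, rule: str, axis: str, n_removed: int) -> None:
        self.rules.append({"rule": rule, "axis": axis, "n_removed": int(n_removed)})

    @property
    def cells_removed(self) -> int:
        return sum(r["n_removed"] for r in self.rules if r["axis"] == "cells")

    @property
    def genes_removed(self) -> int:
        return sum(r["n_removed"] for r in self.rules if r["axis"] == "genes")

    def validate_conservation(self) -> None:
        """removed + surviving must equal the input dimensions on both axes."""
        if self.input_shape[0] != self.surviving_shape[0] + self.cells_removed:
            raise AssertionError("cell bookkeeping does not conserve input cells")
        if self.input_shape[1] != self.surviving_shape[1] + self.genes_removed:
            raise AssertionError("gene bookkeeping does not conserve input genes")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "rules": self.rules,
            "warnings": self.warnings,
            "surviving_shape": list(self.surviving_shape),
        }


def apply_qc(
    matrix: LabeledExpressionMatrix,
    params: Optional[QCParams] = None,
    exclude_cells: Optional[np.ndarray] = None,
) -> Tuple[LabeledExpressionMatrix, QCReport]:
    """Single pass of the four filters in order; returns matrix and report.

    ``exclude_cells`` is an optional boolean mask (True = drop) applied
    before rule 1, standing in for external doublet calls, which are out of
    scope here.
    """
    params = QCParams() if params is None else params
    report = QCReport(input_shape=matrix.shape)
    m = matrix

    if exclude_cells is not None:
        exclude_cells = np.asarray(exclude_cells, dtype=bool)
        if exclude_cells.shape != (m.n_cells,):
            raise ValueError("exclude_cells mask must have one entry per cell")
        report.add("rule0_external_exclusion", "cells", exclude_cells.sum())
        m = m.subset_cells(~exclude_cells)

    # Rule 1: minimum detected genes per cell at object creation.
    keep = m.genes_per_cell() >= params.min_genes_at_creation
    report.add("rule1_min_genes_per_cell", "cells", (~keep).sum())
    m = m.subset_cells(keep)

    # Rule 2: genes detected in too few cells.
    keep_g = m.cells_per_gene() >= params.min_cells_per_gene
    report.add("rule2_min_cells_per_gene", "genes", (~keep_g).sum())
    m = m.subset_genes(keep_g)

    # Rule 3: feature-count window (recomputed on the gene-filtered matrix).
    feats = m.genes_per_cell()
    low = feats < params.min_features
    high = feats > params.max_features
    report.add("rule3_min_features", "cells", low.sum())
    report.add("rule3_max_features", "cells", (high & ~low).sum())
    m = m.subset_cells(~(low | high))

    # Rule 4: mitochondrial UMI fraction.
    mito_mask = np.array([g.startswith(params.mito_prefix) for g in m.gene_ids])
    if not mito_mask.any():
        report.warnings.append(
            f"mito_prefix {params.mito_prefix!r} matches no gene; rule 4 removes nothing"
        )
        report.add("rule4_max_mito_fraction", "cells", 0)
    else:
        total = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
        mito = np.asarray(m.counts[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        bad = frac > params.max_mito_fraction
        report.add("rule4_max_mito_fraction", "cells", bad.sum())
        m = m.subset_cells(~bad)

    report.surviving_shape = m.shape
    report.validate_conservation()
    return m, report
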