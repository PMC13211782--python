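"""Container for labelled sparse cell×gene count matrices.

The ependymal-surface analyses operate on raw UMI counts with two optional
per-cell annotations: a ground-truth subtype (known for synthetic data,
usually absent for real data) and a FACS fraction label (``PE`` for the
CD133-antibody-positive sort, ``NC`` for the negative sort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

FACS_LABELS = ("PE", "NC")


@dataclass
class LabeledExpressionMatrix:
    """Sparse nonnegative-integer cell×gene counts with optional labels.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` sparse matrix of raw counts (stored CSR).
    cell_ids, gene_ids
        Unique identifiers for rows and columns.
    truth_subtype
        Optional per-cell ground-truth subtype label (synthetic data).
    facs_fraction
        Optional per-cell label in ``{"PE", "NC"}``.
    """

    counts: sp.spmatrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    truth_subtype: Optional[pd.Series] = None
    facs_fraction: Optional[pd.Series] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cell ids and {len(self.gene_ids)} gene ids"
            )
        for name, idx in (("cell_ids", self.cell_ids), ("gene_ids", self.gene_ids)):
            if idx.has_duplicates:
                dupes = idx[idx.duplicated()].unique().tolist()[:5]
                raise ValueError(f"duplicate {name}: {dupes}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        for name in ("truth_subtype", "facs_fraction"):
            series = getattr(self, name)
            if series is not None:
                series = pd.Series(np.asarray(series), index=self.cell_ids, name=name)
                setattr(self, name, series)
        if self.facs_fraction is not None:
            bad = set(self.facs_fraction.dropna().unique()) - set(FACS_LABELS)
            if bad:
                raise ValueError(f"facs_fraction labels must be in {FACS_LABELS}, got {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_positions(self, genes: Sequence[str]) -> np.ndarray:
        """Column positions of ``genes``; raises listing any missing ones."""
        indexer = self.gene_ids.get_indexer(list(genes))
        if (indexer < 0).any():
            missing = [g for g, i in zip(genes, indexer) if i < 0]
            raise KeyError(f"genes not present in matrix: {missing}")
        return indexer

    def marker_counts(self, genes: Sequence[str]) -> pd.DataFrame:
        """Dense per-cell counts for a small set of genes."""
        cols = self.gene_positions(genes)
        dense = np.asarray(self.counts[:, cols].todense())
        return pd.DataFrame(dense, index=self.cell_ids, columns=list(genes))

    def subset_cells(self, mask: np.ndarray) -> "LabeledExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LabeledExpressionMatrix(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            truth_subtype=None if self.truth_subtype is None else self.truth_subtype.iloc[idx].to_numpy(),
            facs_fraction=None if self.facs_fraction is None else self.facs_fraction.iloc[idx].to_numpy(),
            meta=dict(self.meta),
        )

    def subset_genes(self, mask: np.ndarray) -> "LabeledExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LabeledExpressionMatrix(
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            truth_subtype=None if self.truth_subtype is None else self.truth_subtype.to_numpy(),
            facs_fraction=None if self.facs_fraction is None else self.facs_fraction.to_numpy(),
            meta=dict(self.meta),
        )

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected genes (count >= 1) per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells in which each gene is detected."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (optional dependency)."""
        import anndata as ad

        obs = pd.DataFrame(index=self.cell_ids.astype(str))
        if self.truth_subtype is not None:
            obs["truth_subtype"] = self.truth_subtype.to_numpy()
        if self.facs_fraction is not None:
            obs["facs_fraction"] = self.facs_fraction.to_numpy()
        var = pd.DataFrame(index=self.gene_ids.astype(str))
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)
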