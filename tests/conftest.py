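"""Shared fixtures: small synthetic runs and the hand-built QC matrix."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import ependymap as em


@pytest.fixture(scope="session")
def default_run():
    """A mid-sized calibrated synthetic run shared across read-only tests."""
    config = em.default_sim_config(n_cells=20_000, seed=11)
    matrix = em.generate_expression(config)
    truth = em.default_planted_truth(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def default_binary(default_run):
    _, matrix, _ = default_run
    scheme = em.GatingScheme.default()
    return em.binarize(matrix, scheme.markers)


def make_matrix(dense, cell_ids=None, gene_ids=None, **kw) -> em.LabeledExpressionMatrix:
    dense = np.asarray(dense)
    n, g = dense.shape
    return em.LabeledExpressionMatrix(
        counts=sp.csr_matrix(dense),
        cell_ids=cell_ids or [f"c{i + 1}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j + 1}" for j in range(g)],
        **kw,
    )


# Hand-built 10-cell x 8-gene QC fixture.  With thresholds
# (min_genes=3, min_cells_per_gene=3, min_features in [3, 6], mito > 0.2):
# rule 1 removes c2 (2 genes) and c10 (1 gene); rule 2 removes g6 and mt-B
# (each detected in 2 remaining cells); rule 3 removes c5 (2 features after
# the gene drop); rule 4 removes c6 (mito fraction 1/4 > 0.2).  Survivors:
# cells {c1,c3,c4,c7,c8,c9} x genes {g1..g5, mt-A}.
QC_GENES = ["g1", "g2", "g3", "g4", "g5", "g6", "mt-A", "mt-B"]
QC_DENSE = np.array(
    [
        [1, 1, 1, 0, 0, 0, 0, 0],  # c1
        [1, 1, 0, 0, 0, 0, 0, 0],  # c2  <- rule 1
        [2, 3, 1, 1, 0, 0, 1, 0],  # c3
        [1, 1, 1, 1, 1, 1, 1, 1],  # c4
        [0, 0, 0, 0, 1, 1, 1, 0],  # c5  <- rule 3 (after g6/mt-B drop)
        [1, 0, 1, 0, 1, 0, 1, 0],  # c6  <- rule 4 (mito 1/4)
        [5, 5, 5, 0, 0, 0, 0, 5],  # c7
        [1, 1, 1, 1, 1, 0, 0, 0],  # c8
        [0, 1, 1, 1, 1, 0, 1, 0],  # c9  (mito exactly 0.2: kept)
        [1, 0, 0, 0, 0, 0, 0, 0],  # c10 <- rule 1
    ]
)


@pytest.fixture
def qc_fixture():
    matrix = make_matrix(QC_DENSE, gene_ids=list(QC_GENES))
    params = em.QCParams(
        min_genes_at_creation=3,
        min_cells_per_gene=3,
        min_features=3,
        max_features=6,
        max_mito_fraction=0.2,
        mito_prefix="mt-",
    )
    return matrix, params


def qc_bruteforce(dense, genes, params):
    """Independent dense-array enumeration of the four QC rules, in order."""
    dense = np.asarray(dense).copy()
    cells = np.arange(dense.shape[0])
    gidx = np.arange(dense.shape[1])
    keep_c = (dense > 0).sum(axis=1) >= params.min_genes_at_creation
    dense, cells = dense[keep_c], cells[keep_c]
    keep_g = (dense > 0).sum(axis=0) >= params.min_cells_per_gene
    dense, gidx = dense[:, keep_g], gidx[keep_g]
    feats = (dense > 0).sum(axis=1)
    keep_c = (feats >= params.min_features) & (feats <= params.max_features)
    dense, cells = dense[keep_c], cells[keep_c]
    mito_cols = np.array([genes[j].startswith(params.mito_prefix) for j in gidx])
    if mito_cols.any():
        total = dense.sum(axis=1)
        frac = np.where(total > 0, dense[:, mito_cols].sum(axis=1) / np.maximum(total, 1), 0.0)
        keep_c = frac <= params.max_mito_fraction
        dense, cells = dense[keep_c], cells[keep_c]
    return cells, gidx
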