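"""Gating: binarization, serial depletion vs oracle, co-expression, subtyping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ependymap as em
from ependymap.gating import (
    AUDIT_LABELS,
    PRIMARY_LABELS,
    BinaryMarkerMatrix,
    serial_depletion_bruteforce,
)
from conftest import make_matrix

MARKERS = ["Prom1", "Flt1", "Sox2", "Pdgfrb", "Vim"]


def binary_from(rows, markers=MARKERS):
    frame = pd.DataFrame(np.asarray(rows, dtype=bool), columns=markers)
    return BinaryMarkerMatrix(values=frame)


# ----------------------------------------------------------------------
# binarize
# ----------------------------------------------------------------------
def test_binarize_all_zero_is_all_false():
    matrix = make_matrix(np.zeros((4, 5), dtype=int), gene_ids=MARKERS)
    binary = em.binarize(matrix, MARKERS)
    assert not binary.values.to_numpy().any()


def test_binarize_threshold_monotone():
    rng = np.random.default_rng(0)
    matrix = make_matrix(rng.poisson(1.0, size=(50, 5)), gene_ids=MARKERS)
    pos1 = em.binarize(matrix, MARKERS, threshold=1).values.to_numpy()
    pos2 = em.binarize(matrix, MARKERS, threshold=2).values.to_numpy()
    assert (pos2 <= pos1).all()


def test_binarize_missing_genes_listed():
    matrix = make_matrix(np.ones((2, 2), dtype=int), gene_ids=["Prom1", "Flt1"])
    with pytest.raises(KeyError, match="Sox2"):
        em.binarize(matrix, ["Prom1", "Sox2"])


# ----------------------------------------------------------------------
# serial depletion
# ----------------------------------------------------------------------
def test_four_cell_hand_example():
    binary = binary_from(
        [
            [1, 0, 0, 0, 0],  # Prom1+
            [0, 1, 0, 0, 0],  # Prom1-, Flt1+
            [0, 0, 0, 0, 1],  # only Vim
            [0, 0, 0, 0, 0],  # nothing
        ]
    )
    table, assign = em.serial_depletion(binary)
    counts = dict(zip(table.table["bin"], table.table["n_cells"]))
    assert counts == {
        "Prom1+": 1,
        "Prom1-/Flt1+": 1,
        "Prom1-/Flt1-/Sox2+": 0,
        "Prom1-/Flt1-/Sox2-/Pdgfrb+": 0,
        "Prom1-/Flt1-/Sox2-/Pdgfrb-/Vim+": 1,
        "undefined": 1,
    }


def test_all_positive_goes_to_first_bin():
    binary = binary_from(np.ones((7, 5)))
    table, _ = em.serial_depletion(binary)
    assert table.table["fraction"].iloc[0] == 1.0


def test_partition_is_disjoint_and_exhaustive(default_binary):
    table, assign = em.serial_depletion(default_binary)
    assert int(table.table["n_cells"].sum()) == default_binary.n_cells
    assert len(assign) == default_binary.n_cells
    # every assignment label is one of the table's bins
    assert set(assign.unique()) <= set(table.table["bin"])


def test_remainder_invariant_under_marker_permutations(default_binary):
    base = None
    for order in itertools.islice(itertools.permutations(MARKERS), 0, None, 10):
        scheme = em.GatingScheme.from_markers(list(order))
        table, _ = em.serial_depletion(default_binary, scheme)
        if base is None:
            base = table.remainder_fraction
        assert table.remainder_fraction == base


def test_matches_bruteforce_oracle_on_truth_table_and_random():
    scheme = em.GatingScheme.default()
    rows = list(itertools.product([0, 1], repeat=5))
    binary = binary_from(rows)
    _, fast = em.serial_depletion(binary, scheme)
    slow = serial_depletion_bruteforce(binary, scheme)
    assert (fast == slow).all()

    rng = np.random.default_rng(123)
    for _ in range(50):
        binary = binary_from(rng.random((10, 5)) < rng.random(5))
        _, fast = em.serial_depletion(binary, scheme)
        slow = serial_depletion_bruteforce(binary, scheme)
        assert (fast == slow).all()


def test_empty_scheme_rejected():
    with pytest.raises(ValueError):
        em.GatingScheme(bins=[])
    with pytest.raises(ValueError, match="unique"):
        em.GatingScheme(bins=[("a", "Prom1"), ("b", "Prom1")])


# ----------------------------------------------------------------------
# co-expression
# ----------------------------------------------------------------------
def test_self_conditional_is_one_and_disjoint_is_zero():
    binary = binary_from([[1, 0, 0, 0, 0], [1, 0, 0, 0, 0], [0, 1, 0, 0, 0]])
    coex = em.coexpression(binary, [("Prom1", "Prom1"), ("Prom1", "Flt1")])
    assert coex.loc[0, "conditional"] == 1.0
    assert coex.loc[1, "conditional"] == 0.0


def test_empty_condition_is_undefined_not_zero():
    binary = binary_from([[0, 1, 0, 0, 0]])
    coex = em.coexpression(binary, [("Prom1", "Flt1")])
    assert np.isnan(coex.loc[0, "conditional"])
    assert coex.loc[0, "n_condition"] == 0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**30 - 1), st.integers(2, 40))
def test_bayes_symmetry_identity(seed, n):
    """P(B|A)·P(A) equals P(A|B)·P(B) on any binary matrix (joint agreement)."""
    rng = np.random.default_rng(seed)
    binary = binary_from(rng.random((n, 5)) < 0.4)
    coex = em.coexpression(binary, [("Prom1", "Vim"), ("Vim", "Prom1")])
    rates = em.marker_positive_rates(binary, ["Prom1", "Vim"])
    ab = coex.loc[0, "conditional"] * rates["Prom1"]
    ba = coex.loc[1, "conditional"] * rates["Vim"]
    if not (np.isnan(ab) or np.isnan(ba)):
        assert abs(ab - ba) < 1e-12


# ----------------------------------------------------------------------
# marker_positive_rates
# ----------------------------------------------------------------------
def test_positive_rates_edges():
    binary = binary_from(np.zeros((3, 5)))
    rates = em.marker_positive_rates(binary, MARKERS)
    assert (rates == 0).all()
    assert em.marker_positive_rates(binary, []).empty
    with pytest.raises(ValueError):
        em.marker_positive_rates(binary_from(np.zeros((0, 5))), MARKERS)


# ----------------------------------------------------------------------
# twelve-class assignment
# ----------------------------------------------------------------------
def test_truth_table_total_unique_and_reaches_all_primary_classes():
    rows = list(itertools.product([0, 1], repeat=5))
    binary = binary_from(rows)
    labels = em.assign_subtypes(binary)
    assert len(labels) == 32 and labels.notna().all()
    allowed = set(PRIMARY_LABELS) | set(AUDIT_LABELS)
    assert set(labels.unique()) <= allowed
    assert set(PRIMARY_LABELS) <= set(labels.unique())


def test_specific_label_examples():
    binary = binary_from(
        [
            [1, 1, 0, 1, 0],  # Prom1+ Flt1+ Pdgfrb+ -> endo-peri
            [0, 0, 0, 0, 0],  # all negative
            [0, 0, 0, 0, 1],  # Prom1- only Vim
            [1, 0, 1, 1, 0],  # Prom1+ Sox2+ Pdgfrb+ -> audit Foxj1-peri
        ]
    )
    labels = em.assign_subtypes(binary)
    assert labels.iloc[0] == "CD133+ endo-peri-like"
    assert labels.iloc[1] == "CD133- negative-for-all"
    assert labels.iloc[2] == "CD133- Vim-only"
    assert labels.iloc[3] == "CD133+ Foxj1-peri-like"


def test_cluster_level_relabel_map():
    binary = binary_from([[1, 1, 0, 1, 0]])
    relabel = {"CD133+ endo-peri-like": "CD133+ pericyte-like"}
    labels = em.assign_subtypes(binary, relabel=relabel)
    assert labels.iloc[0] == "CD133+ pericyte-like"


def test_marker_panel_rejects_shared_and_empty_genes():
    with pytest.raises(ValueError, match="appears in both"):
        em.MarkerPanel(groups={"a": ["Flt1"], "b": ["Flt1"]})
    with pytest.raises(ValueError, match="empty"):
        em.MarkerPanel(groups={"a": []})


def test_truth_exclusion_mirrors_microglia_rule():
    from ependymap.gating import exclude_by_truth

    matrix = make_matrix(
        np.ones((4, 2), dtype=int),
        truth_subtype=["multiciliated", "microglia", "microglia", "vim_only"],
    )
    kept = exclude_by_truth(matrix)
    assert kept.n_cells == 2
    assert "microglia" not in set(kept.truth_subtype)
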