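"""Marker binarization, serial-depletion partitioning, co-expression, subtyping.

Serial depletion is the study's first-match partition: cells are assigned to
the first bin of an ordered marker list whose marker they express; cells
expressing none of the markers fall into an explicit remainder bin.  The
five-marker default order is Prom1 → Flt1 → Sox2 → Pdgfrb → Vim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import LabeledExpressionMatrix

# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
DEFAULT_PANEL: Dict[str, List[str]] = {
    "endothelial_like": ["Flt1", "Pecam1", "Sox17", "Cldn5", "Nes", "Notch1"],
    "pericyte_like": ["Pdgfrb", "Cspg4", "Vtn"],
    "foxj1_ependymal": ["Sox2", "Foxj1", "S100b", "Acta2", "Cd24a"],
    "pan": ["Vim", "Vps35"],
    "subependymal_nsc": ["Ccn1", "Gfap", "Vcam1", "Egfr"],
    "housekeeping": ["Actb", "Malat1"],
    "cilia": ["Prom1"],
}

#: Representative gene used per subtype group when assigning cell labels.
REPRESENTATIVE = {"endothelial_like": "Flt1", "foxj1_ependymal": "Sox2", "pericyte_like": "Pdgfrb"}


@dataclass
class MarkerPanel:
    """Subtype-group → marker-gene lists; a gene may belong to one group only."""

    groups: Dict[str, List[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_PANEL.items()})

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for group, genes in self.groups.items():
            if not genes:
                raise ValueError(f"marker group {group!r} has an empty gene list")
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in both {seen[g]!r} and {group!r}")
                seen[g] = group

    @property
    def all_genes(self) -> List[str]:
        return [g for genes in self.groups.values() for g in genes]


@dataclass
class GatingScheme:
    """Ordered (bin_name, marker) pairs plus a remainder label.

    Only positive gates are supported; the order is meaningful (first match).
    """

    bins: List[Tuple[str, str]]
    remainder_name: str = "undefined"

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("gating scheme must contain at least one bin")
        markers = [m for _, m in self.bins]
        if len(set(markers)) != len(markers):
            raise ValueError(f"markers must be unique within a scheme, got {markers}")

    @property
    def markers(self) -> List[str]:
        return [m for _, m in self.bins]

    @classmethod
    def default(cls) -> "GatingScheme":
        order = ["Prom1", "Flt1", "Sox2", "Pdgfrb", "Vim"]
        names, prefix = [], ""
        for m in order:
            names.append((prefix + m + "+", m))
            prefix += m + "-/"
        return cls(bins=names)

    @classmethod
    def from_markers(cls, markers: Sequence[str], remainder_name: str = "undefined") -> "GatingScheme":
        names, prefix = [], ""
        for m in markers:
            names.append((prefix + m + "+", m))
            prefix += m + "-/"
        return cls(bins=names, remainder_name=remainder_name)


@dataclass
class BinaryMarkerMatrix:
    """Boolean cells×markers table derived from counts at a fixed threshold."""

    values: pd.DataFrame
    threshold: int = 1

    def __post_init__(self) -> None:
        self.values = self.values.astype(bool)

    @property
    def markers(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def require(self, markers: Iterable[str]) -> None:
        missing = [m for m in markers if m not in self.values.columns]
        if missing:
            raise KeyError(f"markers not present in binary matrix: {missing}")


@dataclass
class CompositionTable:
    """Named disjoint bins with counts/fractions and an explicit remainder row."""

    table: pd.DataFrame  # columns: bin, n_cells (nullable), fraction
    remainder_name: str = "undefined"
    total_cells: Optional[int] = None

    def __post_init__(self) -> None:
        required = {"bin", "fraction"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"composition table needs columns {sorted(required)}")
        if "n_cells" not in self.table.columns:
            self.table = self.table.assign(n_cells=pd.NA)
        self.table = self.table.reset_index(drop=True)
        fr = self.table["fraction"].to_numpy(dtype=float)
        if ((fr < -1e-12) | (fr > 1 + 1e-12)).any():
            raise ValueError("fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {fr.sum()!r}")
        if self.total_cells is not None:
            n = self.table["n_cells"].to_numpy()
            if int(np.nansum(np.array(n, dtype=float))) != self.total_cells:
                raise ValueError("n_cells must sum to total_cells")

    def fraction(self, bin_name: str) -> float:
        row = self.table.loc[self.table["bin"] == bin_name, "fraction"]
        if row.empty:
            raise KeyError(f"no bin named {bin_name!r}")
        return float(row.iloc[0])

    @property
    def remainder_fraction(self) -> float:
        return self.fraction(self.remainder_name)

    @property
    def coverage(self) -> float:
        """Fraction of cells falling in named (non-remainder) bins."""
        return 1.0 - self.remainder_fraction

    @classmethod
    def from_counts(
        cls, names: Sequence[str], counts: Sequence[int], remainder_name: str
    ) -> "CompositionTable":
        counts = np.asarray(counts, dtype=int)
        total = int(counts.sum())
        frac = counts / total if total else np.zeros(len(counts))
        if total == 0:
            raise ValueError("cannot build a composition from zero cells")
        return cls(
            table=pd.DataFrame({"bin": list(names), "n_cells": counts, "fraction": frac}),
            remainder_name=remainder_name,
            total_cells=total,
        )


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------
def binarize(
    matrix: LabeledExpressionMatrix,
    markers: Optional[Sequence[str]] = None,
    threshold: int = 1,
) -> BinaryMarkerMatrix:
    """Positivity table: True iff raw count >= ``threshold`` (default 1).

    The study reports fractions of cells "expressing" a gene without stating
    a numeric cutoff; count >= 1 on raw counts is this package's default
    reading, and the threshold is exposed for sensitivity analyses.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be a positive integer, got {threshold}")
    markers = list(matrix.gene_ids) if markers is None else list(markers)
    dense = matrix.marker_counts(markers)
    return BinaryMarkerMatrix(values=dense >= threshold, threshold=threshold)


def serial_depletion(
    binary: BinaryMarkerMatrix, scheme: Optional[GatingScheme] = None
) -> Tuple[CompositionTable, pd.Series]:
    """First-match partition of cells over an ordered marker list.

    Returns the composition (bins in scheme order plus remainder) and the
    per-cell bin assignment.  Bins are disjoint and exhaustive by
    construction.
    """
    scheme = GatingScheme.default() if scheme is None else scheme
    binary.require(scheme.markers)
    pos = binary.values[scheme.markers].to_numpy()
    n_markers = pos.shape[1]
    # argmax over booleans gives the first True; all-False rows go to remainder.
    first = np.where(pos.any(axis=1), pos.argmax(axis=1), n_markers)
    names = [name for name, _ in scheme.bins] + [scheme.remainder_name]
    counts = np.bincount(first, minlength=n_markers + 1)
    assignment = pd.Series(
        np.array(names, dtype=object)[first], index=binary.values.index, name="bin"
    )
    return CompositionTable.from_counts(names, counts, scheme.remainder_name), assignment


def serial_depletion_bruteforce(
    binary: BinaryMarkerMatrix, scheme: GatingScheme
) -> pd.Series:
    """Independent per-cell first-match implementation (oracle for tests)."""
    binary.require(scheme.markers)
    out = []
    for _, row in binary.values.iterrows():
        label = scheme.remainder_name
        for name, marker in scheme.bins:
            if bool(row[marker]):
                label = name
                break
        out.append(label)
    return pd.Series(out, index=binary.values.index, name="bin")


def coexpression(
    binary: BinaryMarkerMatrix, pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """Conditional co-expression table P(target+ | condition+) per pair.

    Pairs whose condition has no positive cells get NaN (undefined), not 0.
    """
    binary.require([m for pair in pairs for m in pair])
    rows = []
    for cond, target in pairs:
        a = binary.values[cond].to_numpy()
        b = binary.values[target].to_numpy()
        n_a = int(a.sum())
        n_ab = int((a & b).sum())
        rows.append(
            {
                "condition": cond,
                "target": target,
                "n_condition": n_a,
                "n_joint": n_ab,
                "conditional": n_ab / n_a if n_a else np.nan,
            }
        )
    return pd.DataFrame(rows)


def marker_positive_rates(
    binary: BinaryMarkerMatrix, genes: Optional[Sequence[str]] = None
) -> pd.Series:
    """Marginal positive fraction per gene; undefined (error) on zero cells."""
    genes = binary.markers if genes is None else list(genes)
    binary.require(genes)
    if binary.n_cells == 0:
        raise ValueError("marker_positive_rates undefined on an empty matrix")
    if not genes:
        return pd.Series(dtype=float, name="positive_rate")
    return binary.values[genes].mean(axis=0).rename("positive_rate")


# ----------------------------------------------------------------------
# Twelve-class subtype assignment
# ----------------------------------------------------------------------
#: The twelve primary classes of the surface composition.
PRIMARY_LABELS = [
    "CD133+ endothelial-like",
    "CD133+ Foxj1+",
    "CD133+ pericyte-like",
    "CD133+ endo-peri-like",
    "CD133+ Foxj1-endo-like",
    "CD133- endothelial-like",
    "CD133- Foxj1+",
    "CD133- pericyte-like",
    "CD133- endo-peri-like",
    "CD133- Foxj1-endo-like",
    "CD133- Vim-only",
    "CD133- negative-for-all",
]

#: Audit classes: combinations the study flags as rare/unassigned rather than
#: folding silently into a primary class.
AUDIT_LABELS = [
    "CD133+ Foxj1-peri-like",
    "CD133- Foxj1-peri-like",
    "CD133+ Vim-only",
    "CD133+ negative-for-others",
]


def assign_subtypes(
    binary: BinaryMarkerMatrix,
    panel: Optional[MarkerPanel] = None,
    relabel: Optional[Mapping[str, str]] = None,
) -> pd.Series:
    """Label every cell with exactly one surface subtype.

    Cells split first on Prom1 (CD133); within a stratum the representative
    markers Flt1 (endothelial, E), Sox2 (Foxj1 group, F) and Pdgfrb
    (pericyte, P) define: E-only, F-only, P-only, endo–peri (E∧P, including
    triple positives — documented tie-break), and Foxj1–endo (E∧F).  F∧P
    cells receive an explicit Foxj1–peri audit label.  Cells negative for
    E/F/P are Vim-only or negative-for-all; in the CD133+ stratum these are
    audit classes (the published partition does not include them).

    ``relabel`` optionally applies a final label→label map (e.g. the
    cluster-level convention of folding endo–peri cells into pericyte-like).
    """
    panel = MarkerPanel() if panel is None else panel
    needed = ["Prom1", REPRESENTATIVE["endothelial_like"], REPRESENTATIVE["foxj1_ependymal"], REPRESENTATIVE["pericyte_like"], "Vim"]
    binary.require(needed)
    v = binary.values
    prom1 = v["Prom1"].to_numpy()
    e = v[REPRESENTATIVE["endothelial_like"]].to_numpy()
    f = v[REPRESENTATIVE["foxj1_ependymal"]].to_numpy()
    p = v[REPRESENTATIVE["pericyte_like"]].to_numpy()
    vim = v["Vim"].to_numpy()

    stratum = np.where(prom1, "CD133+", "CD133-")
    body = np.empty(len(v), dtype=object)
    body[e & p] = "endo-peri-like"                      # includes E∧F∧P
    body[e & f & ~p] = "Foxj1-endo-like"
    body[f & p & ~e] = "Foxj1-peri-like"                # audit class
    body[e & ~f & ~p] = "endothelial-like"
    body[f & ~e & ~p] = "Foxj1+"
    body[p & ~e & ~f] = "pericyte-like"
    none = ~(e | f | p)
    body[none & vim] = "Vim-only"
    body[none & ~vim & prom1] = "negative-for-others"
    body[none & ~vim & ~prom1] = "negative-for-all"

    labels = pd.Series(
        [f"{s} {b}" for s, b in zip(stratum, body)], index=v.index, name="subtype"
    )
    if relabel:
        labels = labels.map(lambda x: relabel.get(x, x))
    return labels


def exclude_by_truth(
    matrix: LabeledExpressionMatrix, excluded_subtypes: Sequence[str] = ("microglia",)
) -> LabeledExpressionMatrix:
    """Drop cells whose ground-truth subtype is in ``excluded_subtypes``.

    Mirrors the study's removal of microglia-like cells before composition
    analysis; on real data pass a boolean mask to
    :meth:`LabeledExpressionMatrix.subset_cells` instead.
    """
    if matrix.truth_subtype is None:
        return matrix
    keep = ~matrix.truth_subtype.isin(excluded_subtypes).to_numpy()
    return matrix.subset_cells(keep)
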