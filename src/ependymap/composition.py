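"""Reconstruction of the complete ependymal-surface composition.

The surface partition is reconstituted from immunostaining-derived rates:
cells are stratified by CD133 (gene *Prom1*; multi-ciliated cells), and
within each stratum the endothelial-like group is measured by a marker trio
(FLT1, CD31, NESTIN), the Foxj1 group by a second trio (SOX2, FOXJ1, S100β)
and the pericyte group by PDGFRβ.  Co-labeling rates for endo∧peri,
Foxj1∧endo and Foxj1∧peri give the overlap sectors; exclusive sectors follow
by inclusion–exclusion, the CD133− stratum additionally carries a VIM-only
sector and an all-negative sector, and the final twelve-sector vector is
renormalized to sum to one.  The published account states the measured
rates and the final split but not the sector arithmetic; the
inclusion–exclusion reconstruction here is this package's own, with every
intermediate value exposed for audit.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .gating import CompositionTable

STRATA = ("CD133+", "CD133-")
ENDO_TRIO = ["FLT1", "CD31", "NESTIN"]
FOXJ1_TRIO = ["SOX2", "FOXJ1", "S100B"]
OVERLAP_CHANNELS = {
    "endo_peri": "FLT1&PDGFRB",
    "foxj1_endo": "FLT1&SOX2",
    "foxj1_peri": "SOX2&PDGFRB",
}

SECTOR_ORDER = [
    "endothelial-like",
    "Foxj1+",
    "pericyte-like",
    "endo-peri-like",
    "Foxj1-endo-like",
]


class Channel(NamedTuple):
    """One staining channel: conditional rate within a stratum."""

    stratum: str
    marker: str
    rate: float
    stratum_weight: float


@dataclass
class StratumRates:
    """Measured conditional rates within one CD133 stratum.

    ``endo_trio`` and ``foxj1_trio`` hold the per-marker rates before trio
    averaging; overlap rates are the co-label fractions.  ``vim`` is only
    meaningful in the CD133− stratum.
    """

    endo_trio: Dict[str, float]
    foxj1_trio: Dict[str, float]
    pericyte: float
    endo_peri: float
    foxj1_endo: float
    foxj1_peri: float = 0.0
    vim: Optional[float] = None

    @property
    def endothelial(self) -> float:
        return trio_average(self.endo_trio.values())

    @property
    def foxj1(self) -> float:
        return trio_average(self.foxj1_trio.values())


@dataclass
class SubgroupRates:
    """Per-stratum measured rates feeding the reconstruction."""

    cd133_pos: Optional[StratumRates] = None
    cd133_neg: Optional[StratumRates] = None

    def stratum(self, name: str) -> Optional[StratumRates]:
        return self.cd133_pos if name == "CD133+" else self.cd133_neg


def trio_average(rates: Iterable[float]) -> float:
    """Arithmetic mean of marker rates within a trio (all in [0, 1])."""
    vals = [float(v) for v in rates]
    if not vals:
        raise ValueError("trio_average needs at least one rate")
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rates must lie in [0, 1], got {v}")
    return float(np.mean(vals))


# ----------------------------------------------------------------------
# Default planted composition
# ----------------------------------------------------------------------
def default_composition() -> CompositionTable:
    """The shipped twelve-sector surface composition (fractions of all cells).

    The CD133+/CD133− split (67.6 / 32.4 %) follows the published total;
    the sub-sector values are synthetic package defaults constructed to be
    consistent with the published co-label marginals and are documented in
    the shipped YAML.
    """
    ref = importlib.resources.files("ependymap.data").joinpath("default_composition.yaml")
    with ref.open("r") as fh:
        doc = yaml.safe_load(fh)
    rows = [
        {"bin": f"{stratum} {sector}", "fraction": frac / 100.0}
        for stratum, sectors in doc["sectors_percent"].items()
        for sector, frac in sectors.items()
    ]
    return CompositionTable(
        table=pd.DataFrame(rows), remainder_name="CD133- negative-for-all"
    )


def stratum_totals(composition: CompositionTable) -> Dict[str, float]:
    out = {s: 0.0 for s in STRATA}
    for _, row in composition.table.iterrows():
        for s in STRATA:
            if str(row["bin"]).startswith(s + " "):
                out[s] += float(row["fraction"])
    return out


def _sector(composition: CompositionTable, stratum: str, sector: str) -> float:
    name = f"{stratum} {sector}"
    hit = composition.table.loc[composition.table["bin"] == name, "fraction"]
    return float(hit.iloc[0]) if len(hit) else 0.0


def channel_rates_from_composition(composition: CompositionTable) -> List[Channel]:
    """Forward map: planted sectors → per-channel conditional staining rates.

    Marker marginals are sums of the sectors containing the marker group
    (exclusive + its overlaps); the CD133− VIM marginal covers the VIM-only
    sector plus every marker-positive cell, matching the observation that
    VIM co-labels broadly.
    """
    totals = stratum_totals(composition)
    cd133 = totals["CD133+"]
    channels = [Channel("all", "CD133", cd133, 1.0)]
    for stratum in STRATA:
        w = totals[stratum]
        if w <= 0:
            continue
        e_x = _sector(composition, stratum, "endothelial-like")
        f_x = _sector(composition, stratum, "Foxj1+")
        p_x = _sector(composition, stratum, "pericyte-like")
        ep = _sector(composition, stratum, "endo-peri-like")
        ef = _sector(composition, stratum, "Foxj1-endo-like")
        fp = _sector(composition, stratum, "Foxj1-peri-like")
        e_marg = (e_x + ep + ef) / w
        f_marg = (f_x + ef + fp) / w
        p_marg = (p_x + ep + fp) / w
        for marker in ENDO_TRIO:
            channels.append(Channel(stratum, marker, e_marg, w))
        for marker in FOXJ1_TRIO:
            channels.append(Channel(stratum, marker, f_marg, w))
        channels.append(Channel(stratum, "PDGFRB", p_marg, w))
        channels.append(Channel(stratum, OVERLAP_CHANNELS["endo_peri"], ep / w, w))
        channels.append(Channel(stratum, OVERLAP_CHANNELS["foxj1_endo"], ef / w, w))
        channels.append(Channel(stratum, OVERLAP_CHANNELS["foxj1_peri"], fp / w, w))
        if stratum == "CD133-":
            coverage = e_marg + f_marg + p_marg - (ep + ef + fp) / w
            vim_marg = coverage + _sector(composition, stratum, "Vim-only") / w
            channels.append(Channel(stratum, "VIM", min(vim_marg, 1.0), w))
    for ch in channels:
        if not 0.0 <= ch.rate <= 1.0 + 1e-12:
            raise ValueError(f"channel {ch.stratum}/{ch.marker}: rate {ch.rate} outside [0, 1]")
    return channels


def subgroup_rates_from_quant(
    quant: pd.DataFrame, estimator: str = "average1"
) -> Tuple[float, SubgroupRates]:
    """Extract (cd133_rate, SubgroupRates) from a :func:`ependymap.zstack.quantify` table."""
    from .zstack import get_estimate

    est = get_estimate(quant, estimator)

    def get(stratum: str, marker: str, required: bool = True) -> Optional[float]:
        try:
            return float(est.loc[(stratum, marker)])
        except KeyError:
            if required:
                raise KeyError(f"missing channel {stratum}/{marker} in quant table") from None
            return None

    cd133 = get("all", "CD133")
    strata: Dict[str, Optional[StratumRates]] = {}
    for stratum in STRATA:
        if not (est.index.get_level_values("stratum") == stratum).any():
            strata[stratum] = None
            continue
        strata[stratum] = StratumRates(
            endo_trio={m: get(stratum, m) for m in ENDO_TRIO},
            foxj1_trio={m: get(stratum, m) for m in FOXJ1_TRIO},
            pericyte=get(stratum, "PDGFRB"),
            endo_peri=get(stratum, OVERLAP_CHANNELS["endo_peri"]),
            foxj1_endo=get(stratum, OVERLAP_CHANNELS["foxj1_endo"]),
            foxj1_peri=get(stratum, OVERLAP_CHANNELS["foxj1_peri"]) or 0.0,
            vim=get(stratum, "VIM", required=False),
        )
    return cd133, SubgroupRates(cd133_pos=strata["CD133+"], cd133_neg=strata["CD133-"])


# ----------------------------------------------------------------------
# Reconstitution
# ----------------------------------------------------------------------
def reconstitute(
    cd133_rate: float, rates: SubgroupRates
) -> Tuple[CompositionTable, Dict]:
    """Rebuild the full twelve-sector composition from measured rates.

    Within each stratum, exclusive sectors are parents minus their overlaps
    (endothelial − endo∧peri − Foxj1∧endo, and so on); overlap sectors are
    kept explicit.  The CD133− stratum adds VIM-only (VIM marginal minus the
    inclusion–exclusion coverage of the three groups) and all-negative
    (stratum total minus everything else).  Negative intermediates are
    clipped to zero and recorded; the final vector is renormalized to sum to
    one, with the pre-normalization total reported in the audit dict.
    """
    if not 0.0 <= cd133_rate <= 1.0:
        raise ValueError(f"cd133_rate {cd133_rate} outside [0, 1]")
    if rates.cd133_pos is None and rates.cd133_neg is None:
        raise ValueError("reconstitute needs rates for at least one CD133 stratum")

    audit: Dict = {"clipped": [], "intermediates": {}}
    rows: List[dict] = []
    for stratum, weight in (("CD133+", cd133_rate), ("CD133-", 1.0 - cd133_rate)):
        sr = rates.stratum(stratum)
        if sr is None:
            continue
        e, f, p = sr.endothelial, sr.foxj1, sr.pericyte
        ep, ef, fp = sr.endo_peri, sr.foxj1_endo, sr.foxj1_peri

        def clip(name: str, value: float) -> float:
            if value < 0:
                audit["clipped"].append({"stratum": stratum, "sector": name, "value": float(value)})
                return 0.0
            return float(value)

        sectors = {
            "endothelial-like": clip("endothelial-like", e - ep - ef),
            "Foxj1+": clip("Foxj1+", f - ef - fp),
            "pericyte-like": clip("pericyte-like", p - ep - fp),
            "endo-peri-like": clip("endo-peri-like", ep),
            "Foxj1-endo-like": clip("Foxj1-endo-like", ef),
        }
        coverage = sum(sectors.values()) + fp
        if fp > 0:
            sectors["Foxj1-peri-like"] = fp
        if stratum == "CD133-":
            vim = sr.vim if sr.vim is not None else coverage
            sectors["Vim-only"] = clip("Vim-only", vim - coverage)
            sectors["negative-for-all"] = clip(
                "negative-for-all", 1.0 - coverage - sectors["Vim-only"]
            )
        audit["intermediates"][stratum] = {
            "group_rates": {"endothelial": e, "foxj1": f, "pericyte": p},
            "overlaps": {"endo_peri": ep, "foxj1_endo": ef, "foxj1_peri": fp},
            "coverage": coverage,
        }
        for sector, cond in sectors.items():
            rows.append({"bin": f"{stratum} {sector}", "fraction": cond * weight})

    frame = pd.DataFrame(rows)
    pre_total = float(frame["fraction"].sum())
    audit["pre_normalization_total"] = pre_total
    if pre_total <= 0:
        raise ValueError("reconstitution produced an all-zero composition")
    frame["fraction"] = frame["fraction"] / pre_total
    remainder = "CD133- negative-for-all" if (frame["bin"] == "CD133- negative-for-all").any() else frame["bin"].iloc[-1]
    table = CompositionTable(table=frame, remainder_name=remainder)
    audit["cd133_pos_total"] = float(
        frame.loc[frame["bin"].str.startswith("CD133+ "), "fraction"].sum()
    )
    return table, audit
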