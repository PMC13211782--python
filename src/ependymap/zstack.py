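"""Estimators for marker-positive rates from layered z-stack counts.

Counts come from confocal optical sections A (0 µm), B (−1 µm), C (−2 µm)
and their merged projection D.  Two counting conventions and two averages
combine them into one marker-positive rate:

* ``added``  = (A + B + C) / 3 — mean of the three per-layer rates;
* ``merged`` = D — rate counted on the projection;
* ``average1`` = (A + B + C + D) / 4 — the study's preferred estimator;
* ``average2_literal`` = (A + B + C)/3 + D/2 — the expression as printed,
  which exceeds 1 whenever rates are appreciable (on the identity input
  A=B=C=D=r it returns 1.5 r) and is therefore only reported, flagged;
* ``average2_corrected`` = ((A + B + C)/3 + D) / 2 — the same quantity read
  as a mean of the added and merged estimates, which passes the identity
  check and is the default "Average 2" downstream.

Rates are pooled over fields (sum of positives over sum of nuclei);
per-field rates are available for dispersion reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

LAYERS = ["A", "B", "C", "D"]

ESTIMATORS = ("average1", "average2", "average2_literal", "added", "merged")


@dataclass
class ZStackCounts:
    """Per-field, per-layer positive/nuclei counts for each staining channel.

    Wraps a tidy table with columns ``field_id, stratum, marker, layer,
    positive, nuclei`` (``stratum`` distinguishes the CD133+/CD133− co-stain
    pools; plain single-stain tables may use a constant stratum).
    """

    table: pd.DataFrame

    REQUIRED = ["field_id", "marker", "layer", "positive", "nuclei"]

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"z-stack table missing columns: {missing}")
        if "stratum" not in t.columns:
            t["stratum"] = "all"
        bad_layer = set(t["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValueError(f"unknown layers {sorted(bad_layer)}; expected {LAYERS}")
        if (t["positive"] < 0).any() or (t["positive"] > t["nuclei"]).any():
            raise ValueError("positive counts must satisfy 0 <= positive <= nuclei")
        self.table = t

    def channels(self) -> pd.DataFrame:
        return self.table[["stratum", "marker"]].drop_duplicates().reset_index(drop=True)


def layer_rates(counts: ZStackCounts) -> pd.DataFrame:
    """Pooled positive rate per (stratum, marker, layer): Σpositive / Σnuclei.

    Layers with zero nuclei in every field are undefined and reported as NaN.
    """
    g = counts.table.groupby(["stratum", "marker", "layer"], sort=False)[["positive", "nuclei"]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        g["rate"] = np.where(g["nuclei"] > 0, g["positive"] / g["nuclei"].clip(lower=1), np.nan)
    return g.reset_index()


def per_field_rates(counts: ZStackCounts) -> pd.DataFrame:
    """Per-field rates, for mean ± SD style reporting."""
    t = counts.table.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t["rate"] = np.where(t["nuclei"] > 0, t["positive"] / t["nuclei"].clip(lower=1), np.nan)
    return t


def quantify(counts: ZStackCounts) -> pd.DataFrame:
    """All estimators per (stratum, marker) from pooled layer rates.

    Channels missing one of the four layers are marked ``partial`` and get
    NaN for any estimator needing the missing layer.  ``literal_exceeds_one``
    flags channels where the as-printed Average 2 leaves [0, 1].
    """
    rates = layer_rates(counts)
    rows = []
    for (stratum, marker), grp in rates.groupby(["stratum", "marker"], sort=False):
        r = dict(zip(grp["layer"], grp["rate"]))
        a, b, c, d = (r.get(l, np.nan) for l in LAYERS)
        partial = any(np.isnan(x) for x in (a, b, c, d))
        added = (a + b + c) / 3.0
        average1 = (a + b + c + d) / 4.0
        literal = added + d / 2.0
        corrected = (added + d) / 2.0
        rows.append(
            {
                "stratum": stratum,
                "marker": marker,
                "rate_A": a,
                "rate_B": b,
                "rate_C": c,
                "rate_D": d,
                "added": added,
                "merged": d,
                "average1": average1,
                "average2_literal": literal,
                "average2_corrected": corrected,
                "literal_exceeds_one": bool(literal > 1.0) if not np.isnan(literal) else False,
                "partial": partial,
            }
        )
    return pd.DataFrame(rows)


def get_estimate(quant: pd.DataFrame, estimator: str = "average1") -> pd.Series:
    """Pick one estimator column, indexed by (stratum, marker)."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}, got {estimator!r}")
    col = {"average2": "average2_corrected"}.get(estimator, estimator)
    return quant.set_index(["stratum", "marker"])[col]
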