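"""Composition reconstruction: trio averages, inclusion–exclusion, round trip."""

import numpy as np
import pytest

import ependymap as em
from ependymap.composition import (
    Channel,
    channel_rates_from_composition,
    stratum_totals,
)


def hand_rates():
    pos = em.StratumRates(
        endo_trio={"FLT1": 0.50, "CD31": 0.52, "NESTIN": 0.48},
        foxj1_trio={"SOX2": 0.30, "FOXJ1": 0.30, "S100B": 0.30},
        pericyte=0.20,
        endo_peri=0.10,
        foxj1_endo=0.05,
    )
    neg = em.StratumRates(
        endo_trio={"FLT1": 0.20, "CD31": 0.20, "NESTIN": 0.20},
        foxj1_trio={"SOX2": 0.10, "FOXJ1": 0.10, "S100B": 0.10},
        pericyte=0.10,
        endo_peri=0.02,
        foxj1_endo=0.02,
        vim=0.50,
    )
    return em.SubgroupRates(cd133_pos=pos, cd133_neg=neg)


def test_trio_average_examples():
    assert em.trio_average([0.5, 0.52, 0.48]) == pytest.approx(0.50)
    assert em.trio_average([0.0, 0.0, 0.0]) == 0.0
    assert em.trio_average([0.7, 0.7, 0.7]) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        em.trio_average([1.2, 0.0, 0.0])


def test_single_sector_degenerate_case():
    rates = em.SubgroupRates(
        cd133_pos=em.StratumRates(
            endo_trio={"FLT1": 1.0, "CD31": 1.0, "NESTIN": 1.0},
            foxj1_trio={"SOX2": 0.0, "FOXJ1": 0.0, "S100B": 0.0},
            pericyte=0.0,
            endo_peri=0.0,
            foxj1_endo=0.0,
        )
    )
    table, audit = em.reconstitute(1.0, rates)
    assert table.fraction("CD133+ endothelial-like") == pytest.approx(1.0)


def test_hand_inclusion_exclusion_fixture():
    # Independently computed by hand:
    # CD133+ (weight 0.6): exclusives 0.35/0.25/0.10, overlaps 0.10/0.05
    # CD133- (weight 0.4): exclusives 0.16/0.08/0.08, overlaps 0.02/0.02,
    #   coverage 0.36, Vim-only 0.14, negative 0.50; pre-norm total 0.91.
    expected = {
        "CD133+ endothelial-like": 0.6 * 0.35,
        "CD133+ Foxj1+": 0.6 * 0.25,
        "CD133+ pericyte-like": 0.6 * 0.10,
        "CD133+ endo-peri-like": 0.6 * 0.10,
        "CD133+ Foxj1-endo-like": 0.6 * 0.05,
        "CD133- endothelial-like": 0.4 * 0.16,
        "CD133- Foxj1+": 0.4 * 0.08,
        "CD133- pericyte-like": 0.4 * 0.08,
        "CD133- endo-peri-like": 0.4 * 0.02,
        "CD133- Foxj1-endo-like": 0.4 * 0.02,
        "CD133- Vim-only": 0.4 * 0.14,
        "CD133- negative-for-all": 0.4 * 0.50,
    }
    table, audit = em.reconstitute(0.6, hand_rates())
    assert audit["pre_normalization_total"] == pytest.approx(0.91)
    for name, raw in expected.items():
        assert table.fraction(name) == pytest.approx(raw / 0.91, abs=1e-12), name
    assert table.table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    assert len(table.table) == 12


def test_negative_intermediates_clipped_and_recorded():
    rates = hand_rates()
    rates.cd133_pos.endo_peri = 0.6  # overlap larger than its parents
    table, audit = em.reconstitute(0.6, rates)
    clipped = {(c["stratum"], c["sector"]) for c in audit["clipped"]}
    assert ("CD133+", "endothelial-like") in clipped
    assert (table.table["fraction"] >= 0).all()
    assert table.table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)


def test_monotonicity_in_exclusive_rate():
    base, _ = em.reconstitute(0.6, hand_rates())
    bumped_rates = hand_rates()
    for k in bumped_rates.cd133_pos.endo_trio:
        bumped_rates.cd133_pos.endo_trio[k] += 0.05
    bumped, _ = em.reconstitute(0.6, bumped_rates)
    assert bumped.fraction("CD133+ endothelial-like") > base.fraction("CD133+ endothelial-like")


def test_requires_some_stratum_and_valid_rate():
    with pytest.raises(ValueError):
        em.reconstitute(0.5, em.SubgroupRates())
    with pytest.raises(ValueError):
        em.reconstitute(1.5, hand_rates())


def test_default_composition_is_consistent():
    comp = em.default_composition()
    totals = stratum_totals(comp)
    assert totals["CD133+"] == pytest.approx(0.676, abs=1e-12)
    assert totals["CD133-"] == pytest.approx(0.324, abs=1e-12)
    assert comp.table["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
    for ch in channel_rates_from_composition(comp):
        assert 0.0 <= ch.rate <= 1.0


def test_channel_rates_invert_exactly_through_reconstitute():
    """Noise-free round trip: planted sectors -> channel rates -> sectors."""
    comp = em.default_composition()
    channels = {(c.stratum, c.marker): c.rate for c in channel_rates_from_composition(comp)}

    def sr(stratum):
        return em.StratumRates(
            endo_trio={m: channels[(stratum, m)] for m in ("FLT1", "CD31", "NESTIN")},
            foxj1_trio={m: channels[(stratum, m)] for m in ("SOX2", "FOXJ1", "S100B")},
            pericyte=channels[(stratum, "PDGFRB")],
            endo_peri=channels[(stratum, "FLT1&PDGFRB")],
            foxj1_endo=channels[(stratum, "FLT1&SOX2")],
            foxj1_peri=channels[(stratum, "SOX2&PDGFRB")],
            vim=channels.get((stratum, "VIM")),
        )

    table, audit = em.reconstitute(
        channels[("all", "CD133")], em.SubgroupRates(cd133_pos=sr("CD133+"), cd133_neg=sr("CD133-"))
    )
    merged = table.table.merge(comp.table, on="bin", suffixes=("_rec", "_planted"))
    assert len(merged) == 12
    np.testing.assert_allclose(
        merged["fraction_rec"], merged["fraction_planted"], atol=1e-12
    )
    assert audit["pre_normalization_total"] == pytest.approx(1.0, abs=1e-12)


def test_sampled_round_trip_recovers_sectors():
    comp = em.default_composition()
    zc = em.generate_zstack(comp, n_fields=30, cells_per_field=200, seed=17)
    quant = em.quantify(zc)
    cd133, rates = em.subgroup_rates_from_quant(quant, "average1")
    table, _ = em.reconstitute(cd133, rates)
    merged = table.table.merge(comp.table, on="bin", suffixes=("_rec", "_planted"))
    n = 30 * 200
    for _, row in merged.iterrows():
        p = row["fraction_planted"]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(row["fraction_rec"] - p) < 3 * se + 5e-3, row["bin"]
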