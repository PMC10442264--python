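import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest

from alliancenet.association import AssociationMatrix
from alliancenet.strength import (
    SnapshotSpec,
    bstrength_by_partner,
    strength_table,
    subgroup_strength,
    temporal_snapshots,
    unit_mean_hwi,
)
from alliancenet.survey_io import AllianceRegistry

from conftest import make_survey


def matrix(ids, entries):
    k = len(ids)
    vals = np.zeros((k, k))
    idx = {i: n for n, i in enumerate(ids)}
    for (a, b), v in entries.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return AssociationMatrix(ids=tuple(ids), values=vals)


@pytest.fixture
def star_matrix():
    return matrix(
        "ABCD", {("A", "B"): 0.5, ("A", "C"): 0.5, ("A", "D"): 0.5}
    )


class TestSubgroupStrength:
    def test_empty_subset_is_zero(self, star_matrix):
        assert subgroup_strength(star_matrix, "A", frozenset()) == 0.0

    def test_star_node(self, star_matrix):
        assert subgroup_strength(star_matrix, "A", set("ABCD")) == pytest.approx(1.5)

    def test_self_excluded(self, star_matrix):
        assert subgroup_strength(star_matrix, "A", {"A", "B"}) == pytest.approx(0.5)

    def test_additivity_over_complement_partition(self):
        rng = np.random.default_rng(0)
        from conftest import random_matrix

        m = random_matrix(rng, [f"I{k}" for k in range(9)])
        ind = m.ids[0]
        rest = list(m.ids[1:])
        part1, part2, part3 = rest[:3], rest[3:5], rest[5:]
        total = subgroup_strength(m, ind, m.ids)
        assert total == pytest.approx(
            sum(subgroup_strength(m, ind, p) for p in (part1, part2, part3))
        )

    def test_missing_individual_raises(self, star_matrix):
        with pytest.raises(KeyError):
            subgroup_strength(star_matrix, "Z", {"A"})


@pytest.fixture
def five_male_registry():
    """KS trio + PD pair, allied in period P."""
    return AllianceRegistry(
        second_order={"K1": "KS", "K2": "KS", "K3": "KS", "P1": "PD", "P2": "PD"},
        first_order_units={
            "P": (frozenset({"K1", "K2", "K3"}), frozenset({"P1", "P2"}))
        },
        third_order_pairs={"P": frozenset({frozenset({"KS", "PD"})})},
    )


@pytest.fixture
def five_male_matrix():
    return matrix(
        ["K1", "K2", "K3", "P1", "P2"],
        {
            ("K1", "K2"): 0.9,
            ("K1", "K3"): 0.8,
            ("K2", "K3"): 0.7,
            ("P1", "P2"): 0.95,
            ("K1", "P1"): 0.3,
            ("K1", "P2"): 0.1,
            ("K2", "P1"): 0.2,
            # all other cross dyads 0
        },
    )


class TestStrengthTable:
    def test_hand_computed_five_male_society(
        self, five_male_matrix, five_male_registry
    ):
        tbl = strength_table(five_male_matrix, five_male_registry, "P").set_index("id")
        # within sums
        assert tbl.loc["K1", "wStrength"] == pytest.approx(1.7)
        assert tbl.loc["K2", "wStrength"] == pytest.approx(1.6)
        assert tbl.loc["K3", "wStrength"] == pytest.approx(1.5)
        assert tbl.loc["P1", "wStrength"] == pytest.approx(0.95)
        # between sums
        assert tbl.loc["K1", "bStrength"] == pytest.approx(0.4)
        assert tbl.loc["K2", "bStrength"] == pytest.approx(0.2)
        assert tbl.loc["K3", "bStrength"] == pytest.approx(0.0)
        assert tbl.loc["P1", "bStrength"] == pytest.approx(0.5)
        assert tbl.loc["P2", "bStrength"] == pytest.approx(0.1)
        # normalization by own-alliance maximum
        assert tbl.loc["K1", "wStrength_N"] == pytest.approx(1.0)
        assert tbl.loc["K3", "wStrength_N"] == pytest.approx(1.5 / 1.7)
        assert tbl.loc["K1", "bStrength_N"] == pytest.approx(1.0)
        assert tbl.loc["K2", "bStrength_N"] == pytest.approx(0.5)
        assert tbl.loc["P2", "bStrength_N"] == pytest.approx(0.2)

    def test_equal_dyads_all_normalized_to_one(self, five_male_registry):
        ids = ["K1", "K2", "K3", "P1", "P2"]
        m = matrix(
            ids, {p: 0.5 for p in itertools.combinations(ids, 2)}
        )
        tbl = strength_table(m, five_male_registry, "P")
        # within each alliance the raw strengths tie, so every male is at max
        assert (tbl["wStrength_N"] == 1.0).all()
        assert (tbl["bStrength_N"] == 1.0).all()

    def test_normalized_in_unit_interval_with_max_exactly_one(
        self, five_male_matrix, five_male_registry
    ):
        tbl = strength_table(five_male_matrix, five_male_registry, "P")
        for col in ("wStrength_N", "bStrength_N"):
            assert tbl[col].dropna().between(0, 1).all()
        for alliance, grp in tbl.groupby("alliance"):
            assert grp["wStrength_N"].max() == pytest.approx(1.0)

    def test_alliance_relabelling_invariance(
        self, five_male_matrix, five_male_registry
    ):
        relabeled = AllianceRegistry(
            second_order={
                i: {"KS": "G1", "PD": "G2"}[a]
                for i, a in five_male_registry.second_order.items()
            },
            first_order_units=five_male_registry.first_order_units,
            third_order_pairs={"P": frozenset({frozenset({"G1", "G2"})})},
        )
        t1 = strength_table(five_male_matrix, five_male_registry, "P").set_index("id")
        t2 = strength_table(five_male_matrix, relabeled, "P").set_index("id")
        for col in ("wStrength", "bStrength", "wStrength_N", "bStrength_N"):
            pd.testing.assert_series_equal(t1[col], t2[col])

    def test_network_scope_normalization(self, five_male_matrix, five_male_registry):
        tbl = strength_table(
            five_male_matrix, five_male_registry, "P", normalization_scope="network"
        )
        assert (tbl["wStrength_N"] == 1.0).sum() == 1

    def test_no_ally_gives_nan_normalized(self, caplog):
        reg = AllianceRegistry(
            second_order={"A1": "X", "A2": "X"},
            first_order_units={"P": (frozenset({"A1", "A2"}),)},
            third_order_pairs={"P": frozenset()},
        )
        m = matrix(["A1", "A2"], {("A1", "A2"): 0.4})
        with caplog.at_level("WARNING"):
            tbl = strength_table(m, reg, "P").set_index("id")
        assert tbl["bStrength"].eq(0).all()
        assert tbl["bStrength_N"].isna().all()

    def test_partner_breakdown_sums_to_pooled(self):
        reg = AllianceRegistry(
            second_order={
                "K1": "KS", "K2": "KS", "P1": "PD", "P2": "PD", "R1": "RR", "R2": "RR",
            },
            first_order_units={
                "P": (
                    frozenset({"K1", "K2"}),
                    frozenset({"P1", "P2"}),
                    frozenset({"R1", "R2"}),
                )
            },
            third_order_pairs={
                "P": frozenset(
                    {frozenset({"KS", "PD"}), frozenset({"KS", "RR"})}
                )
            },
        )
        ids = ["K1", "K2", "P1", "P2", "R1", "R2"]
        rng = np.random.default_rng(1)
        from conftest import random_matrix

        m = random_matrix(rng, ids)
        pooled = strength_table(m, reg, "P").set_index("id")["bStrength"]
        per_partner = bstrength_by_partner(m, reg, "P")
        summed = per_partner.groupby("id")["bStrength"].sum()
        for ind in ("K1", "K2"):
            assert summed[ind] == pytest.approx(pooled[ind])
        assert set(per_partner[per_partner["id"] == "K1"]["partner"]) == {"PD", "RR"}


class TestUnitMeanHWI:
    def test_constant_cross_dyads(self):
        m = matrix(
            "ABCDE",
            {(a, b): 0.5 for a in "AB" for b in "CDE"},
        )
        assert unit_mean_hwi(m, {"A", "B"}, {"C", "D", "E"}) == pytest.approx(0.5)

    def test_pair_by_trio_hand_mean(self):
        entries = {
            ("A", "C"): 0.1,
            ("A", "D"): 0.2,
            ("A", "E"): 0.3,
            ("B", "C"): 0.4,
            ("B", "D"): 0.5,
            ("B", "E"): 0.6,
        }
        m = matrix("ABCDE", entries)
        assert unit_mean_hwi(m, {"A", "B"}, {"C", "D", "E"}) == pytest.approx(0.35)

    def test_overlapping_units_rejected(self):
        m = matrix("ABC", {("A", "B"): 0.5})
        with pytest.raises(ValueError, match="overlap"):
            unit_mean_hwi(m, {"A", "B"}, {"B", "C"})


class TestTemporalSnapshots:
    @pytest.fixture
    def spec(self):
        roster = frozenset({"A", "B", "C", "D"})
        return SnapshotSpec(
            periods=(("T1", 2009, 2010), ("T2", 2011, 2012)),
            rosters={"T1": roster, "T2": roster - {"D"}},
        )

    @pytest.fixture
    def registry(self):
        return AllianceRegistry(
            second_order={"A": "X", "B": "X", "C": "Y", "D": "Y"},
            first_order_units={
                "T1": (frozenset({"A", "B"}), frozenset({"C", "D"})),
                "T2": (frozenset({"A", "B"}), frozenset({"C", "D"})),
            },
            third_order_pairs={
                "T1": frozenset({frozenset({"X", "Y"})}),
                "T2": frozenset({frozenset({"X", "Y"})}),
            },
        )

    def surveys(self, years):
        out = []
        k = 0
        for year in years:
            for members in ({"A", "B"}, {"C", "D"}, {"A", "B", "C", "D"}):
                out.append(make_survey(f"S{k}", members, date(year, 9, 1 + k % 20)))
                k += 1
        return out

    def test_single_period_when_surveys_span_one_window(self, spec, registry):
        snaps = temporal_snapshots(self.surveys([2009, 2010]), spec, registry)
        assert set(snaps) == {"T1"}
        assert snaps["T1"].n_surveys == 6

    def test_roster_removal_propagates(self, spec, registry):
        snaps = temporal_snapshots(self.surveys([2009, 2011]), spec, registry)
        assert "D" in snaps["T1"].matrix.ids
        assert "D" not in snaps["T2"].matrix.ids
        assert "D" not in set(snaps["T2"].strengths["id"])

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SnapshotSpec(
                periods=(("T1", 2009, 2011), ("T2", 2011, 2012)),
                rosters={"T1": frozenset("AB"), "T2": frozenset("AB")},
            )

    def test_sparse_period_skipped_with_warning(self, spec, registry, caplog):
        surveys = self.surveys([2009]) + [
            make_survey("SX", {"A"}, date(2011, 9, 1))
        ]
        with caplog.at_level("WARNING"):
            snaps = temporal_snapshots(surveys, spec, registry)
        assert set(snaps) == {"T1"}
        assert "skipped" in caplog.text
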