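"""Packaged example datasets.

``table1_fusion_dataset`` reconstructs, record by record, a behavior log for
ten inter-alliance fusion events whose unique-pair tallies match the
published per-event counts for the study population (three alliances KS, PD,
RR; seven KS-RR fusions, two PD-KS, one PD-RR).  Individual identities of
the acting pairs are synthetic — the published table reports pair *counts*,
not pair identities — so pairs are drawn deterministically from the period
roster; the per-event and cross-event count structure is what the fixture
preserves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import date as Date, timedelta

import pandas as pd

from .fusion_coding import BehaviorRecord, FusionEvent
from .survey_io import AllianceRegistry

ROSTER = {
    "KS": ("PON", "QUA", "PAS", "BOL", "KRO", "DEE", "GRI", "HAL", "JAB", "LUK"),
    "PD": ("WAB", "NAT", "DNG", "TIM", "ROQ"),
    "RR": ("SMO", "URC", "COO", "REA", "LAN"),
}

FUSION_PERIOD = "T3"

# Per-event unique-pair counts: (alliance pair, third PR, third PR+D0,
# second PR, second PR+D0, third synch, second synch by alliance)
TABLE1_EXPECTED = [
    ("F01", "KS-RR", 5, 6, 5, 5, 1, {"KS": 1, "RR": 1}),
    ("F02", "KS-RR", 0, 0, 0, 1, 0, {}),
    ("F03", "KS-RR", 0, 1, 0, 1, 0, {"RR": 1}),
    ("F04", "KS-RR", 5, 7, 5, 5, 0, {}),
    ("F05", "KS-RR", 0, 0, 0, 2, 0, {"KS": 2}),
    ("F06", "KS-RR", 1, 2, 0, 2, 1, {}),
    ("F07", "KS-RR", 1, 1, 2, 3, 0, {}),
    ("F08", "KS-PD", 2, 4, 1, 2, 0, {"KS": 1}),
    ("F09", "KS-PD", 4, 6, 2, 3, 1, {"KS": 2, "PD": 1}),
    ("F10", "PD-RR", 2, 4, 0, 2, 2, {"RR": 1}),
]

# Third-order PR column total and third-order synch column total
THIRD_ORDER_PR_TOTAL = 20
THIRD_ORDER_SYNCH_TOTAL = 5
# Cross-event unique intra-alliance petting/rubbing pairs
SECOND_ORDER_PR_UNIQUE = {"KS": 7, "RR": 4, "PD": 2}


FIRST_ORDER_UNITS = (
    frozenset({"PON", "QUA", "PAS"}),
    frozenset({"BOL", "KRO", "DEE"}),
    frozenset({"GRI", "HAL"}),
    frozenset({"JAB", "LUK"}),
    frozenset({"WAB", "NAT"}),
    frozenset({"DNG", "TIM", "ROQ"}),
    frozenset({"SMO", "URC", "COO"}),
    frozenset({"REA", "LAN"}),
)


def fusion_registry() -> AllianceRegistry:
    """Registry for the fusion-event period: all three alliance pairs allied."""
    second_order = {
        ind: aid for aid, members in ROSTER.items() for ind in members
    }
    units = FIRST_ORDER_UNITS
    return AllianceRegistry(
        second_order=second_order,
        first_order_units={FUSION_PERIOD: units},
        third_order_pairs={
            FUSION_PERIOD: frozenset(
                {
                    frozenset({"KS", "PD"}),
                    frozenset({"KS", "RR"}),
                    frozenset({"PD", "RR"}),
                }
            )
        },
    )


class _PairPools:
    """Deterministic streams of fresh pairs, cross- and within-alliance."""

    def __init__(self) -> None:
        self._cross = {
            frozenset({a, b}): iter(
                [frozenset(p) for p in itertools.product(ROSTER[a], ROSTER[b])]
            )
            for a, b in itertools.combinations(ROSTER, 2)
        }
        self._within = {
            aid: iter(
                [frozenset(p) for p in itertools.combinations(members, 2)]
            )
            for aid, members in ROSTER.items()
        }

    def cross(self, a: str, b: str, k: int) -> list[frozenset[str]]:
        pool = self._cross[frozenset({a, b})]
        return [next(pool) for _ in range(k)]

    def within(self, aid: str, k: int) -> list[frozenset[str]]:
        pool = self._within[aid]
        return [next(pool) for _ in range(k)]


@dataclass
class FusionDataset:
    registry: AllianceRegistry
    period: str
    events: list[FusionEvent]
    records: list[BehaviorRecord]
    expected: pd.DataFrame


def _records(event_id: str, behavior: str, pairs) -> list[BehaviorRecord]:
    return [
        BehaviorRecord(event_id=event_id, behavior=behavior, actors=p)
        for p in pairs
    ]


def table1_fusion_dataset() -> FusionDataset:
    """Build the ten-event fusion behavior log.

    Third-order (cross-alliance) pairs are all distinct across events.
    Within-alliance petting/rubbing pairs include two deliberate repeats —
    one RR pair recurring in event 4 and one KS pair in event 9 — so the
    cross-event unique counts come to 7 KS + 4 RR + 2 PD = 13 while the
    per-event column sums to 15.
    """
    pools = _PairPools()
    records: list[BehaviorRecord] = []
    events: list[FusionEvent] = []

    # event 1 (KS-RR): 5 third PR (+1 D0), 5 second PR (2 KS + 3 RR),
    # 1 third synch, second synchs KS(1) RR(1)
    e1_ks_pr = pools.within("KS", 2)
    e1_rr_pr = pools.within("RR", 3)
    ev_specs = []
    ev_specs.append(
        (
            "F01",
            ("KS", "RR"),
            dict(
                third_pr=pools.cross("KS", "RR", 5),
                third_d0=pools.cross("KS", "RR", 1),
                second_pr=e1_ks_pr + e1_rr_pr,
                second_d0=[],
                third_synch=pools.cross("KS", "RR", 1),
                second_synch=pools.within("KS", 1) + pools.within("RR", 1),
            ),
        )
    )
    ev_specs.append(
        ("F02", ("KS", "RR"),
         dict(third_pr=[], third_d0=[], second_pr=[],
              second_d0=pools.within("KS", 1), third_synch=[], second_synch=[]))
    )
    ev_specs.append(
        ("F03", ("KS", "RR"),
         dict(third_pr=[], third_d0=pools.cross("KS", "RR", 1), second_pr=[],
              second_d0=pools.within("RR", 1), third_synch=[],
              second_synch=pools.within("RR", 1)))
    )
    # event 4: one of the RR PR pairs repeats event 1's first RR pair
    ev_specs.append(
        ("F04", ("KS", "RR"),
         dict(third_pr=pools.cross("KS", "RR", 5),
              third_d0=pools.cross("KS", "RR", 2),
              second_pr=pools.within("KS", 3) + [e1_rr_pr[0]] + pools.within("RR", 1),
              second_d0=[], third_synch=[], second_synch=[]))
    )
    ev_specs.append(
        ("F05", ("KS", "RR"),
         dict(third_pr=[], third_d0=[], second_pr=[],
              second_d0=pools.within("KS", 2), third_synch=[],
              second_synch=pools.within("KS", 2)))
    )
    # D0-only pairs in events 6 and 10 reuse event-1 RR pairs: uniqueness is
    # per event, and the small RR alliance has only ten possible pairs
    ev_specs.append(
        ("F06", ("KS", "RR"),
         dict(third_pr=pools.cross("KS", "RR", 1),
              third_d0=pools.cross("KS", "RR", 1), second_pr=[],
              second_d0=[e1_rr_pr[1], e1_rr_pr[2]],
              third_synch=pools.cross("KS", "RR", 1), second_synch=[]))
    )
    ev_specs.append(
        ("F07", ("KS", "RR"),
         dict(third_pr=pools.cross("KS", "RR", 1), third_d0=[],
              second_pr=pools.within("KS", 2),
              second_d0=pools.within("KS", 1), third_synch=[], second_synch=[]))
    )
    ev_specs.append(
        ("F08", ("KS", "PD"),
         dict(third_pr=pools.cross("KS", "PD", 2),
              third_d0=pools.cross("KS", "PD", 2),
              second_pr=pools.within("PD", 1),
              second_d0=pools.within("PD", 1), third_synch=[],
              second_synch=pools.within("KS", 1)))
    )
    # event 9: one KS PR pair repeats event 1's first KS pair
    ev_specs.append(
        ("F09", ("KS", "PD"),
         dict(third_pr=pools.cross("KS", "PD", 4),
              third_d0=pools.cross("KS", "PD", 2),
              second_pr=pools.within("PD", 1) + [e1_ks_pr[0]],
              second_d0=pools.within("PD", 1),
              third_synch=pools.cross("KS", "PD", 1),
              second_synch=pools.within("KS", 2) + pools.within("PD", 1)))
    )
    ev_specs.append(
        ("F10", ("PD", "RR"),
         dict(third_pr=pools.cross("PD", "RR", 2),
              third_d0=pools.cross("PD", "RR", 2),
              second_pr=[],
              second_d0=pools.within("PD", 1) + [e1_rr_pr[0]],
              third_synch=pools.cross("PD", "RR", 2),
              second_synch=pools.within("RR", 1)))
    )

    for k, (event_id, alliances, spec) in enumerate(ev_specs):
        ev_records: list[BehaviorRecord] = []
        # alternate PET/RUB across the contact pairs for realism
        for j, pair in enumerate(spec["third_pr"] + spec["second_pr"]):
            ev_records.append(
                BehaviorRecord(
                    event_id=event_id,
                    behavior="PET" if j % 2 == 0 else "RUB",
                    actors=pair,
                )
            )
        ev_records += _records(event_id, "D0", spec["third_d0"] + spec["second_d0"])
        ev_records += _records(
            event_id, "SYNCH", spec["third_synch"] + spec["second_synch"]
        )
        participants = frozenset(
            a for r in ev_records for a in r.actors
        ) or frozenset(ROSTER[alliances[0]][:2] + ROSTER[alliances[1]][:2])
        events.append(
            FusionEvent(
                event_id=event_id,
                date=Date(2013, 11, 15) + timedelta(days=k),
                alliances=frozenset(alliances),
                participants=participants,
            )
        )
        records.extend(ev_records)

    expected = pd.DataFrame(
        TABLE1_EXPECTED,
        columns=[
            "event_id",
            "alliances",
            "third_pr",
            "third_pr_d0",
            "second_pr",
            "second_pr_d0",
            "third_synch",
            "second_synch_by_alliance",
        ],
    )
    return FusionDataset(
        registry=fusion_registry(),
        period=FUSION_PERIOD,
        events=events,
        records=records,
        expected=expected,
    )
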