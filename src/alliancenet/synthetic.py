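"""Synthetic multi-level society generator.

Emulates the sampling process behind group-composition surveys of a society
with three organizational levels: first-order units (pairs/trios) nested in
second-order alliances, some of which hold third-order alliances with each
other.  Groups are *unit-seeded*: a survey starts from one first-order unit
(the behavioral atom of consortship groups), each of whose members shows up
with probability ``p_unit_cohesion``; each other unit of the same alliance
attaches independently with probability ``p2``; and for each third-order alliance the
seed's alliance holds, a unit from the partner alliance attaches with the
pair's join probability ``p3``, chosen with extra weight (``bridge_bias``)
on a designated bridge unit.  The result is high within-unit co-sighting,
moderate within-alliance co-sighting, and weak between-alliance co-sighting
concentrated on bridge trios — the association texture the analysis chain
is meant to resolve.

Every generated quantity has a closed-form expectation (``expected_hwi``),
so recovery of the planted structure can be checked against exact targets
rather than against another simulation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .fusion_coding import BehaviorRecord, FusionEvent, PairTally, tally_event
from .survey_io import Activity, AllianceRegistry, Survey

logger = logging.getLogger(__name__)

DEFAULT_ACTIVITY_DIST = {
    Activity.TRAVEL: 0.45,
    Activity.REST: 0.25,
    Activity.SOCIAL: 0.30,
}

DYAD_CLASSES = (
    "within_unit",
    "within_alliance",
    "third_order_bridge",
    "third_order_nonbridge",
    "non_allied",
)


@dataclass(frozen=True)
class SocietyConfig:
    """Planted society and survey-sampling parameters.

    ``alliances`` maps alliance id -> tuple of first-order units (frozensets
    of 2-3 ids); ``third_order`` maps an alliance-id pair to its per-survey
    join probability p3; ``bridge_units`` designates, per alliance, the unit
    that carries most third-order contact.
    """

    alliances: Mapping[str, tuple[frozenset[str], ...]]
    third_order: Mapping[frozenset[str], float]
    bridge_units: Mapping[str, frozenset[str]] = field(default_factory=dict)
    p_unit_cohesion: float = 0.95
    p2: float = 0.35
    bridge_bias: float = 3.0
    activity_dist: Mapping[Activity, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_DIST)
    )
    start: Date = Date(2009, 8, 1)
    end: Date = Date(2010, 12, 31)
    n_surveys: int = 2000
    mortality: tuple[tuple[str, Date], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_unit_cohesion, self.p2, *self.third_order.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        all_ids: set[str] = set()
        for aid, units in self.alliances.items():
            for unit in units:
                if not 2 <= len(unit) <= 3:
                    raise ValueError(f"unit {sorted(unit)} must have 2-3 members")
                if all_ids & unit:
                    raise ValueError(f"units overlap on {sorted(all_ids & unit)}")
                all_ids |= unit
        for aid, unit in self.bridge_units.items():
            if unit not in tuple(self.alliances.get(aid, ())):
                raise ValueError(
                    f"bridge unit {sorted(unit)} not a unit of alliance {aid!r}"
                )
        for pair in self.third_order:
            if not pair <= set(self.alliances):
                raise ValueError(f"third-order pair {sorted(pair)} unknown")

    # -- structure helpers ---------------------------------------------------

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(
            sorted(i for units in self.alliances.values() for u in units for i in u)
        )

    def alliance_of(self, individual: str) -> str:
        for aid, units in self.alliances.items():
            for u in units:
                if individual in u:
                    return aid
        raise KeyError(individual)

    def unit_of(self, individual: str) -> frozenset[str]:
        for units in self.alliances.values():
            for u in units:
                if individual in u:
                    return u
        raise KeyError(individual)

    def partners_of(self, alliance_id: str) -> list[tuple[str, float]]:
        out = []
        for pair, p3 in self.third_order.items():
            if alliance_id in pair:
                (other,) = pair - {alliance_id}
                out.append((other, p3))
        return sorted(out)

    def unit_weight(self, alliance_id: str, unit: frozenset[str]) -> float:
        return (
            self.bridge_bias
            if self.bridge_units.get(alliance_id) == unit
            else 1.0
        )

    def to_registry(self, periods: Sequence[str] = ("ALL",)) -> AllianceRegistry:
        """Ground-truth registry matching the planted structure."""
        second_order = {
            i: aid
            for aid, units in self.alliances.items()
            for u in units
            for i in u
        }
        units = tuple(u for us in self.alliances.values() for u in us)
        pairs = frozenset(frozenset(p) for p in self.third_order)
        return AllianceRegistry(
            second_order=second_order,
            first_order_units={p: units for p in periods},
            third_order_pairs={p: pairs for p in periods},
        )

    def planted_partition(self) -> dict[str, str]:
        return {
            i: aid
            for aid, units in self.alliances.items()
            for u in units
            for i in u
        }


@dataclass
class GroundTruth:
    """The config plus its analytic expectations, for oracle-style checks."""

    config: SocietyConfig
    expected_hwi_by_class: dict[str, float]
    expected_cosighting_by_class: dict[str, float]
    planted_partition: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "expected_hwi_by_class": self.expected_hwi_by_class,
                    "expected_cosighting_by_class": self.expected_cosighting_by_class,
                    "planted_partition": self.planted_partition,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------


def _alive(cfg: SocietyConfig, day: Date) -> set[str]:
    dead = {i for i, last in cfg.mortality if day > last}
    return set(cfg.individuals) - dead


def generate_surveys(
    cfg: SocietyConfig,
) -> tuple[list[Survey], GroundTruth]:
    """Sample surveys from the planted society.

    Dates are drawn uniformly over the config's date range; the member draw
    follows the unit-seeded group process described in the module docstring.
    Reproducible: all randomness flows from ``cfg.seed`` through one
    generator.  Surveys whose member draw comes out empty are redrawn (they
    correspond to groups with no identifiable focal male, which produce no
    survey in the field).
    """
    rng = np.random.default_rng(cfg.seed)
    n_days = (cfg.end - cfg.start).days + 1
    activities = list(cfg.activity_dist.keys())
    act_probs = np.array([cfg.activity_dist[a] for a in activities], dtype=float)
    act_probs = act_probs / act_probs.sum()

    surveys: list[Survey] = []
    truth = ground_truth(cfg)
    i = 0
    while len(surveys) < cfg.n_surveys:
        i += 1
        day = cfg.start + timedelta(days=int(rng.integers(0, n_days)))
        alive = _alive(cfg, day)
        living_units = [
            (aid, u)
            for aid, units in cfg.alliances.items()
            for u in units
            if u & alive
        ]
        if not living_units:
            raise ValueError("no living first-order units: check mortality config")
        aid, seed_unit = living_units[int(rng.integers(0, len(living_units)))]
        members: set[str] = {
            m for m in seed_unit & alive if rng.random() < cfg.p_unit_cohesion
        }
        # same-alliance attachment: each other unit joins independently
        own_others = [
            u for a2, u in living_units if a2 == aid and u != seed_unit
        ]
        for attach in own_others:
            if rng.random() < cfg.p2:
                members |= {
                    m for m in attach & alive if rng.random() < cfg.p_unit_cohesion
                }
        # third-order attachments, one potential unit per allied alliance
        for partner, p3 in cfg.partners_of(aid):
            if rng.random() >= p3:
                continue
            partner_units = [u for a2, u in living_units if a2 == partner]
            if not partner_units:
                continue
            weights = np.array(
                [cfg.unit_weight(partner, u) for u in partner_units], dtype=float
            )
            weights /= weights.sum()
            attach = partner_units[int(rng.choice(len(partner_units), p=weights))]
            members |= {
                m for m in attach & alive if rng.random() < cfg.p_unit_cohesion
            }
        if not members:
            continue
        activity = activities[int(rng.choice(len(activities), p=act_probs))]
        surveys.append(
            Survey(
                survey_id=f"SYN{len(surveys) + 1:05d}",
                date=day,
                members=frozenset(members),
                activity=activity,
            )
        )
    surveys.sort(key=lambda s: (s.date, s.survey_id))
    return surveys, truth


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------


def _per_survey_presence(cfg: SocietyConfig, individual: str) -> float:
    """P(a survey contains `individual`), ignoring mortality."""
    units = [(aid, u) for aid, us in cfg.alliances.items() for u in us]
    n_units = len(units)
    aid = cfg.alliance_of(individual)
    unit = cfg.unit_of(individual)
    pc = cfg.p_unit_cohesion
    prob = 0.0
    for seed_aid, seed_unit in units:
        p_seed = 1.0 / n_units
        if seed_unit == unit:
            prob += p_seed * pc
        elif seed_aid == aid:
            prob += p_seed * cfg.p2 * pc
        else:
            for partner, p3 in cfg.partners_of(seed_aid):
                if partner != aid:
                    continue
                w = cfg.unit_weight(aid, unit)
                total_w = sum(
                    cfg.unit_weight(aid, u) for a2, u in units if a2 == aid
                )
                prob += p_seed * p3 * (w / total_w) * pc
    return prob


def _per_survey_cosighting(cfg: SocietyConfig, a: str, b: str) -> float:
    """P(a survey contains both `a` and `b`), ignoring mortality."""
    units = [(aid, u) for aid, us in cfg.alliances.items() for u in us]
    n_units = len(units)
    aid_a, aid_b = cfg.alliance_of(a), cfg.alliance_of(b)
    unit_a, unit_b = cfg.unit_of(a), cfg.unit_of(b)
    pc = cfg.p_unit_cohesion
    prob = 0.0
    if unit_a == unit_b:
        for seed_aid, seed_unit in units:
            p_seed = 1.0 / n_units
            if seed_unit == unit_a:
                prob += p_seed * pc * pc
            elif seed_aid == aid_a:
                prob += p_seed * cfg.p2 * pc * pc
            else:
                for partner, p3 in cfg.partners_of(seed_aid):
                    if partner != aid_a:
                        continue
                    w = cfg.unit_weight(aid_a, unit_a)
                    total_w = sum(
                        cfg.unit_weight(aid_a, u)
                        for a2, u in units
                        if a2 == aid_a
                    )
                    prob += p_seed * p3 * (w / total_w) * pc * pc
    elif aid_a == aid_b:
        # each same-alliance unit attaches independently with p2; a p3
        # attachment brings at most one unit of the alliance, so a seed in
        # an allied alliance cannot produce this dyad
        for seed_aid, seed_unit in units:
            p_seed = 1.0 / n_units
            if seed_unit == unit_a or seed_unit == unit_b:
                prob += p_seed * pc * cfg.p2 * pc
            elif seed_aid == aid_a:
                prob += p_seed * (cfg.p2 * pc) ** 2
    else:
        # P(an attachment of `ind`'s unit happens, given the seed), per path
        def attach_prob(seed_aid: str, seed_unit: frozenset[str], ind: str) -> float:
            i_aid, i_unit = cfg.alliance_of(ind), cfg.unit_of(ind)
            if seed_unit == i_unit:
                return 1.0
            if seed_aid == i_aid:
                return cfg.p2
            for partner, p3 in cfg.partners_of(seed_aid):
                if partner == i_aid:
                    w = cfg.unit_weight(i_aid, i_unit)
                    total_w = sum(
                        cfg.unit_weight(i_aid, u) for a2, u in units if a2 == i_aid
                    )
                    return p3 * (w / total_w)
            return 0.0

        # the p2 attachment and each per-partner p3 attachment are
        # independent draws, so joint presence factorizes given the seed
        for seed_aid, seed_unit in units:
            pa = attach_prob(seed_aid, seed_unit, a)
            pb = attach_prob(seed_aid, seed_unit, b)
            prob += (1.0 / n_units) * pa * pc * pb * pc
    return prob


def expected_hwi_dyad(cfg: SocietyConfig, a: str, b: str) -> float:
    """Large-sample expected HWI for one dyad: 2 E[x] / (E[n_a] + E[n_b]).

    Ignores mortality (expectations refer to the full-roster process).
    """
    if cfg.mortality:
        logger.warning("expected_hwi ignores mortality; interpret accordingly")
    ex = _per_survey_cosighting(cfg, a, b)
    na = _per_survey_presence(cfg, a)
    nb = _per_survey_presence(cfg, b)
    if na + nb == 0:
        return 0.0
    return 2.0 * ex / (na + nb)


def classify_dyad(cfg: SocietyConfig, a: str, b: str) -> str:
    aid_a, aid_b = cfg.alliance_of(a), cfg.alliance_of(b)
    if cfg.unit_of(a) == cfg.unit_of(b):
        return "within_unit"
    if aid_a == aid_b:
        return "within_alliance"
    if frozenset({aid_a, aid_b}) in cfg.third_order:
        both_bridge = (
            cfg.bridge_units.get(aid_a) == cfg.unit_of(a)
            and cfg.bridge_units.get(aid_b) == cfg.unit_of(b)
        )
        return "third_order_bridge" if both_bridge else "third_order_nonbridge"
    return "non_allied"


def expected_hwi(cfg: SocietyConfig, dyad_class: str) -> float:
    """Mean expected HWI over all dyads of a class (0.0 for an empty class)."""
    if dyad_class not in DYAD_CLASSES:
        raise ValueError(f"unknown dyad class {dyad_class!r}")
    vals = [
        expected_hwi_dyad(cfg, a, b)
        for a, b in itertools.combinations(cfg.individuals, 2)
        if classify_dyad(cfg, a, b) == dyad_class
    ]
    return float(np.mean(vals)) if vals else 0.0


def ground_truth(cfg: SocietyConfig) -> GroundTruth:
    cos = {}
    for cls in DYAD_CLASSES:
        vals = [
            _per_survey_cosighting(cfg, a, b)
            for a, b in itertools.combinations(cfg.individuals, 2)
            if classify_dyad(cfg, a, b) == cls
        ]
        cos[cls] = float(np.mean(vals)) if vals else 0.0
    return GroundTruth(
        config=cfg,
        expected_hwi_by_class={c: expected_hwi(cfg, c) for c in DYAD_CLASSES},
        expected_cosighting_by_class=cos,
        planted_partition=cfg.planted_partition(),
    )


# ---------------------------------------------------------------------------
# Fusion-event log generation
# ---------------------------------------------------------------------------

DEFAULT_BEHAVIOR_RATES = {"PET": 0.12, "RUB": 0.08, "D0": 0.10, "SYNCH": 0.10}


def generate_fusion_log(
    cfg: SocietyConfig,
    n_events: int,
    rates: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> tuple[list[FusionEvent], list[BehaviorRecord], list[PairTally]]:
    """Simulate fusion events between third-order-allied alliances.

    Each event joins one unit from each alliance of a (uniformly chosen)
    registered third-order pair; every unordered pair of participants emits
    each behavior independently at the given per-pair rate.  Returns the
    events, the flat record log, and the generator's own tally of each event
    (computed with the same dedup rules the coder uses), for self-consistency
    checks.
    """
    if not cfg.third_order:
        raise ValueError("no third-order pairs configured")
    rates = dict(DEFAULT_BEHAVIOR_RATES if rates is None else rates)
    for k, v in rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rate {k}={v} outside [0,1]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    registry = cfg.to_registry(periods=("ALL",))
    pairs = sorted(cfg.third_order, key=lambda p: tuple(sorted(p)))

    events: list[FusionEvent] = []
    records: list[BehaviorRecord] = []
    tallies: list[PairTally] = []
    for k in range(n_events):
        pair = pairs[int(rng.integers(0, len(pairs)))]
        a_id, b_id = sorted(pair)
        unit_a = tuple(cfg.alliances[a_id])[int(rng.integers(0, len(cfg.alliances[a_id])))]
        unit_b = tuple(cfg.alliances[b_id])[int(rng.integers(0, len(cfg.alliances[b_id])))]
        participants = frozenset(unit_a | unit_b)
        event = FusionEvent(
            event_id=f"F{k + 1:03d}",
            date=cfg.start,
            alliances=frozenset({a_id, b_id}),
            participants=participants,
        )
        ev_records: list[BehaviorRecord] = []
        for x, y in itertools.combinations(sorted(participants), 2):
            for behavior, rate in rates.items():
                if rng.random() < rate:
                    ev_records.append(
                        BehaviorRecord(
                            event_id=event.event_id,
                            behavior=behavior,
                            actors=frozenset({x, y}),
                        )
                    )
        events.append(event)
        records.extend(ev_records)
        tallies.append(tally_event(ev_records, registry, "ALL", event=event))
    return events, records, tallies


# ---------------------------------------------------------------------------
# Presets: three alliances with the study population's sizes
# ---------------------------------------------------------------------------

_KS_UNITS = (
    frozenset({"MID", "PON", "QUA"}),
    frozenset({"PAS", "BOL", "KRO"}),
    frozenset({"DEE", "GRI", "HAL"}),
    frozenset({"JAB", "LUK", "VAX"}),
)
_PD_UNITS = (
    frozenset({"PRI", "WAB", "NAT"}),
    frozenset({"BAR", "DNG"}),
    frozenset({"TIM", "ROQ"}),
)
_RR_UNITS = (
    frozenset({"SMO", "URC", "COO"}),
    frozenset({"REA", "LAN"}),
)


def preset_t1(seed: int = 0, n_surveys: int = 2000) -> SocietyConfig:
    """Early-period preset: 12-member KS + 7-member PD allied; 5-member RR
    isolated.  Bridge trios: MID-PON-QUA (KS) and PRI-WAB-NAT (PD)."""
    return SocietyConfig(
        alliances={"KS": _KS_UNITS, "PD": _PD_UNITS, "RR": _RR_UNITS},
        third_order={frozenset({"KS", "PD"}): 0.12},
        bridge_units={"KS": _KS_UNITS[0], "PD": _PD_UNITS[0]},
        start=Date(2009, 8, 1),
        end=Date(2010, 12, 31),
        n_surveys=n_surveys,
        seed=seed,
    )


def preset_t3(seed: int = 0, n_surveys: int = 2000) -> SocietyConfig:
    """Late-period preset: KS reduced to 10 (MID lost from the bridge trio,
    PAS stepping in), PD to 5, and a new KS-RR alliance alongside KS-PD."""
    ks_units = (
        frozenset({"PON", "QUA", "PAS"}),
        frozenset({"BOL", "KRO"}),
        frozenset({"DEE", "GRI", "HAL"}),
        frozenset({"JAB", "LUK"}),
    )
    pd_units = (
        frozenset({"WAB", "NAT"}),
        frozenset({"DNG", "TIM", "ROQ"}),
    )
    rr_units = (
        frozenset({"SMO", "URC", "COO"}),
        frozenset({"REA", "LAN"}),
    )
    return SocietyConfig(
        alliances={"KS": ks_units, "PD": pd_units, "RR": rr_units},
        third_order={
            frozenset({"KS", "RR"}): 0.12,
            frozenset({"KS", "PD"}): 0.08,
        },
        bridge_units={
            "KS": ks_units[0],
            "RR": rr_units[0],
            "PD": pd_units[0],
        },
        start=Date(2013, 8, 1),
        end=Date(2014, 12, 31),
        n_surveys=n_surveys,
        seed=seed,
    )


def config_from_yaml(path: str | Path) -> SocietyConfig:
    data = yaml.safe_load(Path(path).read_text())
    return SocietyConfig(
        alliances={
            aid: tuple(frozenset(u) for u in units)
            for aid, units in data["alliances"].items()
        },
        third_order={
            frozenset(p["pair"]): float(p["p3"]) for p in data["third_order"]
        },
        bridge_units={
            aid: frozenset(u) for aid, u in data.get("bridge_units", {}).items()
        },
        p_unit_cohesion=float(data.get("p_unit_cohesion", 0.95)),
        p2=float(data.get("p2", 0.35)),
        bridge_bias=float(data.get("bridge_bias", 3.0)),
        start=Date.fromisoformat(str(data.get("start", "2009-08-01"))),
        end=Date.fromisoformat(str(data.get("end", "2010-12-31"))),
        n_surveys=int(data.get("n_surveys", 2000)),
        mortality=tuple(
            (m["id"], Date.fromisoformat(str(m["last_date"])))
            for m in data.get("mortality", [])
        ),
        seed=int(data.get("seed", 0)),
    )
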