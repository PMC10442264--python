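"""Coding of affiliative behavior during inter-alliance fusion events.

A fusion event is the moment members of two different second-order alliances
join to within 10 m.  Video-coded behaviors are tallied into *unique pair*
counts per event: petting/rubbing (PR) pairs, PR plus within-touching-
distance contacts whose occurrence could not be confirmed on video (D0), and
synchronous surfacing (synch) pairs — each split into third-order pairs
(across allied alliances) and second-order pairs (within an alliance).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_io import AllianceRegistry

logger = logging.getLogger(__name__)

AFFILIATIVE_CONTACT = ("PET", "RUB")
PR_D0 = ("PET", "RUB", "D0")
BEHAVIORS = ("PET", "RUB", "D0", "SYNCH", "AGG", "CONSORT_FORMATION", "CONSORT_CONTACT")

TALLY_COLUMNS = [
    "event_id",
    "alliances",
    "third_pr",
    "third_pr_d0",
    "second_pr",
    "second_pr_d0",
    "third_synch",
    "second_synch",
    "second_synch_by_alliance",
]


class PairClass:
    SECOND_ORDER = "second_order"
    THIRD_ORDER = "third_order"
    NON_ALLIED = "non_allied"


@dataclass(frozen=True)
class FusionEvent:
    event_id: str
    date: Date
    alliances: frozenset[str]
    participants: frozenset[str]
    consorts: Mapping[str, str | None] = field(default_factory=dict)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if len(self.alliances) != 2:
            raise ValueError(
                f"event {self.event_id!r}: alliances must be a distinct pair"
            )


@dataclass(frozen=True)
class BehaviorRecord:
    event_id: str
    behavior: str
    actors: frozenset[str]
    target: str | None = None

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior code {self.behavior!r}")
        if self.behavior == "SYNCH":
            if len(self.actors) not in (2, 3):
                raise ValueError("SYNCH takes 2 or 3 actors")
        elif self.behavior in PR_D0:
            if len(self.actors) != 2:
                raise ValueError(f"{self.behavior} takes exactly 2 actors")

    def pairs(self, decompose_trios: bool = True) -> set[frozenset[str]]:
        """Constituent unordered pairs; a 3-actor synch yields its 3 pairs."""
        actors = sorted(self.actors)
        if len(actors) == 2:
            return {frozenset(actors)}
        if not decompose_trios:
            return set()
        return {
            frozenset({a, b})
            for i, a in enumerate(actors)
            for b in actors[i + 1 :]
        }


def classify_pair(
    pair: Iterable[str], registry: AllianceRegistry, period: str
) -> str:
    """second_order / third_order / non_allied classification of a male pair."""
    a, b = sorted(pair)
    aa, ab = registry.alliance_of(a), registry.alliance_of(b)
    if aa is None or ab is None:
        missing = [i for i, al in ((a, aa), (b, ab)) if al is None]
        raise KeyError(f"unregistered individuals: {missing}")
    if aa == ab:
        return PairClass.SECOND_ORDER
    if registry.is_third_order_pair(aa, ab, period):
        return PairClass.THIRD_ORDER
    return PairClass.NON_ALLIED


def _unique_pairs(
    records: Iterable[BehaviorRecord],
    behaviors: tuple[str, ...],
    decompose_trios: bool = True,
) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for r in records:
        if r.behavior in behaviors:
            pairs |= r.pairs(decompose_trios=decompose_trios)
    return pairs


@dataclass
class PairTally:
    """Unique-pair counts for one fusion event, split by alliance level."""

    event_id: str
    alliances: frozenset[str]
    third_pr_pairs: frozenset[frozenset[str]]
    third_pr_d0_pairs: frozenset[frozenset[str]]
    second_pr_pairs: frozenset[frozenset[str]]
    second_pr_d0_pairs: frozenset[frozenset[str]]
    third_synch_pairs: frozenset[frozenset[str]]
    second_synch_pairs: frozenset[frozenset[str]]
    second_synch_by_alliance: dict[str, int]
    non_allied_pr_pairs: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        if not self.third_pr_pairs <= self.third_pr_d0_pairs:
            raise ValueError("PR pairs must be a subset of PR+D0 pairs")
        if not self.second_pr_pairs <= self.second_pr_d0_pairs:
            raise ValueError("PR pairs must be a subset of PR+D0 pairs")

    def to_row(self) -> dict:
        return {
            "event_id": self.event_id,
            "alliances": "-".join(sorted(self.alliances)),
            "third_pr": len(self.third_pr_pairs),
            "third_pr_d0": len(self.third_pr_d0_pairs),
            "second_pr": len(self.second_pr_pairs),
            "second_pr_d0": len(self.second_pr_d0_pairs),
            "third_synch": len(self.third_synch_pairs),
            "second_synch": len(self.second_synch_pairs),
            "second_synch_by_alliance": " ".join(
                f"{a}({n})"
                for a, n in sorted(self.second_synch_by_alliance.items())
                if n
            ),
        }


def tally_event(
    records: Sequence[BehaviorRecord],
    registry: AllianceRegistry,
    period: str,
    event: FusionEvent | None = None,
    decompose_trios: bool = True,
) -> PairTally:
    """Tally one event's records into unique-pair counts.

    A pair counts once per event per category regardless of how many records
    it appears in; PR+D0 is a superset of PR by construction.  Pairs spanning
    alliances without a registered third-order alliance are tallied as
    non-allied (and logged), matching how opportunistic bystanders are
    handled in the field coding.
    """
    event_ids = {r.event_id for r in records}
    if len(event_ids) > 1:
        raise ValueError(f"records span multiple events: {sorted(event_ids)}")
    event_id = event.event_id if event else (event_ids.pop() if event_ids else "")

    def split(pairs: set[frozenset[str]]) -> dict[str, set[frozenset[str]]]:
        out = {
            PairClass.SECOND_ORDER: set(),
            PairClass.THIRD_ORDER: set(),
            PairClass.NON_ALLIED: set(),
        }
        for p in pairs:
            cls = classify_pair(p, registry, period)
            if cls == PairClass.NON_ALLIED:
                logger.warning(
                    "event %s: pair %s spans non-allied alliances",
                    event_id,
                    sorted(p),
                )
            out[cls].add(p)
        return out

    pr = split(_unique_pairs(records, AFFILIATIVE_CONTACT, decompose_trios))
    pr_d0 = split(_unique_pairs(records, PR_D0, decompose_trios))
    synch = split(_unique_pairs(records, ("SYNCH",), decompose_trios))

    second_synch_by_alliance = Counter(
        registry.alliance_of(min(p)) for p in synch[PairClass.SECOND_ORDER]
    )
    if event is not None:
        alliances = event.alliances
    else:
        spanned = {
            registry.alliance_of(i)
            for r in records
            for i in r.actors
            if registry.alliance_of(i)
        }
        alliances = frozenset(sorted(spanned)[:2]) if len(spanned) >= 2 else frozenset(
            list(spanned) + ["?"]
        )
    return PairTally(
        event_id=event_id,
        alliances=alliances,
        third_pr_pairs=frozenset(pr[PairClass.THIRD_ORDER]),
        third_pr_d0_pairs=frozenset(pr_d0[PairClass.THIRD_ORDER]),
        second_pr_pairs=frozenset(pr[PairClass.SECOND_ORDER]),
        second_pr_d0_pairs=frozenset(pr_d0[PairClass.SECOND_ORDER]),
        third_synch_pairs=frozenset(synch[PairClass.THIRD_ORDER]),
        second_synch_pairs=frozenset(synch[PairClass.SECOND_ORDER]),
        second_synch_by_alliance=dict(second_synch_by_alliance),
        non_allied_pr_pairs=frozenset(pr_d0[PairClass.NON_ALLIED]),
    )


@dataclass
class TallySummary:
    per_event: pd.DataFrame
    column_totals: dict[str, int]
    unique_across_events: dict[str, int]
    unique_across_events_by_alliance: dict[str, dict[str, int]]


def summarize_tallies(tallies: Sequence[PairTally]) -> TallySummary:
    """Per-event table plus column totals and cross-event unique-pair counts.

    Column totals sum the per-event unique counts (a pair active in two
    events counts twice); the cross-event numbers deduplicate pairs over the
    whole event set.  Both are reported because "unique pairs" is ambiguous
    between the two framings.
    """
    if not tallies:
        raise ValueError("need at least one event tally")
    per_event = pd.DataFrame([t.to_row() for t in tallies], columns=TALLY_COLUMNS)
    count_cols = ["third_pr", "third_pr_d0", "second_pr", "second_pr_d0",
                  "third_synch", "second_synch"]
    column_totals = {c: int(per_event[c].sum()) for c in count_cols}

    def union(attr: str) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for t in tallies:
            out |= getattr(t, attr)
        return out

    attr_map = {
        "third_pr": "third_pr_pairs",
        "third_pr_d0": "third_pr_d0_pairs",
        "second_pr": "second_pr_pairs",
        "second_pr_d0": "second_pr_d0_pairs",
        "third_synch": "third_synch_pairs",
        "second_synch": "second_synch_pairs",
    }
    unique_across = {c: len(union(a)) for c, a in attr_map.items()}
    return TallySummary(
        per_event=per_event,
        column_totals=column_totals,
        unique_across_events=unique_across,
        unique_across_events_by_alliance={},
    )


def summarize_tallies_by_alliance(
    tallies: Sequence[PairTally], registry: AllianceRegistry, period: str
) -> TallySummary:
    """summarize_tallies plus cross-event unique counts split by alliance
    (second-order categories) or alliance pair (third-order categories)."""
    summary = summarize_tallies(tallies)

    def alliance_key(pair: frozenset[str]) -> str:
        alls = sorted({registry.alliance_of(i) for i in pair})
        return "-".join(alls) if len(alls) > 1 else alls[0]

    by_alliance: dict[str, dict[str, int]] = {}
    attr_map = {
        "third_pr": "third_pr_pairs",
        "second_pr": "second_pr_pairs",
        "third_synch": "third_synch_pairs",
        "second_synch": "second_synch_pairs",
    }
    for col, attr in attr_map.items():
        pairs: set[frozenset[str]] = set()
        for t in tallies:
            pairs |= getattr(t, attr)
        counts = Counter(alliance_key(p) for p in pairs)
        by_alliance[col] = dict(sorted(counts.items()))
    summary.unique_across_events_by_alliance = by_alliance
    return summary


# ---------------------------------------------------------------------------
# Inter-coder reliability
# ---------------------------------------------------------------------------


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two coders' category sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement rate and
    p_e the chance agreement from the two coders' marginal frequencies.
    When both coders use a single identical label throughout, p_e = 1 and
    kappa is undefined; returned as 1.0 by convention, with a warning.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    if len(labels_a) == 0:
        raise ValueError("label sequences must be non-empty")
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    labels = set(ca) | set(cb)
    p_e = sum((ca[l] / n) * (cb[l] / n) for l in labels)
    if p_e >= 1.0 - 1e-15:
        logger.warning(
            "cohens_kappa undefined (single shared label); 1.0 by convention"
        )
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def multi_coder_kappa(label_sets: Sequence[Sequence]) -> float:
    """Mean pairwise Cohen's kappa over more than two coders."""
    if len(label_sets) < 2:
        raise ValueError("need at least two coders")
    kappas = [
        cohens_kappa(label_sets[i], label_sets[j])
        for i in range(len(label_sets))
        for j in range(i + 1, len(label_sets))
    ]
    return float(np.mean(kappas))


# ---------------------------------------------------------------------------
# Behavior log I/O
# ---------------------------------------------------------------------------


def read_behavior_log(
    path: str | Path, actor_delimiter: str = ";"
) -> list[BehaviorRecord]:
    """Read a behavior log CSV: event_id,timestamp,behavior,actors,target."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"event_id", "behavior", "actors"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        actors = frozenset(
            a.strip() for a in row["actors"].split(actor_delimiter) if a.strip()
        )
        records.append(
            BehaviorRecord(
                event_id=row["event_id"],
                behavior=row["behavior"].strip().upper(),
                actors=actors,
                target=row.get("target") or None,
            )
        )
    return records


def write_behavior_log(
    records: Iterable[BehaviorRecord], path: str | Path, actor_delimiter: str = ";"
) -> None:
    rows = [
        {
            "event_id": r.event_id,
            "timestamp": "",
            "behavior": r.behavior,
            "actors": actor_delimiter.join(sorted(r.actors)),
            "target": r.target or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["event_id", "timestamp", "behavior", "actors", "target"]
    ).to_csv(path, index=False)
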