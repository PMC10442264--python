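"""Reading, validating and filtering group-composition survey data.

The sampling unit throughout is the *survey*: a timestamped snapshot of one
dolphin group's composition together with the group's predominant activity.
Surveys feed the half-weight association indices downstream, so the filters
here (activity restriction, seasonal window, same-day resight removal)
determine what "association" means for the rest of the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class Activity(str, Enum):
    """Predominant group activity recorded on a survey."""

    REST = "rest"
    TRAVEL = "travel"
    SOCIAL = "social"
    FORAGE = "forage"
    UNKNOWN = "unknown"
    COMPETITIVE = "competitive"


class SurveyLevel(str, Enum):
    """Alliance-level content of one survey."""

    WITHIN_ALLIANCE = "within_alliance"
    THIRD_ORDER = "third_order"
    MIXED_NONALLIED = "mixed_nonallied"


class SchemaError(ValueError):
    """A required column cannot be resolved in the input file."""


class SurveyValidationError(ValueError):
    """A row violates the survey invariants (empty members, bad date, ...)."""


@dataclass(frozen=True)
class Survey:
    """One group-composition snapshot.

    Parameters
    ----------
    survey_id : unique identifier of the snapshot.
    date : calendar date of the observation.
    members : ids of all individuals in the group (10 m chain rule upstream).
    activity : predominant group activity.
    is_resight : optional flag; when ``None`` resights are inferred by
        :func:`filter_surveys` from same-day membership overlap.
    notes : free text; a note containing ``conflict`` marks a large
        inter-group conflict for exclusion.
    """

    survey_id: str
    date: Date
    members: frozenset[str]
    activity: Activity
    is_resight: bool | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise SurveyValidationError(
                f"survey {self.survey_id!r}: members must be non-empty"
            )

    @property
    def is_conflict(self) -> bool:
        return "conflict" in self.notes.lower()


@dataclass(frozen=True)
class AllianceRegistry:
    """Asserted multi-level membership.

    ``second_order`` maps each focal individual to its (stable) second-order
    alliance.  ``first_order_units`` and ``third_order_pairs`` are keyed by
    period id because first-order partners shift and third-order alliances
    form and dissolve between periods.
    """

    second_order: Mapping[str, str]
    first_order_units: Mapping[str, tuple[frozenset[str], ...]]
    third_order_pairs: Mapping[str, frozenset[frozenset[str]]]

    def __post_init__(self) -> None:
        alliance_ids = set(self.second_order.values())
        for period, units in self.first_order_units.items():
            for unit in units:
                if not 2 <= len(unit) <= 3:
                    raise ValueError(
                        f"first-order unit {sorted(unit)} in period {period!r} "
                        f"must have 2-3 members"
                    )
                homes = {self.second_order.get(m) for m in unit}
                if len(homes) != 1 or None in homes:
                    raise ValueError(
                        f"first-order unit {sorted(unit)} in period {period!r} "
                        f"must share one second-order alliance (got {homes})"
                    )
        for period, pairs in self.third_order_pairs.items():
            for pair in pairs:
                if len(pair) != 2 or not pair <= alliance_ids:
                    raise ValueError(
                        f"third-order pair {sorted(pair)} in period {period!r} "
                        f"references unknown alliance ids"
                    )

    def alliance_of(self, individual: str) -> str | None:
        return self.second_order.get(individual)

    def members_of(self, alliance_id: str) -> frozenset[str]:
        return frozenset(
            i for i, a in self.second_order.items() if a == alliance_id
        )

    def allied_partners(self, alliance_id: str, period: str) -> frozenset[str]:
        """Second-order alliances third-order-allied to `alliance_id` in `period`."""
        if period not in self.third_order_pairs:
            raise KeyError(f"unknown period {period!r}")
        partners = set()
        for pair in self.third_order_pairs[period]:
            if alliance_id in pair:
                partners.update(pair - {alliance_id})
        return frozenset(partners)

    def is_third_order_pair(self, a: str, b: str, period: str) -> bool:
        if period not in self.third_order_pairs:
            raise KeyError(f"unknown period {period!r}")
        return frozenset({a, b}) in self.third_order_pairs[period]


@dataclass(frozen=True)
class SurveyFilterConfig:
    """Filters applied before association analysis.

    Defaults follow the field protocol: keep resting / travelling /
    socializing groups (foraging groups aggregate at food sources and would
    inflate association), restrict to the August-December field season, and
    drop same-day resights of the same group.
    """

    allowed_activities: frozenset[Activity] = frozenset(
        {Activity.REST, Activity.TRAVEL, Activity.SOCIAL}
    )
    month_window: tuple[int, int] = (8, 12)
    drop_same_day_resights: bool = True
    resight_overlap_threshold: float = 0.5
    exclude_conflicts: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.month_window
        if not (1 <= lo <= 12 and 1 <= hi <= 12):
            raise ValueError(f"invalid month window {self.month_window}")
        if not 0.0 <= self.resight_overlap_threshold <= 1.0:
            raise ValueError(
                f"resight_overlap_threshold must be in [0,1], "
                f"got {self.resight_overlap_threshold}"
            )


DEFAULT_SCHEMA = {
    "survey_id": "survey_id",
    "date": "date",
    "activity": "activity",
    "members": "members",
    "notes": "notes",
}


def read_surveys(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    member_delimiter: str = ";",
    activity_aliases: Mapping[str, Activity] | None = None,
) -> list[Survey]:
    """Read surveys from a CSV file.

    The file must carry (via `schema`, mapping canonical -> actual column
    names) columns for survey id, ISO-8601 date, activity and a delimited
    member list.  Unrecognized activity strings map to ``unknown`` with a
    warning unless covered by `activity_aliases`.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    aliases = {k.lower(): v for k, v in (activity_aliases or {}).items()}

    df = pd.read_csv(path, dtype=str).fillna("")
    for canonical in ("survey_id", "date", "activity", "members"):
        if colmap[canonical] not in df.columns:
            raise SchemaError(
                f"required column {colmap[canonical]!r} (for {canonical}) "
                f"not found in {path}"
            )
    has_notes = colmap["notes"] in df.columns

    if df[colmap["survey_id"]].duplicated().any():
        dupes = df[colmap["survey_id"]][df[colmap["survey_id"]].duplicated()]
        raise SurveyValidationError(
            f"duplicate survey ids: {sorted(set(dupes))}"
        )

    surveys: list[Survey] = []
    for idx, row in df.iterrows():
        sid = row[colmap["survey_id"]]
        raw_date = row[colmap["date"]]
        try:
            parsed = datetime.strptime(raw_date, "%Y-%m-%d").date()
        except ValueError as exc:
            raise SurveyValidationError(
                f"row {idx} (survey {sid!r}): unparseable date {raw_date!r}"
            ) from exc
        members = frozenset(
            m.strip()
            for m in row[colmap["members"]].split(member_delimiter)
            if m.strip()
        )
        if not members:
            raise SurveyValidationError(
                f"row {idx} (survey {sid!r}): empty members cell"
            )
        raw_act = row[colmap["activity"]].strip().lower()
        if raw_act in aliases:
            activity = Activity(aliases[raw_act])
        else:
            try:
                activity = Activity(raw_act)
            except ValueError:
                logger.warning(
                    "survey %s: unknown activity %r mapped to 'unknown'",
                    sid,
                    raw_act,
                )
                activity = Activity.UNKNOWN
        notes = row[colmap["notes"]] if has_notes else ""
        surveys.append(
            Survey(
                survey_id=sid,
                date=parsed,
                members=members,
                activity=activity,
                notes=notes,
            )
        )
    return surveys


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def filter_surveys(
    surveys: Sequence[Survey], cfg: SurveyFilterConfig | None = None
) -> list[Survey]:
    """Apply activity / season / conflict / resight filters.

    Same-day resights: a survey is dropped when an earlier *retained* survey
    of the same date has membership Jaccard overlap above the threshold (or
    when its ``is_resight`` flag is explicitly set).  Order is preserved and
    the operation is idempotent; the first survey of a date is never dropped
    as a resight.
    """
    cfg = cfg or SurveyFilterConfig()
    lo, hi = cfg.month_window
    retained: list[Survey] = []
    by_date: dict[Date, list[Survey]] = {}
    for s in surveys:
        if s.activity not in cfg.allowed_activities:
            continue
        in_window = lo <= s.date.month <= hi if lo <= hi else (
            s.date.month >= lo or s.date.month <= hi
        )
        if not in_window:
            continue
        if cfg.exclude_conflicts and s.is_conflict:
            continue
        if cfg.drop_same_day_resights:
            if s.is_resight:
                continue
            earlier = by_date.get(s.date, [])
            if any(
                _jaccard(s.members, e.members) > cfg.resight_overlap_threshold
                for e in earlier
            ):
                continue
        retained.append(s)
        by_date.setdefault(s.date, []).append(s)
    if not retained:
        logger.warning("filter_surveys: no surveys retained")
    return retained


def classify_survey_level(
    survey: Survey, registry: AllianceRegistry, period: str
) -> tuple[SurveyLevel, frozenset[frozenset[str]]]:
    """Classify one survey by the alliances it spans.

    Returns the classification and the set of spanned alliance pairs.
    A survey is a *third-order association* when its members span at least
    two second-order alliances and every spanned pair is a registered
    third-order alliance for the period; if some spanned pair is not
    registered, the survey is ``mixed_nonallied``.  Individuals absent from
    the registry are ignored (with a warning) but remain valid survey members
    for association counting.
    """
    if period not in registry.third_order_pairs:
        raise KeyError(f"unknown period {period!r}")
    alliances = set()
    for m in survey.members:
        a = registry.alliance_of(m)
        if a is None:
            logger.warning(
                "survey %s: individual %r not in registry, ignored",
                survey.survey_id,
                m,
            )
        else:
            alliances.add(a)
    if len(alliances) <= 1:
        return SurveyLevel.WITHIN_ALLIANCE, frozenset()
    ordered = sorted(alliances)
    pairs = frozenset(
        frozenset({a, b})
        for i, a in enumerate(ordered)
        for b in ordered[i + 1 :]
    )
    registered = registry.third_order_pairs[period]
    if all(p in registered for p in pairs):
        return SurveyLevel.THIRD_ORDER, pairs
    return SurveyLevel.MIXED_NONALLIED, pairs


def load_registry(path: str | Path) -> AllianceRegistry:
    """Load an alliance registry from YAML or JSON.

    Expected keys: ``second_order`` (id -> alliance), ``first_order_units``
    (period -> list of member lists), ``third_order_pairs`` (period -> list
    of 2-element alliance-id lists).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return registry_from_dict(data)


def registry_from_dict(data: Mapping) -> AllianceRegistry:
    return AllianceRegistry(
        second_order=dict(data["second_order"]),
        first_order_units={
            period: tuple(frozenset(u) for u in units)
            for period, units in data.get("first_order_units", {}).items()
        },
        third_order_pairs={
            period: frozenset(frozenset(p) for p in pairs)
            for period, pairs in data.get("third_order_pairs", {}).items()
        },
    )


def registry_to_dict(reg: AllianceRegistry) -> dict:
    return {
        "second_order": dict(reg.second_order),
        "first_order_units": {
            period: [sorted(u) for u in units]
            for period, units in reg.first_order_units.items()
        },
        "third_order_pairs": {
            period: sorted(sorted(p) for p in pairs)
            for period, pairs in reg.third_order_pairs.items()
        },
    }


def save_registry(reg: AllianceRegistry, path: str | Path) -> None:
    path = Path(path)
    data = registry_to_dict(reg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def surveys_to_csv(
    surveys: Iterable[Survey], path: str | Path, member_delimiter: str = ";"
) -> None:
    rows = [
        {
            "survey_id": s.survey_id,
            "date": s.date.isoformat(),
            "activity": s.activity.value,
            "members": member_delimiter.join(sorted(s.members)),
            "notes": s.notes,
        }
        for s in surveys
    ]
    pd.DataFrame(
        rows, columns=["survey_id", "date", "activity", "members", "notes"]
    ).to_csv(path, index=False)
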