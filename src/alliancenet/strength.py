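"""Within- and between-alliance weighted degree (strength) and temporal
snapshots.

For each male, ``wStrength`` sums his HWI to members of his own second-order
alliance and ``bStrength`` sums his HWI to members of second-order alliances
with which his alliance holds a third-order alliance.  Because raw strength
grows with network size, each measure is also normalized by the maximum of
that measure among members of the individual's own second-order alliance
(``wStrength_N`` / ``bStrength_N`` in [0, 1]): the male carrying the most
between-alliance weight in his alliance scores exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssociationMatrix, association_matrix
from .community import ClusterDiagnostics, cluster_diagnostics
from .survey_io import AllianceRegistry, Survey

logger = logging.getLogger(__name__)

STRENGTH_COLUMNS = [
    "id",
    "alliance",
    "period",
    "wStrength",
    "bStrength",
    "wStrength_N",
    "bStrength_N",
]


def subgroup_strength(
    matrix: AssociationMatrix, individual: str, subset: Sequence[str] | frozenset[str]
) -> float:
    """Sum of HWI from `individual` to `subset` (self excluded)."""
    if individual not in matrix.index:
        raise KeyError(f"individual {individual!r} not in matrix")
    idx = matrix.index
    return float(
        sum(
            matrix.values[idx[individual], idx[j]]
            for j in subset
            if j != individual and j in idx
        )
    )


def _normalize(group: pd.Series) -> pd.Series:
    top = group.max()
    if top <= 0 or not np.isfinite(top):
        return pd.Series(np.nan, index=group.index)
    return group / top


def strength_table(
    matrix: AssociationMatrix,
    registry: AllianceRegistry,
    period: str,
    normalization_scope: str = "alliance",
) -> pd.DataFrame:
    """Per-individual strength table (id, alliance, w/bStrength, normalized).

    `normalization_scope` is ``"alliance"`` (default: divide by the maximum
    within the individual's own second-order alliance) or ``"network"``
    (divide by the global maximum).  Alliances whose maximum is zero get NaN
    normalized values, with a warning.
    """
    if normalization_scope not in ("alliance", "network"):
        raise ValueError(f"unknown normalization scope {normalization_scope!r}")
    rows = []
    for ind in matrix.ids:
        alliance = registry.alliance_of(ind)
        if alliance is None:
            logger.warning("strength_table: %r not registered, skipped", ind)
            continue
        own = registry.members_of(alliance)
        partners = registry.allied_partners(alliance, period)
        allied_members: set[str] = set()
        for p in partners:
            allied_members |= registry.members_of(p)
        rows.append(
            {
                "id": ind,
                "alliance": alliance,
                "period": period,
                "wStrength": subgroup_strength(matrix, ind, own),
                "bStrength": subgroup_strength(matrix, ind, allied_members),
            }
        )
    df = pd.DataFrame(rows, columns=STRENGTH_COLUMNS[:5])
    if df.empty:
        return pd.DataFrame(columns=STRENGTH_COLUMNS)
    if normalization_scope == "alliance":
        df["wStrength_N"] = df.groupby("alliance")["wStrength"].transform(_normalize)
        df["bStrength_N"] = df.groupby("alliance")["bStrength"].transform(_normalize)
    else:
        df["wStrength_N"] = _normalize(df["wStrength"])
        df["bStrength_N"] = _normalize(df["bStrength"])
    if df[["wStrength_N", "bStrength_N"]].isna().any().any():
        logger.warning(
            "strength_table: some normalization groups have zero maximum; "
            "normalized values reported as NaN"
        )
    return df


def bstrength_by_partner(
    matrix: AssociationMatrix, registry: AllianceRegistry, period: str
) -> pd.DataFrame:
    """Between-alliance strength broken down per third-order partner.

    When an alliance holds several third-order alliances at once, the pooled
    ``bStrength`` hides which partner carries the weight; this emits one row
    per (individual, partner alliance).
    """
    rows = []
    for ind in matrix.ids:
        alliance = registry.alliance_of(ind)
        if alliance is None:
            continue
        for partner in sorted(registry.allied_partners(alliance, period)):
            rows.append(
                {
                    "id": ind,
                    "alliance": alliance,
                    "partner": partner,
                    "period": period,
                    "bStrength": subgroup_strength(
                        matrix, ind, registry.members_of(partner)
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["id", "alliance", "partner", "period", "bStrength"]
    )


def unit_mean_hwi(
    matrix: AssociationMatrix,
    unit_a: Sequence[str] | frozenset[str],
    unit_b: Sequence[str] | frozenset[str],
) -> float:
    """Arithmetic mean HWI over all cross-unit dyads (e.g. pair x trio)."""
    set_a, set_b = frozenset(unit_a), frozenset(unit_b)
    if not set_a or not set_b:
        raise ValueError("units must be non-empty")
    if set_a & set_b:
        raise ValueError(f"units overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(matrix.ids)
    if missing:
        raise KeyError(f"individuals not in matrix: {sorted(missing)}")
    vals = [matrix.get(a, b) for a in sorted(set_a) for b in sorted(set_b)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Temporal snapshots
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnapshotSpec:
    """Discrete snapshot windows (e.g. three 2-year intervals) and rosters.

    ``periods`` maps period id -> (start_year, end_year) inclusive;
    ``rosters`` maps period id -> the individuals eligible in that window
    (survivors; presence thresholds applied upstream).
    """

    periods: tuple[tuple[str, int, int], ...]
    rosters: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        spans = sorted((s, e, p) for p, s, e in self.periods)
        for (s1, e1, p1), (s2, e2, p2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"periods {p1!r} and {p2!r} overlap")
        for p, _, _ in self.periods:
            if p not in self.rosters:
                raise ValueError(f"no roster for period {p!r}")


@dataclass
class Snapshot:
    period: str
    matrix: AssociationMatrix
    diagnostics: ClusterDiagnostics
    strengths: pd.DataFrame
    n_surveys: int


def temporal_snapshots(
    surveys: Sequence[Survey],
    spec: SnapshotSpec,
    registry: AllianceRegistry,
    min_sightings: int = 1,
    normalization_scope: str = "alliance",
    registry_periods: Mapping[str, str] | None = None,
) -> dict[str, Snapshot]:
    """Recompute the full chain (HWI -> clustering -> strengths) per window.

    Surveys are subset by calendar year, the period roster applied, and each
    period analysed independently.  Periods in which fewer than two rostered
    individuals were sighted are skipped with a warning.  When the registry
    keys its units/alliances by different period ids than the snapshot spec
    (e.g. a registry with one "ALL" period), `registry_periods` maps snapshot
    period -> registry period.
    """
    out: dict[str, Snapshot] = {}
    for period, start, end in spec.periods:
        reg_period = (registry_periods or {}).get(period, period)
        roster = spec.rosters[period]
        subset = [s for s in surveys if start <= s.date.year <= end]
        sighted = set().union(*(s.members for s in subset)) if subset else set()
        usable = roster & sighted
        if len(usable) < 2:
            logger.warning(
                "period %s: only %d rostered individuals sighted, skipped",
                period,
                len(usable),
            )
            continue
        matrix = association_matrix(
            subset, usable, min_sightings=min_sightings, period=period
        )
        if len(matrix.ids) < 2:
            logger.warning(
                "period %s: fewer than 2 individuals above sighting "
                "threshold, skipped",
                period,
            )
            continue
        diagnostics = cluster_diagnostics(matrix)
        strengths = strength_table(
            matrix, registry, reg_period, normalization_scope=normalization_scope
        )
        if not strengths.empty:
            strengths["period"] = period
        out[period] = Snapshot(
            period=period,
            matrix=matrix,
            diagnostics=diagnostics,
            strengths=strengths,
            n_surveys=len(subset),
        )
    return out
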