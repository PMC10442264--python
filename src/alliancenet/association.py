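"""Dyadic sighting counts, half-weight association indices, permutation null.

The half-weight index (HWI) for a dyad (a, b) is

    HWI = x / (x + y_ab + (y_a + y_b) / 2)

where x is the number of sampling periods with both together, y_ab the
number with both seen but in different groups, and y_a / y_b the number with
only one seen.  With one group per sampling period (same-day resights
removed upstream) y_ab = 0 and the index reduces to 2x / (n_a + n_b).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_io import Survey

logger = logging.getLogger(__name__)

Dyad = frozenset


@dataclass
class SightingCounts:
    """Per-individual and per-dyad sighting tallies.

    ``y_joint_apart`` (both seen in one sampling period but not together) is
    identically zero under the one-group-per-period sampling design but kept
    explicit so day-based sampling periods can be configured later.
    """

    n: dict[str, int]
    x: dict[frozenset[str], int]
    y_joint_apart: dict[frozenset[str], int] = field(default_factory=dict)
    n_surveys: int = 0

    def __post_init__(self) -> None:
        for dyad, xab in self.x.items():
            a, b = sorted(dyad)
            if xab > min(self.n.get(a, 0), self.n.get(b, 0)):
                raise ValueError(
                    f"x({a},{b})={xab} exceeds min sighting count"
                )


@dataclass
class AssociationMatrix:
    """Symmetric HWI matrix over an ordered individual set."""

    ids: tuple[str, ...]
    values: np.ndarray
    n_surveys: int = 0
    period: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("association matrix must be symmetric")
        off = self.values[~np.eye(k, dtype=bool)]
        off = off[~np.isnan(off)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("HWI values must lie in [0, 1]")

    @property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle dyadic values in (i<j) order."""
        k = len(self.ids)
        iu = np.triu_indices(k, 1)
        return self.values[iu]

    def dyads(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.ids, 2))

    def subset(self, ids: Sequence[str]) -> "AssociationMatrix":
        idx = self.index
        sel = [idx[i] for i in ids]
        return AssociationMatrix(
            ids=tuple(ids),
            values=self.values[np.ix_(sel, sel)],
            n_surveys=self.n_surveys,
            period=self.period,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe().round(4)
        df.to_csv(path, float_format="%.4f")

    @classmethod
    def from_csv(
        cls, path: str | Path, n_surveys: int = 0, period: str = ""
    ) -> "AssociationMatrix":
        df = pd.read_csv(path, index_col=0)
        df.columns = [str(c) for c in df.columns]
        df.index = [str(i) for i in df.index]
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: matrix rows and columns differ")
        vals = df.to_numpy(dtype=float)
        np.fill_diagonal(vals, 0.0)
        vals = (vals + vals.T) / 2.0  # tolerate asymmetric rounding
        return cls(
            ids=tuple(df.index), values=vals, n_surveys=n_surveys, period=period
        )


def count_sightings(
    surveys: Sequence[Survey], ids: Sequence[str] | frozenset[str]
) -> SightingCounts:
    """Tally per-individual (n) and per-dyad joint (x) sighting counts.

    One survey is one sampling period, so joint-but-apart counts are zero.
    """
    id_list = sorted(ids) if not isinstance(ids, (list, tuple)) else list(ids)
    if not id_list:
        raise ValueError("ids must be non-empty")
    focal = set(id_list)
    n = {i: 0 for i in id_list}
    x: dict[frozenset[str], int] = {}
    for s in surveys:
        present = sorted(s.members & focal)
        for i in present:
            n[i] += 1
        for a, b in itertools.combinations(present, 2):
            dyad = frozenset({a, b})
            x[dyad] = x.get(dyad, 0) + 1
    return SightingCounts(n=n, x=x, n_surveys=len(surveys))


def half_weight_index(
    counts: SightingCounts,
    min_sightings: int = 1,
    period: str = "",
) -> AssociationMatrix:
    """Half-weight index matrix from sighting counts.

    Individuals sighted fewer than `min_sightings` times are dropped (with a
    warning): their indices are undefined or unstable.
    """
    kept = [i for i in sorted(counts.n) if counts.n[i] >= min_sightings]
    dropped = sorted(set(counts.n) - set(kept))
    if dropped:
        logger.warning(
            "half_weight_index: dropping %d individuals below %d sightings: %s",
            len(dropped),
            min_sightings,
            dropped,
        )
    k = len(kept)
    values = np.zeros((k, k), dtype=float)
    for ia, a in enumerate(kept):
        for ib in range(ia + 1, k):
            b = kept[ib]
            dyad = frozenset({a, b})
            x = counts.x.get(dyad, 0)
            y_ab = counts.y_joint_apart.get(dyad, 0)
            y_a = counts.n[a] - x - y_ab
            y_b = counts.n[b] - x - y_ab
            denom = x + y_ab + (y_a + y_b) / 2.0
            hwi = x / denom if denom > 0 else 0.0
            values[ia, ib] = values[ib, ia] = hwi
    return AssociationMatrix(
        ids=tuple(kept),
        values=values,
        n_surveys=counts.n_surveys,
        period=period,
    )


def association_matrix(
    surveys: Sequence[Survey],
    ids: Sequence[str] | frozenset[str],
    min_sightings: int = 1,
    period: str = "",
) -> AssociationMatrix:
    """Convenience chain: count sightings then compute the HWI matrix."""
    return half_weight_index(
        count_sightings(surveys, ids), min_sightings=min_sightings, period=period
    )


# ---------------------------------------------------------------------------
# Permutation null for preferential association
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))


def _incidence(surveys: Sequence[Survey], ids: Sequence[str]) -> np.ndarray:
    m = np.zeros((len(ids), len(surveys)), dtype=bool)
    idx = {i: k for k, i in enumerate(ids)}
    for j, s in enumerate(surveys):
        for member in s.members:
            if member in idx:
                m[idx[member], j] = True
    return m


def _hwi_from_incidence(m: np.ndarray) -> np.ndarray:
    n = m.sum(axis=1).astype(float)
    x = (m.astype(np.int32) @ m.astype(np.int32).T).astype(float)
    denom = n[:, None] + n[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        hwi = np.where(denom > 0, 2.0 * x / denom, 0.0)
    np.fill_diagonal(hwi, 0.0)
    return hwi


def _statistic(hwi: np.ndarray, which: str) -> float:
    iu = np.triu_indices(hwi.shape[0], 1)
    vals = hwi[iu]
    if vals.size < 2 and which != "mean_hwi":
        return 0.0
    if which == "mean_hwi":
        return float(np.mean(vals))
    if which == "sd_hwi":
        return float(np.std(vals, ddof=1))
    if which == "cv_hwi":
        mean = np.mean(vals)
        if mean == 0:
            return 0.0
        return float(np.std(vals, ddof=1) / mean)
    raise ValueError(f"unknown statistic {which!r}")


def _checkerboard_swaps(
    m: np.ndarray, n_swaps: int, rng: np.random.Generator, max_trials: int
) -> None:
    """Perform `n_swaps` accepted checkerboard swaps in place.

    A swap picks individuals (i, j) and surveys (s, t) with the 2x2 pattern
    [[1,0],[0,1]] and flips it to [[0,1],[1,0]], preserving every row and
    column total (group sizes and individual sighting counts).
    """
    n_ind, n_sur = m.shape
    done = 0
    trials_since_success = 0
    batch = 512
    while done < n_swaps:
        ii = rng.integers(0, n_ind, size=batch)
        jj = rng.integers(0, n_ind, size=batch)
        ss = rng.integers(0, n_sur, size=batch)
        tt = rng.integers(0, n_sur, size=batch)
        for i, j, s, t in zip(ii, jj, ss, tt):
            trials_since_success += 1
            if trials_since_success > max_trials:
                raise RuntimeError(
                    "no valid checkerboard swap found: association data are "
                    "degenerate (all groups identical or counts saturated)"
                )
            if i == j or s == t:
                continue
            if m[i, s] and m[j, t] and not m[i, t] and not m[j, s]:
                m[i, s] = m[j, t] = False
                m[i, t] = m[j, s] = True
                done += 1
                trials_since_success = 0
                if done >= n_swaps:
                    break


def permutation_null(
    surveys: Sequence[Survey],
    n_perm: int,
    seed: int,
    statistic: Literal["cv_hwi", "mean_hwi", "sd_hwi"] = "cv_hwi",
    ids: Sequence[str] | None = None,
    burn_in: int = 1000,
    swaps_between: int = 100,
) -> PermutationResult:
    """Group-membership permutation test for preferential association.

    Null model: sequential checkerboard swaps of the individual x survey
    incidence matrix, preserving each survey's group size and each
    individual's sighting count.  Two-sided p-value with add-one correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(surveys) < 2:
        raise ValueError("need at least 2 surveys")
    if ids is None:
        ids = sorted(set().union(*(s.members for s in surveys)))
    rng = np.random.default_rng(seed)
    m = _incidence(surveys, list(ids))
    observed = _statistic(_hwi_from_incidence(m), statistic)

    max_trials = max(100_000, 200 * m.size)
    work = m.copy()
    _checkerboard_swaps(work, burn_in, rng, max_trials)
    null = np.empty(n_perm)
    for k in range(n_perm):
        _checkerboard_swaps(work, swaps_between, rng, max_trials)
        null[k] = _statistic(_hwi_from_incidence(work), statistic)

    n_ge = int(np.sum(null >= observed))
    n_le = int(np.sum(null <= observed))
    p_one = (min(n_ge, n_le) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * p_one)
    return PermutationResult(
        statistic=statistic,
        observed=observed,
        null=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
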