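"""Average-linkage clustering on association indices, with cophenetic and
modularity diagnostics.

Agglomeration runs directly on the similarity (HWI) scale: at each step the
pair of clusters with the highest average pairwise HWI is merged, and the
merge height is that average.  Heights are therefore non-increasing along
the merge sequence.  A partition is chosen by cutting the tree at every
distinct merge height and keeping the cut that maximizes Newman's weighted
modularity Q on the HWI-weighted graph:

    Q = sum_c [ W_c / W - (S_c / (2 W))^2 ]

with W the total edge weight, W_c the within-cluster edge weight and S_c the
summed node strengths of cluster c.  The cophenetic correlation coefficient
(CCC) — the Pearson correlation between dyadic HWI and the height at which
each dyad joins the tree — measures how faithfully the hierarchy represents
the raw association structure; CCC > 0.8 is conventionally read as a good
representation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .association import AssociationMatrix

logger = logging.getLogger(__name__)

GOOD_CCC_THRESHOLD = 0.8


@dataclass(frozen=True)
class Merge:
    cluster_a: frozenset[str]
    cluster_b: frozenset[str]
    height: float

    @property
    def merged(self) -> frozenset[str]:
        return self.cluster_a | self.cluster_b


@dataclass
class Dendrogram:
    """Average-linkage merge tree on the similarity scale."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")
        heights = [m.height for m in self.merges]
        if any(h2 > h1 + 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-increasing")

    def cophenetic_heights(self) -> dict[frozenset[str], float]:
        """Height (HWI level) at which each dyad is first joined."""
        joined: dict[frozenset[str], float] = {}
        for m in self.merges:
            for a in m.cluster_a:
                for b in m.cluster_b:
                    joined[frozenset({a, b})] = m.height
        return joined

    def cut(self, level: float) -> "Partition":
        """Partition grouping all dyads whose cophenetic height >= level."""
        clusters = {i: frozenset({i}) for i in self.leaves}
        membership = {i: i for i in self.leaves}  # leaf -> representative
        for m in self.merges:
            if m.height >= level - 1e-12:
                rep_a = membership[next(iter(m.cluster_a))]
                rep_b = membership[next(iter(m.cluster_b))]
                merged = clusters[rep_a] | clusters[rep_b]
                for leaf in merged:
                    membership[leaf] = rep_a
                clusters[rep_a] = merged
                del clusters[rep_b]
        assignment = {}
        for rep, members in clusters.items():
            label = min(members)
            for leaf in members:
                assignment[leaf] = label
        return Partition(assignment=assignment, cut_level=level)

    def distinct_heights(self) -> list[float]:
        seen: list[float] = []
        for m in self.merges:
            if not seen or abs(m.height - seen[-1]) > 1e-12:
                seen.append(m.height)
        return seen

    def to_newick(self) -> str:
        """Newick string; internal node labels carry the merge height (HWI)."""
        reps: dict[str, str] = {i: i for i in self.leaves}
        trees: dict[str, str] = {i: i for i in self.leaves}
        members: dict[str, frozenset[str]] = {
            i: frozenset({i}) for i in self.leaves
        }
        for m in self.merges:
            rep_a = reps[next(iter(m.cluster_a))]
            rep_b = reps[next(iter(m.cluster_b))]
            newick = f"({trees[rep_a]},{trees[rep_b]}){m.height:.4f}"
            merged = members[rep_a] | members[rep_b]
            for leaf in merged:
                reps[leaf] = rep_a
            trees[rep_a] = newick
            members[rep_a] = merged
            del trees[rep_b], members[rep_b]
        (root,) = trees.values()
        return root + ";"


@dataclass
class Partition:
    assignment: dict[str, str]
    cut_level: float = float("nan")

    def clusters(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for ind, label in self.assignment.items():
            out.setdefault(label, set()).add(ind)
        return {k: frozenset(v) for k, v in out.items()}

    def labels(self, ids: Sequence[str]) -> list[str]:
        return [self.assignment[i] for i in ids]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class ClusterDiagnostics:
    ccc: float
    q_by_cut: list[tuple[float, float]]
    q_max: float
    cut_at_qmax: float
    cut_midpoint: float
    best: Partition

    def to_dict(self) -> dict:
        return {
            "ccc": self.ccc,
            "ccc_good": bool(self.ccc > GOOD_CCC_THRESHOLD),
            "q_by_cut": [[lvl, q] for lvl, q in self.q_by_cut],
            "q_max": self.q_max,
            "cut_at_qmax": self.cut_at_qmax,
            "cut_midpoint": self.cut_midpoint,
            "n_clusters": self.best.n_clusters,
            "clusters": {
                label: sorted(members)
                for label, members in self.best.clusters().items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def average_linkage(matrix: AssociationMatrix) -> Dendrogram:
    """Greedy agglomeration merging the pair with maximal average HWI.

    Tie-break: among pairs with equal average similarity, merge the pair
    whose lexicographically smallest member id sorts first (then the second
    smallest), so results are deterministic across platforms.
    """
    ids = list(matrix.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals to cluster")
    vals = matrix.values
    k = len(ids)
    off = vals[~np.eye(k, dtype=bool)]
    if np.isnan(off).any():
        raise ValueError("association matrix contains NaN off-diagonal values")

    idx = matrix.index
    clusters: dict[frozenset[str], None] = {frozenset({i}): None for i in ids}

    def avg_sim(ca: frozenset[str], cb: frozenset[str]) -> float:
        total = sum(vals[idx[a], idx[b]] for a in ca for b in cb)
        return total / (len(ca) * len(cb))

    def tie_key(ca: frozenset[str], cb: frozenset[str]):
        return tuple(sorted(sorted(ca | cb)))

    merges: list[Merge] = []
    active = list(clusters)
    while len(active) > 1:
        best_pair = None
        best_sim = -np.inf
        best_key = None
        for ca, cb in itertools.combinations(active, 2):
            sim = avg_sim(ca, cb)
            key = tie_key(ca, cb)
            if sim > best_sim + 1e-12 or (
                abs(sim - best_sim) <= 1e-12
                and (best_key is None or key < best_key)
            ):
                best_sim = sim
                best_pair = (ca, cb)
                best_key = key
        ca, cb = best_pair
        if sorted(ca)[0] > sorted(cb)[0]:
            ca, cb = cb, ca
        merges.append(Merge(cluster_a=ca, cluster_b=cb, height=best_sim))
        active.remove(ca)
        active.remove(cb)
        active.append(ca | cb)
    return Dendrogram(leaves=matrix.ids, merges=tuple(merges))


def cophenetic_correlation(
    dendrogram: Dendrogram, matrix: AssociationMatrix
) -> float:
    """Pearson correlation between dyadic HWI and cophenetic join heights.

    Computed on the similarity scale directly, so a faithful hierarchy gives
    a positive coefficient.  Returns NaN (with a warning) when either vector
    has zero variance.
    """
    if set(dendrogram.leaves) != set(matrix.ids):
        raise ValueError("dendrogram and matrix cover different individuals")
    heights = dendrogram.cophenetic_heights()
    sims, cophs = [], []
    for a, b in matrix.dyads():
        sims.append(matrix.get(a, b))
        cophs.append(heights[frozenset({a, b})])
    sims_arr = np.asarray(sims)
    cophs_arr = np.asarray(cophs)
    if np.ptp(sims_arr) == 0 or np.ptp(cophs_arr) == 0:
        logger.warning("cophenetic correlation undefined: zero variance")
        return float("nan")
    r, _ = stats.pearsonr(sims_arr, cophs_arr)
    return float(r)


def modularity(partition: Partition, matrix: AssociationMatrix) -> float:
    """Newman weighted modularity of a partition of the HWI graph.

    Zero-weight dyads contribute nothing; a single-cluster partition has
    Q = 0 exactly.  Undefined (NaN) for an all-zero matrix.
    """
    ids = matrix.ids
    missing = set(ids) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover individuals {sorted(missing)}")
    vals = matrix.values
    total_w = vals[np.triu_indices(len(ids), 1)].sum()
    if total_w == 0:
        logger.warning("modularity undefined: all-zero association matrix")
        return float("nan")
    strengths = vals.sum(axis=1)
    idx = matrix.index
    q = 0.0
    for members in partition.clusters().values():
        sel = [idx[i] for i in members if i in idx]
        sub = vals[np.ix_(sel, sel)]
        w_c = sub[np.triu_indices(len(sel), 1)].sum() if len(sel) > 1 else 0.0
        s_c = strengths[sel].sum()
        q += w_c / total_w - (s_c / (2.0 * total_w)) ** 2
    return float(q)


def best_partition(
    dendrogram: Dendrogram, matrix: AssociationMatrix
) -> ClusterDiagnostics:
    """Modularity-maximized cut of the dendrogram, with diagnostics.

    Q is evaluated at the partition induced by each distinct merge height
    (cutting at a height keeps together every dyad joined at or above it),
    plus the all-singletons cut.  Ties on Q resolve to the highest cut level
    (fewest merges applied), which is deterministic.  The report carries both
    the maximizing merge height and the midpoint between it and the next
    higher distinct height, since "the" cut level of a dendrogram band is
    ambiguous by half a band.
    """
    heights = dendrogram.distinct_heights()
    # all-singletons cut: any level strictly above the first merge height
    candidate_levels = [heights[0] + 1.0] + heights
    q_by_cut: list[tuple[float, float]] = []
    best_q = -np.inf
    best_part: Partition | None = None
    best_level = float("nan")
    for level in candidate_levels:
        part = dendrogram.cut(level)
        q = modularity(part, matrix)
        q_by_cut.append((level, q))
        if not np.isnan(q) and q > best_q + 1e-12:
            best_q = q
            best_part = part
            best_level = level
    if best_part is None:  # all-zero matrix: fall back to single cluster
        best_part = dendrogram.cut(heights[-1])
        best_q = float("nan")
        best_level = heights[-1]
    pos = candidate_levels.index(best_level)
    next_higher = candidate_levels[pos - 1] if pos > 0 else best_level
    midpoint = (best_level + min(next_higher, 1.0)) / 2.0
    ccc = cophenetic_correlation(dendrogram, matrix)
    return ClusterDiagnostics(
        ccc=ccc,
        q_by_cut=q_by_cut,
        q_max=float(best_q),
        cut_at_qmax=float(best_level),
        cut_midpoint=float(midpoint),
        best=best_part,
    )


def cluster_diagnostics(matrix: AssociationMatrix) -> ClusterDiagnostics:
    """Full chain: average linkage, then modularity-maximized cut + CCC."""
    return best_partition(average_linkage(matrix), matrix)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def to_graph(
    matrix: AssociationMatrix, partition: Partition | None = None
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    if partition is not None:
        nx.set_node_attributes(g, partition.assignment, "cluster")
    for a, b in matrix.dyads():
        w = matrix.get(a, b)
        if w > 0:
            g.add_edge(a, b, weight=w)
    return g


def export_graphml(
    matrix: AssociationMatrix,
    path: str | Path,
    partition: Partition | None = None,
) -> None:
    nx.write_graphml(to_graph(matrix, partition), str(path))


def export_edge_list(matrix: AssociationMatrix, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"id_a": a, "id_b": b, "hwi": round(matrix.get(a, b), 4)}
        for a, b in matrix.dyads()
        if matrix.get(a, b) > 0
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "hwi"]).to_csv(path, index=False)
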