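"""Comparator methods: k-nearest-neighbour voting and UPGMA majority reassignment.

Two established distance-based relabelling schemes against which the kernel
classifier is compared. The k-NN comparator assigns the label held by at
least a fraction ``r`` of the focal accession's ``k`` nearest determined
neighbours. The UPGMA comparator cuts an average-linkage dendrogram at a
fixed height and, within every cluster dominated by a single taxon, gives
all members the dominant label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_model import AssignmentTable, DistanceMatrix


@dataclass(frozen=True)
class KnnParams:
    """k-NN voting parameters: neighbour count ``k`` and unassignment cutoff
    ``r`` (minimum vote fraction of the winning label; 4/6 in the reference
    configuration with ``k = 6``)."""

    k: int = 6
    r: float = 4 / 6
    relaxed_undetermined: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.r <= 1:
            raise ValueError("r must lie in (0, 1]")


@dataclass(frozen=True)
class UpgmaParams:
    """UPGMA reassignment parameters.

    ``height_cutoff`` is the dendrogram cut height (no sensible universal
    default exists — it is dataset-specific and must be supplied).
    ``majority_fraction`` is the share of a cluster's *determined* members a
    taxon needs before the whole cluster is relabelled to it.
    """

    height_cutoff: float
    majority_fraction: float = 0.8
    relaxed_undetermined: bool = False

    def __post_init__(self) -> None:
        if not self.height_cutoff > 0:
            raise ValueError("height_cutoff must be positive")
        if not 0.5 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must lie in (0.5, 1]")


def knn_classify(
    m: DistanceMatrix, a: AssignmentTable, p: KnnParams
) -> AssignmentTable:
    """Majority vote over each accession's ``k`` nearest determined neighbours.

    The focal accession never votes for itself. Neighbours tied with the
    rank-``k`` distance are all included and the vote is taken over the
    enlarged set; if fewer than ``k`` determined neighbours exist, the vote
    is over those available. The winning label is assigned only when unique
    and supported by at least a fraction ``r`` of the voters (any unique
    plurality suffices in relaxed mode); otherwise undetermined.
    """
    if m.mask.any():
        raise ValueError("matrix contains missing entries; run trim_invalid first")
    labels = [a.get(i) for i in m.ids]
    determined = np.array([t != a.undetermined for t in labels])
    values = m.values
    out: dict[str, str] = {}
    for i, focal in enumerate(m.ids):
        sel = determined.copy()
        sel[i] = False
        idx = np.flatnonzero(sel)
        dists = values[i, idx]
        if idx.size > p.k:
            cutoff = np.partition(dists, p.k - 1)[p.k - 1]
            keep = dists <= cutoff
            idx = idx[keep]
        votes = Counter(labels[j] for j in idx)
        if not votes:
            out[focal] = a.undetermined
            continue
        top = max(votes.values())
        winners = [t for t, c in votes.items() if c == top]
        if len(winners) != 1:
            out[focal] = a.undetermined
            continue
        fraction = top / idx.size
        if p.relaxed_undetermined or fraction >= p.r:
            out[focal] = winners[0]
        else:
            out[focal] = a.undetermined
    return AssignmentTable(out, a.undetermined)


def upgma_partition(m: DistanceMatrix, p: UpgmaParams) -> list[list[str]]:
    """Cut the average-linkage dendrogram of ``m`` at ``height_cutoff``.

    Clusters are the maximal subtrees whose merge heights all lie at or
    below the cutoff; together they cover every accession. Returned in
    order of each cluster's first accession in the matrix.
    """
    if m.mask.any():
        raise ValueError("matrix contains missing entries; run trim_invalid first")
    if m.n == 1:
        return [[m.ids[0]]]
    condensed = squareform(m.values, checks=False)
    tree = linkage(condensed, method="average")
    flat = fcluster(tree, t=p.height_cutoff, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for accession, label in zip(m.ids, flat):
        clusters.setdefault(int(label), []).append(accession)
    return sorted(clusters.values(), key=lambda c: m.index(c[0]))


def upgma_reassign(
    partition: list[list[str]], a: AssignmentTable, p: UpgmaParams
) -> AssignmentTable:
    """Relabel minority members of taxon-dominated clusters.

    Within each cluster the dominant taxon is sought among *determined*
    members only; undetermined members are reassignable but do not count
    toward the denominator. When a unique taxon reaches
    ``majority_fraction`` (any unique plurality in relaxed mode) every
    cluster member receives it; otherwise the cluster is left untouched.
    """
    out: dict[str, str] = {}
    for cluster in partition:
        current = {accession: a.get(accession) for accession in cluster}
        votes = Counter(t for t in current.values() if t != a.undetermined)
        winner: str | None = None
        if votes:
            top = max(votes.values())
            winners = [t for t, c in votes.items() if c == top]
            if len(winners) == 1:
                fraction = top / sum(votes.values())
                if p.relaxed_undetermined or fraction >= p.majority_fraction:
                    winner = winners[0]
        if winner is None:
            out.update(current)
        else:
            out.update({accession: winner for accession in cluster})
    return AssignmentTable(out, a.undetermined)


def upgma_classify(
    m: DistanceMatrix, a: AssignmentTable, p: UpgmaParams
) -> AssignmentTable:
    """Partition then reassign in one call."""
    return upgma_reassign(upgma_partition(m, p), a, p)


def relaxed_knn(p: KnnParams) -> KnnParams:
    return replace(p, relaxed_undetermined=True)


def relaxed_upgma(p: UpgmaParams) -> UpgmaParams:
    return replace(p, relaxed_undetermined=True)
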