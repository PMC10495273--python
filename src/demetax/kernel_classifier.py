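"""Distance-kernel taxonomic assignment with inverse-frequency normalisation.

The classifier suggests a taxon for every accession from the assignments of
its genetic neighbours. Each determined neighbour within distance ``d`` of
the focal accession contributes weight ``exp(-lambda * distance)`` to its
own taxon's score (a Parzen–Rosenblatt-window style vote); the focal
accession itself never contributes. Optionally only the ``k`` nearest such
neighbours are kept, and optionally each taxon's summed score is rescaled
by the inverse frequency of that taxon among the neighbours — the guard
against a heavily over-sampled taxon swallowing small, genetically distinct
ones. The top-scoring taxon is suggested only when its share of the total
score reaches the cutoff ``r``; otherwise the suggestion is the
undetermined sentinel.

With ``lambda = 0``, ``d = inf`` and normalisation off, the procedure
reduces to plain k-nearest-neighbour majority voting (focal excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AssignmentTable, DistanceMatrix

#: Relative tolerance used to declare two top scores tied.
TIE_RTOL = 1e-12


@dataclass(frozen=True)
class KernelParams:
    """Tuning parameters of the kernel classifier.

    Attributes
    ----------
    lambda_decay:
        Exponential decay rate of neighbour influence with distance
        (``>= 0``; 0 makes all neighbours within ``d`` weigh equally).
    d:
        Neighbourhood radius in distance units; the boundary is closed
        (``distance <= d``). ``inf`` disables the radius filter.
    r:
        Assignment cutoff in ``(0, 1]``: minimum share of the total
        (normalised) score the winning taxon must hold.
    k:
        Keep only the ``k`` nearest admissible neighbours (``inf`` disables;
        ties at rank ``k`` are all kept).
    normalize:
        Rescale each taxon's score by ``neighbours / neighbours_of_taxon``.
    relaxed_undetermined:
        Evaluation mode: suggest the top taxon regardless of ``r`` and of
        ties, returning undetermined only when no determined neighbour lies
        within ``d``. Used by the label-reshuffle robustness experiment.
    """

    lambda_decay: float = 320.0
    d: float = 0.2
    r: float = 0.66
    k: float = math.inf
    normalize: bool = True
    relaxed_undetermined: bool = False

    def __post_init__(self) -> None:
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be >= 0")
        if not self.d > 0:
            raise ValueError("d must be positive")
        if not 0 < self.r <= 1:
            raise ValueError("r must lie in (0, 1]")
        if not (self.k == math.inf or (float(self.k).is_integer() and self.k >= 1)):
            raise ValueError("k must be a positive integer or inf")


@dataclass
class ClassificationResult:
    """Per-accession scoring detail behind a suggestion."""

    focal: str
    raw_scores: dict[str, float]
    normalized_scores: dict[str, float]
    winning_proportion: float
    suggestion: str
    neighbor_count: int


def neighbor_set(
    focal: str,
    m: DistanceMatrix,
    a: AssignmentTable,
    p: KernelParams,
) -> list[tuple[str, float]]:
    """Admissible neighbours of ``focal``: determined, within ``d``, k-nearest.

    Returns ``(identifier, distance)`` pairs sorted by distance then
    identifier. The distance filter is applied before the ``k`` filter;
    neighbours tied with the rank-``k`` distance are all kept. Neighbours
    whose distance to the focal accession is missing are excluded.
    """
    i = m.index(focal)
    row = m.values[i]
    out: list[tuple[str, float]] = []
    for j, other in enumerate(m.ids):
        if j == i or not a.is_determined(other):
            continue
        dist = row[j]
        if np.isnan(dist) or dist > p.d:
            continue
        out.append((other, float(dist)))
    out.sort(key=lambda t: (t[1], t[0]))
    if math.isfinite(p.k) and len(out) > p.k:
        cutoff = out[int(p.k) - 1][1]
        out = [t for t in out if t[1] <= cutoff]
    return out


def _decide(
    taxa: Sequence[str],
    normalized: np.ndarray,
    p: KernelParams,
    undetermined: str,
) -> tuple[str, float]:
    """Shared suggestion rule: returns (suggestion, winning_proportion)."""
    total = float(normalized.sum())
    if len(taxa) == 0 or total <= 0.0:
        return undetermined, 0.0
    top = float(normalized.max())
    tied = [t for t, s in zip(taxa, normalized) if s >= top * (1.0 - TIE_RTOL)]
    proportion = top / total
    if p.relaxed_undetermined:
        return min(tied), proportion
    if len(tied) > 1 or proportion < p.r:
        return undetermined, proportion
    return tied[0], proportion


def score_candidates(
    focal: str,
    neighbours: Sequence[tuple[str, float]],
    a: AssignmentTable,
    p: KernelParams,
) -> ClassificationResult:
    """Score candidate taxa for ``focal`` from its admissible neighbours.

    Raw score of taxon ``T`` is the sum of ``exp(-lambda * distance)`` over
    neighbours labelled ``T``; with normalisation on it is rescaled by
    ``len(neighbours) / count(T)`` (ten neighbours of which four carry taxon
    A scale A's total by 10/4). The winning proportion is the top normalised
    score divided by the sum of all normalised scores. An empty neighbour
    list yields an undetermined suggestion, not an error.
    """
    labels = []
    for nid, _ in neighbours:
        if not a.is_determined(nid):
            raise ValueError(f"neighbour {nid!r} has an undetermined assignment")
        labels.append(a.get(nid))
    taxa = sorted(set(labels))
    t_index = {t: c for c, t in enumerate(taxa)}
    raw = np.zeros(len(taxa))
    counts = np.zeros(len(taxa))
    for (nid, dist), label in zip(neighbours, labels):
        c = t_index[label]
        raw[c] += math.exp(-p.lambda_decay * dist)
        counts[c] += 1
    n_total = len(neighbours)
    if p.normalize and n_total:
        normalized = raw * (n_total / counts)
    else:
        normalized = raw.copy()
    suggestion, proportion = _decide(taxa, normalized, p, a.undetermined)
    return ClassificationResult(
        focal=focal,
        raw_scores={t: float(raw[t_index[t]]) for t in taxa},
        normalized_scores={t: float(normalized[t_index[t]]) for t in taxa},
        winning_proportion=proportion,
        suggestion=suggestion,
        neighbor_count=n_total,
    )


def classify_accession(
    focal: str, m: DistanceMatrix, a: AssignmentTable, p: KernelParams
) -> ClassificationResult:
    """Convenience: neighbour search plus scoring for a single accession."""
    return score_candidates(focal, neighbor_set(focal, m, a, p), a, p)


def classify_all(
    m: DistanceMatrix,
    a: AssignmentTable,
    p: KernelParams,
) -> tuple[AssignmentTable, list[ClassificationResult]]:
    """Suggest an assignment for every accession in the matrix.

    All suggestions are computed against the *input* assignments in a single
    pass — no suggestion feeds back into another within the pass. Accessions
    that are themselves undetermined receive suggestions the same way (they
    simply contribute nothing as neighbours). Requires a curated matrix with
    no missing entries.
    """
    if m.mask.any():
        raise ValueError("matrix contains missing entries; run trim_invalid first")
    n = m.n
    labels = [a.get(i) for i in m.ids]
    taxa = sorted({t for t in labels if t != a.undetermined})
    t_index = {t: c for c, t in enumerate(taxa)}
    codes = np.array([t_index.get(t, -1) for t in labels])
    determined = codes >= 0
    n_taxa = len(taxa)
    lam = p.lambda_decay
    k = p.k
    values = m.values

    suggestions: dict[str, str] = {}
    results: list[ClassificationResult] = []
    for i, focal in enumerate(m.ids):
        row = values[i]
        sel = determined & (row <= p.d)
        sel[i] = False
        idx = np.flatnonzero(sel)
        dsel = row[idx]
        if math.isfinite(k) and dsel.size > k:
            cutoff = np.partition(dsel, int(k) - 1)[int(k) - 1]
            keep = dsel <= cutoff
            idx, dsel = idx[keep], dsel[keep]
        csel = codes[idx]
        weights = np.exp(-lam * dsel)
        raw = np.bincount(csel, weights=weights, minlength=n_taxa)
        counts = np.bincount(csel, minlength=n_taxa)
        present = counts > 0
        ptaxa = [taxa[c] for c in np.flatnonzero(present)]
        praw = raw[present]
        if p.normalize and idx.size:
            pnorm = praw * (idx.size / counts[present])
        else:
            pnorm = praw.copy()
        suggestion, proportion = _decide(ptaxa, pnorm, p, a.undetermined)
        suggestions[focal] = suggestion
        results.append(
            ClassificationResult(
                focal=focal,
                raw_scores=dict(zip(ptaxa, praw.tolist())),
                normalized_scores=dict(zip(ptaxa, pnorm.tolist())),
                winning_proportion=proportion,
                suggestion=suggestion,
                neighbor_count=int(idx.size),
            )
        )
    return AssignmentTable(suggestions, a.undetermined), results


def iterate_classification(
    m: DistanceMatrix,
    a: AssignmentTable,
    p: KernelParams,
    max_rounds: int = 10,
) -> tuple[AssignmentTable, int, bool]:
    """Feed suggestions back as inputs until a full pass changes nothing.

    Returns ``(final_table, rounds_used, converged)``. A fixed-point input
    converges after one round; ``converged`` is False when ``max_rounds``
    passes still changed something (e.g. an oscillation).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    current = a.restrict(m.ids)
    for round_no in range(1, max_rounds + 1):
        suggested, _ = classify_all(m, current, p)
        if all(suggested.get(i) == current.get(i) for i in m.ids):
            return suggested, round_no, True
        current = suggested
    return current, max_rounds, False


def results_to_frame(
    results: Sequence[ClassificationResult], original: AssignmentTable
) -> pd.DataFrame:
    """Tidy per-accession output: original vs suggested assignment."""
    return pd.DataFrame(
        {
            "accession_id": [r.focal for r in results],
            "original_assignment": [original.get(r.focal) for r in results],
            "suggested_assignment": [r.suggestion for r in results],
            "winning_proportion": [r.winning_proportion for r in results],
            "neighbor_count": [r.neighbor_count for r in results],
        }
    )


def relaxed(p: KernelParams) -> KernelParams:
    """Copy of ``p`` in relaxed-undetermined evaluation mode."""
    return replace(p, relaxed_undetermined=True)
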