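"""Method comparison statistics and robustness experiments.

Implements the W50 statistic (how many accessions can be drawn at random
before the odds of hitting an assignment that disagrees with a reference
exceed one half), summary statistics contrasting two relabelling methods
against the original passport assignments, and the label-reshuffle
experiment that measures how quickly each method degrades as an increasing
share of the input labels is randomly permuted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baseline_classifiers import (
    KnnParams,
    UpgmaParams,
    knn_classify,
    upgma_classify,
)
from .data_model import AssignmentTable, DistanceMatrix
from .kernel_classifier import KernelParams, classify_all

#: A classifier as the evaluation machinery sees it.
Classifier = Callable[[DistanceMatrix, AssignmentTable], AssignmentTable]


def kernel_classifier(p: KernelParams) -> Classifier:
    """Wrap kernel parameters into a ``(matrix, table) -> table`` callable."""

    def run(m: DistanceMatrix, a: AssignmentTable) -> AssignmentTable:
        return classify_all(m, a, p)[0]

    return run


def knn_classifier(p: KnnParams) -> Classifier:
    def run(m: DistanceMatrix, a: AssignmentTable) -> AssignmentTable:
        return knn_classify(m, a, p)

    return run


def upgma_classifier(p: UpgmaParams) -> Classifier:
    def run(m: DistanceMatrix, a: AssignmentTable) -> AssignmentTable:
        return upgma_classify(m, a, p)

    return run


# ---------------------------------------------------------------------------
# W50
# ---------------------------------------------------------------------------


def w50(
    labels: AssignmentTable,
    reference: AssignmentTable,
    exclusions: Iterable[str] = (),
) -> int:
    """Largest clean random sample size under a disagreement-free criterion.

    With ``N`` accessions of which ``E`` disagree with the reference, draws
    are without replacement, so the probability that ``n`` draws contain no
    disagreement is hypergeometric:
    ``P(clean, n) = C(N-E, n) / C(N, n)``. Returns the largest ``n`` with
    ``P(clean, n) >= 0.5`` — the number of accessions one can pick before
    the odds of encountering an unintuitive assignment pass one half.
    ``E = 0`` gives ``N``; ``E = N`` gives 0.

    ``exclusions`` (e.g. a taxonomically mixed cluster) are removed from
    both tables before counting.
    """
    excluded = set(exclusions)
    ids = [i for i in reference.entries if i not in excluded]
    n_total = len(ids)
    if n_total == 0:
        raise ValueError("no accessions left after exclusions")
    errors = sum(1 for i in ids if labels.get(i) != reference.get(i))
    good = n_total - errors
    if errors == 0:
        return n_total
    p_clean = 1.0
    n = 0
    while n < good:
        p_next = p_clean * (good - n) / (n_total - n)
        if p_next < 0.5:
            break
        p_clean = p_next
        n += 1
    return n


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonStats:
    """Contrast of two relabelling methods against the original assignments.

    ``altered_fraction_*`` — share of accessions whose suggestion differs
    from the original assignment. ``agreement_on_altered`` — among the
    accessions method A altered, the share where method B arrived at the
    same final label (None when A altered nothing).
    ``undetermined_resolved_*`` — share of originally undetermined
    accessions given a determinate label (None when none were undetermined).
    """

    altered_fraction_a: float
    altered_fraction_b: float
    agreement_on_altered: float | None
    undetermined_resolved_a: float | None
    undetermined_resolved_b: float | None


def comparison_stats(
    original: AssignmentTable,
    method_a: AssignmentTable,
    method_b: AssignmentTable,
    exclusions: Iterable[str] = (),
) -> ComparisonStats:
    excluded = set(exclusions)
    ids = [i for i in original.entries if i not in excluded]
    if not ids:
        raise ValueError("no accessions left after exclusions")

    def altered(method: AssignmentTable) -> list[str]:
        return [i for i in ids if method.get(i) != original.get(i)]

    altered_a = altered(method_a)
    altered_b = altered(method_b)
    agreement = None
    if altered_a:
        agreement = sum(
            1 for i in altered_a if method_b.get(i) == method_a.get(i)
        ) / len(altered_a)
    undetermined_ids = [i for i in ids if not original.is_determined(i)]
    resolved_a = resolved_b = None
    if undetermined_ids:
        resolved_a = sum(
            1 for i in undetermined_ids if method_a.is_determined(i)
        ) / len(undetermined_ids)
        resolved_b = sum(
            1 for i in undetermined_ids if method_b.is_determined(i)
        ) / len(undetermined_ids)
    return ComparisonStats(
        altered_fraction_a=len(altered_a) / len(ids),
        altered_fraction_b=len(altered_b) / len(ids),
        agreement_on_altered=agreement,
        undetermined_resolved_a=resolved_a,
        undetermined_resolved_b=resolved_b,
    )


# ---------------------------------------------------------------------------
# label-reshuffle robustness
# ---------------------------------------------------------------------------


@dataclass
class ShuffleRecord:
    rate: float
    replicate: int
    seed: int
    misassigned_fraction: float
    undetermined_fraction: float


@dataclass
class ShuffleCurve:
    """Degradation curve of one method across reshuffle rates."""

    method: str
    records: list[ShuffleRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "rate": [r.rate for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "seed": [r.seed for r in self.records],
                "misassigned_fraction": [r.misassigned_fraction for r in self.records],
                "undetermined_fraction": [r.undetermined_fraction for r in self.records],
            }
        )

    def mean_misassigned(self, rate: float) -> float:
        vals = [r.misassigned_fraction for r in self.records if r.rate == rate]
        if not vals:
            raise KeyError(f"no records at rate {rate}")
        return float(np.mean(vals))


def shuffle_labels(
    a: AssignmentTable, rate: float, rng: np.random.Generator
) -> AssignmentTable:
    """Randomly permute the labels of a fraction ``rate`` of accessions.

    ``ceil(rate * N)`` accessions are selected and their labels permuted
    *among themselves* — the label multiset is preserved, no labels are
    resampled or invented. Undetermined entries take part like any other.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    ids = sorted(a.entries)
    n_sel = math.ceil(rate * len(ids))
    if n_sel < 2:
        return AssignmentTable(dict(a.entries), a.undetermined)
    chosen = rng.choice(len(ids), size=n_sel, replace=False)
    labels = [a.entries[ids[i]] for i in chosen]
    order = rng.permutation(n_sel)
    entries = dict(a.entries)
    for pos, i in enumerate(chosen):
        entries[ids[i]] = labels[order[pos]]
    return AssignmentTable(entries, a.undetermined)


def shuffle_experiment(
    m: DistanceMatrix,
    a: AssignmentTable,
    reference: AssignmentTable,
    methods: Mapping[str, Classifier],
    rates: Sequence[float],
    replicates: int = 10,
    seed: int = 0,
    exclusions: Iterable[str] = (),
) -> dict[str, ShuffleCurve]:
    """Measure each method's degradation under label reshuffling.

    For every rate and replicate, a random fraction of the input labels is
    permuted, each classifier is run on the noised table, and the resulting
    misassigned fraction (determined suggestion disagreeing with the
    reference) and undetermined fraction are recorded over the non-excluded
    accessions. Classifiers should be configured in relaxed-undetermined
    mode so the comparison focuses on misassignment rather than on each
    method's abstention habits. The reference is conventionally the kernel
    classifier's output on the clean data.
    """
    excluded = set(exclusions)
    eval_ids = [i for i in m.ids if i not in excluded]
    if not eval_ids:
        raise ValueError("no accessions left after exclusions")
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(len(rates), replicates))
    curves = {name: ShuffleCurve(name, []) for name in methods}
    for ri, rate in enumerate(rates):
        for rep in range(replicates):
            rep_seed = int(rep_seeds[ri, rep])
            rng = np.random.default_rng(rep_seed)
            noised = shuffle_labels(a, rate, rng)
            for name, classify in methods.items():
                out = classify(m, noised)
                mis = sum(
                    1
                    for i in eval_ids
                    if out.is_determined(i) and out.get(i) != reference.get(i)
                ) / len(eval_ids)
                und = sum(1 for i in eval_ids if not out.is_determined(i)) / len(
                    eval_ids
                )
                curves[name].records.append(
                    ShuffleRecord(
                        rate=float(rate),
                        replicate=rep,
                        seed=rep_seed,
                        misassigned_fraction=mis,
                        undetermined_fraction=und,
                    )
                )
    return curves


def curves_to_frame(curves: Mapping[str, ShuffleCurve]) -> pd.DataFrame:
    """Stack shuffle curves into one tidy frame for export or plotting."""
    return pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
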