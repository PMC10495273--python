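"""Deme-structured synthetic genotype and distance data.

Generates benchmark inputs that emulate the class of data the classifiers
are built for: a handful of genetic demes of highly unequal sizes (one
dominant taxon and a tiny relict one), an admixed deme carrying a mixture
of taxon labels, passport noise (mislabels and undetermined entries),
exact-duplicate accessions, and a few invalid distance cells.

Demes follow a Balding–Nichols-style drift model: per-marker ancestral
allele frequencies are drawn uniformly, each deme's frequencies are Beta
perturbations of them governed by a single divergence parameter, and
diploid dosages are binomial draws. Identity-by-state distance between two
accessions is the mean absolute dosage difference over markers, divided by
two, so it lies in [0, 1].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baseline_classifiers import KnnParams, UpgmaParams
from .data_model import (
    UNDETERMINED,
    AssignmentTable,
    DistanceMatrix,
    DuplicateSets,
)
from .kernel_classifier import KernelParams

PRESETS = ("capsicum_like", "two_deme_toy", "tiny_worked")


@dataclass
class DemeSpec:
    """One genetic deme.

    ``divergence`` is the Balding–Nichols drift parameter (an F_ST-like
    quantity in [0, 1); 0 keeps the ancestral frequencies). ``admixture``
    makes the deme's frequencies a weighted mixture of other, non-admixed
    demes' frequencies. ``label_mixture`` draws members' true taxon labels
    from a weighted pool instead of using ``name`` — how a genetically
    coherent but taxonomically mixed cluster is emulated. ``parent`` makes
    the deme drift from another deme's frequencies instead of the ancestral
    ones, producing a sister-taxon pair that sits closer to its parent than
    to anything else (the situation in which nearest-neighbour voting with
    large ``k`` absorbs a small taxon into its bigger sister).
    """

    name: str
    size: int
    divergence: float = 0.2
    admixture: dict[str, float] | None = None
    label_mixture: dict[str, float] | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("deme size must be >= 1")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")
        for weights in (self.admixture, self.label_mixture):
            if weights is not None:
                if abs(sum(weights.values()) - 1.0) > 1e-9:
                    raise ValueError("mixture weights must sum to 1")


@dataclass
class NoiseSpec:
    """Passport-noise configuration: fractions of accessions whose labels
    are replaced by a random wrong taxon or by the undetermined sentinel
    (disjoint selections), and the number of exact-duplicate groups."""

    mislabel_rate: float = 0.0
    undetermined_rate: float = 0.0
    duplicate_groups: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mislabel_rate <= 1 or not 0 <= self.undetermined_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.mislabel_rate + self.undetermined_rate > 1:
            raise ValueError("mislabel_rate + undetermined_rate must be <= 1")


def simulate_genotypes(
    demes: Sequence[DemeSpec], n_markers: int, seed: int
) -> tuple[np.ndarray, list[str]]:
    """Draw diploid dosage genotypes (0/1/2) for all deme members.

    Returns ``(genotypes, true_labels)`` with one row per accession, demes
    concatenated in the given order. Ancestral frequencies are uniform on
    (0.05, 0.95); a deme with divergence ``F > 0`` draws its frequencies
    from ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` so that drift has mean ``p`` and
    variance ``F p (1-p)``. Admixed demes average the frequencies of their
    parent demes (parents must not themselves be admixed).
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    freqs: dict[str, np.ndarray] = {}
    for deme in demes:
        if deme.admixture is not None:
            continue
        if deme.parent is None:
            base = p_anc
        else:
            if deme.parent not in freqs:
                raise ValueError(
                    f"parent deme {deme.parent!r} of {deme.name!r} must be "
                    "simulated first"
                )
            base = freqs[deme.parent]
        if deme.divergence == 0:
            freqs[deme.name] = base.copy()
        else:
            ratio = (1 - deme.divergence) / deme.divergence
            # clip keeps the Beta parameters valid at frequencies drifted
            # close to fixation by a parent deme
            b = np.clip(base, 0.01, 0.99)
            freqs[deme.name] = rng.beta(b * ratio, (1 - b) * ratio)
    for deme in demes:
        if deme.admixture is None:
            continue
        mixed = np.zeros(n_markers)
        for parent, weight in deme.admixture.items():
            if parent not in freqs:
                raise ValueError(f"admixture parent {parent!r} is not a simulated deme")
            mixed += weight * freqs[parent]
        freqs[deme.name] = mixed
    genotypes = []
    labels: list[str] = []
    for deme in demes:
        genotypes.append(rng.binomial(2, freqs[deme.name], size=(deme.size, n_markers)))
        if deme.label_mixture is None:
            labels.extend([deme.name] * deme.size)
        else:
            pool = sorted(deme.label_mixture)
            weights = [deme.label_mixture[t] for t in pool]
            labels.extend(rng.choice(pool, size=deme.size, p=weights).tolist())
    return np.vstack(genotypes).astype(np.int8), labels


def ibs_distance(genotypes: np.ndarray, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Identity-by-state distance: mean |dosage difference| / 2 over markers.

    0 for identical genotypes, 1 for opposite homozygotes at every marker.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D accessions × markers array")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotype dosages must be 0, 1 or 2")
    n, n_markers = g.shape
    # |a-b| over {0,1,2} decomposes into indicator products: pairs differing
    # by 1 (het vs hom) and by 2 (opposite homozygotes).
    hom0 = (g == 0).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    one_apart = het @ (hom0 + hom2).T
    two_apart = hom0 @ hom2.T
    total = one_apart + one_apart.T + 2.0 * (two_apart + two_apart.T)
    values = total / (2.0 * n_markers)
    np.fill_diagonal(values, 0.0)
    if ids is None:
        ids = [f"ACC{i:05d}" for i in range(n)]
    return DistanceMatrix(list(ids), values)


def corrupt_labels(
    true_labels: AssignmentTable,
    noise: NoiseSpec,
    mislabel_weights: dict[str, float] | None = None,
) -> AssignmentTable:
    """Inject passport noise into a table of true labels.

    A seeded draw selects disjoint sets of accessions: mislabelled ones
    receive a random *different* taxon from the labels present,
    undetermined ones receive the sentinel. Counts are
    ``round(rate * N)`` each, so the noise level is exact by construction.

    By default the wrong taxon is drawn uniformly. ``mislabel_weights``
    biases the draw (weights are renormalised over the candidate wrong
    taxa); weighting by taxon abundance mimics real passport errors, which
    overwhelmingly carry common crop names rather than rare wild ones.
    """
    ids = sorted(true_labels.entries)
    n = len(ids)
    n_mis = int(round(noise.mislabel_rate * n))
    n_und = int(round(noise.undetermined_rate * n))
    rng = np.random.default_rng(noise.seed)
    chosen = rng.choice(n, size=n_mis + n_und, replace=False)
    taxa = sorted(true_labels.taxa())
    entries = dict(true_labels.entries)
    for i in chosen[:n_mis]:
        accession = ids[i]
        others = [t for t in taxa if t != entries[accession]]
        if mislabel_weights is None:
            entries[accession] = others[int(rng.integers(len(others)))]
        else:
            w = np.array([mislabel_weights.get(t, 0.0) for t in others], dtype=float)
            if w.sum() <= 0:
                raise ValueError("mislabel_weights give no mass to any wrong taxon")
            entries[accession] = others[int(rng.choice(len(others), p=w / w.sum()))]
    for i in chosen[n_mis:]:
        entries[ids[i]] = true_labels.undetermined
    return AssignmentTable(entries, true_labels.undetermined)


@dataclass
class Benchmark:
    """A complete synthetic fixture plus its recommended classifier settings."""

    preset: str
    seed: int
    matrix: DistanceMatrix
    labels: AssignmentTable          # noisy passport labels, the classifier input
    true_labels: AssignmentTable     # ground truth behind the noise
    duplicates: DuplicateSets
    demes: dict[str, str]            # accession -> deme name (incl. duplicates)
    mixed_ids: frozenset[str]        # members of the taxonomically mixed deme
    kernel_params: KernelParams
    knn_params: KnnParams
    upgma_params: UpgmaParams
    noise: NoiseSpec = field(default_factory=NoiseSpec)


# Fixture geometry and classifier settings for the flagship benchmark.
# Deme sizes echo a collection dominated by one crop species with a
# seven-member relict taxon; divergence and marker count give demes that
# are cleanly separated in IBS space while keeping desk-scale runtimes.
_CAPSICUM_SIZES = {
    "C. annuum": 2000,
    "C. frutescens": 400,
    "C. chinense": 300,
    "mixed": 150,
    "C. chacoense": 30,
    "C. eximium": 7,
}
_CAPSICUM_MARKERS = 1000
_CAPSICUM_DIVERGENCE = 0.3
_CAPSICUM_SISTER_DIVERGENCE = 0.20  # C. eximium drifts from C. chacoense
_CAPSICUM_NOISE = dict(mislabel_rate=0.05, undetermined_rate=0.10, duplicate_groups=20)
# Kernel settings calibrated once on this fixture (see docs/methods.md).
# d encompasses all demes so that a scattered wrong label's inverse-frequency
# boost is cancelled by its own taxon's full in-neighbourhood count, while
# lambda damps those far members' weights; r sits below the typical winning
# share inside pure demes but above the shares seen in the admixed deme.
_CAPSICUM_KERNEL = KernelParams(lambda_decay=40.0, d=0.35, r=0.5, k=math.inf)
_CAPSICUM_KNN = KnnParams(k=6, r=4 / 6)
_CAPSICUM_UPGMA = UpgmaParams(height_cutoff=0.20, majority_fraction=0.8)
_CAPSICUM_NA_CELLS = 5  # accessions given invalid distance entries

_TOY_KERNEL = KernelParams(lambda_decay=40.0, d=0.35, r=0.5, k=math.inf)


def _capsicum_like(seed: int) -> Benchmark:
    ss = np.random.SeedSequence(seed)
    s_geno, s_noise, s_pick = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    demes = [
        DemeSpec("C. annuum", _CAPSICUM_SIZES["C. annuum"], _CAPSICUM_DIVERGENCE),
        DemeSpec("C. frutescens", _CAPSICUM_SIZES["C. frutescens"], _CAPSICUM_DIVERGENCE),
        DemeSpec("C. chinense", _CAPSICUM_SIZES["C. chinense"], _CAPSICUM_DIVERGENCE),
        DemeSpec(
            "mixed",
            _CAPSICUM_SIZES["mixed"],
            admixture={"C. annuum": 0.5, "C. frutescens": 0.5},
            label_mixture={"C. annuum": 0.5, "C. frutescens": 0.3, "C. chinense": 0.2},
        ),
        DemeSpec("C. chacoense", _CAPSICUM_SIZES["C. chacoense"], _CAPSICUM_DIVERGENCE),
        DemeSpec(
            "C. eximium",
            _CAPSICUM_SIZES["C. eximium"],
            _CAPSICUM_SISTER_DIVERGENCE,
            parent="C. chacoense",
        ),
    ]
    genotypes, labels = simulate_genotypes(demes, _CAPSICUM_MARKERS, s_geno)
    deme_of = [d.name for d in demes for _ in range(d.size)]
    ids = [f"ACC{i:05d}" for i in range(len(labels))]

    # exact-duplicate accessions: copy rows before computing distances
    rng = np.random.default_rng(s_pick)
    n_groups = _CAPSICUM_NOISE["duplicate_groups"]
    sources = rng.choice(len(ids), size=n_groups, replace=False)
    dup_rows = genotypes[sources]
    dup_ids = [f"{ids[i]}D" for i in sources]
    genotypes = np.vstack([genotypes, dup_rows])
    labels = labels + [labels[i] for i in sources]
    deme_of = deme_of + [deme_of[i] for i in sources]
    all_ids = ids + dup_ids
    duplicates = DuplicateSets(
        [frozenset({ids[i], f"{ids[i]}D"}) for i in sources]
    )

    matrix = ibs_distance(genotypes, all_ids)
    true = AssignmentTable(dict(zip(all_ids, labels)), UNDETERMINED)
    noise = NoiseSpec(seed=s_noise, **_CAPSICUM_NOISE)
    # passport errors carry common names far more often than rare ones:
    # weight wrong-taxon draws by taxon abundance
    abundance = Counter(true.entries.values())
    noisy = corrupt_labels(
        true, noise, mislabel_weights={t: float(abundance[t]) for t in true.taxa()}
    )

    # a few invalid cells so curation has something to trim; keep them away
    # from duplicate groups so collapsing stays well-defined after trimming
    eligible = [i for i, a in enumerate(all_ids) if a not in duplicates.members()]
    na_targets = rng.choice(eligible, size=_CAPSICUM_NA_CELLS, replace=False)
    for i in na_targets:
        n_cells = int(rng.integers(1, 4))
        partners = rng.choice(matrix.n, size=n_cells, replace=False)
        for j in partners:
            if j != i:
                matrix.values[i, j] = matrix.values[j, i] = np.nan

    mixed_ids = frozenset(a for a, d in zip(all_ids, deme_of) if d == "mixed")
    return Benchmark(
        preset="capsicum_like",
        seed=seed,
        matrix=matrix,
        labels=noisy,
        true_labels=true,
        duplicates=duplicates,
        demes=dict(zip(all_ids, deme_of)),
        mixed_ids=mixed_ids,
        kernel_params=_CAPSICUM_KERNEL,
        knn_params=_CAPSICUM_KNN,
        upgma_params=_CAPSICUM_UPGMA,
        noise=noise,
    )


def _two_deme_toy(seed: int) -> Benchmark:
    ss = np.random.SeedSequence(seed)
    s_geno, s_noise = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    demes = [DemeSpec("deme_A", 20, 0.3), DemeSpec("deme_B", 20, 0.3)]
    genotypes, labels = simulate_genotypes(demes, 300, s_geno)
    ids = [f"T{i:03d}" for i in range(40)]
    matrix = ibs_distance(genotypes, ids)
    true = AssignmentTable(dict(zip(ids, labels)), UNDETERMINED)
    noise = NoiseSpec(mislabel_rate=0.05, undetermined_rate=0.10, seed=s_noise)
    return Benchmark(
        preset="two_deme_toy",
        seed=seed,
        matrix=matrix,
        labels=corrupt_labels(true, noise),
        true_labels=true,
        duplicates=DuplicateSets([]),
        demes={a: d.name for a, d in zip(ids, [demes[0]] * 20 + [demes[1]] * 20)},
        mixed_ids=frozenset(),
        kernel_params=_TOY_KERNEL,
        knn_params=KnnParams(k=6, r=4 / 6),
        upgma_params=UpgmaParams(height_cutoff=0.26, majority_fraction=0.8),
        noise=noise,
    )


def _tiny_worked(seed: int) -> Benchmark:
    """Eleven accessions realising the canonical ten-neighbour geometry.

    A focal accession has ten determined neighbours within ``d = 0.2``,
    four of taxon A and six of taxon B; everything else sits at 0.25. With
    ``lambda = 0`` and normalisation on, A's total is scaled by 10/4 and
    B's by 10/6 — an exact tie, hence an undetermined suggestion.
    """
    ids = ["FOCAL"] + [f"A{i}" for i in range(1, 5)] + [f"B{i}" for i in range(1, 7)]
    n = len(ids)
    values = np.full((n, n), 0.25)
    focal_d = [0.05, 0.08, 0.11, 0.14, 0.06, 0.09, 0.10, 0.12, 0.13, 0.15]
    values[0, 1:] = values[1:, 0] = focal_d
    np.fill_diagonal(values, 0.0)
    matrix = DistanceMatrix(ids, values)
    labels = {"FOCAL": UNDETERMINED}
    labels.update({f"A{i}": "taxon_A" for i in range(1, 5)})
    labels.update({f"B{i}": "taxon_B" for i in range(1, 7)})
    table = AssignmentTable(labels, UNDETERMINED)
    true = AssignmentTable({**labels, "FOCAL": "taxon_B"}, UNDETERMINED)
    return Benchmark(
        preset="tiny_worked",
        seed=seed,
        matrix=matrix,
        labels=table,
        true_labels=true,
        duplicates=DuplicateSets([]),
        demes={a: ("A" if a.startswith("A") else "B") for a in ids},
        mixed_ids=frozenset(),
        kernel_params=KernelParams(lambda_decay=0.0, d=0.2, r=0.66, k=math.inf),
        knn_params=KnnParams(k=6, r=4 / 6),
        upgma_params=UpgmaParams(height_cutoff=0.2, majority_fraction=0.8),
    )


def make_benchmark(preset: str, seed: int) -> Benchmark:
    """Build a named benchmark fixture, fully determined by ``seed``."""
    builders = {
        "capsicum_like": _capsicum_like,
        "two_deme_toy": _two_deme_toy,
        "tiny_worked": _tiny_worked,
    }
    try:
        builder = builders[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose one of {', '.join(PRESETS)}"
        ) from None
    return builder(seed)
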