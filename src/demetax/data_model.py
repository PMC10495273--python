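"""Core data containers and curation steps.

This module defines the three tabular objects the rest of the package
operates on — a labelled pairwise genetic distance matrix, a passport
assignment table, and sets of known duplicate accessions — together with
delimited-text readers/writers and the curation operations applied before
classification: trimming accessions whose rows contain invalid (missing)
distance entries, collapsing each duplicate set to a single randomly chosen
representative, and propagating final assignments back to all duplicates.

Missing distances are stored as ``NaN``; the :attr:`DistanceMatrix.mask`
property exposes them as a boolean array.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved sentinel for accessions without a taxon assignment.
UNDETERMINED = "undetermined"

#: Absolute tolerance for symmetry of distance matrices read from text.
SYMMETRY_ATOL = 1e-8


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise genetic distances.

    Parameters
    ----------
    ids:
        Unique accession identifiers, one per row/column.
    values:
        ``(n, n)`` float array of nonnegative distances. ``NaN`` marks a
        missing (invalid) entry. Must be symmetric within
        :data:`SYMMETRY_ATOL`; small asymmetries are averaged away. The
        diagonal is forced to zero (an accession's distance to itself).
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"distance matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(self.ids):
            raise ValidationError(
                f"{len(self.ids)} identifiers but matrix dimension {v.shape[0]}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("accession identifiers must be unique")
        # NaN pattern must itself be symmetric: a distance is missing for a
        # pair, not for an ordered pair.
        nan = np.isnan(v)
        bad = nan ^ nan.T
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"asymmetric missing entry between {self.ids[i]!r} and {self.ids[j]!r}"
            )
        both = ~nan & ~nan.T
        diff = np.zeros_like(v)
        diff[both] = np.abs(v - v.T)[both]
        if diff.max(initial=0.0) > SYMMETRY_ATOL:
            i, j = np.unravel_index(np.argmax(diff), diff.shape)
            raise ValidationError(
                "matrix asymmetric beyond tolerance "
                f"{SYMMETRY_ATOL:g}: worst cell ({self.ids[i]!r}, {self.ids[j]!r}) "
                f"with |difference| = {diff[i, j]:.3g}"
            )
        v = np.where(both, (v + v.T) / 2.0, v)  # average out text round-off
        np.fill_diagonal(v, 0.0)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < 0:
                raise ValidationError("distances must be nonnegative")
        self.values = v
        self._index = {a: i for i, a in enumerate(self.ids)}

    # -- basic queries ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array flagging missing entries."""
        return np.isnan(self.values)

    def index(self, accession: str) -> int:
        try:
            return self._index[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} not in distance matrix") from None

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        """Restrict to ``keep`` (original row order is preserved)."""
        keep_set = set(keep)
        missing = keep_set - set(self.ids)
        if missing:
            raise KeyError(f"accessions not in matrix: {sorted(missing)}")
        idx = [i for i, a in enumerate(self.ids) if a in keep_set]
        return DistanceMatrix([self.ids[i] for i in idx], self.values[np.ix_(idx, idx)])


@dataclass
class AssignmentTable:
    """Mapping accession identifier → taxon label.

    A reserved sentinel (``undetermined`` by default) marks accessions with
    no usable taxon assignment. Accessions absent from the table are treated
    as undetermined by :meth:`get`.
    """

    entries: dict[str, str]
    undetermined: str = UNDETERMINED

    def __post_init__(self) -> None:
        self.entries = {str(k): str(v) for k, v in self.entries.items()}

    def get(self, accession: str) -> str:
        return self.entries.get(accession, self.undetermined)

    def is_determined(self, accession: str) -> bool:
        return self.get(accession) != self.undetermined

    def determined_ids(self) -> list[str]:
        return [a for a, t in self.entries.items() if t != self.undetermined]

    def taxa(self) -> set[str]:
        """Set of distinct determined taxon labels."""
        return {t for t in self.entries.values() if t != self.undetermined}

    def restrict(self, ids: Iterable[str]) -> "AssignmentTable":
        """Entries for ``ids`` only; missing accessions become undetermined."""
        return AssignmentTable({a: self.get(a) for a in ids}, self.undetermined)

    def with_updates(self, updates: Mapping[str, str]) -> "AssignmentTable":
        merged = dict(self.entries)
        merged.update({str(k): str(v) for k, v in updates.items()})
        return AssignmentTable(merged, self.undetermined)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DuplicateSets:
    """Disjoint groups of accessions known to be duplicates of each other."""

    groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.groups = [frozenset(str(m) for m in g) for g in self.groups]
        seen: set[str] = set()
        for g in self.groups:
            if len(g) < 2:
                raise ValidationError("duplicate groups need at least two members")
            if seen & g:
                raise ValidationError(
                    f"duplicate groups overlap on {sorted(seen & g)}"
                )
            seen |= g

    def members(self) -> set[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g
        return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_NA_TOKENS = ["NA", "N.A.", "nan", "NaN", ""]


def _sniff_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_distance_matrix(path: str, sep: str | None = None) -> DistanceMatrix:
    """Read a labelled square distance matrix from delimited text.

    The first row and first column must carry accession identifiers; cells
    are numeric or one of the recognised NA tokens (``NA``, ``nan``, empty).
    The delimiter is sniffed from the header when not given.
    """
    sep = _sniff_sep(path, sep)
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=_NA_TOKENS, keep_default_na=False
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path!r} as a delimited matrix: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"distance matrix must be square, got {df.shape[0]} rows × {df.shape[1]} columns"
        )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if set(row_ids) != set(col_ids):
        raise FormatError("row and column identifiers differ")
    df = df.loc[:, row_ids]  # align column order to row order
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path!r}: {exc}") from exc
    # Symmetrise the NA pattern: a missing score invalidates the pair.
    nan = np.isnan(values)
    values[nan.T] = np.nan
    return DistanceMatrix(row_ids, values)


def write_distance_matrix(m: DistanceMatrix, path: str, sep: str = ",") -> None:
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    df.to_csv(path, sep=sep, na_rep="NA")


def read_assignments(
    path: str,
    sep: str | None = None,
    undetermined: str = UNDETERMINED,
    id_column: str = "accession_id",
    taxon_column: str = "taxon",
) -> AssignmentTable:
    """Read an accession → taxon table (CSV with header)."""
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=_NA_TOKENS, keep_default_na=False, dtype=str)
    for col in (id_column, taxon_column):
        if col not in df.columns:
            raise FormatError(f"assignment table {path!r} lacks column {col!r}")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"accession {dup!r} appears more than once")
    taxa = df[taxon_column].fillna(undetermined)
    return AssignmentTable(dict(zip(ids, taxa)), undetermined)


def write_assignments(a: AssignmentTable, path: str, sep: str = ",") -> None:
    df = pd.DataFrame(
        {"accession_id": list(a.entries), "taxon": list(a.entries.values())}
    )
    df.to_csv(path, sep=sep, index=False)


def read_duplicate_sets(path: str, sep: str | None = None) -> DuplicateSets:
    """Read duplicate groups from a CSV with columns group_id, accession_id."""
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("group_id", "accession_id"):
        if col not in df.columns:
            raise FormatError(f"duplicate table {path!r} lacks column {col!r}")
    groups = [
        frozenset(sub["accession_id"]) for _, sub in df.groupby("group_id", sort=True)
    ]
    return DuplicateSets(groups)


def write_duplicate_sets(d: DuplicateSets, path: str, sep: str = ",") -> None:
    rows = []
    for gi, g in enumerate(d.groups):
        for m in sorted(g):
            rows.append({"group_id": f"g{gi:04d}", "accession_id": m})
    pd.DataFrame(rows, columns=["group_id", "accession_id"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def trim_invalid(
    m: DistanceMatrix, a: AssignmentTable
) -> tuple[DistanceMatrix, AssignmentTable]:
    """Drop accessions until no missing distance entries remain.

    Accessions are removed greedily, most missing cells first (ties broken
    by identifier), which is deterministic and near-minimal. A final pass
    re-adds any removed accession that conflicts only with other removed
    accessions, so the result is locally maximal: re-adding any removed
    accession would reintroduce a missing cell.
    """
    mask = m.mask.copy()
    np.fill_diagonal(mask, False)
    alive = np.ones(m.n, dtype=bool)
    removed: list[int] = []
    while True:
        counts = (mask & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        worst = counts.max()
        if worst == 0:
            break
        tied = np.flatnonzero(counts == worst)
        victim = min(tied, key=lambda i: m.ids[i])
        alive[victim] = False
        removed.append(victim)
    # local-maximality pass: restore accessions whose conflicts are all gone
    for i in sorted(removed, key=lambda i: m.ids[i]):
        if not mask[i, alive].any():
            alive[i] = True
    survivors = [m.ids[i] for i in np.flatnonzero(alive)]
    if not survivors:
        raise ValidationError("no accessions survive NA trimming")
    return m.submatrix(survivors), a.restrict(survivors)


def collapse_duplicates(
    m: DistanceMatrix,
    a: AssignmentTable,
    dups: DuplicateSets,
    seed: int,
) -> tuple[DistanceMatrix, AssignmentTable, dict[str, frozenset[str]]]:
    """Replace each duplicate group by one randomly chosen representative.

    Returns the reduced matrix and table plus a mapping
    ``representative → full group`` for later back-propagation of the
    representative's final assignment. The draw is seeded for
    reproducibility; record the seed alongside published assignments.
    """
    for g in dups.groups:
        for member in sorted(g):
            if member not in m:
                raise KeyError(
                    f"duplicate-group member {member!r} absent from distance matrix"
                )
    rng = np.random.default_rng(seed)
    mapping: dict[str, frozenset[str]] = {}
    drop: set[str] = set()
    for g in sorted(dups.groups, key=lambda g: sorted(g)):
        members = sorted(g)
        rep = members[int(rng.integers(len(members)))]
        mapping[rep] = g
        drop |= set(members) - {rep}
    survivors = [i for i in m.ids if i not in drop]
    return m.submatrix(survivors), a.restrict(survivors), mapping


def propagate_assignments(
    final: AssignmentTable, mapping: Mapping[str, frozenset[str]]
) -> AssignmentTable:
    """Copy each representative's final assignment to its whole duplicate set."""
    updates: dict[str, str] = {}
    for rep, group in mapping.items():
        if rep not in final.entries:
            raise KeyError(f"representative {rep!r} missing from final assignments")
        label = final.entries[rep]
        for member in group:
            updates[member] = label
    return final.with_updates(updates)
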