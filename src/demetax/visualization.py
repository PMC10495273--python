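"""t-SNE embedding of distance matrices and assignment-coloured scatter plots.

The embedding is the instrument for judging whether assignments are
"intuitive": genetic demes appear as coherent point clouds, and a sensible
assignment scheme colours each cloud homogeneously. The distance matrix is
consumed directly as precomputed distances — no re-embedding through a
feature space — and the initialisation is seeded so figures reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe; no-op if a GUI backend is active

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .data_model import AssignmentTable, DistanceMatrix


@dataclass
class Embedding:
    """2-D coordinates for each accession (arbitrary units)."""

    ids: list[str]
    coords: np.ndarray
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be N×2 with one row per identifier")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")


def tsne_embed(m: DistanceMatrix, perplexity: float = 30.0, seed: int = 0) -> Embedding:
    """Embed a distance matrix in two dimensions with t-SNE.

    Requires ``N > 3 * perplexity`` (the standard t-SNE constraint) and a
    matrix with no missing entries. Deterministic for a given seed.
    """
    if m.mask.any():
        raise ValueError("matrix contains missing entries; run trim_invalid first")
    if not m.n > 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {m.n} accessions: "
            "t-SNE requires N > 3 * perplexity"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    coords = tsne.fit_transform(m.values)
    return Embedding(list(m.ids), coords, perplexity, seed)


def write_embedding(e: Embedding, path: str) -> None:
    pd.DataFrame(
        {"accession_id": e.ids, "x": e.coords[:, 0], "y": e.coords[:, 1]}
    ).to_csv(path, index=False)


def read_embedding(path: str, perplexity: float = float("nan"), seed: int = -1) -> Embedding:
    df = pd.read_csv(path, dtype={"accession_id": str})
    return Embedding(
        list(df["accession_id"]), df[["x", "y"]].to_numpy(), perplexity, seed
    )


def plot_assignments(
    e: Embedding,
    tables: AssignmentTable | Sequence[AssignmentTable],
    out: str,
    titles: Sequence[str] | None = None,
    point_size: float = 4.0,
) -> str:
    """Scatter the embedding once per assignment table, coloured by taxon.

    All panels share coordinates and the taxon → colour mapping, so the
    same taxon keeps its colour across panels. Undetermined accessions are
    drawn in grey at reduced opacity to keep deme structure visible.
    Every table must cover every embedded accession.
    """
    if isinstance(tables, AssignmentTable):
        tables = [tables]
    if not tables:
        raise ValueError("need at least one assignment table")
    for t in tables:
        missing = [i for i in e.ids if i not in t.entries]
        if missing:
            shown = ", ".join(missing[:5]) + ("…" if len(missing) > 5 else "")
            raise KeyError(
                f"assignment table missing {len(missing)} embedded accessions: {shown}"
            )
    taxa = sorted(set().union(*(t.taxa() for t in tables)))
    cmap = plt.get_cmap("tab20")
    colors = {t: cmap(i % 20) for i, t in enumerate(taxa)}

    n_panels = len(tables)
    ncols = min(n_panels, 2)
    nrows = -(-n_panels // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(6 * ncols, 5 * nrows), squeeze=False
    )
    for ax in axes.flat[n_panels:]:
        ax.set_visible(False)
    for panel, (table, ax) in enumerate(zip(tables, axes.flat)):
        labels = np.array([table.get(i) for i in e.ids])
        undet = labels == table.undetermined
        ax.scatter(
            e.coords[undet, 0], e.coords[undet, 1],
            s=point_size, c="0.6", alpha=0.35, label=table.undetermined,
        )
        for taxon in taxa:
            sel = labels == taxon
            if sel.any():
                ax.scatter(
                    e.coords[sel, 0], e.coords[sel, 1],
                    s=point_size, color=colors[taxon], label=taxon,
                )
        ax.set_xticks([])
        ax.set_yticks([])
        if titles is not None and panel < len(titles):
            ax.set_title(titles[panel])
    handles, labels_ = axes.flat[0].get_legend_handles_labels()
    fig.legend(handles, labels_, loc="outside right upper", markerscale=3, frameon=False)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
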