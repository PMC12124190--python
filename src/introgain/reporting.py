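"""Summary tables and figures: presence matrices, age/length/position counts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .errors import NotFoundError
from .gain_inference import GainEvent
from .marker_alignment import ABSENT, PRESENT, PresenceMatrix

# deterministic SVG output
matplotlib.rcParams["svg.hashsalt"] = "introgain"

_STATUS_CODE = {PRESENT: 0, ABSENT: 1}
_CMAP = ListedColormap(["#c22222", "#2244cc", "#aaaaaa"])  # present, absent, uncovered


def render_matrix(matrix: PresenceMatrix, tree, path: str | Path) -> Path:
    """Draw the species × intron grid (red present, blue absent, grey uncovered).

    Rows follow the tree's leaf traversal order; every matrix species must be
    a leaf of the tree.
    """
    if not matrix.ordinals:
        raise ValueError("cannot render an empty presence matrix")
    tree_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(matrix.species) - set(tree_order)
    if missing:
        raise NotFoundError(f"species missing from tree: {sorted(missing)}")
    species = [sp for sp in tree_order if sp in set(matrix.species)]
    grid = np.full((len(species), len(matrix.ordinals)), 2, dtype=int)
    for i, sp in enumerate(species):
        for j, k in enumerate(matrix.ordinals):
            grid[i, j] = _STATUS_CODE.get(matrix.status(k, sp), 2)
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.5 * len(matrix.ordinals) + 2), max(2.0, 0.3 * len(species) + 1))
    )
    ax.imshow(grid, cmap=_CMAP, vmin=0, vmax=2, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(len(matrix.ordinals)), [str(k) for k in matrix.ordinals])
    ax.set_yticks(range(len(species)), species, fontsize=7)
    ax.set_xlabel("focal intron ordinal")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
    return path


@dataclass
class EventSummary:
    """Per-event features plus binned counts for reporting."""

    table: pd.DataFrame  #: gene, ordinal, intron_length, relative_position, clade_age
    age_hist: tuple[np.ndarray, np.ndarray]
    length_hist: tuple[np.ndarray, np.ndarray]
    position_hist: tuple[np.ndarray, np.ndarray]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


def summarize_events(events: list[GainEvent], *, age_bins=5, length_bins=10,
                     position_bins=10) -> EventSummary:
    """Tabulate intron length, relative position and clade age per event.

    Relative position is the intron's protein-coordinate index divided by
    the protein length, in [0, 1]. Histogram counts always sum to the number
    of events.
    """
    rows = []
    for e in events:
        if e.protein_index is None or e.protein_length is None:
            raise ValueError(f"event {e.gene}:{e.ordinal} lacks position information")
        rel = e.protein_index / e.protein_length
        if not 0.0 <= rel <= 1.0:
            raise ValueError(f"relative position {rel} outside [0, 1]")
        rows.append(
            {
                "gene": e.gene,
                "intron_ordinal": e.ordinal,
                "intron_length": e.intron_length,
                "relative_position": rel,
                "clade_age": e.clade_age,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "intron_ordinal", "intron_length",
                       "relative_position", "clade_age"]
    )
    ages = table["clade_age"].fillna(0.0).to_numpy(dtype=float) if rows else np.array([])
    lengths = table["intron_length"].to_numpy(dtype=float) if rows else np.array([])
    positions = table["relative_position"].to_numpy(dtype=float) if rows else np.array([])
    return EventSummary(
        table=table,
        age_hist=np.histogram(ages, bins=age_bins) if rows else (np.array([]), np.array([])),
        length_hist=np.histogram(lengths, bins=length_bins) if rows else (np.array([]), np.array([])),
        position_hist=(
            np.histogram(positions, bins=position_bins, range=(0.0, 1.0))
            if rows else (np.array([]), np.array([]))
        ),
    )


def plot_summary(summary: EventSummary, path: str | Path) -> Path:
    """Three-panel histogram figure (clade age, intron length, position)."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    for ax, (counts, edges), title in zip(
        axes,
        [summary.age_hist, summary.length_hist, summary.position_hist],
        ["clade age", "intron length (nt)", "relative position"],
    ):
        if len(counts):
            ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
                   color="#446688", edgecolor="white")
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
    return path
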