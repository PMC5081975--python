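"""Figures summarising a pairwise alignment comparison.

Four standard views are provided: a greyscale heatmap of the similarity
matrix S (dark diagonals mark regions of consensus), a categorical heatmap of
the dissimilarity matrix D, a line plot of normalised per-column match (with
an optional cysteine-proportion track), and a stacked area plot of the
normalised merge/split/shift proportions.  A fifth plot shows per-column
sum-of-pairs retention.

All functions draw the underlying matrices and summaries as-is — the plotted
arrays are views of the computed data, never recomputations — and return the
matplotlib Figure.  Axis labels use 1-based column indices; in the similarity
heatmap comparison column 1 sits at the bottom.
"""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .core import CATEGORY_NAMES, Category, ComparisonResult

#: Colour-blind-safe categorical palette, keyed by category name and shared by
#: the dissimilarity heatmap and the stacked dissimilarity summary.
CATEGORY_COLOURS = {
    "match": "#4477AA",
    "conserved_gap": "#DDDDDD",
    "merge": "#EE6677",
    "split": "#CCBB44",
    "shift": "#AA3377",
}


def _new_axes(ax, figsize):
    if ax is not None:
        return ax.figure, ax
    fig, ax = plt.subplots(figsize=figsize)
    return fig, ax


def plot_similarity_heatmap(S: np.ndarray, ax=None, cmap: str = "Greys"):
    """Heatmap of the similarity matrix S.

    Reference columns run along x, comparison columns along y (column 1 at
    the bottom); intensity is the similarity fraction on a fixed 0-1 scale,
    so fully agreeing column pairs are darkest.
    """
    S = np.asarray(S)
    p, q = S.shape
    fig, ax = _new_axes(ax, (max(4, p / 12), max(3, q / 12)))
    im = ax.imshow(
        S.T,
        origin="lower",
        cmap=cmap,
        vmin=0.0,
        vmax=1.0,
        aspect="auto",
        interpolation="nearest",
        extent=(0.5, p + 0.5, 0.5, q + 0.5),
    )
    fig.colorbar(im, ax=ax, label="column similarity")
    ax.set_xlabel("reference column")
    ax.set_ylabel("comparison column")
    ax.set_title("Similarity matrix")
    return fig


def plot_dissimilarity_matrix(D: np.ndarray, ids=None, ax=None):
    """Discrete heatmap of the dissimilarity matrix D.

    Reference columns run along x and sequences along y (first sequence at
    the top); each cell is coloured by its category, with a legend.
    """
    D = np.asarray(D)
    n, p = D.shape
    fig, ax = _new_axes(ax, (max(4, p / 12), max(3, n / 8)))
    cmap = ListedColormap([CATEGORY_COLOURS[name] for name in CATEGORY_NAMES])
    ax.imshow(
        D,
        cmap=cmap,
        vmin=Category.MATCH,
        vmax=Category.SHIFT,
        aspect="auto",
        interpolation="nearest",
        extent=(0.5, p + 0.5, n + 0.5, 0.5),
    )
    handles = [
        Patch(facecolor=CATEGORY_COLOURS[name], label=name.replace("_", " "))
        for name in CATEGORY_NAMES
    ]
    ax.legend(handles=handles, bbox_to_anchor=(1.02, 1), loc="upper left")
    ax.set_xlabel("reference column")
    ax.set_ylabel("sequence")
    if ids is not None and len(ids) <= 40:
        ax.set_yticks(np.arange(1, n + 1), labels=list(ids), fontsize=6)
    ax.set_title("Dissimilarity matrix")
    return fig


def plot_similarity_summary(
    result: ComparisonResult, show_cysteine: bool = False, ax=None
):
    """Line plot of the normalised per-column match proportion.

    Columns consisting entirely of conserved gaps have no defined value and
    appear as breaks in the line.  With ``show_cysteine`` a second series
    traces the per-column cysteine proportion of the reference alignment.
    """
    p = result.p
    x = np.arange(1, p + 1)
    y = np.where(result.summaries.defined, result.summaries.match, np.nan)
    fig, ax = _new_axes(ax, (max(4, p / 12), 3))
    ax.plot(x, y, color=CATEGORY_COLOURS["match"], label="normalised match")
    if show_cysteine:
        ax.plot(
            x,
            result.cysteine,
            color="#DDAA33",
            linestyle="--",
            label="cysteine proportion",
        )
    ax.set_xlabel("reference column")
    ax.set_ylabel("proportion")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    ax.set_title("Similarity summary")
    return fig


def plot_dissimilarity_summary(result: ComparisonResult, ax=None):
    """Stacked area plot of normalised merge, split and shift per column.

    Stack colours follow :data:`CATEGORY_COLOURS`.  Undefined columns (all
    conserved gaps) appear as breaks; stack heights are bounded by 1.
    """
    p = result.p
    x = np.arange(1, p + 1)
    s = result.summaries
    defined = s.defined
    merge = np.where(defined, s.merge, np.nan)
    split = np.where(defined, s.split, np.nan)
    shift = np.where(defined, s.shift, np.nan)
    c1 = merge
    c2 = merge + split
    c3 = merge + split + shift
    fig, ax = _new_axes(ax, (max(4, p / 12), 3))
    ax.fill_between(x, 0, c1, where=defined, color=CATEGORY_COLOURS["merge"], label="merge")
    ax.fill_between(x, c1, c2, where=defined, color=CATEGORY_COLOURS["split"], label="split")
    ax.fill_between(x, c2, c3, where=defined, color=CATEGORY_COLOURS["shift"], label="shift")
    ax.set_xlabel("reference column")
    ax.set_ylabel("proportion of non-conserved-gap cells")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="upper right")
    ax.set_title("Dissimilarity summary")
    return fig


def plot_sps(result, ax=None):
    """Per-column sum-of-pairs retention over reference columns.

    Accepts a :class:`alncompare.pairscores.PairScoreResult` or anything with
    an ``sps_per_column`` array.  Columns with fewer than two residues have
    no defined value and appear as breaks; if no column has one, the figure
    carries a warning annotation instead of a line.
    """
    y = np.asarray(result.sps_per_column, dtype=float)
    p = y.size
    x = np.arange(1, p + 1)
    fig, ax = _new_axes(ax, (max(4, p / 12), 3))
    if np.isnan(y).all():
        ax.annotate(
            "no column holds two or more residues;\nsum of pairs undefined",
            xy=(0.5, 0.5),
            xycoords="axes fraction",
            ha="center",
        )
    else:
        ax.plot(x, y, color="#225555", label="per-column SPS")
        ax.legend(loc="lower right")
    ax.set_xlabel("reference column")
    ax.set_ylabel("retained pair fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Sum of pairs")
    return fig
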