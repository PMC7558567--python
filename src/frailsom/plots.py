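"""Hexagon-tiled component-plane rendering and PCA score plots.

Each component plane is drawn as the hexagonal map with its own
min-to-max colour scale: copper for the class planes, grayscale for the
feature planes (light = high value / positive finding, dark = low /
negative). Hexagon centres follow the odd-r offset geometry, alternate
rows shifted half a cell.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import RegularPolygon

from .som import SupervisedSOM

_CLASS_MARKERS = {1: ("o", "Non-frail"), 2: ("D", "Pre-frail"), 3: ("*", "Frail")}


def _draw_plane(ax, grid, values, vmin, vmax, cmap):
    coords = grid.plot_coords()
    span = vmax - vmin
    colors = (values - vmin) / span if span > 0 else np.full_like(values, 0.5)
    cm = plt.get_cmap(cmap)
    for (x, y), v in zip(coords, colors):
        ax.add_patch(
            RegularPolygon(
                (x, y), numVertices=6, radius=1 / np.sqrt(3),
                orientation=0.0, facecolor=cm(v), edgecolor="white", linewidth=0.4,
            )
        )
    ax.set_xlim(-1, grid.cols + 1)
    ax.set_ylim(-1, grid.rows * np.sqrt(3) / 2 + 1)
    ax.set_aspect("equal")
    ax.axis("off")


def render_hex_planes(som: SupervisedSOM, out_dir, variable_names=None) -> list[Path]:
    """Write one hexagon-tiled PNG per component plane (features + classes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for plane in som.component_planes(variable_names):
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        cmap = "copper" if plane.is_class_plane else "gray"
        _draw_plane(ax, som.grid_, plane.values, plane.vmin, plane.vmax, cmap)
        ax.set_title(plane.name, fontsize=9)
        path = out / f"{plane.name}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def render_pca_scores(point_sets: dict, path, explained=None) -> Path:
    """PC1-vs-PC2 score plot with one marker per frailty class."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for cls, (marker, label) in _CLASS_MARKERS.items():
        pts = point_sets.get(cls)
        if pts is not None and len(pts):
            ax.scatter(pts[:, 0], pts[:, 1], marker=marker, s=28, alpha=0.7, label=label)
    if explained is not None and len(explained) >= 2:
        ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    else:
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
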