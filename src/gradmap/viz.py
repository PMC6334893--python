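"""Gradient scatterplots and QC glass-brain figures.

Every plotting function returns the arrays that back the figure (positions,
color classes, intensities) so behavior can be tested without asserting
pixels; saving the PNG is a side effect when a path is given.  All modes plot
every atlas voxel — the scatterplot is the whole cerebellum, with the user's
cluster highlighted on top of neutral background points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .atlas import GradientAtlas, GradientCoordinates
from .volumes import QCReport

__all__ = [
    "PlotSpec",
    "scatter_binary",
    "scatter_continuous",
    "scatter_network",
    "scatter_multi",
    "glass_brain",
    "network_color_table",
]


def network_color_table() -> dict:
    """The 7-network label -> (name, color) table, stored as package data."""
    text = resources.files("gradmap").joinpath("data/network_colors.json").read_text()
    raw = json.loads(text)
    return {int(k): (v["name"], v["color"]) for k, v in raw.items()}


@dataclass
class PlotSpec:
    """Styling for gradient scatterplots.

    ``highlight_colors`` is per-cluster for multi mode (defaults to the
    matplotlib tab10 cycle); ``overlap_color`` marks voxels shared by several
    clusters in multi mode.
    """

    mode: str = "binary"
    background_color: str = "#d3d3d3"
    highlight_color: str = "red"
    highlight_colors: list = field(default_factory=list)
    overlap_color: str = "black"
    cmap: str = "Reds"
    point_size: float = 8.0
    path: str | None = None


def _axis_labels(coords: GradientCoordinates) -> tuple:
    return (f"Gradient {coords.axes[0]}", f"Gradient {coords.axes[1]}")


def _positions(coords: GradientCoordinates) -> np.ndarray:
    return coords.table[["g_x", "g_y"]].to_numpy()


def _save(fig, spec: PlotSpec, path) -> str | None:
    out = path if path is not None else spec.path
    if out is not None:
        fig.savefig(str(out), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return str(out) if out is not None else None


def scatter_binary(
    atlas: GradientAtlas,
    coords: GradientCoordinates,
    spec: PlotSpec | None = None,
    path=None,
) -> dict:
    """All atlas voxels as neutral dots, cluster voxels highlighted on top."""
    spec = spec or PlotSpec(mode="binary")
    pos = _positions(coords)
    highlight = coords.table["value"].to_numpy() != 0
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(*pos[~highlight].T, s=spec.point_size, c=spec.background_color)
    ax.scatter(*pos[highlight].T, s=spec.point_size, c=spec.highlight_color)
    xl, yl = _axis_labels(coords)
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    out = _save(fig, spec, path)
    return {
        "positions": pos,
        "highlight": highlight,
        "n_highlighted": int(highlight.sum()),
        "path": out,
    }


def scatter_continuous(
    atlas: GradientAtlas,
    coords: GradientCoordinates,
    spec: PlotSpec | None = None,
    path=None,
) -> dict:
    """Cluster voxels colored by a monotone intensity map of their value.

    ``intensity`` in the backing arrays is the min-max normalized value in
    [0, 1]; higher input value never maps to lower intensity (all-equal
    values collapse to a single intensity).
    """
    spec = spec or PlotSpec(mode="continuous")
    pos = _positions(coords)
    values = coords.table["value"].to_numpy().astype(float)
    inside = values != 0
    v = values[inside]
    if v.size and v.max() > v.min():
        intensity = (v - v.min()) / (v.max() - v.min())
    else:
        intensity = np.ones_like(v)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(*pos[~inside].T, s=spec.point_size, c=spec.background_color)
    cmap = plt.get_cmap(spec.cmap)
    if inside.any():
        ax.scatter(
            *pos[inside].T, s=spec.point_size, c=cmap(0.2 + 0.8 * intensity)
        )
    xl, yl = _axis_labels(coords)
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    out = _save(fig, spec, path)
    return {
        "positions": pos,
        "inside": inside,
        "values": v,
        "intensity": intensity,
        "path": out,
    }


def scatter_network(
    atlas: GradientAtlas,
    coords: GradientCoordinates,
    spec: PlotSpec | None = None,
    path=None,
) -> dict:
    """Every voxel colored by its resting-state network; cluster voxels are
    marked by a dark outline."""
    spec = spec or PlotSpec(mode="network")
    if atlas.network_labels is None:
        raise ValueError(
            "atlas has no network labels; use binary mode instead"
        )
    table = network_color_table()
    labels = atlas.network_labels
    colors = np.array([table[int(l)][1] for l in labels])
    pos = _positions(coords)
    highlight = coords.table["value"].to_numpy() != 0
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(*pos[~highlight].T, s=spec.point_size, c=colors[~highlight])
    ax.scatter(
        *pos[highlight].T,
        s=spec.point_size * 2,
        c=colors[highlight],
        edgecolors="black",
        linewidths=0.6,
    )
    xl, yl = _axis_labels(coords)
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    out = _save(fig, spec, path)
    return {
        "positions": pos,
        "labels": labels,
        "colors": colors,
        "highlight": highlight,
        "color_table": table,
        "path": out,
    }


def scatter_multi(
    atlas: GradientAtlas,
    coords_list: list,
    spec: PlotSpec | None = None,
    path=None,
) -> dict:
    """Several clusters on one map, each in its own color.

    Voxels belonging to more than one cluster are drawn in
    ``spec.overlap_color``; later-listed clusters draw on top.  Backing
    ``class_codes``: -1 background, 0..m-1 single-cluster membership, -2
    overlap.
    """
    spec = spec or PlotSpec(mode="multi")
    if len(coords_list) < 2:
        raise ValueError("multi mode needs at least 2 clusters")
    axes = coords_list[0].axes
    for c in coords_list[1:]:
        if c.axes != axes:
            raise ValueError("all clusters must use the same gradient axes")
    colors = list(spec.highlight_colors) or [
        plt.get_cmap("tab10")(i) for i in range(len(coords_list))
    ]
    if len(colors) < len(coords_list):
        raise ValueError("need one highlight color per cluster")

    pos = _positions(coords_list[0])
    members = np.stack(
        [c.table["value"].to_numpy() != 0 for c in coords_list], axis=1
    )
    counts = members.sum(axis=1)
    class_codes = np.full(len(pos), -1, dtype=int)
    for i in range(len(coords_list)):  # later clusters win the single slot
        class_codes[members[:, i]] = i
    class_codes[counts > 1] = -2

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(*pos[counts == 0].T, s=spec.point_size, c=spec.background_color)
    for i, c in enumerate(coords_list):
        sel = members[:, i] & (counts == 1)
        ax.scatter(*pos[sel].T, s=spec.point_size, color=colors[i])
    ax.scatter(*pos[counts > 1].T, s=spec.point_size, c=spec.overlap_color)
    xl, yl = _axis_labels(coords_list[0])
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    out = _save(fig, spec, path)
    return {
        "positions": pos,
        "members": members,
        "counts": counts,
        "class_codes": class_codes,
        "colors": colors,
        "path": out,
    }


def glass_brain(report: QCReport, path=None) -> dict:
    """Two panels (before / after preprocessing), three maximum-intensity
    projections each — the QC view that in-mask voxels did not move."""
    fig, axes = plt.subplots(2, 3, figsize=(9, 6))
    titles = ("sagittal", "coronal", "axial")
    for row, projs, label in (
        (0, report.projections_before, "before"),
        (1, report.projections_after, "after"),
    ):
        for col, proj in enumerate(projs):
            ax = axes[row, col]
            ax.imshow(proj.T, origin="lower", cmap="gray_r")
            ax.set_title(f"{label} ({titles[col]})", fontsize=9)
            ax.axis("off")
    fig.suptitle(
        f"in-mask voxels before: {report.n_voxels_before_in_mask}, "
        f"after: {report.n_voxels_after}, moved: {len(report.moved_voxels)}"
    )
    if path is not None:
        fig.savefig(str(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return {
        "projections_before": report.projections_before,
        "projections_after": report.projections_after,
        "path": str(path) if path is not None else None,
    }
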