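"""Gradient atlas and the voxel -> gradient-coordinate projection.

A :class:`GradientAtlas` stores, for every gray-matter voxel of the reference
grid (in fixed row-major scan order over the mask), its coordinates along K
functional gradients and optionally a 7-network resting-state label.
:func:`map_cluster` projects a preprocessed cluster volume into gradient
space: one row per atlas voxel carrying (g_x, g_y) on the chosen gradient
axes plus the cluster's value at that voxel.  Gradient axes are 1-indexed
everywhere (gradient 1, gradient 2, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import ReferenceSpace, VolumeGrid

__all__ = [
    "GradientAtlas",
    "GradientCoordinates",
    "load_atlas",
    "map_cluster",
    "export_csv",
    "NETWORK_NAMES",
]

# Standard 7-network resting-state parcellation numbering.
NETWORK_NAMES = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal attention",
    4: "ventral attention",
    5: "limbic",
    6: "frontoparietal",
    7: "default mode",
}


@dataclass
class GradientAtlas:
    """Per-voxel gradient values over the reference mask, in row-major order."""

    reference: ReferenceSpace
    voxels: np.ndarray  # (n, 3) int indices, row-major over the mask
    gradient_values: np.ndarray  # (n, K)
    network_labels: np.ndarray | None = None  # (n,) ints in 1..7
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        self.gradient_values = np.atleast_2d(
            np.asarray(self.gradient_values, dtype=float)
        )
        if self.gradient_values.shape[0] != self.voxels.shape[0]:
            raise ValueError("one gradient row required per voxel")
        mask = self.reference.mask.values
        inside = mask[tuple(self.voxels.T)] > 0
        if not inside.all():
            bad = tuple(self.voxels[~inside][0])
            raise ValueError(f"atlas voxel {bad} lies outside the reference mask")
        if not np.all(np.isfinite(self.gradient_values)):
            bad = tuple(
                self.voxels[~np.isfinite(self.gradient_values).all(axis=1)][0]
            )
            raise ValueError(f"non-finite gradient value at voxel {bad}")
        if self.network_labels is not None:
            self.network_labels = np.asarray(self.network_labels, dtype=int)
            if self.network_labels.shape[0] != self.voxels.shape[0]:
                raise ValueError("network labels must cover every atlas voxel")
            ok = (self.network_labels >= 1) & (self.network_labels <= 7)
            if not ok.all():
                bad = tuple(self.voxels[~ok][0])
                lab = int(self.network_labels[~ok][0])
                raise ValueError(
                    f"network label {lab} at voxel {bad} outside 1..7"
                )

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_components(self) -> int:
        return self.gradient_values.shape[1]

    @classmethod
    def from_reference(
        cls,
        reference: ReferenceSpace,
        gradient_values: np.ndarray,
        network_labels=None,
        provenance: str = "",
    ) -> "GradientAtlas":
        """Build an atlas with the canonical row-major mask voxel order."""
        return cls(
            reference=reference,
            voxels=reference.mask_indices,
            gradient_values=gradient_values,
            network_labels=network_labels,
            provenance=provenance,
        )

    def gradient_volume(self, component: int) -> VolumeGrid:
        """Render one gradient component (1-indexed) back onto the grid."""
        if not 1 <= component <= self.n_components:
            raise ValueError(
                f"gradient {component} out of range 1..{self.n_components}"
            )
        vol = np.zeros(self.reference.shape)
        vol[tuple(self.voxels.T)] = self.gradient_values[:, component - 1]
        return VolumeGrid(vol, self.reference.affine.copy())


@dataclass
class GradientCoordinates:
    """One row per atlas voxel: (voxel index, g_x, g_y, cluster value).

    ``axes`` records which (1-indexed) gradients back the g_x / g_y columns.
    Rows with value 0 are voxels outside the cluster; :meth:`nonzero` is the
    reduced view that backs CSV export and statistics.
    """

    table: pd.DataFrame
    axes: tuple = (1, 2)
    cluster_id: str = ""

    _COLUMNS = ("voxel_i", "voxel_j", "voxel_k", "g_x", "g_y", "value")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"coordinate table missing columns {sorted(missing)}")
        self.axes = tuple(int(a) for a in self.axes)

    def nonzero(self) -> pd.DataFrame:
        return self.table[self.table["value"] != 0].reset_index(drop=True)

    @property
    def n_nonzero(self) -> int:
        return int((self.table["value"] != 0).sum())

    @property
    def n_rows(self) -> int:
        return len(self.table)


def load_atlas(gradients_path, mask_path, networks_path=None, provenance=""):
    """Load a gradient atlas from NIfTI files sharing the reference grid.

    ``gradients_path`` is a 4-D NIfTI (one 3-D volume per gradient) or a list
    of 3-D NIfTI paths.  ``mask_path`` is the binary gray-matter mask that
    defines the reference grid and the atlas voxel order (row-major scan).
    """
    mask_img = nib.load(str(mask_path))
    mask_data = (np.asanyarray(mask_img.dataobj) > 0).astype(float)
    affine = np.asarray(mask_img.affine, dtype=float)
    grid = VolumeGrid(np.zeros(mask_data.shape), affine)
    ref = ReferenceSpace(grid=grid, mask=VolumeGrid(mask_data, affine.copy()))

    if isinstance(gradients_path, (list, tuple)):
        comps = []
        for p in gradients_path:
            img = nib.load(str(p))
            data = np.asanyarray(img.dataobj)
            _check_grid(data.shape, img.affine, ref, p)
            comps.append(np.asarray(data, dtype=float))
        stack = np.stack(comps, axis=-1)
    else:
        img = nib.load(str(gradients_path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError("gradient volume must be 3-D or 4-D")
        _check_grid(data.shape[:3], img.affine, ref, gradients_path)
        stack = np.asarray(data, dtype=float)

    voxels = ref.mask_indices
    gradient_values = stack[tuple(voxels.T)]

    network_labels = None
    if networks_path is not None:
        nimg = nib.load(str(networks_path))
        ndata = np.asanyarray(nimg.dataobj)
        _check_grid(ndata.shape, nimg.affine, ref, networks_path)
        network_labels = np.asarray(ndata, dtype=float)[tuple(voxels.T)]
        network_labels = np.round(network_labels).astype(int)

    return GradientAtlas(
        reference=ref,
        voxels=voxels,
        gradient_values=gradient_values,
        network_labels=network_labels,
        provenance=provenance or f"loaded from {gradients_path}",
    )


def _check_grid(shape, affine, ref: ReferenceSpace, path) -> None:
    if tuple(shape) != tuple(ref.shape) or not np.allclose(affine, ref.affine):
        raise ValueError(f"{path}: grid does not match the reference mask grid")


def map_cluster(
    atlas: GradientAtlas, cluster: VolumeGrid, axes: tuple = (1, 2)
) -> GradientCoordinates:
    """Project a preprocessed cluster volume into gradient coordinates.

    Returns one row per atlas voxel with that voxel's gradient coordinates on
    the chosen 1-indexed axes and the cluster's value there (0 outside the
    cluster).  The cluster must live on the reference grid; nonzero voxels
    outside the mask are ignored with a warning (they should have been
    removed by preprocessing).
    """
    ref = atlas.reference
    if cluster.shape != ref.shape or not np.allclose(cluster.affine, ref.affine):
        raise ValueError(
            "cluster is not on the reference grid; run preprocess first"
        )
    ax_x, ax_y = (int(a) for a in axes)
    for a in (ax_x, ax_y):
        if not 1 <= a <= atlas.n_components:
            raise ValueError(
                f"gradient axis {a} exceeds atlas components "
                f"(1..{atlas.n_components})"
            )
    outside = (cluster.values != 0) & (ref.mask.values == 0)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} nonzero cluster voxels outside the mask are "
            "ignored; run preprocess to remove them",
            stacklevel=2,
        )
    values = cluster.values[tuple(atlas.voxels.T)]
    table = pd.DataFrame(
        {
            "voxel_i": atlas.voxels[:, 0],
            "voxel_j": atlas.voxels[:, 1],
            "voxel_k": atlas.voxels[:, 2],
            "g_x": atlas.gradient_values[:, ax_x - 1],
            "g_y": atlas.gradient_values[:, ax_y - 1],
            "value": values,
        }
    )
    return GradientCoordinates(table=table, axes=(ax_x, ax_y))


def export_csv(coords: GradientCoordinates, path) -> None:
    """Write the nonzero-value rows to CSV at full precision, in atlas order.

    Columns: voxel_i, voxel_j, voxel_k, g_x, g_y, value.  An empty cluster
    yields a header-only file plus a warning.
    """
    rows = coords.nonzero()
    if rows.empty:
        warnings.warn("cluster is empty; writing header-only CSV", stacklevel=2)
    rows.to_csv(path, index=False)
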