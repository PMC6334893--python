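"""Volumetric preprocessing of MNI-space cluster maps.

The pipeline mirrors how volumetric findings (patient-study clusters, task
activation maps) are prepared before gradient-space projection:

1. threshold / binarize the input (strictly-greater-than threshold),
2. resample onto the 2 mm reference grid,
3. pad or crop slices so the grid matches the reference exactly,
4. mask to cerebellar gray matter,

and a quality-control report verifying that in-mask voxels did not move.

Resampling is always affine-driven (world coordinates), never index-driven.
Continuous data use point trilinear interpolation.  Binary data use exact
volume-fraction (box-overlap) accumulation re-binarized at 0.5, so that a
source voxel covering 1/8 of a coarser target voxel does not survive
downsampling.  The box-overlap path requires axis-aligned affines, which is
what MNI-registered volumes have.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "VolumeGrid",
    "ReferenceSpace",
    "QCReport",
    "load_volume",
    "threshold_binarize",
    "resample_to_reference",
    "match_grid",
    "apply_mask",
    "preprocess",
    "mni152_reference_affine",
]

# MNI152 2 mm template: 91 x 109 x 91 voxels, RAS- affine with x flipped.
MNI152_2MM_SHAPE = (91, 109, 91)


def mni152_reference_affine() -> np.ndarray:
    return np.array(
        [
            [-2.0, 0.0, 0.0, 90.0],
            [0.0, 2.0, 0.0, -126.0],
            [0.0, 0.0, 2.0, -72.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


@dataclass
class VolumeGrid:
    """A 3-D voxel array with its voxel-to-world affine (mm)."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume values must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def nonzero_voxels(self) -> np.ndarray:
        """Sorted (n, 3) integer indices of nonzero voxels (row-major order)."""
        return np.argwhere(self.values != 0)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.affine.copy())

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        nib.save(img, str(path))


@dataclass
class ReferenceSpace:
    """The target grid (2 mm template) plus its binary gray-matter mask."""

    grid: VolumeGrid
    mask: VolumeGrid

    def __post_init__(self) -> None:
        mv = self.mask.values
        if not np.isin(mv, (0.0, 1.0)).all():
            raise ValueError("mask must be binary {0, 1}")
        if not mv.any():
            raise ValueError("mask is empty")
        if self.mask.shape != self.grid.shape or not np.allclose(
            self.mask.affine, self.grid.affine
        ):
            raise ValueError("mask grid must be identical to the template grid")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    @property
    def mask_indices(self) -> np.ndarray:
        """Row-major (n, 3) indices of mask voxels; the canonical atlas order."""
        return np.argwhere(self.mask.values > 0)

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.values.sum())


@dataclass
class QCReport:
    """Before/after comparison of in-mask voxels plus glass-brain projections.

    ``moved_voxels`` is the symmetric difference between the in-mask nonzero
    voxel set of the (thresholded, reference-resampled) input and that of the
    final output; empty iff the two sets agree.
    """

    n_voxels_before_in_mask: int
    n_voxels_after: int
    moved_voxels: list
    projections_before: tuple
    projections_after: tuple
    extras: dict = field(default_factory=dict)

    @property
    def in_mask_preserved(self) -> bool:
        return len(self.moved_voxels) == 0


def _mni_plausibility_warning(affine: np.ndarray, shape: tuple) -> None:
    """Warn (never fail) when a volume does not look MNI152-registered."""
    R = affine[:3, :3]
    aligned = True
    for col in R.T:
        a = np.abs(col)
        if a.max() == 0 or (a.sum() - a.max()) > 1e-3 * a.max():
            aligned = False
    if not aligned:
        warnings.warn(
            "affine is not axis-aligned; volume may not be MNI152-registered",
            stacklevel=3,
        )
        return
    # the anterior commissure sits at world (0,0,0) in MNI152; it should fall
    # inside (or within 20 mm of) the volume's world bounding box
    corners = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1)
         for k in (0, shape[2] - 1)],
        dtype=float,
    )
    world = corners @ R.T + affine[:3, 3]
    lo, hi = world.min(axis=0) - 20.0, world.max(axis=0) + 20.0
    if not np.all((lo <= 0) & (0 <= hi)):
        warnings.warn(
            "world origin (anterior commissure in MNI152) lies far outside "
            "the volume; check that the input is MNI152-registered",
            stacklevel=3,
        )


def load_volume(path) -> VolumeGrid:
    """Load a 3-D NIfTI volume (a trailing singleton 4th dim is squeezed).

    4-D time series are rejected; a warning is emitted if the affine does not
    look plausibly MNI152-registered.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] == 1:
            data = data[..., 0]
        else:
            raise ValueError(
                f"expected a 3-D volume, got 4-D with {data.shape[3]} volumes"
            )
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D data")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    _mni_plausibility_warning(affine, data.shape)
    return VolumeGrid(np.asarray(data, dtype=float), affine)


def threshold_binarize(
    vol: VolumeGrid, threshold: float | None = None, binarize: bool = True
) -> VolumeGrid:
    """Keep voxels strictly greater than ``threshold`` (None: all nonzero).

    Surviving voxels are set to 1 when ``binarize`` else keep their value;
    everything else becomes 0.
    """
    v = vol.values
    keep = (v != 0) if threshold is None else (v > threshold)
    out = np.where(keep, 1.0 if binarize else v, 0.0)
    return VolumeGrid(out, vol.affine.copy())


def _axis_alignment(affine: np.ndarray):
    """Map each voxel axis to its world axis for an axis-aligned affine.

    Returns (world_axis_of_voxel_axis, spacing per voxel axis) or None when
    the affine has off-axis terms.
    """
    R = affine[:3, :3]
    world_axes = []
    for col in R.T:
        a = np.abs(col)
        w = int(np.argmax(a))
        if a.max() == 0 or (a.sum() - a.max()) > 1e-6 * a.max():
            return None
        world_axes.append(w)
    if sorted(world_axes) != [0, 1, 2]:
        return None
    return world_axes, np.array([R[world_axes[i], i] for i in range(3)])


def _overlap_matrix(src_centers, src_step, tgt_centers, tgt_step) -> np.ndarray:
    """Fractional interval overlap: entry (i, j) is |src_i ∩ tgt_j| / |tgt_j|."""
    s_lo = src_centers - abs(src_step) / 2.0
    s_hi = src_centers + abs(src_step) / 2.0
    t_lo = tgt_centers - abs(tgt_step) / 2.0
    t_hi = tgt_centers + abs(tgt_step) / 2.0
    ov = np.minimum(s_hi[:, None], t_hi[None, :]) - np.maximum(
        s_lo[:, None], t_lo[None, :]
    )
    np.clip(ov, 0.0, None, out=ov)
    return ov / abs(tgt_step)


def _volume_fraction_resample(vol: VolumeGrid, ref_grid: VolumeGrid) -> np.ndarray:
    """Exact coverage fraction of each reference voxel by nonzero source voxels."""
    src = _axis_alignment(vol.affine)
    tgt = _axis_alignment(ref_grid.affine)
    if src is None or tgt is None:
        raise ValueError(
            "binary volume-fraction resampling requires axis-aligned affines"
        )
    src_world, src_step = src
    tgt_world, tgt_step = tgt
    # reorder source array axes so axis a is the source axis for the world
    # axis handled by target axis a
    src_axis_for_world = {w: i for i, w in enumerate(src_world)}
    perm = [src_axis_for_world[w] for w in tgt_world]
    data = np.transpose(vol.values, perm)
    out = data.astype(float)
    for a in range(3):
        sa = perm[a]
        n_src = vol.shape[sa]
        n_tgt = ref_grid.shape[a]
        src_centers = vol.affine[tgt_world[a], 3] + src_step[sa] * np.arange(n_src)
        tgt_centers = ref_grid.affine[tgt_world[a], 3] + tgt_step[a] * np.arange(
            n_tgt
        )
        O = _overlap_matrix(src_centers, src_step[sa], tgt_centers, tgt_step[a])
        out = np.moveaxis(np.tensordot(np.moveaxis(out, a, 0), O, axes=(0, 0)),
                          -1, a)
    return out


def resample_to_reference(
    vol: VolumeGrid, ref: ReferenceSpace, is_binary: bool = True
) -> VolumeGrid:
    """Resample a volume onto the reference grid, preserving world position.

    Continuous data: trilinear interpolation at reference voxel centers.
    Binary data: exact volume-fraction accumulation, re-binarized at >= 0.5.
    A volume with no world-space overlap with the reference field of view
    yields an empty output plus a warning.
    """
    ref_grid = ref.grid
    if vol.shape == ref_grid.shape and np.allclose(vol.affine, ref_grid.affine):
        return vol.copy()

    if is_binary:
        frac = _volume_fraction_resample(vol, ref_grid)
        out = (frac >= 0.5).astype(float)
    else:
        idx = np.indices(ref_grid.shape, dtype=float).reshape(3, -1)
        world = ref_grid.affine[:3, :3] @ idx + ref_grid.affine[:3, 3:4]
        inv = np.linalg.inv(vol.affine)
        src = inv[:3, :3] @ world + inv[:3, 3:4]
        out = map_coordinates(
            vol.values, src, order=1, mode="constant", cval=0.0
        ).reshape(ref_grid.shape)

    if vol.values.any() and not out.any() and _bboxes_disjoint(vol, ref_grid):
        warnings.warn(
            "input volume has no overlap with the reference field of view; "
            "output is empty",
            stacklevel=2,
        )
    return VolumeGrid(out, ref_grid.affine.copy())


def _world_bbox(vol: VolumeGrid) -> tuple:
    corners = np.array(
        [[i, j, k] for i in (-0.5, vol.shape[0] - 0.5)
         for j in (-0.5, vol.shape[1] - 0.5) for k in (-0.5, vol.shape[2] - 0.5)]
    )
    world = vol.world_coords(corners)
    return world.min(axis=0), world.max(axis=0)


def _bboxes_disjoint(a: VolumeGrid, b: VolumeGrid) -> bool:
    alo, ahi = _world_bbox(a)
    blo, bhi = _world_bbox(b)
    return bool(np.any(ahi < blo) or np.any(bhi < alo))


def match_grid(vol: VolumeGrid, ref: ReferenceSpace) -> VolumeGrid:
    """Pad or crop whole slices so the grid equals the reference grid.

    Requires the reference voxel size and axis orientation; alignment is by
    world coordinates, so no voxel changes world position.
    """
    ref_grid = ref.grid
    if not np.allclose(vol.affine[:3, :3], ref_grid.affine[:3, :3], atol=1e-6):
        raise ValueError(
            "orientation/voxel-size mismatch: match_grid only pads or crops "
            "slices; resample first"
        )
    # voxel offset: vol voxel i sits at ref voxel i + off
    off_world = vol.affine[:3, 3] - ref_grid.affine[:3, 3]
    off = np.linalg.solve(ref_grid.affine[:3, :3], off_world)
    off_int = np.round(off).astype(int)
    if np.abs(off - off_int).max() > 1e-3:
        raise ValueError(
            "grids are offset by a non-integer number of voxels; resample first"
        )
    out = np.zeros(ref_grid.shape, dtype=float)
    src_slices, dst_slices = [], []
    for a in range(3):
        lo = max(0, off_int[a])
        hi = min(ref_grid.shape[a], vol.shape[a] + off_int[a])
        if hi <= lo:
            return VolumeGrid(out, ref_grid.affine.copy())
        dst_slices.append(slice(lo, hi))
        src_slices.append(slice(lo - off_int[a], hi - off_int[a]))
    out[tuple(dst_slices)] = vol.values[tuple(src_slices)]
    return VolumeGrid(out, ref_grid.affine.copy())


def apply_mask(vol: VolumeGrid, ref: ReferenceSpace) -> VolumeGrid:
    """Zero all voxels outside the cerebellar gray-matter mask."""
    if vol.shape != ref.shape or not np.allclose(vol.affine, ref.affine):
        raise ValueError("volume must be on the reference grid before masking")
    out = vol.values * ref.mask.values
    if vol.values.any() and not out.any():
        warnings.warn(
            "no cerebellar gray-matter voxels in input (cluster lies entirely "
            "outside the mask)",
            stacklevel=2,
        )
    return VolumeGrid(out, vol.affine.copy())


def _projections(values: np.ndarray) -> tuple:
    """Maximum-intensity projections along the three axes (glass brain)."""
    return tuple(values.max(axis=a) for a in range(3))


def _in_mask_set(vol: VolumeGrid, ref: ReferenceSpace) -> set:
    inside = (vol.values != 0) & (ref.mask.values > 0)
    return set(map(tuple, np.argwhere(inside)))


def preprocess(
    source,
    ref: ReferenceSpace,
    threshold: float | None = None,
    binarize: bool = True,
) -> tuple[VolumeGrid, QCReport]:
    """Full pipeline: load -> threshold/binarize -> resample -> match -> mask.

    ``source`` is a NIfTI path or an in-memory :class:`VolumeGrid`.  The QC
    report compares the in-mask voxel set of the thresholded input (resampled
    to the reference grid for comparability) against the final output, and
    carries three-axis maximum-intensity projections of both.
    """
    vol = source if isinstance(source, VolumeGrid) else load_volume(source)
    thresholded = threshold_binarize(vol, threshold=threshold, binarize=binarize)
    resampled = resample_to_reference(thresholded, ref, is_binary=binarize)
    matched = match_grid(resampled, ref)
    final = apply_mask(matched, ref)

    before = _in_mask_set(resampled, ref)
    after = _in_mask_set(final, ref)
    moved = sorted(before.symmetric_difference(after))
    report = QCReport(
        n_voxels_before_in_mask=len(before),
        n_voxels_after=int(np.count_nonzero(final.values)),
        moved_voxels=moved,
        projections_before=_projections(resampled.values),
        projections_after=_projections(final.values),
        extras={
            "threshold": threshold,
            "binarize": binarize,
            "n_voxels_input_nonzero": int(np.count_nonzero(thresholded.values)),
        },
    )
    return final, report
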