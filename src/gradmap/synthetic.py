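"""Synthetic fixtures: planted-gradient connectivity, miniature reference
space, gradient atlas, network labels, and cluster volumes.

Everything here stands in for externally-derived data (HCP resting-state
connectivity, the real cerebellar gray-matter mask and gradient maps) with
constructions whose ground truth is known exactly, so every other module can
be tested end to end with no downloads.  All generation is seeded and
integer-indexed; the same seed reproduces the same bytes on any platform.

The planted connectivity model gives each point two latent coordinates
(uniform on [0, 1]^2) and builds rows from smooth Gaussian bump loadings over
each latent axis, the first axis weighted by ``eigenvalue_gap_factor``.
Cosine similarity between rows then decays with latent distance and the
diffusion map's first two components recover the planted axes, axis 1 first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .atlas import GradientAtlas
from .embedding import ConnectivityMatrix
from .volumes import ReferenceSpace, VolumeGrid

__all__ = [
    "PlantedModel",
    "SyntheticCluster",
    "make_connectivity",
    "make_reference_space",
    "make_atlas",
    "make_cluster",
    "make_shifted_cluster_pair",
    "make_fixtures",
]


@dataclass
class PlantedModel:
    """Planted two-axis latent structure behind synthetic connectivity.

    ``latent`` (n x 2, uniform on [0, 1]^2, independent axes) is drawn from
    ``seed`` unless given explicitly.  ``eigenvalue_gap_factor`` (>= 2)
    weights latent axis 1 over axis 2 in the connectivity rows so the leading
    nontrivial eigenvalue pairs with axis 1, removing rotation ambiguity.
    """

    n_voxels: int
    eigenvalue_gap_factor: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0
    n_centers: int = 24  # Gaussian bump centers per latent axis
    bump_width: float = 0.4  # wide bumps keep axis harmonics below the
    # axis-2 fundamental, so components pair with planted axes
    latent: np.ndarray = None

    def __post_init__(self) -> None:
        if self.eigenvalue_gap_factor < 2:
            raise ValueError("eigenvalue_gap_factor must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.latent is None:
            rng = np.random.default_rng([self.seed, 0])
            self.latent = rng.uniform(0.0, 1.0, size=(self.n_voxels, 2))
        else:
            self.latent = np.asarray(self.latent, dtype=float)
        if self.latent.shape != (self.n_voxels, 2):
            raise ValueError("latent must be (n_voxels, 2)")


def _bump_features(u: np.ndarray, n_centers: int, width: float) -> np.ndarray:
    centers = np.linspace(0.0, 1.0, n_centers)
    return np.exp(-((u[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))


def make_connectivity(model: PlantedModel) -> ConnectivityMatrix:
    """Connectivity rows from smooth bump loadings on the planted latents.

    Row v = [gap_factor * phi(axis1_v), phi(axis2_v)] + noise, so cosine
    similarity between rows decays smoothly with latent distance, dominated
    by axis 1.  Deterministic given the model seed.
    """
    if model.n_voxels < 20:
        raise ValueError("need n_voxels >= 20")
    f1 = _bump_features(model.latent[:, 0], model.n_centers, model.bump_width)
    f2 = _bump_features(model.latent[:, 1], model.n_centers, model.bump_width)
    rows = np.concatenate([model.eigenvalue_gap_factor * f1, f2], axis=1)
    if model.noise_sd > 0:
        rng = np.random.default_rng([model.seed, 1])
        rows = rows + model.noise_sd * rng.standard_normal(rows.shape)
    return ConnectivityMatrix(rows)


def make_reference_space(
    shape: tuple = (20, 24, 20),
    mask_fraction: float = 0.25,
    voxel_size: float = 2.0,
) -> ReferenceSpace:
    """Miniature stand-in for the 2 mm MNI grid with an ellipsoidal mask.

    The ellipsoid is centered on the grid (hence mirror-symmetric along the
    first, left-right, axis) and scaled so roughly ``mask_fraction`` of the
    voxels are inside.  The affine centers the world origin on the grid.
    Deterministic (no randomness).
    """
    shape = tuple(int(s) for s in shape)
    n_total = int(np.prod(shape))
    semi = np.array(shape, dtype=float) / 2.0
    s = (mask_fraction * n_total * 3.0 / (4.0 * np.pi * np.prod(semi))) ** (1 / 3)
    semi = semi * s
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    grids = np.indices(shape, dtype=float)
    r2 = sum(
        ((grids[a] - center[a]) / semi[a]) ** 2 for a in range(3)
    )
    mask = (r2 <= 1.0).astype(float)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = -voxel_size * center
    grid = VolumeGrid(np.zeros(shape), affine)
    return ReferenceSpace(grid=grid, mask=VolumeGrid(mask, affine.copy()))


def _network_labels_from_plane(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """7-way partition of the gradient plane by angle around its center.

    Mirrors the observation that resting-state networks occupy contiguous
    territories of gradient space.
    """
    theta = np.arctan2(g2 - 0.5, g1 - 0.5)  # (-pi, pi]
    labels = 1 + np.floor(7.0 * (theta + np.pi) / (2.0 * np.pi)).astype(int)
    return np.clip(labels, 1, 7)


def make_atlas(ref: ReferenceSpace, model: PlantedModel) -> GradientAtlas:
    """Planted gradient atlas: components 1/2 are the model latents, component
    3 is left-right antisymmetric (mirror voxels get opposite values),
    echoing hemispheric asymmetry; network labels partition the gradient
    plane into 7 angular sectors."""
    voxels = ref.mask_indices
    n = voxels.shape[0]
    if model.n_voxels != n:
        raise ValueError(
            f"model has {model.n_voxels} voxels but the mask has {n}"
        )
    g12 = model.latent
    cx = (ref.shape[0] - 1) / 2.0
    xnorm = (voxels[:, 0] - cx) / max(cx, 1.0)
    cj = (ref.shape[1] - 1) / 2.0
    ck = (ref.shape[2] - 1) / 2.0
    rho = np.sqrt(
        ((voxels[:, 1] - cj) / max(cj, 1.0)) ** 2
        + ((voxels[:, 2] - ck) / max(ck, 1.0)) ** 2
    )
    g3 = xnorm * (0.25 + 0.75 * rho)  # antisymmetric under i -> shape-1-i
    gradient_values = np.column_stack([g12, g3])
    labels = _network_labels_from_plane(g12[:, 0], g12[:, 1])
    return GradientAtlas(
        reference=ref,
        voxels=voxels,
        gradient_values=gradient_values,
        network_labels=labels,
        provenance=f"synthetic planted atlas (seed {model.seed})",
    )


@dataclass
class SyntheticCluster:
    """A generated cluster volume plus its exact planted bookkeeping."""

    volume: VolumeGrid
    in_mask_voxels: np.ndarray  # (m, 3) reference-grid indices, sorted
    all_voxels: np.ndarray  # (m_all, 3) incl. out-of-mask spill
    values_by_voxel: dict  # (i,j,k) -> value on the reference grid
    path: str | None = None

    @property
    def n_in_mask(self) -> int:
        return self.in_mask_voxels.shape[0]


def _blob(ref: ReferenceSpace, n_voxels: int, rng, predicate=None) -> np.ndarray:
    """The n_voxels mask voxels nearest a random in-mask center (a compact
    blob), optionally restricted by a world-coordinate predicate."""
    cand = ref.mask_indices
    if predicate is not None:
        world = ref.grid.world_coords(cand)
        keep = np.array([bool(predicate(w)) for w in world])
        cand = cand[keep]
    if cand.shape[0] < n_voxels:
        raise ValueError("not enough eligible mask voxels for the cluster")
    center = cand[rng.integers(cand.shape[0])]
    d = np.linalg.norm(cand - center, axis=1)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d))
    return cand[order[:n_voxels]]


def make_cluster(
    ref: ReferenceSpace,
    n_voxels: int = 17,
    resolution_mm: float | None = None,
    spill_outside: bool = False,
    values: str = "binary",
    seed: int = 0,
    predicate=None,
    path=None,
) -> SyntheticCluster:
    """Generate a cluster volume whose in-mask voxel set is known exactly.

    The cluster is planted at reference-voxel granularity (finer output
    resolutions fill each reference voxel completely with subvoxels), so the
    planted set survives reference resampling exactly.  ``spill_outside``
    adds roughly n_voxels/2 out-of-mask voxels adjacent to the blob —
    emulating clusters that straddle the gray-matter boundary.  ``values``:
    "binary" writes 1s, "graded" writes per-voxel values in (0, 10) for
    threshold tests.
    """
    if values not in ("binary", "graded"):
        raise ValueError("values must be 'binary' or 'graded'")
    rng = np.random.default_rng([seed, 7])
    in_mask = _blob(ref, n_voxels, rng, predicate=predicate)

    chosen = [tuple(v) for v in in_mask]
    if spill_outside:
        out_cand = np.argwhere(ref.mask.values == 0)
        centroid = in_mask.mean(axis=0)
        d = np.linalg.norm(out_cand - centroid, axis=1)
        order = np.lexsort((out_cand[:, 2], out_cand[:, 1], out_cand[:, 0], d))
        n_out = max(1, n_voxels // 2)
        chosen += [tuple(v) for v in out_cand[order[:n_out]]]

    values_by_voxel = {}
    for v in chosen:
        if values == "binary":
            values_by_voxel[v] = 1.0
        else:
            values_by_voxel[v] = float(rng.uniform(0.5, 9.5))

    ref_vs = float(ref.grid.voxel_size[0])
    if resolution_mm is None or np.isclose(resolution_mm, ref_vs):
        data = np.zeros(ref.shape)
        for v, val in values_by_voxel.items():
            data[v] = val
        vol = VolumeGrid(data, ref.affine.copy())
    else:
        factor = ref_vs / resolution_mm
        f = int(round(factor))
        if f < 1 or not np.isclose(factor, f):
            raise ValueError(
                "resolution_mm must evenly divide the reference voxel size"
            )
        fine_shape = tuple(f * s for s in ref.shape)
        data = np.zeros(fine_shape)
        for v, val in values_by_voxel.items():
            sl = tuple(slice(f * a, f * (a + 1)) for a in v)
            data[sl] = val
        affine = ref.affine.copy()
        affine[:3, :3] = affine[:3, :3] / f
        # shift so the fine grid tiles the reference voxels exactly
        affine[:3, 3] = ref.affine[:3, 3] - np.sign(
            np.diag(ref.affine[:3, :3])
        ) * (ref_vs - resolution_mm) / 2.0
        vol = VolumeGrid(data, affine)

    if path is not None:
        vol.save(path)
    return SyntheticCluster(
        volume=vol,
        in_mask_voxels=in_mask,
        all_voxels=np.array(sorted(chosen)),
        values_by_voxel=values_by_voxel,
        path=str(path) if path is not None else None,
    )


def make_shifted_cluster_pair(
    ref: ReferenceSpace,
    atlas: GradientAtlas,
    n_per_cluster: int = 60,
    shift_sd: float = 1.0,
    seed: int = 0,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Two binary clusters differing only along gradient 2.

    Cluster A samples voxels from a band of gradient space; cluster B matches
    each A voxel's gradient-1 coordinate while shifting gradient 2 upward by
    ``shift_sd`` pooled standard deviations.  Their gradient-1 distributions
    are near-identical and gradient-2 distributions are offset — the planted
    analogue of two task maps separated along one functional axis.
    """
    rng = np.random.default_rng([seed, 13])
    g = atlas.gradient_values[:, :2]
    band = (g[:, 1] >= 0.05) & (g[:, 1] <= 0.55) & (g[:, 0] >= 0.05) & (
        g[:, 0] <= 0.95
    )
    cand = np.flatnonzero(band)
    if cand.size < n_per_cluster:
        raise ValueError("atlas too small for the requested cluster size")
    a_idx = rng.choice(cand, size=n_per_cluster, replace=False)
    delta = shift_sd * float(np.std(g[a_idx, 1]))

    targets = g[a_idx].copy()
    targets[:, 1] += delta
    tree = cKDTree(g)
    _, nn = tree.query(targets, k=min(40, g.shape[0]))
    used = set()
    b_idx = []
    for row in nn:
        pick = next((j for j in row if j not in used), None)
        if pick is None:
            pick = int(row[0])
        used.add(pick)
        b_idx.append(pick)
    b_idx = np.array(b_idx)

    def to_volume(idx):
        data = np.zeros(ref.shape)
        data[tuple(atlas.voxels[idx].T)] = 1.0
        return VolumeGrid(data, ref.affine.copy())

    return to_volume(a_idx), to_volume(b_idx)


def make_fixtures(out_dir, seed: int = 0, shape: tuple = (20, 24, 20)) -> dict:
    """Materialize a complete test workspace: atlas files plus example
    clusters, with a JSON manifest recording the planted ground truth."""
    out = Path(out_dir)
    (out / "atlas").mkdir(parents=True, exist_ok=True)
    (out / "clusters").mkdir(parents=True, exist_ok=True)

    ref = make_reference_space(shape=shape)
    model = PlantedModel(n_voxels=ref.n_mask_voxels, seed=seed)
    atl = make_atlas(ref, model)

    import nibabel as nib

    grad_vol = np.zeros(ref.shape + (atl.n_components,))
    grad_vol[tuple(atl.voxels.T)] = atl.gradient_values
    nib.save(
        nib.Nifti1Image(grad_vol.astype(np.float32), ref.affine),
        str(out / "atlas" / "gradients.nii.gz"),
    )
    ref.mask.save(out / "atlas" / "mask.nii.gz")
    net_vol = np.zeros(ref.shape)
    net_vol[tuple(atl.voxels.T)] = atl.network_labels
    nib.save(
        nib.Nifti1Image(net_vol.astype(np.int16), ref.affine),
        str(out / "atlas" / "networks.nii.gz"),
    )

    cluster17 = make_cluster(
        ref, n_voxels=17, seed=seed, path=out / "clusters" / "cluster17.nii.gz"
    )
    straddle = make_cluster(
        ref,
        n_voxels=25,
        resolution_mm=float(ref.grid.voxel_size[0]) / 2.0,
        spill_outside=True,
        seed=seed + 1,
        path=out / "clusters" / "straddle.nii.gz",
    )
    graded = make_cluster(
        ref,
        n_voxels=40,
        values="graded",
        seed=seed + 2,
        path=out / "clusters" / "graded.nii.gz",
    )
    pair_a, pair_b = make_shifted_cluster_pair(ref, atl, seed=seed)
    pair_a.save(out / "clusters" / "pair_a.nii.gz")
    pair_b.save(out / "clusters" / "pair_b.nii.gz")

    manifest = {
        "seed": seed,
        "shape": list(shape),
        "n_mask_voxels": ref.n_mask_voxels,
        "atlas": {
            "gradients": "atlas/gradients.nii.gz",
            "mask": "atlas/mask.nii.gz",
            "networks": "atlas/networks.nii.gz",
            "n_components": atl.n_components,
        },
        "clusters": {
            "cluster17": {
                "file": "clusters/cluster17.nii.gz",
                "in_mask_voxels": cluster17.in_mask_voxels.tolist(),
            },
            "straddle": {
                "file": "clusters/straddle.nii.gz",
                "in_mask_voxels": straddle.in_mask_voxels.tolist(),
            },
            "graded": {
                "file": "clusters/graded.nii.gz",
                "values_by_voxel": {
                    ",".join(map(str, k)): v
                    for k, v in graded.values_by_voxel.items()
                },
            },
            "pair_a": {"file": "clusters/pair_a.nii.gz"},
            "pair_b": {"file": "clusters/pair_b.nii.gz"},
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
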