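"""Diffusion map embedding of connectivity matrices into functional gradients.

Each row of a connectivity matrix describes one seed point (e.g. a cerebellar
voxel) by its connectivity to a set of targets.  Pairwise cosine similarity of
those rows yields an affinity matrix, which — after anisotropic normalization
— defines a Markov chain over the points.  The nontrivial eigenvectors of the
transition matrix are the functional gradients: continuous axes along which
points are ordered by similarity of their connectivity patterns.  In the
cerebellum, gradient 1 runs from motor to task-unfocused (default-mode)
regions and gradient 2 isolates task-focused processing.

The eigenvector sign returned by the solver is arbitrary; use
:func:`orient_gradients` to fix a convention against a reference vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.metrics.pairwise import cosine_similarity
from sklearn.utils.validation import check_array

__all__ = [
    "ConnectivityMatrix",
    "AffinityMatrix",
    "EmbeddingResult",
    "compute_affinity",
    "diffusion_map_embed",
    "orient_gradients",
    "DiffusionMapEmbedding",
]

_SYM_TOL = 1e-10


@dataclass
class ConnectivityMatrix:
    """n_points x n_features connectivity, one row per seed point.

    Rows must be finite and non-zero: a zero row has undefined cosine
    similarity and is rejected up front, naming the offending row.
    """

    values: np.ndarray
    point_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("connectivity must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity contains non-finite entries")
        zero = ~self.values.any(axis=1)
        if zero.any():
            bad = int(np.flatnonzero(zero)[0])
            raise ValueError(f"connectivity row {bad} is all zero")
        if self.point_ids is None:
            self.point_ids = np.arange(self.values.shape[0])
        else:
            self.point_ids = np.asarray(self.point_ids)
            if self.point_ids.shape[0] != self.values.shape[0]:
                raise ValueError("point_ids length does not match row count")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_file(cls, path, delimiter: str = ",") -> "ConnectivityMatrix":
        """Load a dense matrix from a ``.npy`` array file or delimited text."""
        path = str(path)
        if path.endswith(".npy"):
            values = np.load(path)
        else:
            values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        return cls(values)


@dataclass
class AffinityMatrix:
    """Symmetric pairwise similarity in [0, 1] with its construction record."""

    values: np.ndarray
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape if self.values.ndim == 2 else (0, -1)
        if n != m:
            raise ValueError("affinity must be square")
        if np.abs(self.values - self.values.T).max() > _SYM_TOL:
            raise ValueError("affinity is not symmetric")
        if self.values.min() < -_SYM_TOL or self.values.max() > 1 + _SYM_TOL:
            raise ValueError("affinity entries must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


@dataclass
class EmbeddingResult:
    """Eigenvalues (descending, trivial component removed) and gradient
    coordinates.  Column *j* of ``gradients`` is gradient ``j + 1`` in the
    1-indexed naming used throughout (gradient 1, gradient 2, ...)."""

    eigenvalues: np.ndarray
    gradients: np.ndarray
    params: dict = field(default_factory=dict)
    point_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.gradients.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("gradient columns must match eigenvalue count")
        if self.point_ids is None:
            self.point_ids = np.arange(self.gradients.shape[0])

    @property
    def n_components(self) -> int:
        return self.gradients.shape[1]

    def gradient(self, component: int) -> np.ndarray:
        """Return gradient ``component`` (1-indexed)."""
        if not 1 <= component <= self.n_components:
            raise ValueError(
                f"component {component} out of range 1..{self.n_components}"
            )
        return self.gradients[:, component - 1]

    def to_csv(self, path) -> None:
        """Write point_id plus g1..gk columns."""
        cols = {"point_id": self.point_ids}
        for j in range(self.n_components):
            cols[f"g{j + 1}"] = self.gradients[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)


def compute_affinity(
    conn: ConnectivityMatrix,
    sparsify_keep_fraction: float = 1.0,
    negative_policy: str = "clip",
) -> AffinityMatrix:
    """Pairwise cosine similarity of connectivity rows.

    Parameters
    ----------
    conn:
        Connectivity matrix; at least 3 points.
    sparsify_keep_fraction:
        Keep only the top fraction of each row's entries (by value) before
        computing cosine similarity, zeroing the rest.  1.0 disables
        sparsification (default).  Related gradient work keeps the top 10%.
    negative_policy:
        ``"clip"`` maps negative cosines to 0; ``"shift"`` maps cos to
        (1 + cos) / 2.  Either way the result is a valid nonnegative affinity.
    """
    if isinstance(conn, np.ndarray):
        conn = ConnectivityMatrix(conn)
    if conn.n_points < 3:
        raise ValueError("need at least 3 points to build an affinity matrix")
    if not 0 < sparsify_keep_fraction <= 1:
        raise ValueError("sparsify_keep_fraction must be in (0, 1]")
    if negative_policy not in ("clip", "shift"):
        raise ValueError("negative_policy must be 'clip' or 'shift'")

    X = conn.values
    if sparsify_keep_fraction < 1:
        n_keep = max(1, int(np.ceil(sparsify_keep_fraction * X.shape[1])))
        # per-row threshold at the n_keep-th largest entry; ties are kept
        kth = np.partition(X, X.shape[1] - n_keep, axis=1)[:, X.shape[1] - n_keep]
        X = np.where(X >= kth[:, None], X, 0.0)
        zero = ~X.any(axis=1)
        if zero.any():
            bad = int(np.flatnonzero(zero)[0])
            raise ValueError(f"row {bad} is all zero after sparsification")

    A = cosine_similarity(X)
    if negative_policy == "clip":
        A = np.clip(A, 0.0, None)
    else:
        A = (1.0 + A) / 2.0
    A = (A + A.T) / 2.0
    np.clip(A, 0.0, 1.0, out=A)
    return AffinityMatrix(
        A,
        parameters={
            "sparsify_keep_fraction": sparsify_keep_fraction,
            "negative_policy": negative_policy,
        },
    )


def _check_connected(W: np.ndarray) -> None:
    n_comp, _ = connected_components(csr_matrix(W > 0), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components); "
            "diffusion map embedding requires a single component"
        )


def diffusion_map_embed(
    aff: AffinityMatrix | np.ndarray,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> EmbeddingResult:
    """Eigendecompose the diffusion operator of an affinity matrix.

    The affinity W is density-normalized as W' = D^-alpha W D^-alpha (D the
    diagonal of row sums), turned into the Markov transition matrix
    P = D'^-1 W', and eigendecomposed through its symmetric conjugate
    S = D'^1/2 P D'^-1/2.  Coordinates are the right eigenvectors of P,
    normalized so the trivial (eigenvalue-1, constant) eigenvector is the
    all-ones vector, scaled by lambda^t — or by lambda / (1 - lambda) when
    ``diffusion_time`` is 0, which integrates over all diffusion times.
    The trivial component is dropped; columns are ordered by descending
    eigenvalue.  Eigenvector signs are arbitrary.
    """
    W = aff.values if isinstance(aff, AffinityMatrix) else np.asarray(aff, float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise ValueError("affinity must be square")
    if np.abs(W - W.T).max() > _SYM_TOL:
        raise ValueError("affinity is not symmetric")
    if W.min() < 0:
        raise ValueError("affinity entries must be nonnegative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if diffusion_time < 0:
        raise ValueError("diffusion_time must be nonnegative")
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < n_points")
    _check_connected(W)

    d = W.sum(axis=1)
    if alpha > 0:
        inv_da = d ** -alpha
        W = W * np.outer(inv_da, inv_da)
    d2 = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0

    evals, evecs = eigh(S)
    order = np.argsort(evals)[::-1][: n_components + 1]
    lam = evals[order]
    psi = evecs[:, order] * inv_sqrt[:, None]  # right eigenvectors of P
    psi = psi / psi[:, [0]]  # trivial eigenvector -> all ones

    lam_nt = lam[1:]
    if diffusion_time == 0:
        scale = lam_nt / (1.0 - lam_nt)
    else:
        scale = lam_nt ** diffusion_time
    gradients = psi[:, 1:] * scale

    return EmbeddingResult(
        eigenvalues=lam_nt,
        gradients=gradients,
        params={
            "alpha": alpha,
            "diffusion_time": diffusion_time,
            "n_components": n_components,
        },
    )


def orient_gradients(
    emb: EmbeddingResult, reference: np.ndarray, component: int
) -> EmbeddingResult:
    """Fix the arbitrary sign of one gradient against a reference vector.

    The chosen component (1-indexed) is negated iff its Pearson correlation
    with ``reference`` is negative; other components are untouched.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != emb.gradients.shape[0]:
        raise ValueError("reference length must equal the number of points")
    if np.std(reference) == 0:
        raise ValueError("reference has zero variance; orientation undefined")
    col = emb.gradient(component)
    gradients = emb.gradients.copy()
    if np.std(col) > 0:
        r = np.corrcoef(col, reference)[0, 1]
        if r < 0:
            gradients[:, component - 1] = -col
    return EmbeddingResult(
        eigenvalues=emb.eigenvalues.copy(),
        gradients=gradients,
        params=dict(emb.params),
        point_ids=emb.point_ids,
    )


class DiffusionMapEmbedding(BaseEstimator):
    """Diffusion map embedding as a scikit-learn style transformer.

    ``fit(X)`` treats X as a connectivity matrix (rows = points) when
    ``affinity="cosine"``, or as a precomputed symmetric affinity when
    ``affinity="precomputed"``.  Like
    :class:`sklearn.manifold.SpectralEmbedding` there is no out-of-sample
    ``transform``; use :meth:`fit_transform`.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_points, n_components)
        Gradient coordinates (column j is gradient j+1).
    eigenvalues_ : ndarray of shape (n_components,)
        Nontrivial eigenvalues, descending.
    affinity_matrix_ : ndarray of shape (n_points, n_points)
    """

    def __init__(
        self,
        n_components: int = 10,
        alpha: float = 0.5,
        diffusion_time: float = 0.0,
        affinity: str = "cosine",
        sparsify_keep_fraction: float = 1.0,
        negative_policy: str = "clip",
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.diffusion_time = diffusion_time
        self.affinity = affinity
        self.sparsify_keep_fraction = sparsify_keep_fraction
        self.negative_policy = negative_policy

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.affinity == "precomputed":
            aff = AffinityMatrix(X)
        elif self.affinity == "cosine":
            aff = compute_affinity(
                ConnectivityMatrix(X),
                sparsify_keep_fraction=self.sparsify_keep_fraction,
                negative_policy=self.negative_policy,
            )
        else:
            raise ValueError("affinity must be 'cosine' or 'precomputed'")
        result = diffusion_map_embed(
            aff,
            n_components=self.n_components,
            alpha=self.alpha,
            diffusion_time=self.diffusion_time,
        )
        self.affinity_matrix_ = aff.values
        self.embedding_ = result.gradients
        self.eigenvalues_ = result.eigenvalues
        self.embedding_result_ = result
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
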