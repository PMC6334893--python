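"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the code paths they verify: affinity by an explicit
double loop, the diffusion operator by a dense nonsymmetric eigensolver on
the explicitly formed Markov matrix, and Mann-Whitney p-values by exhaustive
enumeration over all group labelings.
"""

from itertools import combinations

import numpy as np
from scipy.linalg import eig
from scipy.stats import rankdata


def pairwise_cosine_loop(X: np.ndarray) -> np.ndarray:
    """Plain double-loop cosine similarity of rows."""
    n = X.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = X[i], X[j]
            A[i, j] = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    return A


def dense_diffusion_oracle(
    W: np.ndarray, n_components: int, alpha: float = 0.5,
    diffusion_time: float = 0.0,
):
    """Diffusion coordinates from a dense eigensolver on the explicit Markov
    matrix P, normalized in the stationary-weighted norm so the scale matches
    the symmetric-conjugate route (up to per-column sign)."""
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    Wa = W / np.outer(d**alpha, d**alpha) if alpha > 0 else W
    d2 = Wa.sum(axis=1)
    P = Wa / d2[:, None]
    evals, evecs = eig(P)
    evals, evecs = evals.real, evecs.real
    order = np.argsort(evals)[::-1][: n_components + 1]
    lam = evals[order]
    psi = evecs[:, order]
    # normalize each right eigenvector in the d2-weighted norm
    psi = psi / np.sqrt((d2[:, None] * psi**2).sum(axis=0))
    psi = psi / psi[:, [0]]
    lam_nt = lam[1:]
    if diffusion_time == 0:
        scale = lam_nt / (1.0 - lam_nt)
    else:
        scale = lam_nt**diffusion_time
    return lam_nt, psi[:, 1:] * scale


def match_up_to_sign(A: np.ndarray, B: np.ndarray) -> float:
    """Max abs deviation between coordinate matrices after per-column sign
    alignment."""
    dev = 0.0
    for j in range(A.shape[1]):
        s = 1.0 if A[:, j] @ B[:, j] >= 0 else -1.0
        dev = max(dev, np.abs(A[:, j] - s * B[:, j]).max())
    return dev


def mw_enumeration_p(x, y, alternative: str = "two_sided") -> float:
    """Exact Mann-Whitney p by enumerating all C(n1+n2, n1) labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    idx = np.array(list(combinations(range(n1 + n2), n1)))
    us = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2
    ge = np.mean(us >= u_obs - 1e-12)
    le = np.mean(us <= u_obs + 1e-12)
    if alternative == "two_sided":
        return float(min(1.0, 2 * min(ge, le)))
    if alternative == "greater":
        return float(ge)
    if alternative == "less":
        return float(le)
    raise ValueError(alternative)
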