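"""Closed-form random-walk PPMI embedding.

Instead of sampling random walks and training a Skip-Gram model, the
window-aggregated co-occurrence statistics of a uniform random walk on the
multilayer graph are computed exactly.  With P = D^-1 A the one-step
transition matrix, D the diagonal degree matrix and vol(G) the sum of
degrees, the matrix

    M = vol(G) / (b T) * (sum_{r=1..T} P^r) D^-1

is the expected walk co-occurrence ratio for window size T and negative
sampling constant b, and the positive pointwise mutual information matrix
is S = max(log M, 0) elementwise (entries with M = 0, i.e. node pairs never
co-visited within T steps, stay 0).  S is symmetric, and its truncated SVD
S ~= U_d Sigma_d V_d^T yields the node embedding

    Omega_d = U_d sqrt(Sigma_d)

whose row dot products approximate S.  The closed form is exact, so the
only tunables are T, b and the dimension d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .multilayer import MultilayerNetwork, NodeRegistry

logger = logging.getLogger(__name__)

__all__ = ["PPMIMatrix", "EmbeddingMatrix", "compute_ppmi", "embed",
           "similarity_matrix"]

#: above this node count the PPMI accumulation stays sparse-matmul based
_DENSE_LIMIT = 10_000


@dataclass
class PPMIMatrix:
    """Symmetric positive PMI matrix S with its random-walk parameters."""

    matrix: np.ndarray
    T: int
    b: float
    volume: float
    registry: NodeRegistry | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.matrix).all():
            raise ValueError("PPMI matrix contains non-finite entries")
        if (self.matrix < 0).any():
            raise ValueError("PPMI matrix must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EmbeddingMatrix:
    """Node embedding Omega_d, row-aligned with the node registry."""

    vectors: np.ndarray  # |N| x d
    singular_values: np.ndarray  # length d, non-increasing
    registry: NodeRegistry | None = None
    left_vectors: np.ndarray | None = None  # U_d
    right_vectors: np.ndarray | None = None  # V_d

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    def row(self, key: str) -> np.ndarray:
        if self.registry is None:
            raise ValueError("embedding has no registry attached")
        return self.vectors[self.registry.index_of_key(key)]


def compute_ppmi(network: MultilayerNetwork, T: int = 3, b: float = 1.0) -> PPMIMatrix:
    """Exact window-T random-walk PPMI matrix of a multilayer network.

    Matrix powers P^1 .. P^T are accumulated explicitly (dense below
    10^4 nodes, sparse matmul above), so no walk sampling is involved.
    """
    if T < 1:
        raise ValueError("window size T must be >= 1")
    if b <= 0:
        raise ValueError("negative-sample constant b must be > 0")
    deg = network.degrees
    if (deg == 0).any():
        bad = network.registry.key(int(np.flatnonzero(deg == 0)[0]))
        raise ValueError(
            f"zero-degree node {bad!r}; run drop_isolated_nodes first"
        )
    vol = network.volume
    n = network.n_nodes
    dinv = 1.0 / deg

    if n <= _DENSE_LIMIT:
        A = network.supra_adjacency.toarray()
        P = dinv[:, None] * A
        acc = P.copy()
        Pr = P
        for _ in range(T - 1):
            Pr = Pr @ P
            acc += Pr
        M = (vol / (b * T)) * acc * dinv[None, :]
    else:  # pragma: no cover - large-graph path, same algebra
        P = sp.diags(dinv) @ network.supra_adjacency.tocsr()
        acc = P.copy()
        Pr = P
        for _ in range(T - 1):
            Pr = Pr @ P
            acc = acc + Pr
        M = (vol / (b * T)) * (acc @ sp.diags(dinv))
        M = np.asarray(M.todense())

    S = np.zeros_like(M)
    pos = M > 0
    S[pos] = np.log(M[pos])
    np.maximum(S, 0.0, out=S)
    S = (S + S.T) / 2.0  # remove float asymmetry from the matmul chain
    return PPMIMatrix(S, T=T, b=float(b), volume=vol, registry=network.registry)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip singular-vector pairs so each U column's largest-|.| entry is
    positive; V is flipped in step so U diag(s) V^T is unchanged."""
    U, V = U.copy(), V.copy()
    for j in range(U.shape[1]):
        i = int(np.abs(U[:, j]).argmax())
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return U, V


def embed(ppmi: PPMIMatrix, d: int) -> EmbeddingMatrix:
    """Top-d SVD factorization of S into Omega_d = U_d sqrt(Sigma_d).

    Columns are ordered by non-increasing singular value; each singular
    vector's sign is fixed deterministically (largest-magnitude component
    positive) so results are reproducible across linear-algebra backends.
    """
    S = ppmi.matrix
    n = S.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension d={d} must be in [1, {n}]")
    if n <= 500 or d > n - 2:
        U, s, Vt = np.linalg.svd(S, hermitian=True)
        U, s, Vt = U[:, :d], s[:d], Vt[:d]
    else:
        U, s, Vt = spla.svds(S, k=d)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    U, V = _fix_signs(U, Vt.T)
    omega = U * np.sqrt(np.maximum(s, 0.0))[None, :]
    return EmbeddingMatrix(vectors=omega, singular_values=s,
                           registry=ppmi.registry,
                           left_vectors=U, right_vectors=V)


def similarity_matrix(embedding: EmbeddingMatrix) -> np.ndarray:
    """Pairwise similarity delta[i, j] = Omega_d[i] . Omega_d[j]."""
    if not np.isfinite(embedding.vectors).all():
        raise ValueError("embedding contains non-finite values")
    return embedding.vectors @ embedding.vectors.T
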