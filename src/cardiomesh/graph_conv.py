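"""Spectral Chebyshev graph convolution on fixed-topology mesh graphs.

A filter of polynomial order K acts on vertex features X as

    out = sum_{k=0}^{K-1} T_k(L~) X theta_k + bias,

where T_k are Chebyshev polynomials evaluated by the recurrence
T_0 = X, T_1 = L~ X, T_k = 2 L~ T_{k-1} - T_{k-2}, and L~ is the symmetric
normalized graph Laplacian rescaled to spectrum [-1, 1].  The spectral upper
bound lambda_max = 2 is used instead of a per-graph eigensolve, the standard
deterministic choice for normalized Laplacians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse

from .errors import ConfigurationError, DimensionError
from .mesh_core import Mesh


def normalized_laplacian(edges: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    """Symmetric normalized graph Laplacian L = I - D^{-1/2} A D^{-1/2}.

    ``edges`` is an (E, 2) array of undirected edges (no self-loops added).
    Isolated vertices get their degree floored at 1 (with a warning), leaving
    an identity row.
    """
    edges = np.asarray(edges, dtype=np.int64)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise DimensionError(f"edges must be (E, 2), got {edges.shape}")
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.ones(len(rows))
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n_vertices, n_vertices))
    A.sum_duplicates()
    A.data[:] = 1.0  # tolerate duplicated input edges
    deg = np.asarray(A.sum(axis=1)).ravel()
    if (deg == 0).any():
        warnings.warn(f"{int((deg == 0).sum())} isolated vertices; degree floored at 1")
        deg = np.maximum(deg, 1.0)
    d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
    return (sparse.identity(n_vertices, format="csr") - d_inv_sqrt @ A @ d_inv_sqrt).tocsr()


def scaled_laplacian(graph: Mesh | sparse.spmatrix | np.ndarray, n_vertices: int | None = None) -> sparse.csr_matrix:
    """L~ = 2 L / lambda_max - I with lambda_max fixed at 2, i.e. L - I.

    Accepts a mesh (edge graph taken from its faces), an (E, 2) edge array
    (``n_vertices`` required), or a precomputed normalized Laplacian.
    """
    if isinstance(graph, Mesh):
        L = normalized_laplacian(graph.edges(), graph.n_vertices)
    elif sparse.issparse(graph):
        L = graph.tocsr()
    else:
        arr = np.asarray(graph)
        if arr.ndim == 2 and arr.shape[1] == 2 and n_vertices is not None:
            L = normalized_laplacian(arr, n_vertices)
        else:
            L = sparse.csr_matrix(arr)
    return (L - sparse.identity(L.shape[0], format="csr")).tocsr()


@dataclass
class ChebLayer:
    """Chebyshev filter coefficients: weights (K, in, out) and bias (out,)."""

    order: int
    in_channels: int
    out_channels: int
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    bias: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigurationError("Chebyshev order must be >= 1")
        if self.weights is None:
            self.weights = np.zeros((self.order, self.in_channels, self.out_channels))
        if self.bias is None:
            self.bias = np.zeros(self.out_channels)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.shape != (self.order, self.in_channels, self.out_channels):
            raise DimensionError(
                f"weights shape {self.weights.shape} != {(self.order, self.in_channels, self.out_channels)}"
            )
        if self.bias.shape != (self.out_channels,):
            raise DimensionError(f"bias shape {self.bias.shape} != ({self.out_channels},)")

    @classmethod
    def glorot(cls, order: int, in_channels: int, out_channels: int, rng: np.random.Generator) -> "ChebLayer":
        limit = np.sqrt(6.0 / (order * in_channels + out_channels))
        w = rng.uniform(-limit, limit, size=(order, in_channels, out_channels))
        return cls(order, in_channels, out_channels, w, np.zeros(out_channels))


def cheb_basis(L_scaled: sparse.spmatrix, features: np.ndarray, order: int) -> np.ndarray:
    """Stack [T_0 X, ..., T_{K-1} X] along a leading axis; X is (V, C) or (B, V, C)."""
    X = np.asarray(features, dtype=np.float64)
    batched = X.ndim == 3
    if not batched:
        X = X[None]
    B, V, C = X.shape
    if L_scaled.shape[0] != V:
        raise DimensionError(f"feature rows {V} != graph vertices {L_scaled.shape[0]}")
    flat = np.moveaxis(X, 1, 0).reshape(V, B * C)
    out = np.empty((order, V, B * C))
    out[0] = flat
    if order > 1:
        out[1] = L_scaled @ flat
    for k in range(2, order):
        out[k] = 2.0 * (L_scaled @ out[k - 1]) - out[k - 2]
    res = np.moveaxis(out.reshape(order, V, B, C), 2, 1)  # (K, B, V, C)
    return res if batched else res[:, 0]


def cheb_conv(features: np.ndarray, L_scaled: sparse.spmatrix, layer: ChebLayer) -> np.ndarray:
    """Apply a Chebyshev filter to (V, in) or batched (B, V, in) features."""
    X = np.asarray(features, dtype=np.float64)
    batched = X.ndim == 3
    if X.shape[-1] != layer.in_channels:
        raise DimensionError(f"input channels {X.shape[-1]} != layer in_channels {layer.in_channels}")
    basis = cheb_basis(L_scaled, X, layer.order)  # (K, [B,] V, in)
    out = np.einsum("k...i,kio->...o", basis, layer.weights) + layer.bias
    return out if batched or out.ndim == 2 else out
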