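"""Sparse assembly and direct solution of the weighted normal equations.

The weighted least-squares step minimizes

    sum_x R[i,j] (phi[i+1,j] - phi[i,j] - dx[i,j])^2
  + sum_y C[i,j] (phi[i,j+1] - phi[i,j] - dy[i,j])^2

over the column-major vectorization ``phi`` of the image.  The normal
equations ``Q phi = s`` have ``Q = A^T W^T W A`` — a weighted 5-point graph
Laplacian on the pixel grid (symmetric, positive semidefinite, constant null
vector, at most 5 nonzeros per row) — and ``s = A^T W^T W d`` with ``d`` the
stacked wrapped gradients.  Q is assembled directly in sparse triplet form;
the singular gauge direction is removed by pinning pixel (0, 0) to zero, and
the reduced strictly-positive-definite system is factorized by a sparse
direct solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .phase_core import GradientField
from .weighting import DataWeights

__all__ = [
    "WEIGHT_FLOOR",
    "LinearSystem",
    "SolverError",
    "vectorize",
    "devectorize",
    "assemble_system",
    "dense_oracle_assemble",
    "solve_direct",
]

#: Lower clamp applied to edge weights before assembly.  Keeps the pixel
#: graph connected (Q irreducible apart from its constant null space) even
#: when the IRLS weights drive an edge to numerical zero.
WEIGHT_FLOOR = 1e-12


class SolverError(RuntimeError):
    """Raised when the direct factorization fails."""


def vectorize(img: np.ndarray) -> np.ndarray:
    """Column-major (Fortran-order) vectorization: entry i + j*M <- pixel (i, j)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("vectorize expects a 2D array")
    return img.ravel(order="F")


def devectorize(v: np.ndarray, m: int, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    v = np.asarray(v)
    if v.size != m * n:
        raise ValueError(f"vector of length {v.size} cannot fill a {m}x{n} grid")
    return v.reshape((m, n), order="F")


@dataclass
class LinearSystem:
    """The assembled system ``Q phi = s`` for an M x N image.

    ``Q`` is stored compressed-sparse-column, whose natural nonzero ordering
    is first by column then by row — the triplet exchange contract.
    """

    Q: sp.csc_matrix
    s: np.ndarray
    image_shape: tuple

    @property
    def order(self) -> int:
        return self.Q.shape[0]

    def triplets(self):
        """Nonzeros as (row, col, value), ordered by column then row."""
        coo = self.Q.tocoo()
        order = np.lexsort((coo.row, coo.col))
        return list(zip(coo.row[order], coo.col[order], coo.data[order]))

    def dump_mtx(self, path) -> None:
        """Write Q in Matrix Market coordinate format (one-based indices)."""
        from scipy.io import mmwrite

        mmwrite(str(path), self.Q, symmetry="symmetric")


def _edge_arrays(grad: GradientField, dw: DataWeights, floor: float):
    m, n = grad.image_shape
    if dw.R.shape != (m - 1, n) or dw.C.shape != (m, n - 1):
        raise ValueError("weight shapes do not match the gradient field")
    rw = np.maximum(dw.R, floor)
    cw = np.maximum(dw.C, floor)

    ii, jj = np.meshgrid(np.arange(m - 1), np.arange(n), indexing="ij")
    ax_lo = (ii + jj * m).ravel(order="F")          # node (i, j)
    ax_hi = ax_lo + 1                               # node (i+1, j)
    ii, jj = np.meshgrid(np.arange(m), np.arange(n - 1), indexing="ij")
    ay_lo = (ii + jj * m).ravel(order="F")          # node (i, j)
    ay_hi = ay_lo + m                               # node (i, j+1)

    lo = np.concatenate([ax_lo, ay_lo])
    hi = np.concatenate([ax_hi, ay_hi])
    w = np.concatenate([rw.ravel(order="F"), cw.ravel(order="F")])
    d = np.concatenate([grad.dx.ravel(order="F"), grad.dy.ravel(order="F")])
    return m, n, lo, hi, w, d


def assemble_system(
    grad: GradientField, dw: DataWeights, floor: float = WEIGHT_FLOOR
) -> LinearSystem:
    """Assemble ``Q = A^T W^T W A`` and ``s = A^T W^T W d`` in sparse form.

    Each grid edge (lo, hi) with weight w contributes +w to both diagonal
    entries, -w to the two symmetric off-diagonals, and +-(w * d) to ``s``
    (the edge difference is oriented phi[hi] - phi[lo] = d).  Dense A and W
    are never formed.
    """
    m, n, lo, hi, w, d = _edge_arrays(grad, dw, floor)
    mn = m * n
    rows = np.concatenate([lo, hi, lo, hi])
    cols = np.concatenate([lo, hi, hi, lo])
    vals = np.concatenate([w, w, -w, -w])
    q = sp.coo_matrix((vals, (rows, cols)), shape=(mn, mn)).tocsc()
    s = np.zeros(mn)
    np.add.at(s, lo, -w * d)
    np.add.at(s, hi, w * d)
    return LinearSystem(Q=q, s=s, image_shape=(m, n))


def dense_oracle_assemble(
    grad: GradientField, dw: DataWeights, floor: float = WEIGHT_FLOOR
):
    """Reference assembly by explicit dense matrix products (test oracle).

    Builds the stacked first-difference operator A, the diagonal weight
    matrix and the gradient stack d as dense arrays and returns
    ``(A.T @ W @ A, A.T @ W @ d)``.  Guarded to tiny images.
    """
    m, n = grad.image_shape
    if m * n > 400:
        raise ValueError("dense oracle limited to M*N <= 400")
    _, _, lo, hi, w, d = _edge_arrays(grad, dw, floor)
    n_edges = lo.size
    a = np.zeros((n_edges, m * n))
    a[np.arange(n_edges), lo] = -1.0
    a[np.arange(n_edges), hi] = 1.0
    wtw = np.diag(w)
    return a.T @ wtw @ a, a.T @ wtw @ d


def solve_direct(system: LinearSystem, rtol: float = 1e-8) -> np.ndarray:
    """Solve ``Q phi = s`` by sparse direct factorization of the pinned system.

    Pixel (0, 0) is pinned to phase 0 (gauge fix for the constant null
    space); the reduced system is strictly positive definite and is
    factorized with SuperLU in symmetric mode (a Cholesky-type route), with
    a plain LU factorization as the defensive fallback.  One step of
    iterative refinement is applied.
    """
    q = system.Q
    s = system.s
    if not np.any(s):
        return np.zeros(q.shape[0])
    qr = q[1:, 1:].tocsc()
    sr = s[1:]
    try:
        lu = splu(
            qr,
            permc_spec="MMD_AT_PLUS_A",
            options={"SymmetricMode": True},
        )
    except RuntimeError:
        try:
            lu = splu(qr)
        except RuntimeError as exc:
            raise SolverError(
                "direct factorization failed; the reduced system is singular "
                "(the pixel graph is likely disconnected from pixel (0, 0))"
            ) from exc
    x = lu.solve(sr)
    x += lu.solve(sr - qr @ x)
    phi = np.concatenate([[0.0], x])
    resid = np.linalg.norm(q @ phi - s)
    norm_s = np.linalg.norm(s)
    if norm_s > 0 and resid > max(rtol * norm_s, 1e2 * rtol):
        # Ill-conditioned IRLS weights can degrade the residual; refine once
        # more against the full system before giving up.
        phi[1:] += lu.solve((s - q @ phi)[1:])
    return phi
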