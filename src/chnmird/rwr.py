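"""Random walk with restart: iterative solver plus a direct-solve oracle.

The walk iterates

    P_{t+1} = (1 - α) · Mᵀ · P_t + α · P₀

from P₀ until the L1 change between successive vectors drops below the
tolerance.  Because the spectral radius of (1-α)Mᵀ is at most (1-α) < 1
for a (sub)stochastic M, the iteration contracts to the unique fixed
point of the affine map, which :func:`rwr_direct` obtains in closed form
by solving (I - (1-α)Mᵀ) P = α P₀.  The direct solve is the independent
numerical oracle for the iterative path; both are exposed.

Matrices may be dense ndarrays or scipy sparse; dense inputs above a
size threshold are converted to CSR automatically.  The contract is
purely numerical — representation never changes results beyond 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["WalkResult", "ConvergenceError", "rwr_iterate", "rwr_direct"]

# dense matvec wins below this size; CSR above
_SPARSE_THRESHOLD = 1024


class ConvergenceError(RuntimeError):
    """Iteration cap reached before the residual fell below tolerance."""

    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"no convergence after {iterations} iterations (L1 residual {residual:.3g})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass(frozen=True)
class WalkResult:
    """Stationary probability vector with convergence diagnostics.

    When the miRNA-block size ``m_split`` is known, ``u_inf`` /``v_inf``
    give the miRNA and disease slices of the stationary vector.
    """

    P_inf: np.ndarray
    iterations: int
    residual: float
    m_split: int | None = None

    @property
    def u_inf(self) -> np.ndarray:
        if self.m_split is None:
            raise ValueError("no block split recorded for this walk")
        return self.P_inf[: self.m_split]

    @property
    def v_inf(self) -> np.ndarray:
        if self.m_split is None:
            raise ValueError("no block split recorded for this walk")
        return self.P_inf[self.m_split:]


def _transpose_op(M):
    if sp.issparse(M):
        return M.T.tocsr()
    M = np.asarray(M, dtype=float)
    if M.shape[0] > _SPARSE_THRESHOLD:
        return sp.csr_matrix(M.T)
    return M.T


def rwr_iterate(
    M,
    P0: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    m_split: int | None = None,
) -> WalkResult:
    """Power-iterate the restart walk to its stationary vector.

    M must be row-stochastic-or-zero and P0 nonnegative with total mass
    at most 1.  Raises :class:`ConvergenceError` (carrying the final
    residual) if ``max_iter`` steps do not reach the tolerance.
    """
    P0 = np.asarray(P0, dtype=float)
    if np.any(P0 < 0) or P0.sum() > 1 + 1e-9:
        raise ValueError("P0 must be nonnegative with total mass <= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    Mt = _transpose_op(M)
    P = P0.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        P_next = (1.0 - alpha) * (Mt @ P) + alpha * P0
        residual = float(np.abs(P_next - P).sum())
        P = P_next
        if residual < tol:
            return WalkResult(P_inf=P, iterations=it, residual=residual, m_split=m_split)
    raise ConvergenceError(max_iter, residual)


def rwr_direct(M, P0: np.ndarray, alpha: float) -> np.ndarray:
    """Fixed point by direct linear solve of (I - (1-α)Mᵀ) P = α P₀."""
    P0 = np.asarray(P0, dtype=float)
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return P0.copy()
    n = P0.shape[0]
    if sp.issparse(M):
        Aop = sp.eye(n, format="csc") - (1.0 - alpha) * M.T.tocsc()
        return spla.spsolve(Aop, alpha * P0)
    Mt = np.asarray(M, dtype=float).T
    return np.linalg.solve(np.eye(n) - (1.0 - alpha) * Mt, alpha * P0)
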