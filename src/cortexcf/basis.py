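"""Laplace-Beltrami eigenfunctions (LBOEs): the connective-field basis.

Eigenfunctions of the generalized problem ``L phi = lambda M phi`` (cotangent
stiffness L, lumped mass M) form an orthogonal family ordered by spatial
scale; truncating at K modes gives a smooth, shape-intrinsic basis in which
any spatial weight profile on the surface — a connective field — can be
expressed as a short coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import sparse
from scipy.sparse.linalg import eigsh

from .mesh import TriangleMesh, cotangent_operators

__all__ = ["LaplaceBasis", "compute_basis"]

# Below this vertex count the dense symmetric solver is both faster and more
# robust than shift-invert Lanczos.
_DENSE_LIMIT = 2200


@dataclass
class LaplaceBasis:
    """Truncated Laplace-Beltrami eigenbasis of a mesh.

    Attributes
    ----------
    eigenfunctions : (n, K) array
        Mass-orthonormal: ``Phi' diag(mass) Phi = I``.
    eigenvalues : (K,) array, 1/mm^2, non-decreasing.
    mass : (n,) array, mm^2 lumped vertex areas.
    includes_constant_mode : bool
        Whether column 0 is the ~zero-eigenvalue constant function.
    """

    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    mass: np.ndarray
    includes_constant_mode: bool

    @property
    def n_vertices(self) -> int:
        return self.eigenfunctions.shape[0]

    @property
    def k(self) -> int:
        return self.eigenfunctions.shape[1]

    def orthonormality_error(self) -> float:
        phi = self.eigenfunctions
        g = phi.T @ (self.mass[:, None] * phi)
        return float(np.abs(g - np.eye(self.k)).max())


def compute_basis(mesh: TriangleMesh, k: int, drop_constant: bool = True) -> LaplaceBasis:
    """First ``k`` Laplace-Beltrami eigenfunctions of ``mesh``.

    With ``drop_constant`` the near-zero-eigenvalue constant mode is excluded
    and ``k`` non-constant modes are returned; its model time course would
    duplicate the mean-time-course null regressor, so this is the default for
    connective-field design matrices.

    Raises
    ------
    ValueError
        If ``k`` (plus the constant mode when dropped) reaches the vertex
        count, or the mesh is degenerate.
    RuntimeError
        If the sparse eigensolver fails to converge (message reports the mesh
        size and requested k).
    """
    n = mesh.n_vertices
    n_solve = k + 1 if drop_constant else k
    if k >= n:
        raise ValueError(f"requested k={k} >= {n} vertices")

    stiffness, mass = cotangent_operators(mesh)
    inv_sqrt_m = 1.0 / np.sqrt(mass)
    # Whiten by the diagonal mass: standard symmetric problem for u = M^1/2 phi.
    a = sparse.diags(inv_sqrt_m) @ stiffness @ sparse.diags(inv_sqrt_m)

    if n <= _DENSE_LIMIT:
        vals, vecs = sla.eigh(a.toarray(), subset_by_index=[0, n_solve - 1])
    else:
        sigma = -1e-6 * float(np.abs(a.diagonal()).mean())
        try:
            vals, vecs = eigsh(a.tocsc(), k=n_solve, sigma=sigma, which="LM")
        except Exception as exc:  # pragma: no cover - solver-dependent
            raise RuntimeError(
                f"eigensolver failed on mesh with {n} vertices, k={n_solve}: {exc}"
            ) from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    vals = np.maximum(vals, 0.0)  # clip negative round-off at the kernel
    phi = inv_sqrt_m[:, None] * vecs

    if drop_constant:
        vals, phi = vals[1:], phi[:, 1:]

    # Deterministic sign: largest-magnitude entry positive per mode.
    peak = np.argmax(np.abs(phi), axis=0)
    signs = np.sign(phi[peak, np.arange(phi.shape[1])])
    signs[signs == 0] = 1.0
    phi = phi * signs

    return LaplaceBasis(
        eigenfunctions=np.ascontiguousarray(phi),
        eigenvalues=vals,
        mass=mass,
        includes_constant_mode=not drop_constant,
    )
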