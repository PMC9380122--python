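"""Linear-elastic finite-element solve on a tetrahedral liver mesh.

The biomechanical model treats the liver as a single homogeneous isotropic
linear-elastic solid (Young's modulus 1000 Pa, Poisson's ratio 0.45) with the
organ-surface displacement prescribed everywhere (a pure Dirichlet problem)
and no body force.  Under those boundary conditions the displacement solution
is independent of the Young's modulus — only the Poisson ratio shapes how the
boundary motion diffuses into the interior — which the test suite exploits as
an exactness check, along with exact reproduction of rigid-body and affine
boundary data by the linear elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .meshing import TetMesh

__all__ = ["ElasticParams", "BoundaryConditions", "SolverError", "solve_linear_elastic"]


class SolverError(RuntimeError):
    """Singular or ill-posed elastic system."""


@dataclass(frozen=True)
class ElasticParams:
    """Homogeneous isotropic material: E in Pa, nu dimensionless."""

    young_modulus: float = 1000.0
    poisson_ratio: float = 0.45

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")

    def lame(self) -> tuple[float, float]:
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


@dataclass
class BoundaryConditions:
    """One prescribed displacement vector (mm) per boundary node.

    ``displacements`` is (n_boundary, 3), aligned with
    ``TetMesh.boundary_node_ids``.
    """

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 3:
            raise ValueError("boundary displacements must be (n, 3)")
        if not np.isfinite(self.displacements).all():
            raise ValueError("boundary displacements must be finite")


def _element_stiffness(mesh: TetMesh, params: ElasticParams) -> tuple[np.ndarray, np.ndarray]:
    """Batched 12x12 stiffness matrices and |volumes| for all tets."""
    lam, mu = params.lame()
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu  # engineering shear strain

    x = mesh.nodes[mesh.tets]  # (M, 4, 3)
    M4 = np.concatenate([np.ones((len(x), 4, 1)), x], axis=2)  # (M, 4, 4)
    det = np.linalg.det(M4)
    vol = np.abs(det) / 6.0
    if np.any(vol < 1e-12):
        raise SolverError("degenerate (zero-volume) tetrahedron in mesh")
    # rows 1..3 of inv(M4) are the shape-function gradients
    grads = np.linalg.inv(M4)[:, 1:, :].transpose(0, 2, 1)  # (M, 4 nodes, 3)

    B = np.zeros((len(x), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    Ke = np.einsum("mia,ij,mjb,m->mab", B, D, B, vol)
    return Ke, vol


def solve_linear_elastic(
    mesh: TetMesh, bc: BoundaryConditions, params: ElasticParams = ElasticParams()
) -> np.ndarray:
    """Static equilibrium displacements (mm) for all mesh nodes.

    Assembles the global stiffness matrix for linear tetrahedra, imposes the
    prescribed boundary displacements, and solves for the interior.  Returns
    an (n_nodes, 3) array; boundary rows equal the prescription exactly.
    Raises :class:`SolverError` if the reduced system is singular or the
    relative residual exceeds 1e-8.
    """
    nb = len(mesh.boundary_node_ids)
    if len(bc.displacements) != nb:
        raise ValueError(
            f"boundary conditions cover {len(bc.displacements)} nodes, "
            f"mesh has {nb} boundary nodes"
        )
    n = mesh.n_nodes
    Ke, _ = _element_stiffness(mesh, params)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(mesh.tets), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * n, 3 * n)).tocsr()

    u = np.zeros((n, 3))
    u[mesh.boundary_node_ids] = bc.displacements
    fixed = np.zeros(n, dtype=bool)
    fixed[mesh.boundary_node_ids] = True
    # nodes untouched by any tet carry no equations; pin them (boundary nodes
    # are prescribed anyway)
    referenced = np.zeros(n, dtype=bool)
    referenced[np.unique(mesh.tets)] = True
    fixed |= ~referenced

    fixed_dof = np.repeat(fixed, 3)
    free = ~fixed_dof
    if not free.any():  # every node prescribed
        return u
    ub = u.reshape(-1)[fixed_dof]
    rhs = -K[free][:, fixed_dof] @ ub
    Kff = K[free][:, free].tocsc()
    try:
        lu = splu(Kff)
        uf = lu.solve(rhs)
        # iterative refinement recovers the digits a single LU pass loses on
        # meshes containing poorly shaped tetrahedra
        for _ in range(3):
            r = rhs - Kff @ uf
            if np.linalg.norm(r) <= 1e-14 * max(np.linalg.norm(rhs), 1e-30):
                break
            uf = uf + lu.solve(r)
    except SolverError:
        raise
    except Exception as exc:  # pragma: no cover - qualifies the error
        raise SolverError(f"elastic system solve failed: {exc}") from exc
    if not np.isfinite(uf).all():
        raise SolverError("elastic system is singular (non-finite solution)")
    res = np.linalg.norm(Kff @ uf - rhs)
    scale = max(np.linalg.norm(rhs), np.linalg.norm(Kff @ uf), 1e-30)
    if res / scale > 1e-8:
        raise SolverError(f"solver residual too large: {res / scale:.2e}")
    out = u.reshape(-1)
    out[free] = uf
    return out.reshape(n, 3)
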