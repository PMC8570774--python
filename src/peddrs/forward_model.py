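"""Diffusion-approximation FEM forward model with Robin boundary conditions.

Cerenkov photons at 630 nm propagate in tissue in the high-scattering,
low-absorption regime, so the radiative transfer equation reduces to the
diffusion equation

    -div( D grad Phi ) + mu_a Phi = S      in the domain,
    Phi + 2 F D dPhi/dn = 0                on the surface,

with diffusion coefficient D = 1 / (3 (mu_a + mu_s')) and boundary
mismatch factor F = (1 + Rf) / (1 - Rf) for internal reflection
coefficient Rf.  Discretizing with linear (P1) tetrahedral elements gives
a sparse symmetric positive-definite system K Phi = S, and restricting
the Green operator K^-1 to surface nodes / candidate source nodes yields
the measurement model A x = B relating internal nodal source strengths x
to the surface photon flow rate B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom_mesh import OpticalProperties, TetMesh

__all__ = [
    "FemSystem",
    "SystemMatrix",
    "diffusion_coefficient",
    "boundary_factor",
    "assemble_fem",
    "build_system_matrix",
    "simulate_surface_flux",
]

#: Internal reflection coefficient for a tissue refractive index of ~1.37.
DEFAULT_RF = 0.431


def diffusion_coefficient(
    optics: OpticalProperties, mus_interpretation: str = "reduced"
) -> float:
    """Diffusion coefficient D (mm) from tissue optics.

    The table values are read as reduced scattering mu_s' = (1-g)*mu_s by
    default, giving D = 1/(3*(mu_a + mu_s')); magnitudes of 0.5-2.5 mm^-1
    match published reduced coefficients at 630 nm.  The ``literal`` mode
    re-applies the (1-g) factor for tables that list plain mu_s.
    """
    if mus_interpretation == "reduced":
        mus = optics.mu_s_prime
    elif mus_interpretation == "literal":
        mus = (1.0 - optics.g) * optics.mu_s_prime
    else:
        raise ValueError(f"unknown mus_interpretation {mus_interpretation!r}")
    denom = optics.mu_a + mus
    if denom <= 0:
        raise ValueError("mu_a + mu_s' must be positive")
    return 1.0 / (3.0 * denom)


def boundary_factor(rf: float) -> float:
    """Boundary mismatch factor F = (1+Rf)/(1-Rf), >= 1 for Rf in [0, 1)."""
    if not (0.0 <= rf < 1.0):
        raise ValueError(f"Rf must be in [0, 1), got {rf}")
    return (1.0 + rf) / (1.0 - rf)


@dataclass
class FemSystem:
    """Assembled P1 FEM system for the diffusion model.

    K is the sparse symmetric operator (stiffness + absorption mass +
    Robin surface term) over all mesh nodes.
    """

    K: sp.csr_matrix
    mesh: TetMesh
    boundary_nodes: np.ndarray
    rf: float
    F: float
    lumped_mass: np.ndarray


# consistent P1 mass matrices (unit volume / unit area factors)
_MASS_TET = (np.ones((4, 4)) + np.eye(4)) / 20.0
_MASS_TRI = (np.ones((3, 3)) + np.eye(3)) / 12.0


def assemble_fem(
    mesh: TetMesh,
    optics: dict[str, OpticalProperties],
    rf: float = DEFAULT_RF,
    mus_interpretation: str = "reduced",
) -> FemSystem:
    """Assemble K = sum_tets (D*stiffness + mu_a*mass) + (1/2F)*surface mass.

    Every region label of the mesh must have an entry in ``optics``.
    The result is symmetric positive definite whenever mu_a > 0 everywhere.
    """
    missing = set(map(str, mesh.region_label)) - set(optics)
    if missing:
        raise ValueError(f"no optical properties for regions: {sorted(missing)}")
    F = boundary_factor(rf)

    n = mesh.n_nodes
    tets = mesh.tets
    ntet = len(tets)
    p = mesh.nodes[tets]  # (ntet, 4, 3)

    # vectorized P1 gradients: J columns are edge vectors from vertex 0
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
    detJ = np.linalg.det(J)
    if np.any(np.abs(detJ) < 1e-300):
        raise ValueError("degenerate element (zero volume)")
    V = np.abs(detJ) / 6.0
    invJ = np.linalg.inv(J)  # row i of J^-1 = grad of barycentric coord i+1
    grads = np.empty((ntet, 4, 3))
    grads[:, 1:, :] = invJ
    grads[:, 0, :] = -invJ.sum(axis=1)

    D = np.empty(ntet)
    mua = np.empty(ntet)
    per_region: dict[str, tuple[float, float]] = {}
    for name, op in optics.items():
        per_region[name] = (diffusion_coefficient(op, mus_interpretation), op.mu_a)
    for r, lbl in enumerate(mesh.region_label):
        D[r], mua[r] = per_region[str(lbl)]

    # element matrices: D*V*(g_i . g_j) + mu_a*V*M_tet
    gg = np.einsum("tia,tja->tij", grads, grads)
    Ke = (D * V)[:, None, None] * gg + (mua * V)[:, None, None] * _MASS_TET

    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    # Robin term: (1/2F) * triangle consistent mass over boundary faces
    bf = mesh.boundary_faces
    if len(bf):
        q = mesh.nodes[bf]
        area = 0.5 * np.linalg.norm(
            np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]), axis=1
        )
        Be = (area / (2.0 * F))[:, None, None] * _MASS_TRI
        rows = np.repeat(bf, 3, axis=1).ravel()
        cols = np.tile(bf, (1, 3)).ravel()
        K = K + sp.coo_matrix((Be.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    # row-sum lumped volume mass (used for source-density loads and audits)
    Me = V[:, None] * np.full(4, 0.25)
    lumped = np.zeros(n)
    np.add.at(lumped, tets.ravel(), Me.ravel())

    return FemSystem(
        K=K.tocsr(),
        mesh=mesh,
        boundary_nodes=mesh.boundary_node_indices(),
        rf=rf,
        F=F,
        lumped_mass=lumped,
    )


@dataclass
class SystemMatrix:
    """Dense M x N measurement operator mapping nodal sources to surface flux."""

    A: np.ndarray
    row_nodes: np.ndarray  # boundary node indices, length M
    col_nodes: np.ndarray  # candidate source node indices, length N

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


def build_system_matrix(
    fem: FemSystem, candidate_nodes: np.ndarray | None = None
) -> SystemMatrix:
    """Restrict the Green operator K^-1 to (boundary rows, candidate columns).

    Column j is the surface photon flow rate produced by a unit point
    source at candidate node j (nodal delta load e_j).  Since K is
    symmetric, A[b, j] = (K^-1)[b, j], computed with one sparse solve per
    boundary node (M << N).
    """
    if candidate_nodes is None:
        boundary = set(fem.boundary_nodes.tolist())
        candidate_nodes = np.array(
            [i for i in range(fem.mesh.n_nodes) if i not in boundary], dtype=np.int64
        )
    candidate_nodes = np.asarray(candidate_nodes, dtype=np.int64)
    if len(candidate_nodes) == 0:
        raise ValueError("candidate_nodes must be nonempty")

    lu = spla.splu(fem.K.tocsc())
    row_nodes = np.asarray(fem.boundary_nodes, dtype=np.int64)
    n = fem.mesh.n_nodes
    rhs = np.zeros((n, len(row_nodes)))
    rhs[row_nodes, np.arange(len(row_nodes))] = 1.0
    G = lu.solve(rhs)  # (n, M): column b = K^-1 e_b
    A = G[candidate_nodes, :].T.copy()  # A[b, j] = K^-1[b, cand_j]
    if not np.all(np.isfinite(A)):
        raise FloatingPointError("system matrix contains NaN/Inf (singular K?)")
    return SystemMatrix(A=A, row_nodes=row_nodes, col_nodes=candidate_nodes)


def simulate_surface_flux(
    system: SystemMatrix | np.ndarray,
    x_true: np.ndarray,
    noise_level: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy surface measurement B = A x (1 + eps), eps ~ N(0, noise_level).

    Multiplicative Gaussian noise is a proxy for CCD shot noise; negative
    entries are clamped to zero.  Deterministic for a given seed.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    A = system.A if isinstance(system, SystemMatrix) else np.asarray(system)
    b = A @ np.asarray(x_true, dtype=float)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        b = b * (1.0 + rng.normal(0.0, noise_level, size=b.shape))
    return np.maximum(b, 0.0)
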