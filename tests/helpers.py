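"""Shared oracles for the test suite."""

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from peddrs.forward_model import assemble_fem, diffusion_coefficient
from peddrs.phantom_mesh import TISSUE_OPTICS, build_structured_tet_mesh


def mms_convergence_slope(hs=(0.25, 0.125, 0.0625)):
    """Empirical convergence order of the FEM solver on a manufactured solution.

    On the unit muscle cube a smooth cosine field phi* is imposed via the
    matching volume source S = -div(D grad phi*) + mu_a phi* and the
    inhomogeneous Robin data g = phi* + 2 F D dphi*/dn; the discrete
    solution is compared to phi* in the (mass-weighted) L2 norm across
    refinements and the log-log slope returned (expect ~2 for P1 elements).
    """
    op = TISSUE_OPTICS["Muscle"]
    D = diffusion_coefficient(op)
    k = np.array([1.0, 2.0, 1.5]) * np.pi / 2
    k2 = float(np.sum(k**2))

    def phi_star(p):
        return np.cos(k[0] * p[:, 0]) * np.cos(k[1] * p[:, 1]) * np.cos(k[2] * p[:, 2]) + 2.0

    def source(p):
        return D * k2 * (phi_star(p) - 2.0) + op.mu_a * phi_star(p)

    def grad_phi(p):
        cx, cy, cz = (np.cos(k[i] * p[:, i]) for i in range(3))
        sx, sy, sz = (np.sin(k[i] * p[:, i]) for i in range(3))
        return np.column_stack(
            [-k[0] * sx * cy * cz, -k[1] * cx * sy * cz, -k[2] * cx * cy * sz]
        )

    errors = []
    for h in hs:
        mesh = build_structured_tet_mesh((1.0, 1.0, 1.0), h)
        fem = assemble_fem(mesh, {"Muscle": op})
        n = mesh.n_nodes
        tets = mesh.tets
        V = mesh.tet_volumes()
        Me = V[:, None, None] * (np.ones((4, 4)) + np.eye(4)) / 20.0
        rows = np.repeat(tets, 4, axis=1).ravel()
        cols = np.tile(tets, (1, 4)).ravel()
        M = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        rhs = M @ source(mesh.nodes)

        # Robin data g assembled per face with that face's outward normal
        # (nodal normals are ambiguous on box edges/corners)
        bf = mesh.boundary_faces
        q = mesh.nodes[bf]
        cr = np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0])
        area = 0.5 * np.linalg.norm(cr, axis=1)
        nrm = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        outward = np.einsum("ij,ij->i", nrm, q.mean(axis=1) - mesh.nodes.mean(axis=0)) < 0
        nrm[outward] *= -1
        tri_mass = (np.ones((3, 3)) + np.eye(3)) / 12.0
        for f in range(len(bf)):
            verts = bf[f]
            gp = grad_phi(mesh.nodes[verts])
            g_vals = phi_star(mesh.nodes[verts]) + 2 * fem.F * D * gp @ nrm[f]
            rhs[verts] += (area[f] / (2.0 * fem.F)) * (tri_mass @ g_vals)

        phi_h = spla.spsolve(fem.K.tocsc(), rhs)
        err = phi_h - phi_star(mesh.nodes)
        errors.append(np.sqrt(err @ (M @ err)))
    return float(np.polyfit(np.log(hs), np.log(errors), 1)[0])
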