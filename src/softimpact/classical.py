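"""Conventional time-stepping FEM comparator.

A deliberately independent implementation of small-strain elastodynamics on
the same P1 tetrahedral meshes: semi-discrete system M dv/dt + C v + K u = f
integrated with backward Euler,

    (M/h + C + h K) v_{n+1} = f + M v_n / h - K u_n,
    u_{n+1} = u_n + h v_{n+1}.

It shares no assembly code with the space-time solver (plain per-element
loops, no caching, no geometry update) and exists solely as a verification
oracle: the space-time slab solution must converge to this classical
solution as the slab size shrinks.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import ViscoelasticMaterial
from .mesh import Mesh

__all__ = ["backward_euler_elastic"]


def _element_geometry(p: np.ndarray):
    J = (p[1:] - p[0]).T
    V = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    grads = np.vstack([-Jinv.sum(axis=0), Jinv])
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    return V, B


def backward_euler_elastic(mesh: Mesh, material: ViscoelasticMaterial, h: float,
                           n_steps: int, f_ext: np.ndarray | None = None,
                           v0: np.ndarray | None = None,
                           fixed_dofs: np.ndarray | None = None):
    """March n_steps of backward Euler; returns (times, velocity history).

    ``f_ext`` is a nodal force vector, or a callable ``f(t)`` evaluated at
    the end of each step; ``fixed_dofs`` are pinned to zero velocity.  The
    Kelvin-Voigt dashpot contributes a strain-rate damping matrix assembled
    like the stiffness.
    """
    ndof = 3 * mesh.n_nodes
    Cel = material.stiffness_matrix()
    Cvis = material.damping_matrix()
    rows, cols, kdata, cdata, mdata = [], [], [], [], []
    for tet in mesh.tets:
        V, B = _element_geometry(mesh.nodes[tet])
        Ke = B.T @ Cel @ B * V
        Ce = B.T @ Cvis @ B * V
        Me = np.kron((np.ones((4, 4)) + np.eye(4)) / 20.0, np.eye(3)) * material.rho * V
        dofs = (3 * tet[:, None] + np.arange(3)).ravel()
        for a in range(12):
            for b in range(12):
                rows.append(dofs[a])
                cols.append(dofs[b])
                kdata.append(Ke[a, b])
                cdata.append(Ce[a, b])
                mdata.append(Me[a, b])
    K = sp.coo_matrix((kdata, (rows, cols)), shape=(ndof, ndof)).tocsr()
    C = sp.coo_matrix((cdata, (rows, cols)), shape=(ndof, ndof)).tocsr()
    M = sp.coo_matrix((mdata, (rows, cols)), shape=(ndof, ndof)).tocsr()

    if f_ext is None:
        f_fun = lambda t: np.zeros(ndof)  # noqa: E731
    elif callable(f_ext):
        f_fun = f_ext
    else:
        f_const = np.asarray(f_ext, dtype=float)
        f_fun = lambda t: f_const  # noqa: E731
    v = np.zeros(ndof) if v0 is None else np.asarray(v0, dtype=float).copy()
    u = np.zeros(ndof)

    A = (M / h + C + h * K).tolil()
    if fixed_dofs is not None:
        for d in fixed_dofs:
            A.rows[d] = [int(d)]
            A.data[d] = [1.0]
    lu = spla.splu(A.tocsc())

    times = np.zeros(n_steps + 1)
    hist = np.zeros((n_steps + 1, ndof))
    hist[0] = v
    for n in range(n_steps):
        b = f_fun((n + 1) * h) + M @ v / h - K @ u
        if fixed_dofs is not None:
            b[fixed_dofs] = 0.0
        v = lu.solve(b)
        u = u + h * v
        times[n + 1] = (n + 1) * h
        hist[n + 1] = v
    return times, hist
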