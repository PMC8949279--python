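"""Space-time finite element solver over successive time slabs.

Unknowns are nodal velocities.  Within one slab [t, t+h] the velocity is
interpolated linearly in time between the (known) slab-start values and the
(unknown) slab-end values, and linearly in space over P1 tetrahedra, so the
space-time interpolation matrices carry twice the columns of their spatial
counterparts.  Testing with the time shape function of the unknown end
values (Bubnov-Galerkin restricted to the unknown parameters) and
integrating the virtual-work terms exactly in time yields one algebraic
system per slab,

    (K + M + Z) v_new = F,

with M the inertia block (rho N^T dN/dt), Z external damping (c N^T N) and K
the slab-weighted constitutive block: rate-dependent apparent viscosity plus
the incompressibility penalty for viscoplastic elements, Kelvin-Voigt
stiffness/damping for (visco)elastic ones.  Displacements are recovered by
exact integration of the linear-in-time velocity.  The time weights of the
elastic displacement integral are shifted toward the slab end (coefficients
1/12 and 1/4, preserving the first-order consistency sum 1/3) so the scheme
stays stable for arbitrarily stiff elastic sub-domains; the pure
test-function weights are only conditionally stable.

The dependence of the viscoplastic matrices on the effective strain rate D
is resolved by Picard iteration with damped, decade-capped log-space updates
of the element viscosities and adaptive under-relaxation of the velocity
iterate (which also contracts contact on/off limit cycles).  The solve is
performed in increment form with translation-exact internal forces, making
rigid motion an exact fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import (
    DEVIATORIC_VISCOUS_VOIGT,
    ViscoelasticMaterial,
    ViscoplasticMaterial,
    apparent_viscosity,
    penalty_block,
)
from .mesh import Mesh

__all__ = [
    "SolverConfig",
    "SolverState",
    "SystemMatrices",
    "Stepper",
    "PicardError",
    "assemble",
    "step",
    "element_matrices",
    "incompressibility_residual",
    "total_momentum",
    "kinetic_energy",
    "save_state",
    "load_state",
]

# consistent P1 tet mass template: int N_a N_b dV = V * (1 + delta_ab) / 20
_LOG_DECADE = np.log(10.0)
_T4 = (np.ones((4, 4)) + np.eye(4)) / 20.0
_MASS_TEMPLATE = np.kron(_T4, np.eye(3))  # (12, 12)


class PicardError(RuntimeError):
    """Picard iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass
class SolverConfig:
    """Numerical knobs of the slab solver.

    picard_tol is the relative velocity-change tolerance, picard_relaxation
    the log-space under-relaxation factor applied to element viscosities
    (1 = full update).  update_geometry selects the updated-Lagrangian mode
    in which the assembly geometry follows the accumulated displacement;
    node positions (and hence contact) always track the motion either way.
    The default is the small-strain geometric treatment: under strongly
    softening flow the deformation localises and linear tetrahedra invert
    long before the impact window ends, and remeshing is out of scope.
    """

    picard_tol: float = 1.0e-6
    picard_max_iter: int = 120
    picard_relaxation: float = 0.7
    update_geometry: bool = False


@dataclass
class SolverState:
    """Solution state at a slab boundary."""

    t: float
    v: np.ndarray                 # (3N,) nodal velocities
    coords: np.ndarray            # (N, 3) current node positions
    u: np.ndarray                 # (3N,) accumulated displacement
    elastic_strain: np.ndarray    # (E, 6) accumulated Voigt strain (elastic elements)
    D_field: np.ndarray           # (E,) effective strain rate of the last slab

    @classmethod
    def initial(cls, mesh: Mesh, velocity: np.ndarray | None = None) -> "SolverState":
        v = np.zeros(3 * mesh.n_nodes)
        if velocity is not None:
            velocity = np.asarray(velocity, dtype=float)
            if velocity.shape == (3,):
                v = np.tile(velocity, mesh.n_nodes)
            else:
                v = velocity.reshape(-1).copy()
        return cls(
            t=0.0,
            v=v,
            coords=mesh.nodes.copy(),
            u=np.zeros(3 * mesh.n_nodes),
            elastic_strain=np.zeros((mesh.n_elements, 6)),
            D_field=np.zeros(mesh.n_elements),
        )

    def copy(self) -> "SolverState":
        return SolverState(self.t, self.v.copy(), self.coords.copy(), self.u.copy(),
                           self.elastic_strain.copy(), self.D_field.copy())


@dataclass
class SystemMatrices:
    """Assembled slab operators of (K + M + Z) v_new = F."""

    K_stiffness: sp.csr_matrix
    M_inertia: sp.csr_matrix
    Z_damping: sp.csr_matrix
    F_load: np.ndarray

    @property
    def lhs(self) -> sp.csr_matrix:
        return (self.K_stiffness + self.M_inertia + self.Z_damping).tocsr()


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _geometry(coords: np.ndarray, tets: np.ndarray):
    """Per-element volumes, strain-displacement matrices and dof maps."""
    p = coords[tets]                      # (E, 4, 3)
    J = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))   # columns = edge vectors
    detJ = np.linalg.det(J)
    V = detJ / 6.0
    if np.any(V <= 0):
        bad = int(np.argmin(V))
        raise RuntimeError(f"element {bad} has degenerate/inverted geometry (V={V[bad]:.3e})")
    Jinv = np.linalg.inv(J)               # (E, 3, 3); row a-1 = grad N_a
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:] = Jinv
    grads[:, 0] = -Jinv.sum(axis=1)

    E = len(tets)
    B = np.zeros((E, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    dofmap = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 12)
    return V, B, dofmap


def _scatter(blocks: np.ndarray, dofmap: np.ndarray, ndof: int) -> sp.csr_matrix:
    """Sum dense (E,12,12) element blocks into a global sparse matrix."""
    rows = np.repeat(dofmap, 12, axis=1).ravel()
    cols = np.tile(dofmap, (1, 12)).ravel()
    A = sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=(ndof, ndof))
    return A.tocsr()


def _element_rates(B, dofmap, v):
    """Voigt strain rates (E,6), deviatoric effective rate D (E,) and div v (E,).

    The first node's velocity is subtracted before applying B (a no-op in
    exact arithmetic) so rigid translations give exactly zero rates instead
    of catastrophically cancelled roundoff — essential because the
    floor-regularised viscosity can amplify such noise by ~1e10.
    """
    ve = v[dofmap].reshape(len(B), 4, 3)
    ve = (ve - ve[:, :1]).reshape(len(B), 12)
    rate = np.einsum("eij,ej->ei", B, ve)           # engineering Voigt
    div = rate[:, :3].sum(axis=1)
    ndev = rate[:, :3] - div[:, None] / 3.0
    inner = (ndev**2).sum(axis=1) + 0.5 * (rate[:, 3:] ** 2).sum(axis=1)
    D = np.sqrt(2.0 / 3.0 * inner)
    return rate, D, div


# ---------------------------------------------------------------------------
# stepper
# ---------------------------------------------------------------------------

class Stepper:
    """Slab-marching solver bound to one mesh and material map.

    ``materials`` maps element material tags to material objects.  Results
    are independent of element order (scatter-add with deterministic sparse
    summation) and bit-reproducible for identical inputs.
    """

    def __init__(self, mesh: Mesh, materials: dict[int, object],
                 config: SolverConfig | None = None):
        mesh.validate()
        self.mesh = mesh
        self.materials = dict(materials)
        self.config = config or SolverConfig()
        missing = set(np.unique(mesh.element_tags)) - set(self.materials)
        if missing:
            raise ValueError(f"no material bound to element tags {sorted(missing)}")
        self.ndof = 3 * mesh.n_nodes
        tags = mesh.element_tags
        self._vp_mask = np.array(
            [isinstance(self.materials[int(t)], ViscoplasticMaterial) for t in tags]
        )
        self._cached_coords = None
        self._lu = None

    # -- per-geometry constants -------------------------------------------
    def _prepare(self, coords: np.ndarray):
        if self._cached_coords is not None and np.array_equal(coords, self._cached_coords):
            return
        self._cached_coords = coords.copy()
        self._lu = None
        mesh, mats = self.mesh, self.materials
        V, B, dofmap = _geometry(coords, mesh.tets)
        self.V, self.B, self.dofmap = V, B, dofmap
        tags = mesh.element_tags
        E = mesh.n_elements

        # shared sparsity pattern: precompute once where every (element, a, b)
        # entry lands in csr data, so per-iteration assembly is a scatter-add
        rows = np.repeat(dofmap, 12, axis=1).ravel()
        cols = np.tile(dofmap, (1, 12)).ravel()
        order = np.lexsort((cols, rows))
        r_s, c_s = rows[order], cols[order]
        new = np.empty(len(r_s), dtype=bool)
        new[0] = True
        new[1:] = (r_s[1:] != r_s[:-1]) | (c_s[1:] != c_s[:-1])
        gid = np.cumsum(new) - 1
        self._entry_pos = np.empty_like(order)
        self._entry_pos[order] = gid
        self._nnz = int(gid[-1]) + 1
        self._indices = c_s[new]
        counts = np.bincount(r_s[new], minlength=self.ndof)
        self._indptr = np.concatenate([[0], np.cumsum(counts)])

        rho = np.array([mats[int(t)].rho for t in tags])
        cdamp = np.array([getattr(mats[int(t)], "c_damping", 0.0) for t in tags])
        # external damping: viscoelastic c is a Kelvin-Voigt dashpot, not an
        # absolute-velocity drag, so Z only collects viscoplastic c
        z_coef = np.where(self._vp_mask, cdamp, 0.0)

        self._dM = self._block_data((rho * V)[:, None, None] * _MASS_TEMPLATE)
        self._dC = self._block_data((z_coef * V)[:, None, None] * _MASS_TEMPLATE)
        self.M_s = self._matrix(self._dM)
        self.C_s = self._matrix(self._dC)

        # constant constitutive blocks: Kelvin-Voigt stiffness + damping,
        # viscoplastic penalty
        Cel = np.zeros((E, 6, 6))
        Cvis_const = np.zeros((E, 6, 6))
        for tag, mat in mats.items():
            m = tags == tag
            if not m.any():
                continue
            if isinstance(mat, ViscoelasticMaterial):
                Cel[m] = mat.stiffness_matrix()
                Cvis_const[m] = mat.damping_matrix()
            elif isinstance(mat, ViscoplasticMaterial):
                Cvis_const[m] = penalty_block(mat.lambda_penalty)
            else:
                raise TypeError(f"unsupported material type {type(mat)!r} for tag {tag}")
        self._Cel = Cel
        self._Cvis_const_blocks = Cvis_const
        BtV = B * V[:, None, None]
        # per-element 12x12 operator templates; the rate-dependent block is
        # mu_e * P_dev_e, so Picard iterations only rescale precomputed data
        self._P_el = np.einsum("eji,ejk,ekl->eil", B, Cel, BtV)
        self._P_vc = np.einsum("eji,ejk,ekl->eil", B, Cvis_const, BtV)
        self._P_dev = np.einsum("eji,jk,ekl->eil", B, DEVIATORIC_VISCOUS_VOIGT, BtV)
        self._dKel = self._block_data(self._P_el)
        self._dKvc = self._block_data(self._P_vc)
        self.K_el = self._matrix(self._dKel)
        self.K_vis_const = self._matrix(self._dKvc)
        self._BtV = BtV

    def _block_data(self, blocks: np.ndarray, element_idx=None) -> np.ndarray:
        """Scatter dense element blocks into the shared csr data layout."""
        data = np.zeros(self._nnz)
        pos = self._entry_pos.reshape(-1, 144)
        if element_idx is not None:
            pos = pos[element_idx]
        np.add.at(data, pos.ravel(), blocks.ravel())
        return data

    def _matrix(self, data: np.ndarray) -> sp.csr_matrix:
        return sp.csr_matrix((data, self._indices, self._indptr),
                             shape=(self.ndof, self.ndof))

    def _dK_vis_vp(self, mu: np.ndarray) -> np.ndarray:
        """Viscoplastic deviatoric-viscosity data for element viscosities mu."""
        if not self._vp_mask.any():
            return np.zeros(self._nnz)
        idx = np.flatnonzero(self._vp_mask)
        blocks = mu[idx, None, None] * self._P_dev[idx]
        return self._block_data(blocks, element_idx=idx)

    def _viscosities(self, D: np.ndarray) -> np.ndarray:
        mu = np.zeros(self.mesh.n_elements)
        tags = self.mesh.element_tags
        for tag, mat in self.materials.items():
            if isinstance(mat, ViscoplasticMaterial):
                m = (tags == tag) & self._vp_mask
                if m.any():
                    mu[m] = apparent_viscosity(mat, D[m])
        return mu

    def _elastic_internal_force(self, elastic_strain: np.ndarray) -> np.ndarray:
        sigma = np.einsum("eij,ej->ei", self._Cel, elastic_strain)
        fe = np.einsum("eji,ej->ei", self._BtV, sigma)      # (E, 12)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofmap.ravel(), fe.ravel())
        return f

    def _constitutive_force(self, C_blocks: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Internal nodal force of per-element 6x6 operators acting on the
        strain rate of ``v`` (translation-exact, see _element_rates)."""
        rate, _, _ = _element_rates(self.B, self.dofmap, v)
        sigma = np.einsum("eij,ej->ei", C_blocks, rate)
        fe = np.einsum("eji,ej->ei", self._BtV, sigma)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofmap.ravel(), fe.ravel())
        return f

    def _template_force(self, P_blocks: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Internal force from precomputed 12x12 element operators, applied to
        translation-removed element velocities (exact on rigid motion)."""
        ve = v[self.dofmap].reshape(-1, 4, 3)
        ve = (ve - ve[:, :1]).reshape(-1, 12)
        fe = np.einsum("eab,eb->ea", P_blocks, ve)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofmap.ravel(), fe.ravel())
        return f

    def _Cvis_blocks(self, mu: np.ndarray | None) -> np.ndarray:
        """Per-element viscous operators: KV damping / penalty plus mu*dev."""
        C = self._Cvis_const_blocks.copy()
        if mu is not None and self._vp_mask.any():
            idx = np.flatnonzero(self._vp_mask)
            C[idx] += mu[idx, None, None] * DEVIATORIC_VISCOUS_VOIGT
        return C

    # -- assembly ----------------------------------------------------------
    def assemble(self, state: SolverState, h: float,
                 mu: np.ndarray | None = None,
                 external_force: np.ndarray | None = None) -> SystemMatrices:
        """Slab operators at the given state; mu overrides element viscosities."""
        self._prepare(state.coords if self.config.update_geometry else self.mesh.nodes)
        if mu is None:
            _, D, _ = _element_rates(self.B, self.dofmap, state.v)
            mu = self._viscosities(D)
        dKv = self._dKvc + self._dK_vis_vp(mu)
        K_v = self._matrix(dKv)
        K = self._matrix((h / 3.0) * dKv + (h * h / 4.0) * self._dKel)
        M = 0.5 * self.M_s
        Z = (h / 3.0) * self.C_s
        F = (
            self.M_s @ state.v * 0.5
            - (h / 6.0) * (self.C_s @ state.v + K_v @ state.v)
            - (h / 2.0) * self._elastic_internal_force(state.elastic_strain)
            - (h * h / 12.0) * (self.K_el @ state.v)
        )
        if external_force is not None:
            F = F + (h / 2.0) * external_force
        return SystemMatrices(K.tocsr(), M.tocsr(), Z.tocsr(), F)

    # -- stepping ----------------------------------------------------------
    def step(self, state: SolverState, h: float, external_force=None,
             fixed_dofs: np.ndarray | None = None,
             fixed_values: np.ndarray | float = 0.0) -> SolverState:
        """Advance one slab of size h.

        ``external_force`` may be a nodal force vector (3N,) or a callable
        ``f(state, v_iterate) -> vector`` re-evaluated inside the Picard loop
        (used for contact).  ``fixed_dofs`` pins velocity dofs to
        ``fixed_values``.
        """
        if h <= 0:
            raise ValueError("slab size h must be positive")
        cfg = self.config
        self._prepare(state.coords if cfg.update_geometry else self.mesh.nodes)

        has_vp = bool(self._vp_mask.any())
        force_callable = callable(external_force)
        v_old = state.v
        v_cur = v_old.copy()

        # warm-start viscosities from the previous slab's rate field
        mu_prev = self._viscosities(state.D_field) if has_vp else None

        lhs_const_cacheable = not has_vp
        history: list[float] = []
        max_iter = cfg.picard_max_iter if (has_vp or force_callable) else 1
        beta = cfg.picard_relaxation

        # solve in increment form A*(v_new - v_old) = residual(v_old); the
        # residual is built from element-wise internal forces that are exact
        # on rigid translations, so force-free uniform motion is an exact
        # fixed point regardless of the floor viscosity's magnitude
        has_fixed = fixed_dofs is not None and len(fixed_dofs) > 0
        alpha = 1.0
        self._prepare(state.coords if cfg.update_geometry else self.mesh.nodes)
        rhs_const = (
            -(h * h / 3.0) * self._template_force(self._P_el, v_old)
            - (h / 2.0) * self._elastic_internal_force(state.elastic_strain)
            - (h / 2.0) * (self.C_s @ v_old)
        )
        for it in range(max_iter):
            if has_vp:
                _, D_mid, _ = _element_rates(self.B, self.dofmap, 0.5 * (v_old + v_cur))
                mu_new = self._viscosities(D_mid)
                if it == 0:
                    mu = np.where(self._vp_mask, mu_new, 0.0)
                else:
                    # damped log-space update, capped to one decade per
                    # iteration: near the regularisation plateau the viscosity
                    # can jump ~1e12 between rigid and yielded states and an
                    # uncapped update cycles instead of converging
                    log_prev = np.log(np.maximum(mu_prev, 1e-300))
                    log_new = np.log(np.maximum(mu_new, 1e-300))
                    step_log = np.clip(beta * (log_new - log_prev),
                                       -_LOG_DECADE, _LOG_DECADE)
                    mu = np.where(self._vp_mask, np.exp(log_prev + step_log), 0.0)
                mu_prev = mu
            else:
                mu = None

            f_ext = external_force(state, v_cur) if force_callable else external_force
            P_vis = self._P_vc
            if has_vp:
                P_vis = P_vis + mu[:, None, None] * self._P_dev
            rhs = rhs_const - (h / 2.0) * self._template_force(P_vis, v_old)
            if f_ext is not None:
                rhs = rhs + (h / 2.0) * f_ext

            dKv = self._dKvc + self._dK_vis_vp(mu) if has_vp else self._dKvc
            A = self._matrix(
                0.5 * self._dM + (h / 3.0) * (self._dC + dKv)
                + (h * h / 4.0) * self._dKel
            )
            if has_fixed:
                vals = np.broadcast_to(
                    np.asarray(fixed_values, dtype=float), (len(fixed_dofs),)
                ) - v_old[fixed_dofs]
                A, rhs = _apply_dirichlet(A, rhs, fixed_dofs, vals)
            if lhs_const_cacheable:
                # elastic-only problems have a constant LHS (per geometry and
                # Dirichlet set): factorise once
                if self._lu is None:
                    self._lu = spla.splu(A.tocsc())
                dv = self._lu.solve(rhs)
            else:
                dv = spla.spsolve(A.tocsc(), rhs)
            v_new = v_old + dv
            if not np.all(np.isfinite(v_new)):
                raise RuntimeError(f"singular slab system at t={state.t:.6g}")

            denom = max(float(np.linalg.norm(v_new)), 1e-30)
            rel = float(np.linalg.norm(v_new - v_cur)) / denom
            history.append(rel)
            # adaptive velocity under-relaxation: a growing residual signals a
            # limit cycle (e.g. contact on/off flip); an averaged iterate
            # turns a pure two-state flip into a contraction, while smooth
            # convergence keeps the full update
            if len(history) > 1 and rel > history[-2]:
                alpha = max(0.5 * alpha, 0.02)
            else:
                alpha = min(1.0, 1.3 * alpha)
            v_cur = v_cur + alpha * (v_new - v_cur)
            if rel < cfg.picard_tol:
                v_cur = v_new
                break
        else:
            if max_iter > 1:
                raise PicardError(
                    f"Picard iteration did not converge in {max_iter} iterations "
                    f"at t={state.t:.6g} (last rel change {history[-1]:.3e})",
                    history,
                )

        # exact time integration of the linear-in-time velocity
        du = 0.5 * h * (v_old + v_cur)
        new = state.copy()
        new.v = v_cur
        new.u = state.u + du
        rate_mid, D_mid, _ = _element_rates(self.B, self.dofmap, 0.5 * (v_old + v_cur))
        new.D_field = D_mid
        # accumulate strain in elastic elements (B at slab-start geometry)
        el = ~self._vp_mask
        if el.any():
            deps = np.einsum("eij,ej->ei", self.B[el], du[self.dofmap[el]])
            new.elastic_strain[el] += deps
        new.coords = state.coords + du.reshape(-1, 3)
        new.t = state.t + h
        return new


def _apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs, values):
    A = A.tolil()
    b = b.copy()
    vals = np.broadcast_to(np.asarray(values, dtype=float), (len(dofs),))
    for d, val in zip(dofs, vals):
        A.rows[d] = [int(d)]
        A.data[d] = [1.0]
        b[d] = val
    return A.tocsr(), b


# ---------------------------------------------------------------------------
# free-function wrappers and diagnostics
# ---------------------------------------------------------------------------

def assemble(mesh: Mesh, materials: dict[int, object], state: SolverState,
             h: float, config: SolverConfig | None = None) -> SystemMatrices:
    """One-shot assembly of the slab system at the given state."""
    return Stepper(mesh, materials, config).assemble(state, h)


def step(state: SolverState, mesh: Mesh, materials: dict[int, object], h: float,
         external_force=None, config: SolverConfig | None = None,
         fixed_dofs=None, fixed_values=0.0) -> SolverState:
    """Advance one slab without retaining solver caches."""
    return Stepper(mesh, materials, config).step(
        state, h, external_force, fixed_dofs=fixed_dofs, fixed_values=fixed_values
    )


def element_matrices(coords4: np.ndarray, material, h: float,
                     v0: np.ndarray | None = None,
                     elastic_strain0: np.ndarray | None = None,
                     external_force: np.ndarray | None = None):
    """Slab matrices of a single tetrahedron, for verification.

    Returns (Ke, Me, Ze, Fe): the 12x12 blocks multiplying the unknown
    end-of-slab velocities and the right-hand side collecting the known
    slab-start contributions.
    """
    mesh = Mesh(np.asarray(coords4, dtype=float), np.arange(4).reshape(1, 4),
                {"measurement_point": np.array([0])})
    st = SolverState.initial(mesh)
    if v0 is not None:
        st.v = np.asarray(v0, dtype=float).reshape(-1).copy()
    if elastic_strain0 is not None:
        st.elastic_strain[0] = np.asarray(elastic_strain0, dtype=float)
    sysm = Stepper(mesh, {1: material}).assemble(st, h, external_force=external_force)
    return (sysm.K_stiffness.toarray(), sysm.M_inertia.toarray(),
            sysm.Z_damping.toarray(), sysm.F_load)


def incompressibility_residual(state: SolverState, mesh: Mesh,
                               materials: dict[int, object] | None = None) -> float:
    """L2 norm of div v over the viscoplastic subdomain, sqrt(sum V_e div_e^2)."""
    V, B, dofmap = _geometry(state.coords, mesh.tets)
    _, _, div = _element_rates(B, dofmap, state.v)
    if materials is not None:
        mask = np.array(
            [isinstance(materials[int(t)], ViscoplasticMaterial) for t in mesh.element_tags]
        )
    else:
        mask = np.ones(mesh.n_elements, dtype=bool)
    return float(np.sqrt(np.sum(V[mask] * div[mask] ** 2)))


def save_state(state: SolverState, path) -> None:
    """Checkpoint a solver state (numpy archive) so long runs can resume."""
    np.savez_compressed(
        path, t=state.t, v=state.v, coords=state.coords, u=state.u,
        elastic_strain=state.elastic_strain, D_field=state.D_field,
    )


def load_state(path) -> SolverState:
    with np.load(path) as data:
        return SolverState(
            t=float(data["t"]), v=data["v"], coords=data["coords"], u=data["u"],
            elastic_strain=data["elastic_strain"], D_field=data["D_field"],
        )


def _mass_matrix(state: SolverState, mesh: Mesh, materials: dict[int, object],
                 current_geometry: bool = True):
    coords = state.coords if current_geometry else mesh.nodes
    V, B, dofmap = _geometry(coords, mesh.tets)
    rho = np.array([materials[int(t)].rho for t in mesh.element_tags])
    return _scatter((rho * V)[:, None, None] * _MASS_TEMPLATE, dofmap, 3 * mesh.n_nodes)


def total_momentum(state: SolverState, mesh: Mesh, materials: dict[int, object],
                   current_geometry: bool = True) -> np.ndarray:
    """Total linear momentum (3,) with the consistent mass matrix."""
    Mv = _mass_matrix(state, mesh, materials, current_geometry) @ state.v
    return Mv.reshape(-1, 3).sum(axis=0)


def kinetic_energy(state: SolverState, mesh: Mesh, materials: dict[int, object],
                   current_geometry: bool = True) -> float:
    """Kinetic energy 0.5 v^T M v; set current_geometry=False to evaluate on
    the reference configuration (the solver's geometry in small-strain mode)."""
    M = _mass_matrix(state, mesh, materials, current_geometry)
    return float(0.5 * state.v @ (M @ state.v))
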