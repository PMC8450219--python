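"""Quasi-static beam mechanics of periodic fiber networks.

Fibers are discretized into two-node geometrically nonlinear beam
elements with axial, bending (two planes) and torsion stiffness plus a
small Timoshenko-style shear compliance (negligible for slender fibers,
kept for regularity).  Each mesh node carries a translation and a
rotation triad; fibers joining at a node are rigidly coupled in both,
which models covalent inter-fiber bonds as rigid joints.

Element kinematics use one-point Cosserat strain measures.  With node
triads ``R_i, R_j``, element vector ``d`` (including the periodic shift
translation) and mid-triad ``R_m = R_i exp(phi/2)`` where
``phi = log(R_i^T R_j)``:

* translational strain  ``Gamma = R_m^T d / L0``   (axial + shear)
* rotational strain     ``kappa = (phi - phi0) / L0``  (bending + torsion)

and the stored energy is quadratic in ``Gamma - Gamma0`` and ``kappa``
with moduli resolved along the element's reference tangent.  Reference
values ``Gamma0, phi0`` are recorded at element creation, which makes
runtime-added cross-links stress-free in the configuration where they
form.  Internal forces are the exact (trivialized) gradient of this
energy — derived with the SO(3) left Jacobian — and the tangent matrix
is obtained by differencing that analytic gradient, so Newton iterations
inherit energy consistency to machine precision.

Units: μm, s, pN; moduli and stress in Pa (1 pN/μm² = 1 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import NetworkGraph
from .periodic import PeriodicBox
from .rotations import exp_so3, hat, left_jacobian, left_jacobian_inv, log_so3

DEFAULT_FIBER_MODULUS = 1.1e6  # Pa, collagen type I fiber


@dataclass
class BeamProperties:
    """Section and material constants of a circular-cross-section fiber."""

    youngs_modulus: float = DEFAULT_FIBER_MODULUS  # Pa = pN/μm²
    diameter: float = 0.18  # μm
    poisson: float = 0.3
    shear_factor: float = 0.9  # Timoshenko shear correction (circular section)

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0 or self.diameter <= 0:
            raise ValueError("modulus and diameter must be positive")

    @property
    def area(self) -> float:
        return np.pi * self.diameter**2 / 4.0

    @property
    def second_moment(self) -> float:
        return np.pi * self.diameter**4 / 64.0

    @property
    def polar_moment(self) -> float:
        return np.pi * self.diameter**4 / 32.0

    @property
    def shear_modulus(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson))

    @property
    def EA(self) -> float:
        return self.youngs_modulus * self.area

    @property
    def EI(self) -> float:
        return self.youngs_modulus * self.second_moment

    @property
    def GJ(self) -> float:
        return self.shear_modulus * self.polar_moment

    @property
    def GAs(self) -> float:
        return self.shear_modulus * self.area * self.shear_factor


class BeamMesh:
    """Discretized beam network: nodes, elements, and periodic metadata.

    Elements may be fiber elements (created by :func:`discretize`) or
    cross-link elements appended at run time; dead cross-links are
    masked out of assembly rather than deleted.
    """

    def __init__(self, X: np.ndarray, box_lengths: np.ndarray):
        self.X = np.asarray(X, float).reshape(-1, 3)
        self.box_lengths = np.asarray(box_lengths, float).reshape(3)
        self.conn = np.empty((0, 2), int)
        self.shift = np.empty((0, 3), float)
        self.L0 = np.empty(0)
        self.gamma0 = np.empty((0, 3))
        self.phi0 = np.empty((0, 3))
        self.EA = np.empty(0)
        self.GAs = np.empty(0)
        self.GJ = np.empty(0)
        self.EI = np.empty(0)
        self.alive = np.empty(0, bool)
        self.element_segment = np.empty(0, int)  # owning network segment, -1 = cross-link
        self.segment_chains: list[np.ndarray] = []  # mesh nodes along each network segment
        self.chain_arcs: list[np.ndarray] = []  # arc-length coordinate of those nodes
        self.network_node_map = np.empty(0, int)

    # -- construction ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.X)

    @property
    def n_elements(self) -> int:
        return len(self.conn)

    def append_elements(
        self,
        conn: np.ndarray,
        shift: np.ndarray,
        L0: np.ndarray,
        gamma0: np.ndarray,
        phi0: np.ndarray,
        props: BeamProperties,
        segment_ids: np.ndarray,
    ) -> np.ndarray:
        k = len(conn)
        ids = np.arange(self.n_elements, self.n_elements + k)
        self.conn = np.vstack([self.conn, np.asarray(conn, int).reshape(-1, 2)])
        self.shift = np.vstack([self.shift, np.asarray(shift, float).reshape(-1, 3)])
        self.L0 = np.concatenate([self.L0, np.asarray(L0, float)])
        self.gamma0 = np.vstack([self.gamma0, np.asarray(gamma0, float).reshape(-1, 3)])
        self.phi0 = np.vstack([self.phi0, np.asarray(phi0, float).reshape(-1, 3)])
        # residual-bending-flexibility (MacNeal) correction: the effective
        # shear stiffness 1/(1/GAs + L0^2/(12 EI)) makes the one-point
        # element nodally exact for linear bending at any mesh density
        L0 = np.asarray(L0, float)
        GAs_eff = 1.0 / (1.0 / props.GAs + L0**2 / (12.0 * props.EI))
        for name, val in (("EA", np.full(k, props.EA)), ("GAs", GAs_eff),
                          ("GJ", np.full(k, props.GJ)), ("EI", np.full(k, props.EI))):
            setattr(self, name, np.concatenate([getattr(self, name), val]))
        self.alive = np.concatenate([self.alive, np.ones(k, bool)])
        self.element_segment = np.concatenate([self.element_segment, np.asarray(segment_ids, int)])
        return ids

    def total_length(self) -> float:
        return float(self.L0[self.alive].sum())


def discretize(net: NetworkGraph, elements_per_segment: int, props: BeamProperties) -> BeamMesh:
    """Subdivide each free-fiber segment into a chain of beam elements.

    Interior nodes are placed on the straight segment, wrapped into the
    box; junction nodes are shared between fibers, coupling translations
    and rotations rigidly.
    """
    if elements_per_segment < 1:
        raise ValueError("elements_per_segment must be >= 1")
    net.validate()
    box = PeriodicBox(net.box_lengths)
    L = net.box_lengths
    lengths = net.segment_lengths()
    if np.any(lengths <= 0):
        raise ValueError("zero-length segment")

    X_list = [net.nodes.copy()]
    n_nodes = net.n_nodes
    conn, shifts, L0s, seg_of = [], [], [], []
    chains, arcs = [], []
    vecs = net.segment_vectors()

    for s, ((a, b), svec, sh) in enumerate(zip(net.segments, vecs, net.shifts)):
        p0 = net.nodes[a]
        n_e = elements_per_segment
        # interior points on the unwrapped straight segment
        ts = np.arange(1, n_e) / n_e
        pts = p0 + ts[:, None] * svec
        wrapped = pts - np.floor(pts / L) * L
        k_int = np.round((pts - wrapped) / L).astype(int)
        ids = [a] + list(range(n_nodes, n_nodes + n_e - 1)) + [b]
        kshift = [np.zeros(3, int)] + list(k_int) + [np.asarray(sh, int)]
        if n_e > 1:
            X_list.append(wrapped)
            n_nodes += n_e - 1
        for t in range(n_e):
            conn.append((ids[t], ids[t + 1]))
            shifts.append(kshift[t + 1] - kshift[t])
            L0s.append(lengths[s] / n_e)
            seg_of.append(s)
        chains.append(np.array(ids))
        arcs.append(np.arange(n_e + 1) * lengths[s] / n_e)

    mesh = BeamMesh(np.vstack(X_list), L)
    conn = np.array(conn)
    shifts = np.array(shifts, float)
    L0s = np.array(L0s)
    d0 = mesh.X[conn[:, 1]] + shifts * L - mesh.X[conn[:, 0]]
    gamma0 = d0 / L0s[:, None]
    mesh.append_elements(conn, shifts, L0s, gamma0, np.zeros((len(conn), 3)), props, np.array(seg_of))
    mesh.segment_chains = chains
    mesh.chain_arcs = arcs
    mesh.network_node_map = np.arange(net.n_nodes)
    assert abs(mesh.total_length() - lengths.sum()) < 1e-8 * max(lengths.sum(), 1.0)
    return mesh


@dataclass
class SpringSet:
    """Tension-only springs between point particles and mesh nodes.

    Used for actin stress fibers: endpoint ``a`` is a particle (cell
    center), endpoint ``b`` a mesh node, with a fixed periodic image
    shift chosen when the spring forms.
    """

    particle: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    node: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    shift: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    k: np.ndarray = field(default_factory=lambda: np.empty(0))
    l0: np.ndarray = field(default_factory=lambda: np.empty(0))
    alive: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def __len__(self) -> int:
        return len(self.particle)

    def add(self, particle: int, node: int, shift, k: float, l0: float) -> int:
        i = len(self.particle)
        self.particle = np.append(self.particle, particle)
        self.node = np.append(self.node, node)
        self.shift = np.vstack([self.shift, np.asarray(shift, float).reshape(1, 3)])
        self.k = np.append(self.k, k)
        self.l0 = np.append(self.l0, l0)
        self.alive = np.append(self.alive, True)
        return i


@dataclass
class MechanicalState:
    """Equilibrium unknowns: nodal translations/rotations and particle positions."""

    u: np.ndarray  # (N, 3) nodal translations, μm
    R: np.ndarray  # (N, 3, 3) nodal rotation triads
    p: np.ndarray  # (P, 3) particle (cell center) positions, μm
    stretch: np.ndarray = field(default_factory=lambda: np.ones(3))
    residual_norm: float = np.inf
    converged: bool = False
    n_iterations: int = 0

    @classmethod
    def reference(cls, mesh: BeamMesh, particles: np.ndarray | None = None) -> "MechanicalState":
        n = mesh.n_nodes
        p = np.empty((0, 3)) if particles is None else np.asarray(particles, float).reshape(-1, 3).copy()
        return cls(np.zeros((n, 3)), np.broadcast_to(np.eye(3), (n, 3, 3)).copy(), p)

    def copy(self) -> "MechanicalState":
        return MechanicalState(
            self.u.copy(), self.R.copy(), self.p.copy(), self.stretch.copy(),
            self.residual_norm, self.converged, self.n_iterations,
        )


@dataclass
class StressRecord:
    """First Piola–Kirchhoff boundary stress of the RVE.

    ``normal_stress[i]`` is the tensile normal stress (Pa) transmitted
    across a periodic cut perpendicular to axis ``i``; ``face_minus`` /
    ``face_plus`` are the same quantity evaluated on two distinct cuts
    (at 0 and L/2), whose agreement is an equilibrium check.  Reference
    (undeformed) face areas are used, per the first PK convention.
    """

    time: float
    face_minus: np.ndarray
    face_plus: np.ndarray
    stretch: np.ndarray
    converged: bool

    @property
    def normal_stress(self) -> np.ndarray:
        return 0.5 * (self.face_minus + self.face_plus)


# ---------------------------------------------------------------------------
# element kernel
# ---------------------------------------------------------------------------


def _beam_energy_grad(xi, Ri, xj, Rj, Delta, L0, gamma0, phi0, t0, EA, GAs, GJ, EI, energy_only=False):
    """Batched element energy and exact trivialized gradient.

    Returns ``(energy (E,), grad (E, 12), force (E, 3))`` with gradient
    blocks ordered ``[du_i, dw_i, du_j, dw_j]``; rotational entries are
    derivatives with respect to spatial (left) rotation increments.
    With ``energy_only`` the gradient and force are ``None``.
    """
    d = xj + Delta - xi
    Rrel = np.einsum("eji,ejk->eik", Ri, Rj)
    phi = log_so3(Rrel)
    Rm = Ri @ exp_so3(0.5 * phi)
    Gam = np.einsum("eji,ej->ei", Rm, d) / L0[:, None]
    eG = Gam - gamma0
    ek = (phi - phi0) / L0[:, None]

    t0eG = np.einsum("ei,ei->e", t0, eG)
    t0ek = np.einsum("ei,ei->e", t0, ek)
    CG_eG = GAs[:, None] * eG + ((EA - GAs) * t0eG)[:, None] * t0
    Ck_ek = EI[:, None] * ek + ((GJ - EI) * t0ek)[:, None] * t0

    energy = 0.5 * L0 * (np.einsum("ei,ei->e", eG, CG_eG) + np.einsum("ei,ei->e", ek, Ck_ek))
    if energy_only:
        return energy, None, None

    n = np.einsum("eij,ej->ei", Rm, CG_eG)  # spatial force
    Jinv = left_jacobian_inv(phi)
    S = 0.5 * Ri @ left_jacobian(0.5 * phi) @ Jinv @ np.swapaxes(Ri, -1, -2)
    gk = np.einsum("eij,ekj,ek->ei", Ri, Jinv, Ck_ek)
    nxd = np.cross(n, d)

    g = np.empty((len(L0), 12))
    g[:, 0:3] = -n
    g[:, 6:9] = n
    ImS_T = np.swapaxes(np.broadcast_to(np.eye(3), S.shape) - S, -1, -2)
    g[:, 3:6] = np.einsum("eij,ej->ei", ImS_T, nxd) - gk
    g[:, 9:12] = np.einsum("eji,ej->ei", S, nxd) + gk
    return energy, g, n


def _gather_element_state(mesh: BeamMesh, state: MechanicalState, alive_idx: np.ndarray):
    i = mesh.conn[alive_idx, 0]
    j = mesh.conn[alive_idx, 1]
    Lcur = mesh.box_lengths * state.stretch
    Delta = mesh.shift[alive_idx] * Lcur
    xi = mesh.X[i] + state.u[i]
    xj = mesh.X[j] + state.u[j]
    return xi, state.R[i], xj, state.R[j], Delta, i, j


def _spring_forces(springs: SpringSet, mesh: BeamMesh, state: MechanicalState):
    """Per-spring geometry and tension; returns (idx, dvec, l, f, uhat)."""
    idx = np.flatnonzero(springs.alive)
    if len(idx) == 0:
        return idx, None, None, None, None
    Lcur = mesh.box_lengths * state.stretch
    a = springs.particle[idx]
    b = springs.node[idx]
    pb = mesh.X[b] + state.u[b] + springs.shift[idx] * Lcur
    dvec = pb - state.p[a]
    l = np.linalg.norm(dvec, axis=1)
    ext = np.maximum(l - springs.l0[idx], 0.0)
    f = springs.k[idx] * ext
    uhat = dvec / np.maximum(l, 1e-12)[:, None]
    return idx, dvec, l, f, uhat


def assemble(
    mesh: BeamMesh,
    state: MechanicalState,
    springs: SpringSet | None = None,
    with_hessian: bool = True,
    with_gradient: bool = True,
    fd_step: float = 1e-6,
):
    """Total energy, gradient and (optionally) tangent of the system.

    DOF layout: ``[node translations (3N) | node rotations (3N) |
    particle translations (3P)]``.  Rotational gradient entries are
    spatial (left-trivialized); the corresponding update is
    ``R <- exp(dw) R``.
    """
    N = mesh.n_nodes
    P = len(state.p)
    ndof = 6 * N + 3 * P
    g = np.zeros(ndof)
    alive_idx = np.flatnonzero(mesh.alive)
    energy = 0.0
    rows, cols, vals = [], [], []

    if len(alive_idx):
        L0 = mesh.L0[alive_idx]
        gamma0 = mesh.gamma0[alive_idx]
        phi0 = mesh.phi0[alive_idx]
        t0 = gamma0 / np.linalg.norm(gamma0, axis=1, keepdims=True)
        EA, GAs = mesh.EA[alive_idx], mesh.GAs[alive_idx]
        GJ, EI = mesh.GJ[alive_idx], mesh.EI[alive_idx]
        xi, Ri, xj, Rj, Delta, inode, jnode = _gather_element_state(mesh, state, alive_idx)

        args = (Delta, L0, gamma0, phi0, t0, EA, GAs, GJ, EI)
        if not with_gradient and not with_hessian:
            e0, _, _ = _beam_energy_grad(xi, Ri, xj, Rj, *args, energy_only=True)
            if springs is not None and len(springs):
                idx, _, _, f, _ = _spring_forces(springs, mesh, state)
                if len(idx):
                    ext = f / springs.k[idx]
                    e0 = np.append(e0, 0.5 * springs.k[idx] * ext**2)
            return float(e0.sum()), None, None
        e0, g0, _ = _beam_energy_grad(xi, Ri, xj, Rj, *args)
        energy += e0.sum()

        dof_blocks = np.stack(
            [3 * inode, 3 * N + 3 * inode, 3 * jnode, 3 * N + 3 * jnode], axis=1
        )  # (E, 4) block starts
        dof_idx = (dof_blocks[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        np.add.at(g, dof_idx, g0)

        if with_hessian:
            E = len(alive_idx)
            H = np.empty((E, 12, 12))
            h = fd_step
            eye = np.eye(3)
            for k in range(12):
                xi_p, Ri_p, xj_p, Rj_p = xi, Ri, xj, Rj
                axis = k % 3
                if k < 3:
                    xi_p = xi + h * eye[axis]
                elif k < 6:
                    Rp = exp_so3(h * eye[axis])[None]
                    Ri_p = Rp @ Ri
                elif k < 9:
                    xj_p = xj + h * eye[axis]
                else:
                    Rp = exp_so3(h * eye[axis])[None]
                    Rj_p = Rp @ Rj
                _, gp, _ = _beam_energy_grad(xi_p, Ri_p, xj_p, Rj_p, *args)
                H[:, :, k] = (gp - g0) / h
            H = 0.5 * (H + np.swapaxes(H, 1, 2))
            rows.append(np.repeat(dof_idx, 12, axis=1).ravel())
            cols.append(np.tile(dof_idx, (1, 12)).ravel())
            vals.append(H.ravel())

    if springs is not None and len(springs):
        idx, dvec, l, f, uhat = _spring_forces(springs, mesh, state)
        if len(idx):
            ext = f / springs.k[idx]
            energy += float(0.5 * np.sum(springs.k[idx] * ext**2))
            a = springs.particle[idx]
            b = springs.node[idx]
            gb = f[:, None] * uhat  # dE/d(pb)
            pdof = 6 * N + 3 * a[:, None] + np.arange(3)[None, :]
            bdof = 3 * b[:, None] + np.arange(3)[None, :]
            np.add.at(g, bdof, gb)
            np.add.at(g, pdof, -gb)
            if with_hessian:
                taut = ext > 0
                kk = springs.k[idx]
                uu = uhat[:, :, None] * uhat[:, None, :]
                Hs = (
                    kk[:, None, None] * uu
                    + (kk * ext / np.maximum(l, 1e-12))[:, None, None]
                    * (np.eye(3)[None] - uu)
                )
                Hs[~taut] = 0.0
                dof2 = np.concatenate([bdof, pdof], axis=1)  # (S, 6)
                Hblock = np.empty((len(idx), 6, 6))
                Hblock[:, :3, :3] = Hs
                Hblock[:, 3:, 3:] = Hs
                Hblock[:, :3, 3:] = -Hs
                Hblock[:, 3:, :3] = -Hs
                rows.append(np.repeat(dof2, 6, axis=1).ravel())
                cols.append(np.tile(dof2, (1, 6)).ravel())
                vals.append(Hblock.ravel())

    if not with_hessian:
        return energy, g, None
    if rows:
        H = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof, ndof),
        ).tocsr()
    else:
        H = sp.csr_matrix((ndof, ndof))
    return energy, g, H


def apply_update(state: MechanicalState, dz: np.ndarray, N: int) -> None:
    """Apply Newton increment: additive on translations, multiplicative on triads."""
    state.u += dz[: 3 * N].reshape(-1, 3)
    dw = dz[3 * N : 6 * N].reshape(-1, 3)
    nz = np.einsum("ni,ni->n", dw, dw) > 0
    if np.any(nz):
        state.R[nz] = exp_so3(dw[nz]) @ state.R[nz]
    if len(state.p):
        state.p += dz[6 * N :].reshape(-1, 3)


def solve_equilibrium(
    mesh: BeamMesh,
    state: MechanicalState,
    springs: SpringSet | None = None,
    external_force: np.ndarray | None = None,
    fixed_dofs: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iterations: int = 60,
    max_rotation_increment: float = 0.5,
) -> MechanicalState:
    """Newton iteration to mechanical equilibrium (in-place on ``state``).

    ``external_force`` is a full DOF vector of applied loads (pN /
    pN·μm); ``fixed_dofs`` are clamped at their current values.  By
    default the three translations of node 0 are pinned to remove the
    rigid-translation null space of the periodic cell.  A Levenberg-style
    diagonal shift is added only when a step fails and is absent from
    the converged residual check.  Non-convergence sets
    ``state.converged = False`` (no exception).
    """
    N = mesh.n_nodes
    P = len(state.p)
    ndof = 6 * N + 3 * P
    f_ext = np.zeros(ndof) if external_force is None else external_force
    if fixed_dofs is None:
        fixed_dofs = np.arange(3)  # pin node-0 translations
    free = np.ones(ndof, bool)
    free[fixed_dofs] = False
    free_idx = np.flatnonzero(free)

    # Levenberg–Marquardt descent on the total potential Pi = E - f_ext . q.
    # With mu -> 0 this is plain Newton (quadratic near the minimum); on an
    # indefinite tangent (buckled fibers) mu grows until the step descends.
    # Rejected trials cost only an energy evaluation; mu carries over
    # between iterations so one factorization per iteration is typical.
    mu = 0.0
    work = 0.0  # accumulated external work f_ext . q
    energy, g, H = assemble(mesh, state, springs, with_hessian=True)
    for it in range(max_iterations):
        r = g - f_ext
        rn = np.linalg.norm(r[free_idx], np.inf)
        if rn <= tol:
            state.residual_norm = float(rn)
            state.converged = True
            state.n_iterations = it
            return state

        Hff = H[free_idx][:, free_idx]
        dref = np.abs(Hff.diagonal())
        marq = sp.diags(np.maximum(dref, 1e-6 * max(dref.max(), 1.0)))
        pi_cur = energy - work
        accepted = False
        trial_dz = None
        for _ in range(20):
            try:
                lu = spla.splu(
                    (Hff + mu * marq).tocsc(),
                    permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True, DiagPivotThresh=0.01),
                )
                dz_f = lu.solve(-r[free_idx])
            except Exception:
                dz_f = None
            if dz_f is None or not np.all(np.isfinite(dz_f)):
                mu = max(mu * 10.0, 1e-8)
                continue
            dz = np.zeros(ndof)
            dz[free_idx] = dz_f
            wmax = np.abs(dz[3 * N : 6 * N]).max() if N else 0.0
            if wmax > max_rotation_increment:
                dz *= max_rotation_increment / wmax
            trial = state.copy()
            apply_update(trial, dz, N)
            try:
                e_t, _, _ = assemble(mesh, trial, springs, with_hessian=False, with_gradient=False)
            except ValueError:  # rotation too large for the log map
                mu = max(mu * 10.0, 1e-8)
                continue
            work_t = work + float(f_ext @ dz)
            if (e_t - work_t) < pi_cur + 1e-12 * max(abs(pi_cur), 1.0):
                try:
                    _, g_t, H_t = assemble(mesh, trial, springs, with_hessian=True)
                except ValueError:  # FD perturbation crossed the chart limit
                    mu = max(mu * 10.0, 1e-8)
                    continue
                state.u, state.R, state.p = trial.u, trial.R, trial.p
                energy, work, g, H = e_t, work_t, g_t, H_t
                mu *= 0.25
                if mu < 1e-12:
                    mu = 0.0
                accepted = True
                break
            mu = max(mu * 10.0, 1e-8)
        if not accepted:
            break

    r = g - f_ext
    state.residual_norm = float(np.linalg.norm(r[free_idx], np.inf))
    state.converged = bool(state.residual_norm <= tol)
    state.n_iterations = max_iterations
    return state


def apply_box_stretch(
    mesh: BeamMesh, state: MechanicalState, stretch, affine_predictor: bool = True
) -> MechanicalState:
    """Set the box stretch and (optionally) move nodes to the affine guess.

    The affine increment ``u += (lambda_new - lambda_old) * X`` is the
    Newton predictor; the subsequent equilibrium solve relaxes the
    interior non-affinely.  Boundary-crossing elements are loaded
    automatically through their shift translations.
    """
    stretch = np.asarray(stretch, float).reshape(3)
    if np.any(stretch <= 0):
        raise ValueError("stretch factors must be positive")
    if affine_predictor:
        dlam = stretch - state.stretch
        state.u += dlam * mesh.X
        if len(state.p):
            state.p += dlam * state.p / np.maximum(state.stretch, 1e-12)
    state.stretch = stretch
    state.converged = False
    return state


#: fractional positions of the two periodic cut planes per axis; chosen
#: away from 0 and 1/2 so that mesh nodes are unlikely to sit exactly on
#: a cut
_CUT_FRACTIONS = (0.31, 0.79)


def _count_crossings(lo: np.ndarray, hi: np.ndarray, cut: float, L: float) -> np.ndarray:
    """Number of planes ``cut + k L`` inside the half-open span ``(lo, hi]``."""
    k1 = np.floor((lo - cut) / L) + 1.0
    k2 = np.floor((hi - cut) / L)
    return np.maximum(k2 - k1 + 1.0, 0.0)


def boundary_first_pk_stress(
    mesh: BeamMesh,
    state: MechanicalState,
    springs: SpringSet | None = None,
    time: float = 0.0,
) -> StressRecord:
    """First PK normal stress from fiber tractions across periodic cuts.

    For each axis the forces of all elements (and stress-fiber springs)
    whose unwrapped span crosses the cut plane are summed, with the
    crossing orientation as sign, and divided by the reference face
    area.  Two cuts per axis (at 0 and at L/2) are reported; their
    agreement is an equilibrium diagnostic.
    """
    L = mesh.box_lengths
    Lcur = L * state.stretch
    area = np.array([L[1] * L[2], L[0] * L[2], L[0] * L[1]])

    alive_idx = np.flatnonzero(mesh.alive)
    face = np.zeros((2, 3))
    if len(alive_idx):
        L0 = mesh.L0[alive_idx]
        gamma0 = mesh.gamma0[alive_idx]
        t0 = gamma0 / np.linalg.norm(gamma0, axis=1, keepdims=True)
        args = (
            mesh.shift[alive_idx] * Lcur,
            L0,
            gamma0,
            mesh.phi0[alive_idx],
            t0,
            mesh.EA[alive_idx],
            mesh.GAs[alive_idx],
            mesh.GJ[alive_idx],
            mesh.EI[alive_idx],
        )
        xi, Ri, xj, Rj, Delta, inode, jnode = _gather_element_state(mesh, state, alive_idx)
        _, _, nforce = _beam_energy_grad(xi, Ri, xj, Rj, *args)
        for ax in range(3):
            a = xi[:, ax]
            bb = xj[:, ax] + Delta[:, ax]
            for ci, frac in enumerate(_CUT_FRACTIONS):
                cut = frac * Lcur[ax]
                n_up = _count_crossings(np.minimum(a, bb), np.maximum(a, bb), cut, Lcur[ax])
                sgn = np.sign(bb - a)
                face[ci, ax] += np.sum(sgn * n_up * nforce[:, ax]) / area[ax]

    if springs is not None and len(springs):
        idx, dvec, l, f, uhat = _spring_forces(springs, mesh, state)
        if len(idx):
            pa = state.p[springs.particle[idx]]
            for ax in range(3):
                a = pa[:, ax]
                bb = a + dvec[:, ax]
                for ci, frac in enumerate(_CUT_FRACTIONS):
                    cut = frac * Lcur[ax]
                    n_up = _count_crossings(np.minimum(a, bb), np.maximum(a, bb), cut, Lcur[ax])
                    sgn = np.sign(bb - a)
                    face[ci, ax] += np.sum(sgn * n_up * f * uhat[:, ax]) / area[ax]

    return StressRecord(
        time=time,
        face_minus=face[0],
        face_plus=face[1],
        stretch=state.stretch.copy(),
        converged=state.converged,
    )


def add_crosslink_element(
    mesh: BeamMesh,
    state: MechanicalState,
    node_a: int,
    node_b: int,
    props: BeamProperties,
    min_length: float = 0.02,
) -> int:
    """Append a stress-free cross-link beam between two mesh nodes.

    The reference strains are recorded in the *current* configuration so
    the new element transmits no force at creation.  Returns the element id.
    """
    Lcur = mesh.box_lengths * state.stretch
    xa = mesh.X[node_a] + state.u[node_a]
    xb = mesh.X[node_b] + state.u[node_b]
    d0 = xb - xa
    shift = -np.round(d0 / Lcur)
    d = d0 + shift * Lcur
    L0 = max(float(np.linalg.norm(d)), min_length)
    Ra = state.R[node_a]
    Rb = state.R[node_b]
    phi = log_so3((Ra.T @ Rb)[None])[0]
    Rm = Ra @ exp_so3(0.5 * phi[None])[0]
    gamma0 = Rm.T @ d / L0
    if np.linalg.norm(gamma0) < 1e-9:  # coincident nodes: use an arbitrary axis
        gamma0 = np.array([1.0, 0.0, 0.0])
    ids = mesh.append_elements(
        np.array([[node_a, node_b]]),
        shift[None],
        np.array([L0]),
        gamma0[None],
        phi[None],
        props,
        np.array([-1]),
    )
    return int(ids[0])


def element_axial_force(mesh: BeamMesh, state: MechanicalState, element_ids: np.ndarray) -> np.ndarray:
    """Axial (tension-positive) force (pN) carried by the given elements."""
    element_ids = np.atleast_1d(element_ids)
    L0 = mesh.L0[element_ids]
    gamma0 = mesh.gamma0[element_ids]
    t0 = gamma0 / np.linalg.norm(gamma0, axis=1, keepdims=True)
    args = (
        mesh.shift[element_ids] * (mesh.box_lengths * state.stretch),
        L0,
        gamma0,
        mesh.phi0[element_ids],
        t0,
        mesh.EA[element_ids],
        mesh.GAs[element_ids],
        mesh.GJ[element_ids],
        mesh.EI[element_ids],
    )
    xi, Ri, xj, Rj, Delta, *_ = _gather_element_state(mesh, state, element_ids)
    _, _, n = _beam_energy_grad(xi, Ri, xj, Rj, *args)
    d = xj + Delta - xi
    dhat = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-12)
    return np.einsum("ei,ei->e", n, dhat)


def young_modulus_from_test(strain: np.ndarray, stress: np.ndarray) -> float:
    """Least-squares slope (Pa) of a stress–strain record.

    Ordinary least squares with intercept over the supplied points
    (small-strain region); raises on fewer than 3 points or degenerate
    (constant) strain.
    """
    strain = np.asarray(strain, float)
    stress = np.asarray(stress, float)
    if strain.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(strain) <= 0:
        raise ValueError("degenerate strain record")
    A = np.vstack([strain, np.ones_like(strain)]).T
    slope, _ = np.linalg.lstsq(A, stress, rcond=None)[0]
    return float(slope)
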