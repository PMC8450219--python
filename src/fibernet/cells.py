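"""Contractile cell agents with molecular-clutch focal adhesions.

A cell is a point particle that can form focal adhesions (FAs) on
integrin binding spots of nearby fibers — spots inside a spherical shell
``R ± dR`` around the cell center.  Each FA bundles 50 integrin
clusters; each cluster holds up to 20 integrins bound in parallel and is
pulled by its own actin stress fiber, modeled as a tension-only spring
whose rest length shortens at the constant rate ``c_dot`` (actomyosin
contraction).  The force on one integrin is the stress-fiber force
divided by the number of currently bound integrins in its cluster, and
integrins unbind with the catch–slip off-rate

    k_off(F) = a1 exp(-((F-b1)/c1)^2) + a2 exp(-((F-b2)/c2)^2)

which makes bonds most stable near 30 pN.  A cluster whose bound count
reaches zero dissolves (its stress fiber with it) and may re-form with a
fresh, uncontracted stress fiber; an FA whose clusters are all dissolved
at once is removed.  Cell centers are mechanical degrees of freedom, so
cell and matrix pull on each other in a genuine two-way coupling.

The catch–slip parameter defaults are a fit of the double-Gaussian form
to published single-integrin lifetime data with the stability optimum
placed at ~30 pN; all constants are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import BeamMesh, MechanicalState, SpringSet
from .periodic import PeriodicBox


@dataclass
class CatchSlipParams:
    """Double-Gaussian catch–slip off-rate parameters (rates 1/s, forces pN)."""

    a1: float = 1.8
    b1: float = -10.0
    c1: float = 18.0
    a2: float = 0.7
    b2: float = 90.0
    c2: float = 35.0
    F_min: float = 5.0  # low-force clamp: F below this is evaluated at F_min

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("Gaussian widths must be positive")


def catch_slip_off_rate(F: float | np.ndarray, p: CatchSlipParams) -> float | np.ndarray:
    """Integrin catch–slip off-rate (1/s) with low-force clamp."""
    F = np.maximum(np.asarray(F, float), p.F_min)
    out = p.a1 * np.exp(-(((F - p.b1) / p.c1) ** 2)) + p.a2 * np.exp(-(((F - p.b2) / p.c2) ** 2))
    return float(out) if out.ndim == 0 else out


def integrin_force(F_SF: float | np.ndarray, n_bonded: int | np.ndarray) -> float | np.ndarray:
    """Equal-sharing force per bound integrin: ``F_SF / N_bonded``."""
    n = np.asarray(n_bonded)
    if np.any(n < 1):
        raise ValueError("n_bonded must be >= 1 (dissolve the cluster instead)")
    out = np.asarray(F_SF, float) / n
    return float(out) if out.ndim == 0 else out


@dataclass
class CellParams:
    """Geometry, adhesion and contractility constants of a cell agent."""

    radius: float = 15.0  # μm
    shell_halfwidth: float = 2.0  # μm
    max_adhesions: int = 65
    clusters_per_adhesion: int = 50
    integrins_per_cluster: int = 20
    k_on_cf: float = 0.5  # 1/s, integrin (cell-fiber) on-rate
    k_sf: float = 25.0  # pN/μm, stress-fiber spring stiffness
    contraction_rate: float = 0.1  # μm/s, rest-length shortening
    reform_delay: float = 0.0  # s, dead-cluster re-formation delay
    catch_slip: CatchSlipParams = field(default_factory=CatchSlipParams)


@dataclass
class IntegrinCluster:
    spring_id: int  # row in the shared SpringSet
    n_bonded: int
    alive: bool = True
    died_at: float = -np.inf  # time of last dissolution (for reform_delay)


@dataclass
class FocalAdhesion:
    anchor_spot: int  # index into the integrin spot table
    anchor_node: int  # mesh node
    clusters: list[IntegrinCluster]
    alive: bool = True


@dataclass
class CellAgent:
    particle: int  # particle index in the mechanical state
    adhesions: list[FocalAdhesion] = field(default_factory=list)

    @property
    def n_adhesions(self) -> int:
        return sum(1 for fa in self.adhesions if fa.alive)


def cell_count_for_density(density_per_ml: float, box: PeriodicBox) -> int:
    """Cells per RVE: ``ceil(density * V)`` with V in ml (1 ml = 1e12 μm³)."""
    if density_per_ml < 0:
        raise ValueError("cell density must be non-negative")
    return int(np.ceil(density_per_ml * box.volume * 1e-12))


def seed_cells(
    density_per_ml: float,
    box: PeriodicBox,
    rng: np.random.Generator,
    radius: float = 15.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform random non-overlapping cell centers (periodic metric).

    Centers keep a minimum pairwise distance of one cell diameter;
    raises if the box cannot host the required count.
    """
    n = cell_count_for_density(density_per_ml, box)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"could not place {n} non-overlapping cells in the box")
        c = rng.uniform(0, 1, 3) * box.lengths
        if all(box.distance(c, o) >= 2 * radius for o in centers):
            centers.append(c)
    return np.array(centers).reshape(n, 3)


@dataclass
class IntegrinSpots:
    """Integrin binding sites on fibers (beam-mesh nodes) with occupancy."""

    nodes: np.ndarray
    occupied: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.occupied is None:
            self.occupied = np.zeros(len(self.nodes), bool)

    @classmethod
    def from_mesh(cls, mesh: BeamMesh) -> "IntegrinSpots":
        return cls(np.arange(mesh.n_nodes))


def eligible_adhesion_sites(
    center: np.ndarray,
    spots: IntegrinSpots,
    mesh: BeamMesh,
    state: MechanicalState,
    params: CellParams,
) -> np.ndarray:
    """Indices of unoccupied spots within ``R ± dR`` of the cell center."""
    box = PeriodicBox(mesh.box_lengths, state.stretch)
    pos = mesh.X[spots.nodes] + state.u[spots.nodes]
    d = box.distance(center, pos)
    lo = params.radius - params.shell_halfwidth
    hi = params.radius + params.shell_halfwidth
    return np.flatnonzero((d >= lo) & (d <= hi) & ~spots.occupied)


@dataclass
class CellSystem:
    """All cells plus their shared stress-fiber springs and spot table."""

    cells: list[CellAgent]
    spots: IntegrinSpots
    springs: SpringSet
    params: CellParams = field(default_factory=CellParams)
    k_on_override: float | None = None  # set to 0.0 to sever cell-ECM coupling
    telemetry: list[dict] = field(default_factory=list)

    @property
    def k_on(self) -> float:
        return self.params.k_on_cf if self.k_on_override is None else self.k_on_override

    def total_adhesions(self) -> int:
        return sum(c.n_adhesions for c in self.cells)

    def total_bound_integrins(self) -> int:
        return sum(
            cl.n_bonded
            for c in self.cells
            for fa in c.adhesions
            if fa.alive
            for cl in fa.clusters
            if cl.alive
        )


def build_cell_system(
    centers: np.ndarray,
    mesh: BeamMesh,
    params: CellParams | None = None,
) -> tuple[CellSystem, np.ndarray]:
    """Create the cell system; returns it plus the particle array for the state."""
    params = params or CellParams()
    cells = [CellAgent(particle=i) for i in range(len(centers))]
    return (
        CellSystem(cells, IntegrinSpots.from_mesh(mesh), SpringSet(), params),
        np.asarray(centers, float).reshape(-1, 3),
    )


def _event_prob(k: float, dt: float) -> float:
    return -np.expm1(-k * dt)


def _spring_geometry(sys: CellSystem, mesh: BeamMesh, state: MechanicalState, sid: int):
    Lcur = mesh.box_lengths * state.stretch
    node = sys.springs.node[sid]
    pb = mesh.X[node] + state.u[node] + sys.springs.shift[sid] * Lcur
    pa = state.p[sys.springs.particle[sid]]
    l = float(np.linalg.norm(pb - pa))
    return l


def _new_cluster(
    sys: CellSystem, mesh: BeamMesh, state: MechanicalState, cell: CellAgent, anchor_node: int
) -> IntegrinCluster:
    """Fresh cluster: uncontracted stress fiber (zero force), one bound integrin."""
    Lcur = mesh.box_lengths * state.stretch
    pa = state.p[cell.particle]
    pb_raw = mesh.X[anchor_node] + state.u[anchor_node]
    shift = -np.round((pb_raw - pa) / Lcur)
    l = float(np.linalg.norm(pb_raw + shift * Lcur - pa))
    sid = sys.springs.add(cell.particle, anchor_node, shift, sys.params.k_sf, l)
    return IntegrinCluster(spring_id=sid, n_bonded=1)


def form_adhesions(
    sys: CellSystem,
    mesh: BeamMesh,
    state: MechanicalState,
    dt: float,
    rng: np.random.Generator,
) -> int:
    """Poisson-process FA formation on eligible sites of every cell.

    Each eligible spot draws ``p = 1 - exp(-k_on_cf dt)``; successful
    spots become focal adhesions (up to the per-cell cap) carrying a full
    complement of fresh clusters.
    """
    p_on = _event_prob(sys.k_on, dt)
    if p_on <= 0:
        return 0
    n_new = 0
    for cell in sys.cells:
        room = sys.params.max_adhesions - cell.n_adhesions
        if room <= 0:
            continue
        sites = eligible_adhesion_sites(state.p[cell.particle], sys.spots, mesh, state, sys.params)
        if len(sites) == 0:
            continue
        hits = sites[rng.random(len(sites)) < p_on]
        rng.shuffle(hits)
        for spot in hits[:room]:
            if sys.spots.occupied[spot]:
                continue
            node = int(sys.spots.nodes[spot])
            clusters = [
                _new_cluster(sys, mesh, state, cell, node)
                for _ in range(sys.params.clusters_per_adhesion)
            ]
            cell.adhesions.append(FocalAdhesion(int(spot), node, clusters))
            sys.spots.occupied[spot] = True
            n_new += 1
    return n_new


def contract_stress_fibers(sys: CellSystem, dt: float) -> None:
    """Shorten the rest length of every live stress fiber by ``c_dot * dt``."""
    rate = sys.params.contraction_rate
    ids = [
        cl.spring_id
        for c in sys.cells
        for fa in c.adhesions
        if fa.alive
        for cl in fa.clusters
        if cl.alive
    ]
    if ids:
        ids = np.asarray(ids)
        sys.springs.l0[ids] = np.maximum(sys.springs.l0[ids] - rate * dt, 0.0)


def step_clutches(
    sys: CellSystem,
    mesh: BeamMesh,
    state: MechanicalState,
    dt: float,
    rng: np.random.Generator,
    time: float = 0.0,
) -> dict:
    """One stochastic step of integrin binding/unbinding for all clusters.

    Per cluster: each bound integrin unbinds with the catch–slip
    probability at the current per-integrin force; each free integrin
    binds with the ``k_on_cf`` probability.  Clusters at zero bound
    integrins dissolve (stress fiber removed) and become immediately
    eligible to re-form on a fresh stress fiber; adhesions whose clusters
    are all dead are removed and their spot freed.
    """
    p = sys.params
    p_on = _event_prob(sys.k_on, dt)
    n_unbind = n_bind = n_cluster_died = n_fa_died = 0

    for cell in sys.cells:
        for fa in cell.adhesions:
            if not fa.alive:
                continue
            for cl in fa.clusters:
                if not cl.alive:
                    # dead cluster may re-form on a fresh stress fiber
                    if time < cl.died_at + p.reform_delay:
                        continue
                    if p_on > 0 and rng.random() < p_on:
                        new = _new_cluster(sys, mesh, state, cell, fa.anchor_node)
                        cl.spring_id = new.spring_id
                        cl.n_bonded = 1
                        cl.alive = True
                        n_bind += 1
                    continue
                l = _spring_geometry(sys, mesh, state, cl.spring_id)
                F_SF = p.k_sf * max(l - sys.springs.l0[cl.spring_id], 0.0)
                F_i = F_SF / cl.n_bonded
                p_off = _event_prob(catch_slip_off_rate(F_i, p.catch_slip), dt)
                lost = int(rng.binomial(cl.n_bonded, p_off))
                gained = int(rng.binomial(p.integrins_per_cluster - cl.n_bonded, p_on))
                cl.n_bonded += gained - lost
                n_unbind += lost
                n_bind += gained
                if cl.n_bonded <= 0:
                    cl.n_bonded = 0
                    cl.alive = False
                    cl.died_at = time
                    sys.springs.alive[cl.spring_id] = False
                    n_cluster_died += 1
            if not any(cl.alive for cl in fa.clusters):
                fa.alive = False
                sys.spots.occupied[fa.anchor_spot] = False
                for cl in fa.clusters:
                    sys.springs.alive[cl.spring_id] = False
                n_fa_died += 1
        cell.adhesions = [fa for fa in cell.adhesions if fa.alive]

    stats = {
        "time": time,
        "bind": n_bind,
        "unbind": n_unbind,
        "clusters_died": n_cluster_died,
        "adhesions_died": n_fa_died,
        "adhesions": sys.total_adhesions(),
        "bound_integrins": sys.total_bound_integrins(),
    }
    sys.telemetry.append(stats)
    return stats


def sever_all_cell_bonds(sys: CellSystem) -> None:
    """Set the cell–fiber on-rate to zero and dissolve every existing bond.

    Used by the residual-matrix-tension protocol to eliminate active
    cellular forces instantaneously.
    """
    sys.k_on_override = 0.0
    for cell in sys.cells:
        for fa in cell.adhesions:
            fa.alive = False
            sys.spots.occupied[fa.anchor_spot] = False
            for cl in fa.clusters:
                cl.alive = False
                sys.springs.alive[cl.spring_id] = False
        cell.adhesions = []
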